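"""Reaction-network parsing and chemical reaction network theory (CRNT) structure.

A network is a list of species and a list of directed reactions between
*complexes* (multisets of species).  From these we build the standard CRNT
objects: the molecularity matrix ``Y`` (species x complexes), the symbolic
kinetic matrix ``A`` (complexes x complexes, entries are rate-constant
symbols), the stoichiometric matrix ``S`` (species x reactions), and the
mass-action monomial vector ``psi`` with ``psi_j(c) = prod_i c_i**Y[i, j]``.
The mass-action ODE right-hand side is then ``c' = Y A psi(c)``.

Linkage classes (connected components of the undirected complex graph) and
terminal strong linkage classes (strongly connected components with no
outgoing edge) classify the network as uniterminal or biterminal; the
bistability search downstream does not depend on this classification, but it
is reported because classical CRNT results do.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import sympy as sp
from lxml import etree

__all__ = [
    "Complex",
    "Reaction",
    "ReactionNetwork",
    "CRNTMatrices",
    "LinkageClassification",
    "NetworkParseError",
    "NetworkValidationError",
    "parse_network",
    "parse_reaction_text",
    "parse_sbml",
    "build_crnt_matrices",
    "classify_linkage",
]


class NetworkParseError(ValueError):
    """Raised when an input file or reaction string cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a parsed network violates a structural invariant."""


@dataclass(frozen=True)
class Complex:
    """A multiset of species with integer molecularities.

    ``composition`` is stored as a tuple of ``(species, molecularity)`` pairs
    sorted by species name, so that equality is multiset equality
    ("A+B" == "B+A").  The empty tuple is the zero complex.
    """

    composition: tuple[tuple[str, int], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "Complex":
        items = tuple(sorted((s, int(m)) for s, m in mapping.items() if m))
        if any(m < 0 for _, m in items):
            raise NetworkValidationError("negative molecularity in complex")
        return cls(items)

    def molecularity(self, species: str) -> int:
        for s, m in self.composition:
            if s == species:
                return m
        return 0

    @property
    def total_molecularity(self) -> int:
        return sum(m for _, m in self.composition)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.composition)

    def label(self) -> str:
        if not self.composition:
            return "0"
        return "+".join(
            (f"{m}{s}" if m != 1 else s) for s, m in self.composition
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label()


@dataclass(frozen=True)
class Reaction:
    """A directed reaction from one complex to another with a rate symbol."""

    source: int
    target: int
    rate_symbol: sp.Symbol


@dataclass
class ReactionNetwork:
    """Parsed reaction network with stable species/reaction/complex ordering."""

    species: list[str]
    complexes: list[Complex]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise NetworkValidationError("duplicate species identifiers")
        if not self.species:
            raise NetworkValidationError("network has no species")
        if not self.reactions:
            raise NetworkValidationError("network has no reactions")
        if len(self.complexes) < 2:
            raise NetworkValidationError("network has fewer than two complexes")
        for r in self.reactions:
            if not (0 <= r.source < len(self.complexes)):
                raise NetworkValidationError("reaction source complex missing")
            if not (0 <= r.target < len(self.complexes)):
                raise NetworkValidationError("reaction target complex missing")
            if r.source == r.target:
                raise NetworkValidationError("reaction source equals target")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @property
    def concentration_symbols(self) -> tuple[sp.Symbol, ...]:
        """Positional concentration symbols c1..cN (c_i is species i+1)."""
        return sp.symbols(f"c1:{self.n_species + 1}", positive=True)

    @property
    def rate_symbols(self) -> tuple[sp.Symbol, ...]:
        return tuple(r.rate_symbol for r in self.reactions)

    def species_symbol(self, name: str) -> sp.Symbol:
        return self.concentration_symbols[self.species.index(name)]


# ---------------------------------------------------------------------------
# Parsing: plain-text reaction DSL
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(\d+)?\s*([A-Za-z_][A-Za-z0-9_*']*)$")


def _parse_side(side: str, lineno: int) -> dict[str, int]:
    side = side.strip()
    if side in ("", "0"):
        return {}
    comp: dict[str, int] = {}
    for term in side.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise NetworkParseError(
                f"line {lineno}: cannot parse species term {term!r}"
            )
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        comp[name] = comp.get(name, 0) + coeff
    return comp


def parse_reaction_text(
    text: str, species_order: Sequence[str] | None = None
) -> ReactionNetwork:
    """Parse the plain-text reaction DSL.

    One reaction per line (or ';'-separated), "+"-separated complexes,
    "->" irreversible, "<->" reversible (expanded forward-then-backward),
    optional integer stoichiometric prefixes ("2A"), "#" comments.

    ``species_order`` optionally fixes the species indexing; by default
    species are ordered by first appearance.
    """
    arrows: list[tuple[dict[str, int], dict[str, int], bool, int]] = []
    lineno = 0
    for rawline in text.splitlines():
        lineno += 1
        line = rawline.split("#", 1)[0].strip()
        if not line:
            continue
        for stmt in line.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            if "<->" in stmt:
                lhs, rhs = stmt.split("<->", 1)
                reversible = True
            elif "->" in stmt:
                lhs, rhs = stmt.split("->", 1)
                reversible = False
            else:
                raise NetworkParseError(
                    f"line {lineno}: no reaction arrow in {stmt!r}"
                )
            src = _parse_side(lhs, lineno)
            tgt = _parse_side(rhs, lineno)
            if not src and not tgt:
                raise NetworkValidationError(
                    f"line {lineno}: reaction with empty source and target"
                )
            arrows.append((src, tgt, reversible, lineno))

    if not arrows:
        raise NetworkParseError("no reactions found in input")

    # species ordering: by first appearance unless fixed by the caller
    seen: list[str] = []
    for src, tgt, _, _ in arrows:
        for name in list(src) + list(tgt):
            if name not in seen:
                seen.append(name)
    if species_order is not None:
        missing = [s for s in seen if s not in species_order]
        if missing:
            raise NetworkValidationError(
                f"species_order is missing species {missing}"
            )
        species = [s for s in species_order if s in seen]
    else:
        species = seen

    complexes: list[Complex] = []

    def complex_index(comp: Mapping[str, int]) -> int:
        cx = Complex.from_mapping(comp)
        try:
            return complexes.index(cx)
        except ValueError:
            complexes.append(cx)
            return len(complexes) - 1

    directed: list[tuple[int, int]] = []
    for src, tgt, reversible, _ in arrows:
        i, j = complex_index(src), complex_index(tgt)
        directed.append((i, j))
        if reversible:
            directed.append((j, i))

    reactions = [
        Reaction(i, j, sp.Symbol(f"k{n + 1}", positive=True))
        for n, (i, j) in enumerate(directed)
    ]
    return ReactionNetwork(species=species, complexes=complexes, reactions=reactions)


# ---------------------------------------------------------------------------
# Parsing: SBML Level 3 core subset
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def parse_sbml(source: str | bytes | io.IOBase) -> ReactionNetwork:
    """Read an SBML Level 3 core document (subset).

    Only species identifiers and reactions (reactants, products, the
    ``reversible`` flag) are used; kinetic laws, compartments, and
    boundary/constant flags are ignored — mass action is imposed from
    stoichiometry alone.  Boundary species trigger a warning.  Reversible
    reactions expand into forward-then-backward irreversible reactions.
    """
    try:
        if isinstance(source, bytes):
            tree = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            tree = etree.fromstring(source.encode())
        else:
            tree = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise NetworkParseError(f"malformed SBML: {exc}") from exc

    species: list[str] = []
    for el in tree.iter():
        if _local(el.tag) == "species":
            sid = el.get("id")
            if sid is None:
                raise NetworkParseError(
                    f"species element without id at line {el.sourceline}"
                )
            if sid in species:
                raise NetworkValidationError(f"duplicate species id {sid!r}")
            species.append(sid)
            if el.get("boundaryCondition", "false") == "true":
                warnings.warn(
                    f"species {sid!r} is a boundary species; treated as dynamic",
                    stacklevel=2,
                )
    if not species:
        raise NetworkParseError("SBML document lists no species")

    complexes: list[Complex] = []

    def complex_index(comp: Mapping[str, int]) -> int:
        cx = Complex.from_mapping(comp)
        try:
            return complexes.index(cx)
        except ValueError:
            complexes.append(cx)
            return len(complexes) - 1

    def read_refs(parent: etree._Element, kind: str) -> dict[str, int]:
        comp: dict[str, int] = {}
        for lst in parent:
            if _local(lst.tag) != kind:
                continue
            for ref in lst:
                if _local(ref.tag) != "speciesReference":
                    continue
                sid = ref.get("species")
                if sid is None or sid not in species:
                    raise NetworkParseError(
                        f"unknown species reference at line {ref.sourceline}"
                    )
                stoich = ref.get("stoichiometry", "1")
                value = Fraction(stoich)
                if value.denominator != 1 or value < 0:
                    raise NetworkParseError(
                        f"non-integer stoichiometry {stoich!r} "
                        f"at line {ref.sourceline}"
                    )
                comp[sid] = comp.get(sid, 0) + int(value)
        return comp

    directed: list[tuple[int, int]] = []
    for el in tree.iter():
        if _local(el.tag) != "reaction":
            continue
        src = read_refs(el, "listOfReactants")
        tgt = read_refs(el, "listOfProducts")
        if not src and not tgt:
            raise NetworkValidationError(
                f"reaction {el.get('id')!r} has empty source and target"
            )
        i, j = complex_index(src), complex_index(tgt)
        directed.append((i, j))
        if el.get("reversible", "true") == "true":
            directed.append((j, i))
    if not directed:
        raise NetworkParseError("SBML document lists no reactions")

    used = [s for s in species if any(cx.molecularity(s) for cx in complexes)]
    reactions = [
        Reaction(i, j, sp.Symbol(f"k{n + 1}", positive=True))
        for n, (i, j) in enumerate(directed)
    ]
    return ReactionNetwork(species=used, complexes=complexes, reactions=reactions)


def parse_network(
    source: str, species_order: Sequence[str] | None = None
) -> ReactionNetwork:
    """Parse either an SBML document/path or reaction-list text."""
    stripped = source.lstrip()
    if stripped.startswith("<"):
        return parse_sbml(source)
    if stripped.endswith(".xml") or stripped.endswith(".sbml"):
        return parse_sbml(source)
    return parse_reaction_text(source, species_order=species_order)


# ---------------------------------------------------------------------------
# CRNT matrices
# ---------------------------------------------------------------------------

@dataclass
class CRNTMatrices:
    """The CRNT matrix bundle for a network.

    ``Y`` is N x M (molecularities), ``A`` is M x M symbolic in the rate
    constants with zero column sums, ``S`` is N x R with column j equal to
    ``Y[:, target_j] - Y[:, source_j]``, and ``psi`` holds the mass-action
    monomials.  ``s = rank(S)`` is computed exactly over the rationals;
    ``lam = N - s`` is the number of conservation laws.
    """

    network: ReactionNetwork
    Y: sp.ImmutableMatrix
    A: sp.ImmutableMatrix
    S: sp.ImmutableMatrix
    psi: sp.ImmutableMatrix
    psi_exponents: tuple[tuple[int, ...], ...]
    s: int
    lam: int

    def rate_vector(self) -> sp.Matrix:
        """Per-reaction mass-action rates k_i * prod_j c_j**Y[j, source_i]."""
        net = self.network
        c = net.concentration_symbols
        rates = []
        for r in net.reactions:
            mono = sp.Integer(1)
            for i in range(net.n_species):
                e = self.Y[i, r.source]
                if e:
                    mono *= c[i] ** e
            rates.append(r.rate_symbol * mono)
        return sp.Matrix(rates)


def build_crnt_matrices(net: ReactionNetwork) -> CRNTMatrices:
    N, M, R = net.n_species, net.n_complexes, net.n_reactions
    c = net.concentration_symbols

    Y = sp.zeros(N, M)
    for j, cx in enumerate(net.complexes):
        for i, name in enumerate(net.species):
            Y[i, j] = cx.molecularity(name)

    A = sp.zeros(M, M)
    for r in net.reactions:
        A[r.target, r.source] += r.rate_symbol
        A[r.source, r.source] -= r.rate_symbol

    S = sp.zeros(N, R)
    for j, r in enumerate(net.reactions):
        for i in range(N):
            S[i, j] = Y[i, r.target] - Y[i, r.source]

    psi = sp.Matrix(
        [
            sp.prod([c[i] ** Y[i, j] for i in range(N)], start=sp.Integer(1))
            for j in range(M)
        ]
    )
    exponents = tuple(tuple(int(Y[i, j]) for i in range(N)) for j in range(M))

    s = S.rank()  # exact rational arithmetic on an integer matrix
    return CRNTMatrices(
        network=net,
        Y=sp.ImmutableMatrix(Y),
        A=sp.ImmutableMatrix(A),
        S=sp.ImmutableMatrix(S),
        psi=sp.ImmutableMatrix(psi),
        psi_exponents=exponents,
        s=s,
        lam=N - s,
    )


# ---------------------------------------------------------------------------
# Linkage classification
# ---------------------------------------------------------------------------

@dataclass
class LinkageClassification:
    """Partition of complexes into linkage classes and their terminal SLCs."""

    linkage_classes: list[frozenset[int]]
    terminal_sl_classes: list[list[frozenset[int]]]
    is_uniterminal: bool

    def to_json(self, net: ReactionNetwork | None = None) -> str:
        def names(group: Iterable[int]) -> list[str]:
            if net is None:
                return sorted(str(i) for i in group)
            return sorted(net.complexes[i].label() for i in group)

        payload = {
            "linkage_classes": [names(lc) for lc in self.linkage_classes],
            "terminal_strong_linkage_classes": [
                [names(t) for t in terms] for terms in self.terminal_sl_classes
            ],
            "is_uniterminal": self.is_uniterminal,
        }
        return json.dumps(payload, indent=2)


def classify_linkage(net: ReactionNetwork) -> LinkageClassification:
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n_complexes))
    g.add_edges_from((r.source, r.target) for r in net.reactions)

    linkage = [
        frozenset(comp) for comp in nx.connected_components(g.to_undirected())
    ]
    linkage.sort(key=min)

    condensation = nx.condensation(g)
    terminal_sccs = [
        frozenset(condensation.nodes[n]["members"])
        for n in condensation.nodes
        if condensation.out_degree(n) == 0
    ]

    per_class: list[list[frozenset[int]]] = []
    for lc in linkage:
        terms = sorted((t for t in terminal_sccs if t <= lc), key=min)
        per_class.append(terms)

    uniterminal = all(len(t) == 1 for t in per_class)
    return LinkageClassification(
        linkage_classes=linkage,
        terminal_sl_classes=per_class,
        is_uniterminal=uniterminal,
    )
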