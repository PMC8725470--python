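"""Random mass-action networks with guaranteed conservation laws.

Species are built from a fixed pool of conserved moieties; reactions only
recombine moieties (binding, unbinding, isomerization), so every moiety
count is a conservation law by construction.  Used by the property-test
suite to exercise the conservation-law and parametrization machinery on
inputs with known structure.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

from .network import Complex, NetworkValidationError, Reaction, ReactionNetwork

__all__ = ["generate_random_network", "moiety_matrix"]


def _compositions(n_species: int, n_moieties: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Moiety composition vectors: the first n_moieties species are the free
    moieties themselves; the rest are random small combinations."""
    comps: list[tuple[int, ...]] = []
    for i in range(n_moieties):
        e = [0] * n_moieties
        e[i] = 1
        comps.append(tuple(e))
    while len(comps) < n_species:
        # bias towards compositions that collide with existing ones so that
        # isomerizations (X -> Y) and bindings (X + Y -> Z) are plentiful
        if n_moieties == 2 and rng.random() < 0.5:
            comps.append((1, 1))
        elif rng.random() < 0.4:
            comps.append(comps[int(rng.integers(0, len(comps)))])
        else:
            total = int(rng.integers(1, 4))
            vec = [0] * n_moieties
            for _ in range(total):
                vec[int(rng.integers(0, n_moieties))] += 1
            comps.append(tuple(vec))
    return comps


def generate_random_network(
    n_species: int,
    n_reactions: int,
    max_molecularity: int = 2,
    seed: int = 0,
) -> ReactionNetwork:
    """Generate a seeded random network whose reactions conserve moieties.

    Guarantees at least one conservation law (lam >= 1).  Raises if the
    requested size cannot be realized.
    """
    if n_species < 2:
        raise NetworkValidationError("n_species must be >= 2")
    if n_reactions < 1:
        raise NetworkValidationError("n_reactions must be >= 1")
    rng = np.random.default_rng(seed)
    n_moieties = 2 if n_species >= 3 else 1
    comps = _compositions(n_species, n_moieties, rng)
    names = [f"X{i+1}" for i in range(n_species)]

    # candidate complexes: single species, doubled species, and pairs
    candidates: list[dict[str, int]] = []
    for i in range(n_species):
        candidates.append({names[i]: 1})
        if max_molecularity >= 2:
            candidates.append({names[i]: 2})
            for j in range(i, n_species):
                if i != j:
                    candidates.append({names[i]: 1, names[j]: 1})

    def comp_total(c: dict[str, int]) -> tuple[int, ...]:
        tot = np.zeros(n_moieties, dtype=int)
        for nm, m in c.items():
            tot += m * np.array(comps[names.index(nm)])
        return tuple(tot)

    # group complexes by total moiety content; reactions stay inside groups
    groups: dict[tuple[int, ...], list[int]] = {}
    for idx, c in enumerate(candidates):
        groups.setdefault(comp_total(c), []).append(idx)
    viable = [g for g in groups.values() if len(g) >= 2]
    if not viable:
        raise NetworkValidationError(
            "cannot build conserved reactions for the requested sizes"
        )

    edges: list[tuple[int, int]] = []
    attempts = 0
    while len(edges) < n_reactions and attempts < 200 * n_reactions:
        attempts += 1
        group = viable[int(rng.integers(0, len(viable)))]
        i, j = rng.choice(group, size=2, replace=False)
        edge = (int(i), int(j))
        if edge not in edges:
            edges.append(edge)
    if len(edges) < n_reactions:
        raise NetworkValidationError(
            f"could only place {len(edges)} of {n_reactions} conserved reactions"
        )

    used_candidates = sorted({i for e in edges for i in e})
    remap = {old: new for new, old in enumerate(used_candidates)}
    complexes = [Complex.from_mapping(candidates[i]) for i in used_candidates]
    used_species = [
        nm for nm in names if any(cx.molecularity(nm) for cx in complexes)
    ]
    reactions = [
        Reaction(remap[a], remap[b], sp.Symbol(f"k{n+1}", positive=True))
        for n, (a, b) in enumerate(edges)
    ]
    return ReactionNetwork(
        species=used_species, complexes=complexes, reactions=reactions
    )


def moiety_matrix(net: ReactionNetwork, seed: int, n_species: int) -> sp.Matrix:
    """Reconstruct the generator's moiety composition matrix for a network
    produced by :func:`generate_random_network` with the same arguments.

    Columns are conservation-law candidates: S.T * moiety_matrix == 0.
    """
    rng = np.random.default_rng(seed)
    n_moieties = 2 if n_species >= 3 else 1
    comps = _compositions(n_species, n_moieties, rng)
    names = [f"X{i+1}" for i in range(n_species)]
    rows = [comps[names.index(s)] for s in net.species]
    return sp.Matrix(rows)
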