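"""Full mass-action ODE system and reduction to an independent subsystem.

With lam conservation laws, only ``s = N - lam`` of the species ODEs are
linearly independent.  Given a response species (the readout) and a signal
(one conservation total, used as the bifurcation parameter), one species per
conservation law is eliminated — never the response — by substituting its
law-derived expression, leaving ``s`` ODEs ``F(ç, signal, k)`` in the
independent concentrations ç.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import cached_property

import sympy as sp

from .conservation import ConservationBasis
from .network import CRNTMatrices, ReactionNetwork

__all__ = [
    "IndependentSystem",
    "ReductionError",
    "full_odes",
    "select_independent_odes",
    "reduced_jacobian",
]


class ReductionError(ValueError):
    """No admissible dependent-species elimination exists."""


def full_odes(matrices: CRNTMatrices) -> sp.Matrix:
    """Per-species polynomial right-hand sides ``c' = Y A psi(c)``."""
    return sp.expand(sp.Matrix(matrices.Y) * sp.Matrix(matrices.A) * sp.Matrix(matrices.psi))


@dataclass
class IndependentSystem:
    """The reduced system F(ç, signal, k) after dependent-species elimination."""

    network: ReactionNetwork
    matrices: CRNTMatrices
    basis: ConservationBasis
    independent_indices: tuple[int, ...]   # species indices retained, in order
    eliminated: dict[sp.Symbol, sp.Expr]   # eliminated species -> law expression
    F: sp.ImmutableMatrix                  # s x 1, in ç, totals C_j, and k
    signal: sp.Symbol                      # the conservation total used as signal
    response: sp.Symbol                    # retained readout concentration symbol

    @property
    def s(self) -> int:
        return len(self.independent_indices)

    @property
    def independent_symbols(self) -> tuple[sp.Symbol, ...]:
        c = self.network.concentration_symbols
        return tuple(c[i] for i in self.independent_indices)

    @property
    def fixed_totals(self) -> tuple[sp.Symbol, ...]:
        """Conservation totals other than the signal (held constant)."""
        return tuple(t for t in self.basis.total_symbols if t != self.signal)

    @cached_property
    def jacobian(self) -> sp.ImmutableMatrix:
        return sp.ImmutableMatrix(
            sp.Matrix(self.F).jacobian(self.independent_symbols)
        )

    @cached_property
    def jacobian_det(self) -> sp.Expr:
        return sp.together(self.jacobian.det())

    def to_json(self) -> str:
        payload = {
            "independent_species": [
                self.network.species[i] for i in self.independent_indices
            ],
            "eliminated": {str(k): str(v) for k, v in self.eliminated.items()},
            "F": [str(e) for e in self.F],
            "signal": str(self.signal),
            "response": str(self.response),
        }
        return json.dumps(payload, indent=2)

    def report(self) -> str:
        lines = ["Independent ODE system"]
        for i, expr in zip(self.independent_indices, self.F):
            lines.append(f"  d{self.network.species[i]}/dt = {expr}")
        lines.append("Eliminated species")
        for sym, expr in self.eliminated.items():
            lines.append(f"  {sym} = {expr}")
        lines.append(f"Signal: {self.signal}   Response: {self.response}")
        return "\n".join(lines)


def select_independent_odes(
    matrices: CRNTMatrices,
    basis: ConservationBasis,
    response: str,
    signal: sp.Symbol | int = 0,
) -> IndependentSystem:
    """Choose lam species to eliminate, one per conservation law.

    Candidate combinations are enumerated in lexicographic species order;
    a combination is accepted when the eliminated species each carry a
    nonzero coefficient in their paired law, the lam x lam pairing matrix is
    invertible (so the laws solve uniquely for the eliminated species), and
    the retained ODE rows keep full rank ``s``.  The first admissible
    combination is taken.
    """
    net = matrices.network
    if response not in net.species:
        raise ReductionError(f"response species {response!r} is not in the network")
    resp_idx = net.species.index(response)
    c = net.concentration_symbols
    odes = full_odes(matrices)

    if isinstance(signal, int):
        signal_sym = basis.total_symbols[signal]
    else:
        signal_sym = signal
        if signal_sym not in basis.total_symbols:
            raise ReductionError(f"signal {signal} is not a conservation total")

    lam, s = matrices.lam, matrices.s
    B = sp.Matrix(basis.B)

    # response must actually participate in the dynamics
    if odes[resp_idx] == 0 and all(
        c[resp_idx] not in e.free_symbols for e in odes
    ):
        raise ReductionError(
            f"response species {response!r} does not participate in the dynamics"
        )

    per_law_candidates = [
        [i for i in range(net.n_species) if B[i, j] != 0 and i != resp_idx]
        for j in range(lam)
    ]

    S = sp.Matrix(matrices.S)
    for combo in itertools.product(*per_law_candidates):
        if len(set(combo)) != lam:
            continue  # a species may be eliminated at most once
        pairing = sp.Matrix(lam, lam, lambda r, col: B[combo[col], r])
        if pairing.det() == 0:
            continue
        retained = [i for i in range(net.n_species) if i not in combo]
        if S[retained, :].rank() != s:
            continue

        # Solve the laws for the eliminated species in terms of retained ones.
        eqs = []
        for j in range(lam):
            law = sum(B[i, j] * c[i] for i in range(net.n_species))
            eqs.append(sp.Eq(law, basis.total_symbols[j]))
        sol = sp.solve(eqs, [c[i] for i in combo], dict=True)
        if not sol:
            continue
        elim_map = {sym: sp.expand(expr) for sym, expr in sol[0].items()}

        F = sp.Matrix([sp.expand(odes[i].subs(elim_map)) for i in retained])
        return IndependentSystem(
            network=net,
            matrices=matrices,
            basis=basis,
            independent_indices=tuple(retained),
            eliminated=elim_map,
            F=sp.ImmutableMatrix(F),
            signal=signal_sym,
            response=c[resp_idx],
        )

    raise ReductionError(
        "no admissible elimination: the response species cannot be retained "
        "with a full-rank independent subsystem"
    )


def reduced_jacobian(sys: IndependentSystem) -> tuple[sp.ImmutableMatrix, sp.Expr]:
    """Symbolic Jacobian of F with respect to ç and its determinant."""
    return sys.jacobian, sys.jacobian_det
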