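"""Closed-form steady-state parametrization of the independent ODE system.

Under mass action every rate constant multiplies exactly one monomial, so
F is linear in any subset of rate constants.  Choosing ``s`` constants
k-tilde whose stoichiometric columns are linearly independent (the RREF
pivot columns of S by default) gives a uniquely solvable linear system
``U k~ = b``; substituting the solutions back enforces F == 0 identically,
which lets the saddle search optimize over the remaining free constants and
the concentrations only.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import sympy as sp

from .odes import IndependentSystem

__all__ = [
    "SteadyStateParametrization",
    "SteadyStateError",
    "choose_pivot_rates",
    "enumerate_alternative_pivots",
    "solve_steady_state",
]


class SteadyStateError(ValueError):
    """No positive steady state: every pivot choice forces a zero rate."""


def choose_pivot_rates(S: sp.Matrix) -> tuple[int, ...]:
    """Pivot column indices of RREF(S), computed over the rationals."""
    _, pivots = sp.Matrix(S).rref()
    return tuple(int(p) for p in pivots)


def enumerate_alternative_pivots(
    S: sp.Matrix, skip: Sequence[tuple[int, ...]] = ()
) -> Iterator[tuple[int, ...]]:
    """Yield s-subsets of linearly independent columns in lexicographic order.

    Combinations whose columns are dependent are skipped; combinations in
    ``skip`` (already tried) are omitted.
    """
    S = sp.Matrix(S)
    s = S.rank()
    skipset = {tuple(c) for c in skip}
    for combo in itertools.combinations(range(S.shape[1]), s):
        if combo in skipset:
            continue
        if S[:, list(combo)].rank() == s:
            yield combo


@dataclass
class SteadyStateParametrization:
    """Solved pivot rate constants and the linear system they came from."""

    system: IndependentSystem
    pivot_indices: tuple[int, ...]
    fixed_symbols: tuple[sp.Symbol, ...]      # k-tilde, one per pivot column
    free_symbols: tuple[sp.Symbol, ...]       # the remaining R - s rate constants
    U: sp.ImmutableMatrix
    b: sp.ImmutableMatrix
    expressions: dict[sp.Symbol, sp.Expr]     # k-tilde -> rational expression

    def denominators(self) -> tuple[sp.Expr, ...]:
        return tuple(
            sp.denom(sp.together(e)) for e in self.expressions.values()
        )

    def residual(self) -> sp.Matrix:
        """F with the k-tilde expressions substituted; zero by construction."""
        return sp.simplify(sp.Matrix(self.system.F).subs(self.expressions))

    def to_json(self) -> str:
        payload = {
            "pivot_reactions": [i + 1 for i in self.pivot_indices],
            "fixed": {str(k): str(v) for k, v in self.expressions.items()},
            "free": [str(k) for k in self.free_symbols],
        }
        return json.dumps(payload, indent=2)

    def report(self) -> str:
        lines = ["Steady-state parametrization"]
        for k, v in self.expressions.items():
            lines.append(f"  {k} = {v}")
        lines.append("Free rate constants: " + ", ".join(map(str, self.free_symbols)))
        return "\n".join(lines)


def _try_pivots(
    sys: IndependentSystem, pivots: tuple[int, ...]
) -> SteadyStateParametrization | None:
    net = sys.network
    ktilde = [net.rate_symbols[i] for i in pivots]
    F = list(sys.F)
    U, b = sp.linear_eq_to_matrix(F, ktilde)
    if U.det(method="berkowitz").is_zero:  # singular over the function field
        return None
    solset = sp.linsolve((U, b), ktilde)
    if not solset:
        return None
    sol = next(iter(solset))
    exprs = {}
    for k, e in zip(ktilde, sol):
        e = sp.cancel(sp.together(e))
        if e == 0:  # forced-zero rate constant: reject this pivot set
            return None
        exprs[k] = e
    free = tuple(k for k in net.rate_symbols if k not in ktilde)
    return SteadyStateParametrization(
        system=sys,
        pivot_indices=pivots,
        fixed_symbols=tuple(ktilde),
        free_symbols=free,
        U=sp.ImmutableMatrix(U),
        b=sp.ImmutableMatrix(b),
        expressions=exprs,
    )


def solve_steady_state(
    sys: IndependentSystem, pivots: tuple[int, ...] | None = None
) -> SteadyStateParametrization:
    """Solve U k~ = b for the pivot rate constants, with fallback search.

    Starts from the RREF pivots of S; if the solve is singular or forces a
    rate constant to be identically zero, falls through the remaining
    linearly independent column combinations in lexicographic order.  If all
    combinations fail, no steady state exists with k > 0 and c > 0.
    """
    S = sp.Matrix(sys.matrices.S)
    tried: list[tuple[int, ...]] = []
    if pivots is None:
        pivots = choose_pivot_rates(S)
    result = _try_pivots(sys, tuple(pivots))
    if result is not None:
        return result
    tried.append(tuple(pivots))
    for combo in enumerate_alternative_pivots(S, skip=tried):
        result = _try_pivots(sys, combo)
        if result is not None:
            return result
    raise SteadyStateError(
        "no steady state exists when k > 0 and c > 0: every independent "
        "column combination forces a zero rate constant"
    )
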