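"""Nonnegative integer conservation-law basis of Null(S^T).

Each moiety-conservation law is a nonnegative vector b with S^T b = 0; the
quantity ``C = b . c`` is constant along every trajectory.  A signed rational
basis of the nullspace is computed exactly; nonnegative representatives are
then found as vertices of the polytope obtained by intersecting the cone
``Null(S^T) ∩ R^N_+`` with the normalization plane "coordinates of x sum to
one", searched from random directions with linear programming.  Each vertex
is rescaled to coprime integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from math import gcd, lcm
from typing import Sequence

import numpy as np
import sympy as sp
from scipy.optimize import linprog

from .network import CRNTMatrices, ReactionNetwork

__all__ = [
    "ConservationBasis",
    "NoConservationLawsError",
    "BasisSearchError",
    "rational_nullspace",
    "integer_scale",
    "nonnegative_basis",
    "conservation_basis",
]


class NoConservationLawsError(ValueError):
    """The network has rank(S) = N, i.e. no conservation laws.

    Networks without mass conservation are outside the scope of this
    package: the bifurcation signal is always a conservation total.
    """


class BasisSearchError(RuntimeError):
    """The LP vertex search did not assemble a full nonnegative basis."""


def rational_nullspace(S: sp.Matrix) -> sp.Matrix:
    """Exact rational basis of Null(S^T), one column per conservation law."""
    vecs = S.T.nullspace()
    if not vecs:
        raise NoConservationLawsError(
            "rank(S) = N: the network has no conservation laws"
        )
    return sp.Matrix.hstack(*vecs)


def integer_scale(v: Sequence) -> tuple[int, ...]:
    """Scale a nonnegative rational vector to coprime nonnegative integers.

    The vector is divided by its smallest nonzero entry, residual rationals
    are cleared by the lcm of denominators, and the result is divided by the
    gcd of its entries.
    """
    fr = [Fraction(sp.nsimplify(x, rational=True)) if not isinstance(x, (int, Fraction)) else Fraction(x) for x in v]
    if any(x < 0 for x in fr):
        raise ValueError("vector has negative entries")
    nonzero = [x for x in fr if x != 0]
    if not nonzero:
        raise ValueError("cannot scale the zero vector")
    smallest = min(nonzero)
    fr = [x / smallest for x in fr]
    denom_lcm = lcm(*(x.denominator for x in fr)) if fr else 1
    ints = [int(x * denom_lcm) for x in fr]
    g = gcd(*ints)
    return tuple(x // g for x in ints)


@dataclass
class ConservationBasis:
    """N x lam nonnegative integer matrix B with S^T B = 0 exactly."""

    B: sp.ImmutableMatrix
    total_symbols: tuple[sp.Symbol, ...]
    species: tuple[str, ...]
    conc_symbols: tuple[sp.Symbol, ...]

    @property
    def lam(self) -> int:
        return self.B.shape[1]

    def law_expression(self, j: int) -> sp.Expr:
        return sum(
            self.B[i, j] * self.conc_symbols[i]
            for i in range(self.B.shape[0])
        )

    @property
    def law_expressions(self) -> tuple[sp.Expr, ...]:
        return tuple(self.law_expression(j) for j in range(self.lam))

    def totals_from_concentrations(self, c: np.ndarray) -> np.ndarray:
        Bnum = np.array(self.B, dtype=float)
        return Bnum.T @ np.asarray(c, dtype=float)

    def to_json(self) -> str:
        laws = []
        for j in range(self.lam):
            coeffs = {
                self.species[i]: int(self.B[i, j])
                for i in range(self.B.shape[0])
                if self.B[i, j] != 0
            }
            laws.append(
                {"total_symbol": str(self.total_symbols[j]), "coefficients": coeffs}
            )
        return json.dumps(laws, indent=2)


def _rationalize(x: np.ndarray, max_denominator: int = 10**9) -> list[Fraction]:
    return [Fraction(float(v)).limit_denominator(max_denominator) for v in x]


def nonnegative_basis(
    Bt: sp.Matrix,
    S: sp.Matrix,
    max_iter: int | None = None,
    rng_seed: int = 0,
) -> list[tuple[int, ...]]:
    """Assemble lam independent nonnegative integer nullspace vectors.

    Repeatedly minimizes a random direction ``w`` over the polytope
    ``{x : Bt x >= 0, (column sums of Bt) . x = 1}`` (a vertex search of the
    nonnegative cone slice), maps each LP vertex back through ``Bt``,
    rescales to integers, and collects unique, linearly independent vectors
    until lam of them are found.
    """
    lam = Bt.shape[1]
    if max_iter is None:
        max_iter = 100 * lam
    rng = np.random.default_rng(rng_seed)

    Bt_num = np.array(Bt, dtype=float)
    col_sums = Bt_num.sum(axis=0)

    found: list[tuple[int, ...]] = []
    found_matrix = sp.zeros(Bt.shape[0], 0)
    any_lp_success = False

    for _ in range(max_iter):
        w = rng.uniform(-1.0, 1.0, size=lam)
        res = linprog(
            c=w,
            A_ub=-Bt_num,
            b_ub=np.zeros(Bt.shape[0]),
            A_eq=col_sums.reshape(1, -1),
            b_eq=[1.0],
            bounds=[(None, None)] * lam,
            method="highs",
        )
        if not res.success:
            continue
        any_lp_success = True
        x_exact = sp.Matrix(_rationalize(res.x))
        v = Bt * x_exact  # exact member of Null(S^T)
        if any(e < 0 for e in v):
            continue
        if all(e == 0 for e in v):
            continue
        vec = integer_scale(list(v))
        if vec in found:
            continue
        col = sp.Matrix(vec)
        if (S.T * col) != sp.zeros(S.shape[1], 1):
            continue  # numerical vertex did not rationalize cleanly
        candidate = found_matrix.row_join(col)
        if candidate.rank() <= found_matrix.rank():
            continue  # dependent duplicate, discard silently
        found.append(vec)
        found_matrix = candidate
        if len(found) == lam:
            return found

    if not any_lp_success:
        raise BasisSearchError(
            "no nonnegative basis was found: every LP direction was infeasible"
        )
    raise BasisSearchError(
        f"found {len(found)} of {lam} nonnegative basis vectors; "
        "the number of iterations should be increased"
    )


def conservation_basis(
    matrices: CRNTMatrices,
    max_iter: int | None = None,
    rng_seed: int = 0,
) -> ConservationBasis:
    """Compute the full nonnegative conservation-law basis for a network."""
    net = matrices.network
    if matrices.lam == 0:
        raise NoConservationLawsError(
            "rank(S) = N: the network has no conservation laws"
        )
    Bt = rational_nullspace(sp.Matrix(matrices.S))
    cols = nonnegative_basis(
        Bt, sp.Matrix(matrices.S), max_iter=max_iter, rng_seed=rng_seed
    )
    # stable order: sort by support pattern for seed-independent presentation
    cols = sorted(cols, key=lambda v: ([i for i, e in enumerate(v) if e], v))
    B = sp.ImmutableMatrix([[col[i] for col in cols] for i in range(net.n_species)])
    totals = sp.symbols(f"C1:{len(cols) + 1}", positive=True)
    return ConservationBasis(
        B=B,
        total_symbols=totals,
        species=tuple(net.species),
        conc_symbols=net.concentration_symbols,
    )
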