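"""Global saddle-node search and the Bayesian multistart stopping rule.

A saddle-node candidate is a point where the reduced system is at a steady
state and det(J) = 0.  Two objective formulations are available:

* ``eq5`` (parametrized): the steady state is enforced symbolically by the
  pivot-rate expressions, and only det(J)**2 is minimized over the free rate
  constants and the concentrations.
* ``eq4`` (explicit residual): all rate constants and concentrations are
  free, and det(J)**2 + sum_i F_i**2 is minimized.  More robust when the
  parametrized Jacobian is ill-conditioned, at the price of a larger
  decision vector.

In both modes the conservation totals are computed from the sampled
concentrations through the conservation laws.  The search runs dual
annealing (simulated annealing plus Nelder-Mead local polish) from n
independent starts with per-start seeds, and reports a Bayesian confidence
q(n, r) that the best minimum found is the global one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from scipy.optimize import dual_annealing, minimize

from .conservation import ConservationBasis
from .odes import IndependentSystem
from .steady_state import SteadyStateParametrization

__all__ = [
    "SearchConfig",
    "SearchResult",
    "Objective",
    "default_bounds",
    "build_objective_eq5",
    "build_objective_eq4",
    "run_search",
    "confidence_level",
    "neighborhood_count",
]

_PENALTY = 1e10


@dataclass
class SearchConfig:
    """Settings for the multistart saddle search."""

    mode: str = "eq5"                    # "eq5" (parametrized) or "eq4"
    n_starts: int = 50
    rng_seed: int = 0
    zero_tol: float = 1e-12              # objective value counted as numerical zero
    neighborhood_eps: float = 0.10       # relative neighborhood for the stopping rule
    beta_a: int = 1
    beta_b: int = 5
    q_stop: float = 0.95                 # stop once this confidence is reached
    stop_on_zero: bool = True
    anneal_maxiter: int = 300
    polish: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("eq4", "eq5"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not (0 < self.neighborhood_eps < 1):
            raise ValueError("neighborhood tolerance must be in (0, 1)")


def default_bounds(
    sys: IndependentSystem,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Physiological default boxes for concentrations and rate constants.

    Concentrations span typical cellular protein levels, 5e-13 to 5e-7 M.
    Rate-constant ranges are inferred from the reaction shape: a bimolecular
    source complex is treated as an association (1e4..1e8 1/(M s)); a
    unimolecular source with a bimolecular target as a dissociation
    (1e-5..1e-3 1/s); anything else as catalysis (1e-3..1 1/s).
    """
    net = sys.network
    c_bounds = [(5e-13, 5e-7)] * net.n_species
    k_bounds = []
    for r in net.reactions:
        src = net.complexes[r.source]
        tgt = net.complexes[r.target]
        if src.total_molecularity >= 2:
            k_bounds.append((1e4, 1e8))
        elif tgt.total_molecularity >= 2:
            k_bounds.append((1e-5, 1e-3))
        else:
            k_bounds.append((1e-3, 1.0))
    return c_bounds, k_bounds


@dataclass
class Objective:
    """A numeric objective over a decision vector with named components."""

    mode: str
    variable_names: tuple[str, ...]
    fun: Callable[[np.ndarray], float]
    bounds: list[tuple[float, float]]
    reconstruct: Callable[[np.ndarray], dict]

    def __call__(self, x: np.ndarray) -> float:
        return self.fun(np.asarray(x, dtype=float))


def _totals_function(basis: ConservationBasis) -> Callable[[np.ndarray], np.ndarray]:
    Bnum = np.array(basis.B, dtype=float).T

    def totals(c: np.ndarray) -> np.ndarray:
        return Bnum @ c

    return totals


def build_objective_eq5(
    sys: IndependentSystem,
    param: SteadyStateParametrization,
    c_bounds: Sequence[tuple[float, float]] | None = None,
    k_bounds: Sequence[tuple[float, float]] | None = None,
    hinge_delta: float = 1e-12,
) -> Objective:
    """Parametrized objective det(J)**2 over free rates and concentrations.

    The pivot rates are reconstructed from their closed forms; a smooth
    hinge penalty keeps them positive, and evaluation at a denominator pole
    returns a large finite penalty instead of raising.
    """
    net = sys.network
    basis = sys.basis
    if c_bounds is None or k_bounds is None:
        dc, dk = default_bounds(sys)
        c_bounds = c_bounds or dc
        k_bounds = k_bounds or dk

    free_k = param.free_symbols
    conc = net.concentration_symbols
    args = list(free_k) + list(conc) + list(basis.total_symbols)
    cc = sys.independent_symbols

    ktilde_funcs = sp.lambdify(args, list(param.expressions.values()), "numpy")
    det_args = list(net.rate_symbols) + list(conc) + list(basis.total_symbols)
    # determinant evaluated numerically from the Jacobian matrix: a symbolic
    # determinant is intractable for larger reduced systems
    J_func = sp.lambdify(det_args, sys.jacobian, "numpy")
    totals_of = _totals_function(basis)

    k_index = {s: i for i, s in enumerate(net.rate_symbols)}
    free_idx = [k_index[s] for s in free_k]
    fixed_idx = [k_index[s] for s in param.fixed_symbols]
    n_free = len(free_k)

    def reconstruct(x: np.ndarray) -> dict:
        kf = x[:n_free]
        c = x[n_free:]
        totals = totals_of(c)
        with np.errstate(all="ignore"):
            kt = np.asarray(ktilde_funcs(*kf, *c, *totals), dtype=float)
        k_full = np.empty(net.n_reactions)
        k_full[free_idx] = kf
        k_full[fixed_idx] = kt
        return {
            "k": k_full,
            "c": np.asarray(c, dtype=float),
            "totals": np.asarray(totals, dtype=float),
            "ktilde": kt,
        }

    def fun(x: np.ndarray) -> float:
        state = reconstruct(x)
        kt = state["ktilde"]
        if not np.all(np.isfinite(kt)):
            return _PENALTY
        penalty = float(np.sum(np.maximum(0.0, -kt + hinge_delta) ** 2))
        with np.errstate(all="ignore"):
            J = np.asarray(
                J_func(*state["k"], *state["c"], *state["totals"]), dtype=float
            )
        if not np.all(np.isfinite(J)):
            return _PENALTY
        return float(np.linalg.det(J)) ** 2 + penalty

    names = tuple(str(s) for s in free_k) + tuple(
        net.species[i] for i in range(net.n_species)
    )
    bounds = [k_bounds[i] for i in free_idx] + list(c_bounds)
    return Objective(
        mode="eq5", variable_names=names, fun=fun, bounds=bounds,
        reconstruct=reconstruct,
    )


def build_objective_eq4(
    sys: IndependentSystem,
    c_bounds: Sequence[tuple[float, float]] | None = None,
    k_bounds: Sequence[tuple[float, float]] | None = None,
) -> Objective:
    """Explicit-residual objective det(J)**2 + sum_i F_i**2 over all k and c."""
    net = sys.network
    basis = sys.basis
    if c_bounds is None or k_bounds is None:
        dc, dk = default_bounds(sys)
        c_bounds = c_bounds or dc
        k_bounds = k_bounds or dk

    conc = net.concentration_symbols
    args = list(net.rate_symbols) + list(conc) + list(basis.total_symbols)
    F_func = sp.lambdify(args, list(sys.F), "numpy")
    J_func = sp.lambdify(args, sys.jacobian, "numpy")
    totals_of = _totals_function(basis)
    R = net.n_reactions

    def reconstruct(x: np.ndarray) -> dict:
        k = x[:R]
        c = x[R:]
        return {
            "k": np.asarray(k, dtype=float),
            "c": np.asarray(c, dtype=float),
            "totals": totals_of(np.asarray(c, dtype=float)),
        }

    def fun(x: np.ndarray) -> float:
        state = reconstruct(x)
        a = (*state["k"], *state["c"], *state["totals"])
        with np.errstate(all="ignore"):
            res = np.asarray(F_func(*a), dtype=float)
            J = np.asarray(J_func(*a), dtype=float)
        if not (np.all(np.isfinite(res)) and np.all(np.isfinite(J))):
            return _PENALTY
        return float(np.linalg.det(J)) ** 2 + float(np.sum(res**2))

    names = tuple(str(s) for s in net.rate_symbols) + tuple(net.species)
    bounds = list(k_bounds) + list(c_bounds)
    return Objective(
        mode="eq4", variable_names=names, fun=fun, bounds=bounds,
        reconstruct=reconstruct,
    )


# ---------------------------------------------------------------------------
# Bayesian stopping rule
# ---------------------------------------------------------------------------

def confidence_level(n: int, r: int, a: int = 1, b: int = 5) -> float:
    """Lower bound on Pr[best of n multistart minima is the global minimum].

    Exact big-integer evaluation of

        q(n, r) = 1 - (n+a+b-1)! (2n+b-r-1)! / ((2n+a+b-1)! (n+b-r-1)!)

    where r is the number of local minima in the relative neighborhood of
    the best one and (a, b) parametrize the Beta prior.
    """
    if not (1 <= r <= n):
        raise ValueError("r must satisfy 1 <= r <= n")
    if a < 1 or b < 1:
        raise ValueError("Beta parameters must be integers >= 1")
    num = math.factorial(n + a + b - 1) * math.factorial(2 * n + b - r - 1)
    den = math.factorial(2 * n + a + b - 1) * math.factorial(n + b - r - 1)
    return float(1 - Fraction(num, den))


def neighborhood_count(minima: Sequence[float], f_best: float, eps: float) -> int:
    """Count minima with relative difference from the best within eps."""
    if f_best <= 0:
        raise ValueError(
            "neighborhood counting requires f_best > 0; "
            "a numerical zero sets q = 1.0 directly"
        )
    return int(sum(1 for f in minima if abs(f_best - f) / f_best <= eps))


# ---------------------------------------------------------------------------
# Multistart driver
# ---------------------------------------------------------------------------

@dataclass
class StartRecord:
    index: int
    seed: int
    f: float
    x: np.ndarray


@dataclass
class SearchResult:
    """Multistart outcome: per-start minima, the best point, and q(n, r)."""

    config: SearchConfig
    starts: list[StartRecord]
    best_f: float
    best_x: np.ndarray
    r: int
    q: float
    candidates: list[StartRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.starts)

    def to_json(self) -> str:
        payload = {
            "mode": self.config.mode,
            "n_starts_run": self.n,
            "best_f": self.best_f,
            "best_x": list(map(float, self.best_x)),
            "r": self.r,
            "q": self.q,
            "candidates": [
                {"start": s.index, "f": s.f, "x": list(map(float, s.x))}
                for s in self.candidates
            ],
        }
        return json.dumps(payload, indent=2)


def run_search(cfg: SearchConfig, objective: Objective) -> SearchResult:
    """Run n_starts independent dual-annealing searches with local polish.

    Per-start seeds are ``rng_seed + start index`` (modulo 2**31), so runs
    are reproducible and trivially partitionable across workers.  The loop
    stops early when a start reaches a numerical zero (q = 1.0) or once the
    stopping-rule confidence exceeds ``q_stop``.
    """
    starts: list[StartRecord] = []
    bounds = objective.bounds

    for i in range(cfg.n_starts):
        seed = int((cfg.rng_seed + i) % (2**31))
        rng = np.random.default_rng(seed)
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = dual_annealing(
            objective.fun,
            bounds=bounds,
            seed=seed,
            maxiter=cfg.anneal_maxiter,
            x0=x0,
            minimizer_kwargs={
                "method": "Nelder-Mead",
                "options": {"maxiter": 600},
            },
        )
        f, x = float(res.fun), np.asarray(res.x, dtype=float)
        if cfg.polish:
            local = minimize(
                objective.fun, x, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-14, "fatol": 1e-16, "maxiter": 2000},
            )
            if local.fun <= f:
                f, x = float(local.fun), np.asarray(local.x, dtype=float)
        starts.append(StartRecord(index=i, seed=seed, f=f, x=x))

        best = min(starts, key=lambda s: s.f)
        if cfg.stop_on_zero and best.f <= cfg.zero_tol:
            break
        if best.f > 0:
            r = neighborhood_count([s.f for s in starts], best.f, cfg.neighborhood_eps)
            if confidence_level(len(starts), r, cfg.beta_a, cfg.beta_b) >= cfg.q_stop:
                break

    best = min(starts, key=lambda s: s.f)
    if best.f <= cfg.zero_tol:
        r = sum(1 for s in starts if s.f <= cfg.zero_tol)
        q = 1.0
    else:
        r = neighborhood_count([s.f for s in starts], best.f, cfg.neighborhood_eps)
        q = confidence_level(len(starts), r, cfg.beta_a, cfg.beta_b)

    candidates = [s for s in starts if s.f <= cfg.zero_tol]
    return SearchResult(
        config=cfg,
        starts=starts,
        best_f=best.f,
        best_x=best.x,
        r=r,
        q=q,
        candidates=candidates,
    )
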