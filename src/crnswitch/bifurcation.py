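"""Saddle-node verification, continuation, and dose-response simulation.

A candidate from the saddle search is accepted as a saddle-node when the
reduced Jacobian has exactly one eigenvalue at zero (within a relative
tolerance) and every other eigenvalue has nonzero real part.  The
transversality conditions of the saddle-node bifurcation theorem — the
signal derivative of F and the second derivative contracted twice with the
kernel vector both nonzero and outside the range of the Jacobian — are
screened as an advisory check; the decisive evidence is the bifurcation
diagram itself, produced either by pseudo-arclength continuation of the
equilibrium curve through its folds, or by direct stiff integration of the
ODEs from low and high starts over a signal grid (the dose-response curve,
whose path dependence is the hysteresis signature).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .odes import IndependentSystem

__all__ = [
    "SaddleNodeReport",
    "BifurcationDiagram",
    "DoseResponse",
    "HysteresisReport",
    "NumericSystem",
    "saddle_node_check",
    "continue_branch",
    "direct_simulation",
    "detect_hysteresis",
]


# ---------------------------------------------------------------------------
# Numeric closures over the reduced system
# ---------------------------------------------------------------------------

class NumericSystem:
    """Lambdified F, J, and derivatives of a reduced system at fixed k/totals.

    The remaining arguments are the independent concentrations ç and the
    signal total; the fixed totals and rate constants are frozen in.
    """

    def __init__(
        self,
        sys: IndependentSystem,
        k_values: Sequence[float],
        fixed_totals: dict[sp.Symbol, float] | None = None,
    ):
        self.sys = sys
        net = sys.network
        subs = dict(zip(net.rate_symbols, [sp.Float(v) for v in k_values]))
        for sym, val in (fixed_totals or {}).items():
            if sym == sys.signal:
                raise ValueError("the signal total cannot be fixed")
            subs[sym] = sp.Float(val)
        cc = list(sys.independent_symbols)
        args = cc + [sys.signal]
        F = sp.Matrix(sys.F).subs(subs)
        leftover = set().union(*[f.free_symbols for f in F]) - set(args)
        if leftover:
            raise ValueError(
                f"unbound symbols {sorted(map(str, leftover))}: provide rate "
                "constants for all reactions and values for all fixed totals"
            )
        J = sp.Matrix(sys.jacobian).subs(subs)
        Fe = sp.Matrix([sp.diff(f, sys.signal) for f in F])
        self._F = sp.lambdify(args, list(F), "numpy")
        self._J = sp.lambdify(args, J, "numpy")
        self._Fe = sp.lambdify(args, list(Fe), "numpy")
        # second derivative tensor rows: H[i] = hessian of F_i w.r.t. ç
        self._H = [
            sp.lambdify(args, sp.hessian(F[i], cc), "numpy")
            for i in range(len(cc))
        ]
        self.s = len(cc)
        # dependent-species reconstruction (for nonnegativity screening)
        elim = [
            (sym, sp.lambdify(args, expr.subs(subs), "numpy"))
            for sym, expr in sys.eliminated.items()
        ]
        self._elim = elim

    def F(self, u: np.ndarray, eps: float) -> np.ndarray:
        return np.asarray(self._F(*u, eps), dtype=float)

    def J(self, u: np.ndarray, eps: float) -> np.ndarray:
        return np.asarray(self._J(*u, eps), dtype=float)

    def F_signal(self, u: np.ndarray, eps: float) -> np.ndarray:
        return np.asarray(self._Fe(*u, eps), dtype=float)

    def Fuu(self, u: np.ndarray, eps: float, v: np.ndarray) -> np.ndarray:
        return np.array(
            [v @ np.asarray(H(*u, eps), dtype=float) @ v for H in self._H]
        )

    def dependent_species(self, u: np.ndarray, eps: float) -> np.ndarray:
        return np.array([f(*u, eps) for _, f in self._elim], dtype=float)


# ---------------------------------------------------------------------------
# Saddle-node check (Definition of a saddle-node + transversality screen)
# ---------------------------------------------------------------------------

@dataclass
class SaddleNodeReport:
    eigenvalues: np.ndarray
    zero_count: int
    kernel_vector: np.ndarray | None
    d_signal_nonzero: bool
    d_signal_outside_range: bool
    second_derivative_nonzero: bool
    second_derivative_outside_range: bool
    verdict: str            # saddle_node | rejected_multiplicity | rejected_transversality
    condition_warning: bool = False

    @property
    def is_saddle_node(self) -> bool:
        return self.verdict == "saddle_node"

    def to_json(self) -> str:
        return json.dumps(
            {
                "eigenvalues": [
                    {"re": float(z.real), "im": float(z.imag)}
                    for z in self.eigenvalues
                ],
                "zero_count": self.zero_count,
                "verdict": self.verdict,
                "condition_warning": self.condition_warning,
            },
            indent=2,
        )


def _rank(a: np.ndarray, cutoff: float) -> int:
    """Numerical rank with an absolute singular-value cutoff."""
    if a.size == 0:
        return 0
    sv = np.linalg.svd(a, compute_uv=False)
    return int(np.sum(sv > cutoff))


def saddle_node_check(
    J: np.ndarray,
    d_signal: np.ndarray | None = None,
    second_derivative: Callable[[np.ndarray], np.ndarray] | None = None,
    zero_tol: float = 1e-6,
) -> SaddleNodeReport:
    """Classify a numeric Jacobian (plus transversality data) at a candidate.

    An eigenvalue counts as zero when |z| < zero_tol * max(1, spectral
    radius); all other eigenvalues must have |Re z| above the same
    threshold.  ``second_derivative`` maps the kernel vector v to
    D_cc F (v, v).  Transversality failures are advisory (verdict
    ``rejected_transversality``) — continuation can still be attempted.
    """
    J = np.asarray(J, dtype=float)
    eig = np.linalg.eigvals(J)
    scale = max(1.0, float(np.max(np.abs(eig))) if eig.size else 1.0)
    thr = zero_tol * scale
    zero_mask = np.abs(eig) < thr
    zero_count = int(np.sum(zero_mask))

    cond_warning = False
    sv = np.linalg.svd(J, compute_uv=False)
    if sv[0] > 0 and (sv[-1] / sv[0]) < 1e-14 and zero_count == 0:
        cond_warning = True

    if zero_count != 1 or np.any(
        ~zero_mask & (np.abs(eig.real) < thr)
    ):
        return SaddleNodeReport(
            eigenvalues=eig,
            zero_count=zero_count,
            kernel_vector=None,
            d_signal_nonzero=False,
            d_signal_outside_range=False,
            second_derivative_nonzero=False,
            second_derivative_outside_range=False,
            verdict="rejected_multiplicity",
            condition_warning=cond_warning,
        )

    # kernel vector from the SVD, normalized with first nonzero entry positive
    _, _, vt = np.linalg.svd(J)
    v = vt[-1]
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if nz.size and v[nz[0]] < 0:
        v = -v
    v = v / np.linalg.norm(v)

    # range membership is judged at the same scale as the zero eigenvalue:
    # the candidate Jacobian is only approximately singular
    rank_J = _rank(J, thr)

    def outside_range(w: np.ndarray) -> bool:
        wn = w / max(np.linalg.norm(w), 1e-300) * max(scale, 1.0)
        return _rank(np.column_stack([J, wn]), thr) > rank_J

    d_nonzero = d_outside = h_nonzero = h_outside = True
    if d_signal is not None:
        d_signal = np.asarray(d_signal, dtype=float)
        d_nonzero = bool(np.linalg.norm(d_signal) > thr * 1e-3)
        d_outside = d_nonzero and outside_range(d_signal)
    if second_derivative is not None:
        hvv = np.asarray(second_derivative(v), dtype=float)
        h_nonzero = bool(np.linalg.norm(hvv) > thr * 1e-3)
        h_outside = h_nonzero and outside_range(hvv)

    verdict = (
        "saddle_node"
        if (d_nonzero and d_outside and h_nonzero and h_outside)
        else "rejected_transversality"
    )
    return SaddleNodeReport(
        eigenvalues=eig,
        zero_count=zero_count,
        kernel_vector=v,
        d_signal_nonzero=d_nonzero,
        d_signal_outside_range=d_outside,
        second_derivative_nonzero=h_nonzero,
        second_derivative_outside_range=h_outside,
        verdict=verdict,
        condition_warning=cond_warning,
    )


def check_candidate(
    numsys: NumericSystem, u: np.ndarray, eps: float, zero_tol: float = 1e-6
) -> SaddleNodeReport:
    """Run the saddle-node check on a reduced-system equilibrium."""
    return saddle_node_check(
        numsys.J(u, eps),
        d_signal=numsys.F_signal(u, eps),
        second_derivative=lambda v: numsys.Fuu(u, eps, v),
        zero_tol=zero_tol,
    )


# ---------------------------------------------------------------------------
# Pseudo-arclength continuation
# ---------------------------------------------------------------------------

@dataclass
class BranchPoint:
    signal: float
    u: np.ndarray
    stable: bool


@dataclass
class FoldPoint:
    signal: float
    u: np.ndarray
    kind: str = "max"   # "max": signal locally maximal along the branch; "min": minimal


@dataclass
class BifurcationDiagram:
    points: list[BranchPoint]
    folds: list[FoldPoint]
    bistable_interval: tuple[float, float] | None
    truncated: bool = False

    def to_frame(self, species_names: Sequence[str]) -> pd.DataFrame:
        rows = []
        fold_signals = {round(f.signal, 12) for f in self.folds}
        for p in self.points:
            row = {"signal": p.signal}
            row.update({n: v for n, v in zip(species_names, p.u)})
            row["stable"] = int(p.stable)
            row["fold"] = int(round(p.signal, 12) in fold_signals)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_points": len(self.points),
            "folds": [f.signal for f in self.folds],
            "bistable_interval": self.bistable_interval,
            "truncated": self.truncated,
        }


def _newton_correct(
    numsys: NumericSystem,
    y: np.ndarray,
    tangent: np.ndarray | None,
    y_pred: np.ndarray,
    tol: float,
    max_iter: int = 12,
) -> np.ndarray | None:
    """Newton iteration on [F; pseudo-arclength constraint] = 0.

    With ``tangent`` None, the signal component is held fixed instead
    (natural-parameter correction).
    """
    s = numsys.s
    y = y.copy()
    for _ in range(max_iter):
        u, eps = y[:s], y[s]
        res_F = numsys.F(u, eps)
        if tangent is None:
            rhs = res_F
            Jfull = numsys.J(u, eps)
            if np.linalg.norm(rhs) <= tol:
                return y
            try:
                step = np.linalg.solve(Jfull, -rhs)
            except np.linalg.LinAlgError:
                return None
            y[:s] += step
            continue
        con = tangent @ (y - y_pred)
        rhs = np.concatenate([res_F, [con]])
        if np.linalg.norm(res_F) <= tol and abs(con) <= tol:
            return y
        A = np.zeros((s + 1, s + 1))
        A[:s, :s] = numsys.J(u, eps)
        A[:s, s] = numsys.F_signal(u, eps)
        A[s, :] = tangent
        try:
            step = np.linalg.solve(A, -rhs)
        except np.linalg.LinAlgError:
            return None
        y += step
        if not np.all(np.isfinite(y)):
            return None
    return None


def _gauss_newton_correct(
    numsys: NumericSystem, y: np.ndarray, tol: float, max_iter: int = 30
) -> np.ndarray | None:
    """Minimal-norm Newton steps onto the equilibrium curve in (ç, signal)."""
    s = numsys.s
    y = y.copy()
    for _ in range(max_iter):
        u, eps = y[:s], y[s]
        res = numsys.F(u, eps)
        if np.linalg.norm(res) <= tol:
            return y
        A = np.column_stack([numsys.J(u, eps), numsys.F_signal(u, eps)])
        step, *_ = np.linalg.lstsq(A, -res, rcond=None)
        y += step
        if not np.all(np.isfinite(y)):
            return None
    return None


def _tangent_vector(
    numsys: NumericSystem, y: np.ndarray, previous: np.ndarray | None
) -> np.ndarray | None:
    """Unit tangent of the equilibrium curve from the bordered system."""
    s = numsys.s
    u, eps = y[:s], y[s]
    A = np.column_stack([numsys.J(u, eps), numsys.F_signal(u, eps)])
    _, _, vt = np.linalg.svd(A)
    t = vt[-1]
    norm = np.linalg.norm(t)
    if norm == 0 or not np.all(np.isfinite(t)):
        return None
    t = t / norm
    if previous is not None and t @ previous < 0:
        t = -t
    return t


def continue_branch(
    sys: IndependentSystem,
    k_values: Sequence[float],
    start_u: Sequence[float],
    start_signal: float,
    signal_bounds: tuple[float, float],
    fixed_totals: dict[sp.Symbol, float] | None = None,
    initial_step: float = 1e-2,
    max_step: float = 0.5,
    max_points: int = 2000,
    corrector_tol: float = 1e-10,
    eig_tol: float = 1e-9,
) -> BifurcationDiagram:
    """Trace the equilibrium curve through folds by pseudo-arclength.

    Starts from an equilibrium ``(start_u, start_signal)`` (corrected at
    fixed signal first), then walks in both arclength directions.  Folds are
    located where the tangent's signal component changes sign, refined by
    bisection on that component.  The branch stops at the signal bounds, the
    point budget, or after repeated corrector failures.
    """
    numsys = NumericSystem(sys, k_values, fixed_totals)
    s = numsys.s
    y0 = np.concatenate([np.asarray(start_u, dtype=float), [float(start_signal)]])
    corrected = _newton_correct(numsys, y0, None, y0, corrector_tol)
    if corrected is None:
        # start may sit at (or near) a fold where J is singular: correct
        # onto the curve by Gauss-Newton on the underdetermined system,
        # letting the signal move as well
        corrected = _gauss_newton_correct(numsys, y0, corrector_tol)
    if corrected is None:
        raise ValueError("start point does not correct to an equilibrium")
    y0 = corrected

    def stability(y: np.ndarray) -> bool:
        eig = np.linalg.eigvals(numsys.J(y[:s], y[s]))
        return bool(np.max(eig.real) < 0)

    points: list[tuple[float, np.ndarray, bool]] = []
    folds: list[FoldPoint] = []
    truncated = False

    for direction in (+1.0, -1.0):
        y = y0.copy()
        t = _tangent_vector(numsys, y, None)
        if t is None:
            truncated = True
            continue
        if t[s] * direction < 0:
            t = -t
        h = initial_step
        fails = 0
        for _ in range(max_points // 2):
            y_pred = y + h * t
            y_new = _newton_correct(numsys, y_pred, t, y_pred, corrector_tol)
            if y_new is None:
                fails += 1
                h *= 0.5
                if fails > 12:
                    truncated = True
                    break
                continue
            fails = 0
            t_new = _tangent_vector(numsys, y_new, t)
            if t_new is None:
                truncated = True
                break
            if t[s] * t_new[s] < 0:  # fold crossed: bisect on tangent signal component
                a, b = y.copy(), y_new.copy()
                ta, tb = t.copy(), t_new.copy()
                for _ in range(60):
                    mid_pred = 0.5 * (a + b)
                    mid = _newton_correct(numsys, mid_pred, ta, mid_pred, corrector_tol)
                    if mid is None:
                        break
                    tm = _tangent_vector(numsys, mid, ta)
                    if tm is None:
                        break
                    if ta[s] * tm[s] < 0:
                        b, tb = mid, tm
                    else:
                        a, ta = mid, tm
                    if np.linalg.norm(b - a) < 1e-11:
                        break
                fold_y = 0.5 * (a + b)
                kind = "max" if ta[s] > 0 else "min"
                folds.append(
                    FoldPoint(signal=float(fold_y[s]), u=fold_y[:s].copy(), kind=kind)
                )
                points.append((float(fold_y[s]), fold_y[:s].copy(), stability(fold_y)))
            points.append((float(y_new[s]), y_new[:s].copy(), stability(y_new)))
            y, t = y_new, t_new
            h = min(h * 1.3, max_step)
            if not (signal_bounds[0] <= y[s] <= signal_bounds[1]):
                break
        else:
            truncated = True

    points.append((float(y0[s]), y0[:s].copy(), stability(y0)))
    points.sort(key=lambda p: p[0])
    branch = [BranchPoint(signal=p[0], u=p[1], stable=p[2]) for p in points]

    # deduplicate folds revisited by the two walk directions (same kind,
    # same signal within resolution), then pair opposite orientations
    folds.sort(key=lambda f: f.signal)
    scale = max(1.0, abs(float(start_signal)))
    unique: list[FoldPoint] = []
    for f in folds:
        if unique and f.kind == unique[-1].kind and abs(
            f.signal - unique[-1].signal
        ) < 1e-9 * scale:
            continue
        unique.append(f)
    folds = unique
    bistable = None
    min_folds = [f.signal for f in folds if f.kind == "min"]
    max_folds = [f.signal for f in folds if f.kind == "max"]
    if min_folds and max_folds:
        lo, hi = min(min_folds), max(max_folds)
        if hi - lo > 1e-9 * scale:
            bistable = (lo, hi)
    return BifurcationDiagram(
        points=branch, folds=folds, bistable_interval=bistable, truncated=truncated
    )


# ---------------------------------------------------------------------------
# Direct simulation (dose-response)
# ---------------------------------------------------------------------------

@dataclass
class DosePoint:
    signal: float
    branch: str              # "low" or "high"
    u: np.ndarray | None
    response: float | None
    converged: bool
    law_consistent: bool = True


@dataclass
class DoseResponse:
    points: list[DosePoint]
    response_name: str

    def branch(self, which: str) -> list[DosePoint]:
        return [p for p in self.points if p.branch == which]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "signal": p.signal,
                    "branch": p.branch,
                    "response": p.response,
                    "converged": p.converged,
                }
                for p in self.points
            ]
        )


def _integrate_to_steady_state(
    numsys: NumericSystem,
    u0: np.ndarray,
    eps: float,
    t_max: float,
    ss_tol: float,
    window: int = 3,
) -> tuple[np.ndarray | None, bool]:
    """Integrate the stiff reduced ODEs until concentrations stop changing.

    The steady-state test accepts when either (a) the max absolute change of
    all independent concentrations between successive checkpoint outputs
    stays below ``ss_tol`` over a trailing window (which avoids declaring
    convergence during a slow transient), or (b) the instantaneous rates at
    the final state are below ``ss_tol`` relative to the solution scale —
    systems with a near-zero eigenvalue crawl along a center manifold and
    would otherwise never satisfy the windowed test.
    """

    def rhs(t: float, u: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            out = numsys.F(np.maximum(u, 0.0), eps)
        return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)

    n_check = 120
    t_eval = np.geomspace(1.0, t_max, n_check)
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        np.asarray(u0, dtype=float),
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        return None, False
    y = sol.y
    diffs = np.max(np.abs(np.diff(y, axis=1)), axis=0)
    tail = diffs[-window:]
    u_end = y[:, -1]
    if np.all(tail < ss_tol):
        return u_end, True
    rate = np.max(np.abs(numsys.F(np.maximum(u_end, 0.0), eps)))
    if rate < ss_tol * max(1.0, float(np.max(np.abs(u_end)))):
        return u_end, True
    return u_end, False


def direct_simulation(
    sys: IndependentSystem,
    k_values: Sequence[float],
    signal_grid: Sequence[float],
    candidate_u: Sequence[float],
    fixed_totals: dict[sp.Symbol, float] | None = None,
    low_factor: float = 0.5,
    high_factor: float = 2.0,
    response_overrides: tuple[float, float] | None = None,
    init_policy: str = "response",
    t_max: float = 1e6,
    ss_tol: float = 1e-6,
) -> DoseResponse:
    """Dose-response by direct integration from low and high starts.

    With ``init_policy="response"`` only the response species is perturbed:
    it starts at ``low_factor`` and ``high_factor`` times its candidate
    value (or at explicit override concentrations) while the other
    independent species start at their candidate values.  With
    ``init_policy="global"`` the low start scales the whole independent
    vector down to 2% of the candidate — probing basins whose switching
    variable is not the response itself (e.g. an autocatalytic seed) — and
    the high start is the candidate state.  Dependent species follow from
    the conservation laws; an equilibrium whose reconstructed dependent
    species go negative is flagged law-inconsistent and excluded from the
    hysteresis verdict.
    """
    if init_policy not in ("response", "global"):
        raise ValueError(f"unknown init_policy {init_policy!r}")
    numsys = NumericSystem(sys, k_values, fixed_totals)
    net = sys.network
    resp_pos = list(sys.independent_symbols).index(sys.response)
    candidate_u = np.asarray(candidate_u, dtype=float)

    def start_values(eps: float) -> tuple[float, float]:
        """Law-consistent low/high initial response concentrations.

        The dependent-species reconstructions are affine in the response
        start value; when they bound it (the response shares a conservation
        law with an eliminated species), the low and high starts are placed
        at 5% and 95% of the feasible interval.  Otherwise the starts are
        ``low_factor`` and ``high_factor`` times the candidate value.
        """
        if response_overrides is not None:
            return response_overrides
        base = candidate_u.copy()
        base[resp_pos] = 0.0
        d0 = numsys.dependent_species(base, eps)
        base[resp_pos] = 1.0
        slope = numsys.dependent_species(base, eps) - d0
        r_lo, r_hi = 0.0, np.inf
        for a, m in zip(d0, slope):
            if m < -1e-12:
                r_hi = min(r_hi, a / -m)
            elif m > 1e-12:
                r_lo = max(r_lo, -a / m)
        if not np.isfinite(r_hi):
            return low_factor * candidate_u[resp_pos], high_factor * candidate_u[resp_pos]
        if r_hi <= r_lo:
            return (max(r_lo, 0.0),) * 2
        width = r_hi - r_lo
        return r_lo + 0.05 * width, r_lo + 0.95 * width

    def starts_for(eps: float) -> list[tuple[str, np.ndarray]]:
        if init_policy == "global":
            return [("low", 0.02 * candidate_u), ("high", candidate_u.copy())]
        low_value, high_value = start_values(eps)
        lo = candidate_u.copy()
        lo[resp_pos] = low_value
        hi = candidate_u.copy()
        hi[resp_pos] = high_value
        return [("low", lo), ("high", hi)]

    points: list[DosePoint] = []
    for eps in signal_grid:
        for branch, u0 in starts_for(float(eps)):
            u_end, ok = _integrate_to_steady_state(numsys, u0, float(eps), t_max, ss_tol)
            if u_end is None:
                points.append(
                    DosePoint(float(eps), branch, None, None, False)
                )
                continue
            dep = numsys.dependent_species(u_end, float(eps))
            law_ok = dep.size == 0 or bool(
                np.all(dep >= -1e-8 * max(1.0, float(np.max(np.abs(dep)))))
            )
            points.append(
                DosePoint(
                    signal=float(eps),
                    branch=branch,
                    u=u_end,
                    response=float(u_end[resp_pos]),
                    converged=ok,
                    law_consistent=law_ok,
                )
            )
    resp_name = net.species[sys.independent_indices[resp_pos]]
    return DoseResponse(points=points, response_name=resp_name)


@dataclass
class HysteresisReport:
    bistable: bool
    inconclusive: bool
    bistable_signals: list[float]
    up_switch: float | None     # signal below which a low start lands high
    down_switch: float | None   # signal above which a high start lands low
    separation: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "bistable": self.bistable,
                "inconclusive": self.inconclusive,
                "bistable_signals": self.bistable_signals,
                "up_switch": self.up_switch,
                "down_switch": self.down_switch,
                "separation": self.separation,
            },
            indent=2,
        )


def detect_hysteresis(
    dr: DoseResponse, separation_tol: float | None = None
) -> HysteresisReport:
    """Compare low-start and high-start equilibria over the signal grid.

    The system is bistable when both sweeps converge on a common signal
    subinterval to equilibria separated by more than ``separation_tol``
    (default: 5% of the overall response range).  The switching thresholds
    are the edges of that subinterval: a low start jumps to the high state
    below ``up_switch``; a high start falls to the low state above
    ``down_switch``.
    """
    low = {p.signal: p for p in dr.branch("low")}
    high = {p.signal: p for p in dr.branch("high")}
    common = sorted(set(low) & set(high))
    usable = [
        e
        for e in common
        if low[e].converged and high[e].converged
        and low[e].law_consistent and high[e].law_consistent
    ]
    if len(usable) < 2:
        return HysteresisReport(
            bistable=False, inconclusive=True, bistable_signals=[],
            up_switch=None, down_switch=None, separation=0.0,
        )
    responses = [low[e].response for e in usable] + [high[e].response for e in usable]
    span = max(responses) - min(responses)
    if separation_tol is None:
        separation_tol = 0.05 * span if span > 0 else 1e-9

    split = [
        e for e in usable if abs(high[e].response - low[e].response) > separation_tol
    ]
    if not split:
        return HysteresisReport(
            bistable=False, inconclusive=False, bistable_signals=[],
            up_switch=None, down_switch=None, separation=0.0,
        )
    sep = max(abs(high[e].response - low[e].response) for e in split)
    return HysteresisReport(
        bistable=True,
        inconclusive=False,
        bistable_signals=split,
        up_switch=min(split),
        down_switch=max(split),
        separation=float(sep),
    )
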