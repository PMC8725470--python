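"""End-to-end bistability detection pipeline.

Runs the full workflow on a reaction network: structure and classification,
conservation laws, independent-system reduction, steady-state
parametrization, multistart saddle search with the Bayesian stopping rule,
saddle-node screening of candidates, and finally continuation and/or
direct simulation to decide bistability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import sympy as sp

from .bifurcation import (
    BifurcationDiagram,
    DoseResponse,
    HysteresisReport,
    NumericSystem,
    SaddleNodeReport,
    check_candidate,
    continue_branch,
    detect_hysteresis,
    direct_simulation,
)
from .conservation import ConservationBasis, conservation_basis
from .network import (
    CRNTMatrices,
    LinkageClassification,
    ReactionNetwork,
    build_crnt_matrices,
    classify_linkage,
    parse_network,
)
from .odes import IndependentSystem, select_independent_odes
from .steady_state import SteadyStateParametrization, solve_steady_state
from .search import (
    Objective,
    SearchConfig,
    SearchResult,
    build_objective_eq4,
    build_objective_eq5,
    run_search,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger("crnswitch")

# exit-status semantics for the CLI
STATUS_BISTABLE = "bistable"
STATUS_NO_SADDLE = "saddle_not_found"
STATUS_NOT_BISTABLE = "saddle_found_not_bistable"


@dataclass
class PipelineConfig:
    """Everything needed for a full run.

    ``model`` is reaction-list text or a path to an SBML file; ``response``
    names the readout species; ``signal`` selects the conservation total
    used as bifurcation parameter (by zero-based law index, or by the tuple
    of species in its support).
    """

    model: str
    response: str
    signal: int | Sequence[str] = 0
    mode: str = "eq5"
    n_starts: int = 50
    seed: int = 0
    c_bounds: tuple[float, float] | list[tuple[float, float]] = (1e-3, 1e2)
    k_bounds: tuple[float, float] | list[tuple[float, float]] = (1e-3, 1e2)
    species_order: Sequence[str] | None = None
    zero_tol: float = 1e-12
    anneal_maxiter: int = 300
    signal_grid_halfwidth: float = 0.20   # fraction of the candidate signal
    signal_grid_points: int = 41
    sim_t_max: float = 1e6
    skip_search_at: dict[str, float] | None = None  # decision vector override
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


@dataclass
class RunReport:
    status: str
    classification: LinkageClassification
    basis: ConservationBasis
    system: IndependentSystem
    parametrization: SteadyStateParametrization | None
    search: SearchResult | None
    saddle_reports: list[SaddleNodeReport] = field(default_factory=list)
    diagram: BifurcationDiagram | None = None
    dose_response: DoseResponse | None = None
    hysteresis: HysteresisReport | None = None

    @property
    def bistable(self) -> bool:
        return self.status == STATUS_BISTABLE

    def summary(self) -> dict:
        out: dict[str, Any] = {
            "status": self.status,
            "uniterminal": self.classification.is_uniterminal,
            "conservation_laws": [
                str(self.basis.law_expression(j)) for j in range(self.basis.lam)
            ],
            "independent_species": [
                self.system.network.species[i]
                for i in self.system.independent_indices
            ],
        }
        if self.search is not None:
            out["best_objective"] = self.search.best_f
            out["confidence_q"] = self.search.q
            out["n_starts_run"] = self.search.n
        if self.diagram is not None:
            out["folds"] = [f.signal for f in self.diagram.folds]
            out["bistable_interval"] = self.diagram.bistable_interval
        if self.hysteresis is not None:
            out["hysteresis"] = json.loads(self.hysteresis.to_json())
        return out


def _expand_bounds(bounds, n) -> list[tuple[float, float]]:
    if isinstance(bounds, (tuple, list)) and len(bounds) == 2 and np.isscalar(bounds[0]):
        return [(float(bounds[0]), float(bounds[1]))] * n
    return [(float(lo), float(hi)) for lo, hi in bounds]


def _step(name: str):
    logger.info("step: %s", name)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full detection workflow; see module docstring."""
    try:
        _step("parse network")
        net = parse_network(cfg.model, species_order=cfg.species_order)
        _step("build CRNT matrices")
        matrices = build_crnt_matrices(net)
        classification = classify_linkage(net)
        _step("conservation laws")
        basis = conservation_basis(matrices, rng_seed=cfg.seed)
        _step("independent ODE system")
        signal = cfg.signal
        if not isinstance(signal, int):
            from .fixtures import signal_total_symbol

            signal = signal_total_symbol(basis, tuple(signal))
        sys = select_independent_odes(matrices, basis, cfg.response, signal=signal)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during structural analysis: {exc}") from exc

    c_bounds = _expand_bounds(cfg.c_bounds, net.n_species)
    k_bounds = _expand_bounds(cfg.k_bounds, net.n_reactions)

    param: SteadyStateParametrization | None = None
    objective: Objective
    _step("steady-state parametrization")
    if cfg.mode == "eq5":
        try:
            param = solve_steady_state(sys)
            objective = build_objective_eq5(
                sys, param, c_bounds=c_bounds, k_bounds=k_bounds
            )
        except Exception:
            logger.warning("parametrized mode failed; falling back to eq4")
            objective = build_objective_eq4(sys, c_bounds=c_bounds, k_bounds=k_bounds)
    else:
        objective = build_objective_eq4(sys, c_bounds=c_bounds, k_bounds=k_bounds)

    search: SearchResult | None = None
    candidates: list[dict] = []
    if cfg.skip_search_at is not None:
        _step("evaluate provided decision vector")
        state = _state_from_decision_vector(net, cfg.skip_search_at)
        candidates.append(state)
    else:
        _step("saddle search")
        scfg = SearchConfig(
            mode=objective.mode,
            n_starts=cfg.n_starts,
            rng_seed=cfg.seed,
            zero_tol=cfg.zero_tol,
            anneal_maxiter=cfg.anneal_maxiter,
        )
        search = run_search(scfg, objective)
        for rec in search.candidates:
            state = objective.reconstruct(rec.x)
            # screen: positive rates and in-bounds concentrations
            if np.any(state["k"] <= 0):
                continue
            if np.any(state["c"] < [b[0] for b in c_bounds]) or np.any(
                state["c"] > [b[1] for b in c_bounds]
            ):
                continue
            candidates.append(state)

    if not candidates:
        return RunReport(
            status=STATUS_NO_SADDLE,
            classification=classification,
            basis=basis,
            system=sys,
            parametrization=param,
            search=search,
        )

    _step("saddle-node screening and bifurcation analysis")
    conc_index = {s: i for i, s in enumerate(net.concentration_symbols)}
    reports: list[SaddleNodeReport] = []
    diagram = dose = hyst = None
    status = STATUS_NOT_BISTABLE
    for state in candidates:
        k_values = state["k"]
        totals = state["totals"]
        if totals is None:
            totals = basis.totals_from_concentrations(state["c"])
        total_map = dict(zip(basis.total_symbols, totals))
        signal_value = float(total_map[sys.signal])
        fixed = {t: float(v) for t, v in total_map.items() if t != sys.signal}
        u = np.array(
            [state["c"][conc_index[s]] for s in sys.independent_symbols]
        )
        numsys = NumericSystem(sys, k_values, fixed)
        rep = check_candidate(numsys, u, signal_value)
        reports.append(rep)
        if rep.verdict == "rejected_multiplicity":
            continue  # codim-2 suspect: not a saddle-node
        lo = signal_value * (1 - cfg.signal_grid_halfwidth)
        hi = signal_value * (1 + cfg.signal_grid_halfwidth)
        try:
            diagram = continue_branch(
                sys, k_values, u, signal_value, (lo, hi), fixed_totals=fixed
            )
        except ValueError:
            diagram = None
        grid = np.linspace(lo, hi, cfg.signal_grid_points)
        for policy in ("response", "global"):
            dose = direct_simulation(
                sys, k_values, grid, u, fixed_totals=fixed,
                init_policy=policy, t_max=cfg.sim_t_max,
            )
            hyst = detect_hysteresis(dose)
            if hyst.bistable:
                break
        diagram_bistable = (
            diagram is not None and diagram.bistable_interval is not None
        )
        if hyst.bistable or diagram_bistable:
            status = STATUS_BISTABLE
            break

    report = RunReport(
        status=status,
        classification=classification,
        basis=basis,
        system=sys,
        parametrization=param,
        search=search,
        saddle_reports=reports,
        diagram=diagram,
        dose_response=dose,
        hysteresis=hyst,
    )
    if cfg.out_dir:
        _write_outputs(report, Path(cfg.out_dir))
    return report


def _state_from_decision_vector(
    net: ReactionNetwork, decision: dict[str, float]
) -> dict:
    """Build a candidate state from named rates and concentrations."""
    k = np.array([decision[str(s)] for s in net.rate_symbols])
    c = np.array([decision[name] for name in net.species])
    return {"k": k, "c": c, "totals": None}


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    (out_dir / "classification.json").write_text(
        report.classification.to_json(report.system.network)
    )
    (out_dir / "conservation_laws.json").write_text(report.basis.to_json())
    (out_dir / "independent_system.json").write_text(report.system.to_json())
    if report.parametrization is not None:
        (out_dir / "parametrization.json").write_text(
            report.parametrization.to_json()
        )
    if report.search is not None:
        (out_dir / "search.json").write_text(report.search.to_json())
    names = [
        report.system.network.species[i]
        for i in report.system.independent_indices
    ]
    if report.diagram is not None:
        report.diagram.to_frame(names).to_csv(
            out_dir / "bifurcation_diagram.csv", index=False
        )
    if report.dose_response is not None:
        report.dose_response.to_frame().to_csv(
            out_dir / "dose_response.csv", index=False
        )
    if report.hysteresis is not None:
        (out_dir / "hysteresis.json").write_text(report.hysteresis.to_json())
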