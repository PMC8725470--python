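"""Saddle-node verification, continuation, and dose-response simulation."""

import numpy as np
import pytest

from crnswitch.bifurcation import (
    NumericSystem,
    check_candidate,
    continue_branch,
    detect_hysteresis,
    direct_simulation,
    saddle_node_check,
)

from conftest import (
    fixed_totals_map,
    independent_values,
    make_normal_form,
    rates_vector,
)


class TestSaddleNodeCheck:
    def test_simple_zero_with_transversality_is_saddle_node(self):
        rep = saddle_node_check(
            np.diag([0.0, -1.0]),
            d_signal=np.array([1.0, 0.0]),
            second_derivative=lambda v: np.array([2.0, 0.0]),
        )
        assert rep.verdict == "saddle_node"
        assert rep.zero_count == 1

    def test_double_zero_rejected_as_codim_two(self):
        rep = saddle_node_check(np.diag([0.0, 0.0]))
        assert rep.verdict == "rejected_multiplicity"
        assert rep.zero_count == 2

    def test_nonsingular_jacobian_rejected(self):
        rep = saddle_node_check(np.diag([-0.5, -1.0]))
        assert rep.verdict == "rejected_multiplicity"
        assert rep.zero_count == 0

    def test_in_range_transversality_vector_rejected(self):
        # d_signal along the nonzero eigendirection lies in range(J)
        rep = saddle_node_check(
            np.diag([0.0, -1.0]),
            d_signal=np.array([0.0, 1.0]),
            second_derivative=lambda v: np.array([2.0, 0.0]),
        )
        assert rep.verdict == "rejected_transversality"

    def test_edelstein_reference_point_is_saddle_node(
        self, edelstein, edelstein_system
    ):
        numsys = NumericSystem(edelstein_system, rates_vector(edelstein))
        u = independent_values(edelstein, edelstein_system)
        rep = check_candidate(numsys, u, edelstein.signal_value)
        assert rep.verdict == "saddle_node"
        others = sorted(rep.eigenvalues.real)[:-1]
        assert all(x < -1e-3 for x in others)

    def test_normal_form_conditions_hold_analytically(self):
        """x' = eps - x^2 at (0, 0): J = [0], F_eps = [1], F_xx(v,v) = [-2]."""
        sys = make_normal_form()
        numsys = NumericSystem(sys, [1.0, 1.0])
        rep = check_candidate(numsys, np.array([0.0]), 0.0)
        assert rep.verdict == "saddle_node"


class TestContinuation:
    def test_normal_form_fold_at_zero(self):
        sys = make_normal_form()
        diag = continue_branch(
            sys, [1.0, 1.0], start_u=[2.0], start_signal=4.0,
            signal_bounds=(-5.0, 5.0),
        )
        assert len(diag.folds) == 1
        assert diag.folds[0].signal == pytest.approx(0.0, abs=1e-6)
        assert diag.bistable_interval is None
        # stability flips exactly at the fold: x > 0 stable, x < 0 unstable
        for p in diag.points:
            if abs(p.u[0]) > 1e-4:
                assert p.stable == (p.u[0] > 0)

    def test_linear_system_has_single_monotone_branch(self):
        """x' = eps - x: the branch x = eps never folds."""
        import sympy as sp

        sys = make_normal_form()
        cX = sys.network.concentration_symbols[0]
        sys.F = sp.ImmutableMatrix([sys.signal - cX])
        sys.__dict__.pop("jacobian", None)  # invalidate the cached Jacobian
        diag = continue_branch(
            sys, [1.0, 1.0], start_u=[1.0], start_signal=1.0,
            signal_bounds=(-3.0, 3.0),
        )
        assert diag.folds == []
        assert all(p.stable for p in diag.points)
        for p in diag.points:
            assert p.u[0] == pytest.approx(p.signal, abs=1e-8)

    def test_edelstein_s_curve_with_two_folds(self, edelstein, edelstein_system):
        diag = continue_branch(
            edelstein_system,
            rates_vector(edelstein),
            independent_values(edelstein, edelstein_system),
            edelstein.signal_value,
            signal_bounds=(7.0, 8.6),
        )
        assert len(diag.folds) == 2
        lo, hi = sorted(f.signal for f in diag.folds)
        assert lo == pytest.approx(7.778340, abs=1e-4)
        assert hi == pytest.approx(7.794893, abs=1e-4)
        assert diag.bistable_interval == pytest.approx((lo, hi))
        # the middle branch between the folds is unstable
        mid = [p for p in diag.points if lo + 1e-4 < p.signal < hi - 1e-4]
        assert any(not p.stable for p in mid)
        # every accepted point is an equilibrium to corrector tolerance
        numsys = NumericSystem(edelstein_system, rates_vector(edelstein))
        for p in diag.points[:: max(1, len(diag.points) // 10)]:
            assert np.linalg.norm(numsys.F(p.u, p.signal)) < 1e-8


@pytest.fixture(scope="module")
def edelstein_dose(edelstein, edelstein_system):
    grid = np.arange(7.5, 8.1001, 0.005)
    return direct_simulation(
        edelstein_system,
        rates_vector(edelstein),
        grid,
        independent_values(edelstein, edelstein_system),
        response_overrides=(0.5, 2.0),
        t_max=65000,
    )


class TestDirectSimulation:
    def test_edelstein_two_equilibrium_levels(self, edelstein_dose):
        """The bistable window shows the two levels read off the reference
        trajectories: lower [A] near 1, upper near 1.7 (the published
        annotation, a figure reading, carries roughly +/-0.1)."""
        hy = detect_hysteresis(edelstein_dose)
        assert hy.bistable
        hi = {p.signal: p.response for p in edelstein_dose.branch("high")}
        lo = {p.signal: p.response for p in edelstein_dose.branch("low")}
        upper = max(hi[e] for e in hy.bistable_signals)
        lower = min(lo[e] for e in hy.bistable_signals)
        assert upper == pytest.approx(1.75, abs=0.1)
        assert lower == pytest.approx(1.0, abs=0.1)

    def test_edelstein_path_dependent_switching(self, edelstein_dose):
        hy = detect_hysteresis(edelstein_dose)
        assert hy.up_switch is not None and hy.down_switch is not None
        assert hy.up_switch < hy.down_switch

    def test_thresholds_agree_with_continuation_folds(
        self, edelstein, edelstein_system, edelstein_dose
    ):
        """Cross-validation: fold signals from continuation match the
        switching thresholds from simulation within grid resolution."""
        diag = continue_branch(
            edelstein_system,
            rates_vector(edelstein),
            independent_values(edelstein, edelstein_system),
            edelstein.signal_value,
            signal_bounds=(7.0, 8.6),
        )
        folds = sorted(f.signal for f in diag.folds)
        hy = detect_hysteresis(edelstein_dose)
        grid_step = 0.005
        assert abs(hy.up_switch - folds[0]) <= 2 * grid_step
        assert abs(hy.down_switch - folds[1]) <= 2 * grid_step

    def test_conservation_respected_at_equilibria(self, edelstein_dose):
        assert all(p.law_consistent for p in edelstein_dose.points if p.converged)

    def test_monostable_relaxation_is_not_bistable(self):
        from crnswitch.conservation import conservation_basis
        from crnswitch.network import build_crnt_matrices, parse_reaction_text
        from crnswitch.odes import select_independent_odes

        net = parse_reaction_text("A <-> B")
        m = build_crnt_matrices(net)
        basis = conservation_basis(m, rng_seed=0)
        sys = select_independent_odes(m, basis, "A")
        grid = np.linspace(0.5, 2.0, 7)
        dr = direct_simulation(
            sys, [1.0, 0.5], grid, [0.5], t_max=1e4
        )
        hy = detect_hysteresis(dr)
        assert not hy.bistable and not hy.inconclusive

    def test_prion_switch_requires_basin_spanning_starts(self, prion, prion_system):
        """The prion motif is a seeding switch: OFF (no active kinase) and
        ON states coexist over a wide range of total substrate."""
        eps0 = prion.signal_value
        grid = np.linspace(0.8 * eps0, 1.2 * eps0, 5)
        fixed = fixed_totals_map(prion, prion_system)
        dr = direct_simulation(
            prion_system,
            rates_vector(prion),
            grid,
            independent_values(prion, prion_system),
            fixed_totals=fixed,
            init_policy="global",
            t_max=3e6,
        )
        hy = detect_hysteresis(dr)
        assert hy.bistable
        assert hy.separation > 50  # ON and OFF differ by >50 conc. units
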