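"""Saddle-search objectives, multistart driver, and the stopping rule."""

import math
from fractions import Fraction

import numpy as np
import pytest
import sympy as sp

from crnswitch.conservation import conservation_basis
from crnswitch.network import build_crnt_matrices, parse_reaction_text
from crnswitch.odes import select_independent_odes
from crnswitch.search import (
    SearchConfig,
    build_objective_eq4,
    build_objective_eq5,
    confidence_level,
    default_bounds,
    neighborhood_count,
    run_search,
)
from crnswitch.steady_state import solve_steady_state

from conftest import rates_vector

WIDE_C = [(1e-3, 1e2)]
WIDE_K = [(1e-3, 1e2)]


def edelstein_x(fixture, param):
    """Decision vector (free rates, concentrations) at the reference point."""
    free = [str(s) for s in param.free_symbols]
    return np.array(
        [fixture.rates[n] for n in free]
        + [fixture.concentrations[s] for s in ("A", "B", "C")]
    )


class TestObjectives:
    def test_eq5_near_zero_at_reference_point(self, edelstein, edelstein_system, edelstein_param):
        obj = build_objective_eq5(
            edelstein_system, edelstein_param, c_bounds=WIDE_C * 3, k_bounds=WIDE_K * 6
        )
        x = edelstein_x(edelstein, edelstein_param)
        state = obj.reconstruct(x)
        # rounding-aware: scaled by the Jacobian magnitude at the point
        J = _numeric_jacobian_at(edelstein_system, state)
        assert obj(x) <= (1e-3 * np.linalg.norm(J)) ** 2
        # derived pivot rates reproduce the reference values
        assert np.allclose(state["ktilde"], [edelstein.rates["k1"], edelstein.rates["k3"]], atol=1e-6)
        assert state["totals"][0] == pytest.approx(7.79489058, abs=1e-8)

    def test_eq4_near_zero_at_prion_reference(self, prion, prion_system):
        obj = build_objective_eq4(
            prion_system, c_bounds=[(1e-3, 1e3)] * 9, k_bounds=[(1e-4, 1e3)] * 14
        )
        x = np.array(
            rates_vector(prion) + [prion.concentrations[s] for s in prion_system.network.species]
        )
        state = obj.reconstruct(x)
        J = _numeric_jacobian_at(prion_system, state)
        assert obj(x) <= (1e-3 * np.linalg.norm(J)) ** 2

    def test_modes_agree_at_parametrized_points(self, edelstein_system, edelstein_param):
        """Eq-4 equals Eq-5 wherever the pivot rates take their closed forms
        (the residual term then vanishes identically)."""
        sys5, param = edelstein_system, edelstein_param
        obj5 = build_objective_eq5(sys5, param, c_bounds=WIDE_C * 3, k_bounds=WIDE_K * 6)
        obj4 = build_objective_eq4(sys5, c_bounds=WIDE_C * 3, k_bounds=WIDE_K * 6)
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 5:
            x5 = np.array([rng.uniform(0.1, 2.0) for _ in range(7)])
            state = obj5.reconstruct(x5)
            if np.any(state["ktilde"] <= 0):
                continue
            x4 = np.concatenate([state["k"], state["c"]])
            assert obj4(x4) == pytest.approx(obj5(x5), rel=1e-9, abs=1e-18)
            checked += 1

    def test_eq5_matches_finite_difference_determinant(
        self, edelstein_system, edelstein_param
    ):
        """det(J)^2 from the symbolic path vs a numeric-differentiation oracle."""
        sys, param = edelstein_system, edelstein_param
        obj = build_objective_eq5(sys, param, c_bounds=WIDE_C * 3, k_bounds=WIDE_K * 6)
        rng = np.random.default_rng(5)
        F_func = sp.lambdify(
            list(sys.network.rate_symbols)
            + list(sys.network.concentration_symbols)
            + [sys.signal],
            list(sys.F),
        )
        checked = 0
        while checked < 5:
            x = np.array([rng.uniform(0.1, 2.0) for _ in range(7)])
            state = obj.reconstruct(x)
            if np.any(state["ktilde"] <= 0):
                continue
            k, c, C1 = state["k"], state["c"], state["totals"][0]

            def F_of_u(u):
                # independent coordinates are (c1, c3); c2 is law-bound
                return np.array(F_func(*k, u[0], C1 - u[1], u[1], C1))

            u0 = np.array([c[0], c[2]])
            h = 1e-7
            J = np.zeros((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                J[:, j] = (F_of_u(u0 + e) - F_of_u(u0 - e)) / (2 * h)
            assert obj(x) == pytest.approx(np.linalg.det(J) ** 2, rel=1e-5)
            checked += 1

    def test_eq4_formula_for_irreversible_decay(self):
        """For A -> B the objective is k1^2 + (k1 c_A)^2: never zero in bounds."""
        net = parse_reaction_text("A -> B")
        m = build_crnt_matrices(net)
        basis = conservation_basis(m, rng_seed=0)
        sys = select_independent_odes(m, basis, "A")
        obj = build_objective_eq4(sys, c_bounds=WIDE_C * 2, k_bounds=WIDE_K * 1)
        k1, cA = 0.7, 1.3
        x = np.array([k1, cA, 0.4])
        assert obj(x) == pytest.approx(k1**2 + (k1 * cA) ** 2)

    def test_default_bounds_reaction_type_inference(self, futile_system):
        c_b, k_b = default_bounds(futile_system)
        net = futile_system.network
        assert all(b == (5e-13, 5e-7) for b in c_b)
        # S + E1 -> E1S is an association
        assert k_b[0] == (1e4, 1e8)
        # E1S -> S + E1 is a dissociation
        assert k_b[1] == (1e-5, 1e-3)
        # E1 -> E2 is unimolecular conversion (catalysis range)
        assert k_b[7] == (1e-3, 1.0)


def _numeric_jacobian_at(sys, state):
    subs = dict(zip(sys.network.rate_symbols, state["k"]))
    subs.update(dict(zip(sys.network.concentration_symbols, state["c"])))
    subs.update(dict(zip(sys.basis.total_symbols, state["totals"])))
    return np.array(sp.Matrix(sys.jacobian).subs(subs), dtype=float)


class TestStoppingRule:
    def test_exact_values_from_bigint_oracle(self):
        """Frozen values computed with exact integer arithmetic:

        q(n,r) = 1 - (n+a+b-1)! (2n+b-r-1)! / ((2n+a+b-1)! (n+b-r-1)!)
        with a=1, b=5:
          q(10,10) = 1 - 15!*14!/(25!*4!)
          q(100,1) = 1 - 105!*203!/(205!*103!) = 1 - (104*105)/(204*205)
        """
        q_10_10 = 1 - Fraction(
            math.factorial(15) * math.factorial(14),
            math.factorial(25) * math.factorial(4),
        )
        assert confidence_level(10, 10) == pytest.approx(float(q_10_10), abs=1e-15)
        q_100_1 = 1 - Fraction(104 * 105, 204 * 205)
        assert confidence_level(100, 1) == pytest.approx(float(q_100_1), abs=1e-15)
        assert confidence_level(100, 1) < confidence_level(100, 100)

    @pytest.mark.parametrize("n", [1, 2, 10, 100, 10_000])
    def test_monotone_in_r_and_bounded(self, n):
        rs = sorted({r for r in (1, 2, n // 2, n) if 1 <= r <= n})
        values = [confidence_level(n, r) for r in rs]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert values == sorted(values)

    @pytest.mark.parametrize("n,r", [(5, 0), (5, 6), (0, 0)])
    def test_invalid_r_rejected(self, n, r):
        with pytest.raises(ValueError):
            confidence_level(n, r)

    def test_neighborhood_examples(self):
        assert neighborhood_count([1.0, 1.05, 2.0], 1.0, 0.10) == 2
        assert neighborhood_count([3.0] * 7, 3.0, 0.10) == 7

    def test_neighborhood_brute_force_recount(self):
        rng = np.random.default_rng(11)
        minima = rng.uniform(0.5, 5.0, size=1000)
        fbest = minima.min()
        eps = 0.10
        expected = sum(1 for f in minima if abs(fbest - f) / fbest <= eps)
        assert neighborhood_count(minima, fbest, eps) == expected

    def test_zero_best_requires_the_q1_branch(self):
        with pytest.raises(ValueError):
            neighborhood_count([0.0, 1.0], 0.0, 0.1)


@pytest.fixture(scope="module")
def edelstein_objective(edelstein_system, edelstein_param):
    return build_objective_eq5(
        edelstein_system, edelstein_param, c_bounds=WIDE_C * 3, k_bounds=WIDE_K * 6
    )


class TestRunSearch:
    def test_same_seed_reproduces_bitwise(self, edelstein_objective):
        cfg = SearchConfig(n_starts=2, rng_seed=42, anneal_maxiter=30)
        r1 = run_search(cfg, edelstein_objective)
        r2 = run_search(cfg, edelstein_objective)
        assert r1.best_f == r2.best_f
        assert np.array_equal(r1.best_x, r2.best_x)
        assert [s.f for s in r1.starts] == [s.f for s in r2.starts]

    def test_finds_saddle_and_sets_q_to_one(self, edelstein_objective):
        cfg = SearchConfig(n_starts=10, rng_seed=0, anneal_maxiter=200)
        res = run_search(cfg, edelstein_objective)
        assert res.best_f <= cfg.zero_tol
        assert res.q == 1.0
        assert res.candidates

    def test_no_saddle_for_irreversible_decay(self):
        """det J = -k1 is bounded away from zero: q is reported instead."""
        net = parse_reaction_text("A -> B")
        m = build_crnt_matrices(net)
        basis = conservation_basis(m, rng_seed=0)
        sys = select_independent_odes(m, basis, "A")
        obj = build_objective_eq4(sys, c_bounds=WIDE_C * 2, k_bounds=[(0.5, 2.0)])
        cfg = SearchConfig(n_starts=6, rng_seed=1, anneal_maxiter=50)
        res = run_search(cfg, obj)
        assert res.best_f >= 0.25  # k1 >= 0.5 so det^2 >= 0.25
        assert not res.candidates
        assert 0.0 <= res.q <= 1.0
        assert res.r >= 1
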