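"""Tests for equilibrium enumeration, reproduction ratio and stability."""

import math

import numpy as np
import pytest

from coopnorms import (
    CommunityState,
    EquilibriumKind,
    StabilityClass,
    crash_analyses,
    crash_invasion_rate,
    enumerate_equilibria,
    fixed_points,
    integrate,
    population_equilibrium,
    reproduction_ratio,
    savvy_coop_equilibria,
    savvy_fraction_eq,
    stability,
)

from conftest import random_params


class TestSavvyFraction:
    def test_equal_rates(self):
        assert savvy_fraction_eq(1.0, 1.0) == pytest.approx(0.5)

    def test_no_outflow(self):
        assert savvy_fraction_eq(0.0, 1.3) == pytest.approx(1.0)

    def test_ratio_formula(self):
        assert savvy_fraction_eq(0.2, 1.0) == pytest.approx(1.0 / 1.2, rel=1e-12)

    def test_no_learning_errors(self):
        with pytest.raises(ValueError, match="learning"):
            savvy_fraction_eq(1.0, 0.0)


class TestSavvyCoopEquilibria:
    def test_vanishing_outflow_recovers_basic_fixed_points(self, coordination_params):
        params = coordination_params.with_(outflow_rate=1e-12)
        roots = [p for p, _ in savvy_coop_equilibria(params)]
        basic = [pt.location for pt in fixed_points(params.norms)]
        assert len(roots) == len(basic)
        assert np.allclose(sorted(roots), sorted(basic), atol=1e-6)

    def test_above_fold_only_high_root(self, coordination_params, p_tilde):
        params = coordination_params.with_(outflow_rate=0.5)  # ratio above the fold
        roots = savvy_coop_equilibria(params)
        assert len(roots) == 1
        assert roots[0][0] == pytest.approx(p_tilde, abs=1e-9)

    def test_small_ratio_three_roots_with_pattern(self, coordination_params):
        params = coordination_params.with_(outflow_rate=0.05)
        roots = savvy_coop_equilibria(params)
        assert len(roots) == 3
        assert [s for _, s in roots] == ["stable", "unstable", "stable"]
        ps = [p for p, _ in roots]
        assert ps == sorted(ps)

    def test_dense_scan_oracle(self, coordination_params):
        params = coordination_params.with_(outflow_rate=0.05)
        y_star = savvy_fraction_eq(params.outflow_rate, params.learning_rate)
        c = params.naive_cooperation
        grid = np.linspace(0.0, params.p_tilde, 200_001)
        g = params.norms.cdf_clipped(y_star * grid + (1 - y_star) * c) - grid
        sign = np.sign(g)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        brute = list(0.5 * (grid[idx] + grid[idx + 1]))
        if abs(g[-1]) < 1e-9:
            brute.append(params.p_tilde)
        # g is O(1e-15) noise right at the naive-belief fixed point; merge
        # any spuriously split brackets.
        merged = []
        for r in sorted(brute):
            if not merged or r - merged[-1] > 1e-4:
                merged.append(r)
        brute = merged
        found = [p for p, _ in savvy_coop_equilibria(params)]
        assert len(found) == len(brute)
        assert np.allclose(sorted(found), sorted(brute), atol=1e-5)


class TestReproductionRatio:
    def test_no_outflow_is_infinite(self, cooperation_params):
        params = cooperation_params.with_(outflow_rate=0.0)
        assert math.isinf(reproduction_ratio(params, 0.1, 0.5))

    def test_linear_in_inflow(self, cooperation_params):
        r1 = reproduction_ratio(cooperation_params, 0.1, 0.5)
        r2 = reproduction_ratio(cooperation_params.with_(inflow_rate=2.0), 0.1, 0.5)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_threshold_decides_community_survival(self, p_tilde):
        # R > 1 at the stable root <=> the community persists from a small seed.
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 10:
            params = random_params(rng, p_tilde)
            eqs = enumerate_equilibria(params)
            mixed = [e for e in eqs if e.kind is EquilibriumKind.MIXED]
            crashes = [e for e in eqs if e.kind is EquilibriumKind.ALL_OUTSIDER_CRASH]
            stable_mixed = [e for e in mixed if e.stability is StabilityClass.STABLE]
            traj = integrate(
                params,
                CommunityState(S=0.99, I=0.01, y=0.0, p=params.naive_cooperation),
                1500.0,
                301,
            )
            I_end = traj.final_state().I
            if stable_mixed and all(not c.attracting for c in crashes):
                assert I_end > 1e-3
                assert all(e.reproduction_ratio > 1.0 for e in stable_mixed)
                checked += 1
            elif not mixed:
                assert I_end < 1e-3
                checked += 1


class TestPopulationEquilibrium:
    def test_sums_to_K(self, cooperation_params):
        roots = savvy_coop_equilibria(cooperation_params)
        y_star = savvy_fraction_eq(
            cooperation_params.outflow_rate, cooperation_params.learning_rate
        )
        p_star = roots[0][0]
        S, I, D = population_equilibrium(cooperation_params, p_star, y_star)
        assert S + I + D == pytest.approx(cooperation_params.K, abs=1e-12)

    def test_large_ratio_limit(self, cooperation_params):
        roots = savvy_coop_equilibria(cooperation_params)
        y_star = savvy_fraction_eq(
            cooperation_params.outflow_rate, cooperation_params.learning_rate
        )
        p_star = roots[0][0]
        big = cooperation_params.with_(inflow_rate=1e6)
        S, I, D = population_equilibrium(big, p_star, y_star)
        assert S == pytest.approx(0.0, abs=1e-5)
        S2, I2, D2 = population_equilibrium(cooperation_params, p_star, y_star)
        assert D / I == pytest.approx(D2 / I2, rel=1e-9)

    def test_subcritical_errors(self, cooperation_params):
        params = cooperation_params.with_(inflow_rate=1e-4)
        roots = savvy_coop_equilibria(params)
        y_star = savvy_fraction_eq(params.outflow_rate, params.learning_rate)
        with pytest.raises(ValueError, match="no interior equilibrium"):
            population_equilibrium(params, roots[0][0], y_star)

    def test_ode_oracle(self, cooperation_params):
        eqs = enumerate_equilibria(cooperation_params)
        target = [
            e for e in eqs
            if e.kind is EquilibriumKind.MIXED and e.stability is StabilityClass.STABLE
        ][0]
        traj = integrate(
            cooperation_params, CommunityState(S=0.5, I=0.5, y=0.3, p=0.3), 2000.0, 201
        )
        f = traj.final_state()
        assert f.S == pytest.approx(target.state.S, abs=1e-6)
        assert f.I == pytest.approx(target.state.I, abs=1e-6)
        assert f.y == pytest.approx(target.state.y, abs=1e-6)
        assert f.p == pytest.approx(target.state.p, abs=1e-6)


class TestEnumerate:
    def test_coordination_has_stable_all_insider(self, coordination_params):
        eqs = enumerate_equilibria(coordination_params)
        highs = [e for e in eqs if e.kind is EquilibriumKind.ALL_INSIDER_HIGH]
        assert len(highs) == 1
        assert highs[0].stability is StabilityClass.MARGINAL_LINE
        assert highs[0].attracting

    def test_cooperation_has_no_all_insider(self, cooperation_params):
        eqs = enumerate_equilibria(cooperation_params)
        assert all(e.kind is not EquilibriumKind.ALL_INSIDER_HIGH for e in eqs)
        kinds = {e.kind for e in eqs}
        assert kinds <= {EquilibriumKind.ALL_OUTSIDER_CRASH, EquilibriumKind.MIXED}

    def test_residuals_vanish(self, cooperation_params):
        from coopnorms.community import _rhs_vec

        for e in enumerate_equilibria(cooperation_params):
            res = _rhs_vec(cooperation_params, e.state.as_array())
            assert np.linalg.norm(res) < 1e-8

    def test_y_p_independent_of_inflow_and_phi(self, cooperation_params):
        base = enumerate_equilibria(cooperation_params)
        base_mixed = sorted(
            (e.state.p, e.state.y) for e in base if e.kind is EquilibriumKind.MIXED
        )
        for inflow in (0.5, 2.0):
            for phi in (0.5, 2.0):
                eqs = enumerate_equilibria(
                    cooperation_params.with_(inflow_rate=inflow, resusceptibility=phi)
                )
                mixed = sorted(
                    (e.state.p, e.state.y) for e in eqs if e.kind is EquilibriumKind.MIXED
                )
                assert np.allclose(mixed, base_mixed, atol=1e-10)


class TestStability:
    def test_rejects_non_equilibrium(self, cooperation_params):
        with pytest.raises(ValueError, match="not an equilibrium"):
            stability(cooperation_params, CommunityState(S=0.5, I=0.3, y=0.5, p=0.5))

    def test_low_root_stable_middle_unstable(self, coordination_params):
        params = coordination_params.with_(outflow_rate=0.05)
        eqs = [
            e for e in enumerate_equilibria(params) if e.kind is EquilibriumKind.MIXED
        ]
        eqs.sort(key=lambda e: e.state.p)
        assert eqs[0].stability is StabilityClass.STABLE
        assert eqs[1].stability is StabilityClass.UNSTABLE

    def test_perturbed_stable_equilibrium_returns(self, cooperation_params):
        eq = [
            e for e in enumerate_equilibria(cooperation_params)
            if e.kind is EquilibriumKind.MIXED and e.stability is StabilityClass.STABLE
        ][0]
        u = eq.state.as_array() + 1e-4 * np.array([1.0, -1.0, 0.5, 0.5])
        traj = integrate(cooperation_params, CommunityState.from_array(u), 500.0, 101)
        assert np.max(np.abs(traj.final_state().as_array() - eq.state.as_array())) < 1e-6

    def test_unstable_equilibrium_departs(self, coordination_params):
        params = coordination_params.with_(outflow_rate=0.05)
        eq = [
            e for e in enumerate_equilibria(params)
            if e.kind is EquilibriumKind.MIXED and e.stability is StabilityClass.UNSTABLE
        ][0]
        from coopnorms.equilibria import jacobian

        u0 = eq.state.as_array()
        direction = np.real(np.linalg.eig(jacobian(params, eq.state))[1][:, 0])
        traj = integrate(
            params, CommunityState.from_array(u0 + 1e-6 * direction), 300.0, 61
        )
        assert np.max(np.abs(traj.final_state().as_array() - u0)) > 1e-3


class TestCrash:
    def test_no_outflow_unstable(self, cooperation_params):
        params = cooperation_params.with_(outflow_rate=0.0)
        analysis = crash_invasion_rate(params)
        assert analysis.rate == pytest.approx(params.inflow_rate, abs=1e-9)
        assert analysis.rate > 0

    def test_no_inflow_stable(self, cooperation_params):
        params = cooperation_params.with_(inflow_rate=0.0)
        analysis = crash_invasion_rate(params)
        assert analysis.rate <= 1e-12

    def test_sign_agrees_with_direct_invasion(self, p_tilde):
        rng = np.random.default_rng(31)
        n_checked = 0
        while n_checked < 8:
            params = random_params(rng, p_tilde)
            analysis = crash_invasion_rate(params)
            if not analysis.converged or abs(analysis.rate) < 1e-3:
                continue
            eps = 1e-6 * params.K
            traj = integrate(
                params,
                CommunityState(
                    S=params.K - eps, I=eps, y=analysis.y_boundary, p=analysis.p_boundary
                ),
                8.0,
                81,
            )
            grew = traj.I[-1] > traj.I[0]
            assert grew == (analysis.rate > 0)
            n_checked += 1

    def test_bistable_boundary_detected(self, cooperation_params, p_tilde):
        # Intermediate inflow: naive invasions grow, savvy-disillusioned
        # boundary states repel nothing (crash locally stable there).
        params = cooperation_params.with_(
            inflow_rate=0.1, outflow_rate=1.0, learning_rate=1.0, resusceptibility=1.0
        )
        analyses = crash_analyses(params)
        rates = sorted(a.rate for a in analyses)
        assert len(analyses) == 2
        assert rates[0] < 0 < rates[1]
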