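import math
from dataclasses import replace

import numpy as np
import pytest

from duplexsis import (
    EpidemicParams,
    MeanFieldConfig,
    MeanFieldState,
    batch_steady_state,
    find_roots,
    rho2_of_rho1,
    run_mf,
    scalar_equation_roots,
    scalar_steady_residual,
    small_resource_residual,
    small_resource_roots,
    steady_state_residuals,
    step_mf,
)


def config(beta=0.02, gamma1=0.08, gamma2=0.08, resource=0.2, k1=30, k2=30, c=1.0):
    return MeanFieldConfig(
        params=EpidemicParams(beta, beta, gamma1, gamma2, resource, c), k1=k1, k2=k2
    )


class TestStepMF:
    def test_disease_free_absorbing(self):
        new = step_mf(MeanFieldState(0.0, 0.0), config())
        assert new == MeanFieldState(0.0, 0.0)

    def test_pure_decay_without_transmission(self):
        cfg = config(beta=0.0, gamma1=0.0, gamma2=0.0, resource=0.4)
        new = step_mf(MeanFieldState(0.1, 0.1), cfg)
        expected = (1 - math.exp(-0.1 / 0.4)) * 0.1
        assert new.rho1 == pytest.approx(expected, abs=1e-14)
        assert new.rho2 == pytest.approx(expected, abs=1e-14)


class TestRunMF:
    def test_zero_initial_gives_trivial_root(self):
        _, root = run_mf(config(), 0.0, 0.0)
        assert root.branch_label == "trivial"
        assert root.rho1_star == 0.0

    def test_si_limit_reaches_full_infection(self):
        _, root = run_mf(config(resource=0.0))
        assert abs(root.rho1_star - 1.0) < 1e-6

    def test_ample_resource_extinguishes_epidemic(self):
        # strong B->A coupling but resource beyond the critical amount
        _, root = run_mf(config(gamma1=1.0, resource=0.6))
        assert root.rho1_star < 1e-6
        assert root.branch_label == "trivial"

    def test_converged_root_satisfies_balance(self):
        for resource in (0.05, 0.1, 0.15):
            _, root = run_mf(config(resource=resource))
            assert abs(root.residual1) < 1e-8
            assert abs(root.residual2) < 1e-8

    def test_layer_swap_symmetry_of_roots(self):
        cfg = config(gamma1=0.3, gamma2=0.08, resource=0.1, k1=30, k2=12)
        swapped = MeanFieldConfig(params=cfg.params.swap_layers(), k1=12, k2=30)
        _, root = run_mf(cfg, 0.1, 0.05)
        _, mirrored = run_mf(swapped, 0.05, 0.1)
        assert abs(root.rho1_star - mirrored.rho2_star) < 1e-14
        assert abs(root.rho2_star - mirrored.rho1_star) < 1e-14


class TestBatchSteadyState:
    def test_scalar_shape_returns_floats(self):
        rho1, rho2, converged, steps = batch_steady_state(config())
        assert isinstance(rho1, float) and isinstance(converged, bool)

    def test_matches_plain_iteration(self):
        cfg = config(gamma1=0.5, resource=0.3)
        _, root = run_mf(cfg)
        rho1, _, converged, _ = batch_steady_state(cfg)
        assert converged
        assert rho1 == pytest.approx(root.rho1_star, abs=1e-7)

    def test_prevalence_nonincreasing_in_resource(self):
        grid = np.linspace(0.0, 1.0, 101)
        for kwargs in ({}, {"gamma1": 0.5}, {"gamma2": 0.4, "gamma1": 0.3}):
            rho1, _, _, _ = batch_steady_state(
                config(**kwargs), overrides={"resource": grid}
            )
            assert np.all(np.diff(rho1) <= 1e-6)

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            batch_steady_state(config(), overrides={"k3": 1})


class TestSteadyStateResiduals:
    def test_origin_balances(self):
        assert steady_state_residuals(0.0, 0.0, config()) == (0.0, 0.0)

    def test_saturated_corner_residual_closed_form(self):
        cfg = config(resource=0.5)
        res1, res2 = steady_state_residuals(1.0, 1.0, cfg)
        assert res1 == pytest.approx(-math.exp(-2.0), abs=1e-14)
        assert res2 == pytest.approx(-math.exp(-2.0), abs=1e-14)


class TestInterLayerMap:
    def test_vanishes_at_origin(self):
        assert rho2_of_rho1(0.0, config()) == 0.0

    def test_small_prevalence_slope(self):
        # with k1*beta1 = 0.6, gamma1 = 0.08 and ample resource the map's
        # slope at the origin is (1 - k1*beta1)/gamma1 = 5.0
        cfg = config(gamma1=0.08, resource=1.0)
        assert rho2_of_rho1(1e-6, cfg) / 1e-6 == pytest.approx(5.0, abs=1e-3)

    def test_substitution_identity(self, rng):
        # substituting rho2 = A(rho1) back into the layer-A balance must
        # cancel exactly, for any c
        for cfg in (config(resource=0.3), config(resource=0.7, c=1.7)):
            rho1 = rng.uniform(1e-6, 0.999, size=1000)
            a = rho2_of_rho1(rho1, cfg)
            ok = (a >= 0) & (a <= 1)
            res_a, _ = steady_state_residuals(rho1[ok], a[ok], cfg)
            assert ok.sum() > 100
            assert np.max(np.abs(res_a)) < 1e-12

    def test_decoupled_layers_rejected(self):
        with pytest.raises(ValueError, match="gamma1"):
            rho2_of_rho1(0.5, config(gamma1=0.0))

    def test_saturated_prevalence_rejected(self):
        with pytest.raises(ValueError, match="rho1"):
            rho2_of_rho1(1.0, config())


class TestScalarEquation:
    def test_out_of_domain_is_nan(self):
        # at tiny resource the admissible window shrinks below any O(1) rho1
        cfg = config(resource=1e-6)
        assert math.isnan(scalar_steady_residual(0.5, cfg))

    def test_symmetric_fixed_point_solves_it(self):
        cfg = config(gamma1=0.3, gamma2=0.3, resource=0.4)
        _, root = run_mf(cfg)
        assert root.rho1_star == pytest.approx(root.rho2_star, abs=1e-9)
        assert abs(scalar_steady_residual(root.rho1_star, cfg)) < 1e-6

    def test_roots_match_dynamical_attractors(self):
        # bistable regime: the scan exposes both the stable endemic branch
        # (the attractor from high initial prevalence) and the unstable
        # branch separating it from extinction
        cfg = config(gamma1=0.5, gamma2=0.08, resource=0.3)
        roots = find_roots(cfg)
        endemic = [r for r in roots if r.branch_label == "endemic"]
        assert len(endemic) >= 2
        _, upper = run_mf(cfg, 0.999, 0.999)
        assert max(r.rho1_star for r in endemic) == pytest.approx(
            upper.rho1_star, abs=1e-6
        )
        for root in roots:
            assert abs(root.residual1) < 1e-8
            assert abs(root.residual2) < 1e-8

    def test_no_transmission_leaves_only_trivial_root(self):
        cfg = config(beta=0.0, gamma1=0.05, gamma2=0.05, resource=0.3)
        roots = find_roots(cfg)
        assert [r.branch_label for r in roots] == ["trivial"]

    def test_si_like_regime_has_saturated_root(self):
        roots = find_roots(config(resource=1e-6))
        assert any(
            r.rho1_star == pytest.approx(1.0, abs=1e-9)
            and r.rho2_star == pytest.approx(1.0, abs=1e-9)
            for r in roots
        )
        _, root = run_mf(config(resource=1e-6))
        assert root.rho1_star == pytest.approx(1.0, abs=1e-6)


class TestSmallResourceLimit:
    def test_origin_is_always_a_root(self):
        assert small_resource_residual(0.0, config()) == 0.0
        assert 0.0 in small_resource_roots(config())

    def test_no_layer_a_transmission_leaves_only_origin(self):
        cfg = config(beta=0.0)
        cfg = MeanFieldConfig(
            params=replace(cfg.params, beta2=0.02), k1=cfg.k1, k2=cfg.k2
        )
        assert small_resource_roots(cfg) == [0.0]

    def test_nontrivial_root_regression(self):
        # a sparse layer B with strong A->B coupling admits a non-zero root
        cfg = MeanFieldConfig(
            params=EpidemicParams(0.02, 0.02, 0.08, 0.27, 0.5), k1=30, k2=2
        )
        roots = small_resource_roots(cfg)
        assert len(roots) == 2
        assert roots[1] == pytest.approx(0.479544, abs=1e-5)
        assert abs(small_resource_residual(roots[1], cfg)) < 1e-10

    def test_decoupled_configuration_rejected(self):
        with pytest.raises(ValueError, match="gamma1"):
            small_resource_roots(config(gamma1=0.0))

    def test_limit_consistency_with_full_equation(self):
        # as R -> 0 the full scalar equation's roots collapse toward the
        # roots of the vanishing-resource reduction (only the origin at
        # these parameters); a log-spaced grid resolves the O(R) window
        grid = np.geomspace(1e-9, 1 - 1e-6, 4000)
        limit_roots = np.array(small_resource_roots(config()))
        gaps = []
        for resource in (1e-4, 1e-5):
            roots = scalar_equation_roots(config(resource=resource), grid=grid)
            assert roots, "expected a root in the O(R) window"
            gaps.append(
                max(np.min(np.abs(limit_roots - r)) for r in roots)
            )
        assert gaps[0] < 1e-2
        assert gaps[1] < gaps[0]
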