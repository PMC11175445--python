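"""Univariable MR estimators: worked values, oracles, and recovery."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (
    AnalysisError,
    SimulationConfig,
    harmonize,
    ivw,
    mr_egger,
    select_instruments,
    simulate_triplet,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from tests.conftest import make_hset


def _random_hset(rng, k=8):
    bx = rng.normal(0.1, 0.05, k)
    bx[np.abs(bx) < 0.01] = 0.02
    by = rng.normal(0.02, 0.01, k)
    se_by = rng.uniform(0.003, 0.02, k)
    return make_hset(bx, by, se_by, se_bx=rng.uniform(0.001, 0.01, k))


class TestWaldRatio:
    def test_delta_method_hand_value(self):
        est = wald_ratio(0.1, 0.02, 0.004)
        assert est.beta == pytest.approx(0.2, rel=1e-12)
        assert est.se == pytest.approx(0.04, rel=1e-12)

    def test_null_outcome_effect(self):
        est = wald_ratio(0.1, 0.0, 0.004)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_sign_symmetry(self):
        est = wald_ratio(-0.1, -0.02, 0.004)
        assert est.beta == pytest.approx(0.2, rel=1e-12)

    def test_null_instrument_errors(self):
        with pytest.raises(AnalysisError, match="null instrument"):
            wald_ratio(0.0, 0.02, 0.004)


class TestIVW:
    def test_two_snp_worked_instance(self, hset_2snp):
        # weights 0.1²/0.004² = 625 and 0.2²/0.004² = 2500;
        # beta = (625·0.2 + 2500·0.15)/3125 = 0.16; fixed se = 3125^-1/2
        fe = ivw(hset_2snp, "fixed")
        assert fe.beta == pytest.approx(0.16, rel=1e-10)
        assert fe.se == pytest.approx(3125**-0.5, rel=1e-10)

    def test_random_effects_inflation(self, hset_2snp):
        # Q = 625·0.04² + 2500·0.01² = 1.25 → inflation √(1.25/1)
        re = ivw(hset_2snp, "random")
        assert re.se == pytest.approx(3125**-0.5 * np.sqrt(1.25), rel=1e-10)
        assert re.beta == pytest.approx(0.16, rel=1e-10)

    def test_homogeneous_ratios_fixed_equals_random(self):
        h = make_hset([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], 0.005)
        fe, re = ivw(h, "fixed"), ivw(h, "random")
        assert fe.beta == pytest.approx(0.3, rel=1e-12)
        assert re.se == pytest.approx(fe.se, rel=1e-12)  # Q = 0 → floor at 1

    def test_single_snp_rejected(self):
        h = make_hset([0.1], [0.02], 0.004)
        with pytest.raises(AnalysisError, match="wald_ratio"):
            ivw(h)

    def test_duplicated_snp_reduces_to_wald_ratio(self):
        h = make_hset([0.1, 0.1], [0.02, 0.02], 0.004)
        assert ivw(h, "fixed").beta == pytest.approx(wald_ratio(0.1, 0.02, 0.004).beta, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_wls_through_origin_oracle(self, seed):
        """IVW beta equals the weighted normal-equations slope of by on bx."""
        rng = np.random.default_rng(seed)
        h = _random_hset(rng)
        fit = sm.WLS(h.beta_outcome, h.bx, weights=1.0 / h.se_outcome**2).fit()
        assert ivw(h, "fixed").beta == pytest.approx(fit.params[0], rel=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        h = _random_hset(rng)
        perm = rng.permutation(h.k)
        assert ivw(h.subset(perm)).beta == pytest.approx(ivw(h).beta, rel=1e-12)
        assert ivw(h.subset(perm)).se == pytest.approx(ivw(h).se, rel=1e-12)


class TestEgger:
    def test_three_snp_worked_instance(self, hset_3snp):
        est = mr_egger(hset_3snp)
        assert est.beta == pytest.approx(0.2, rel=1e-10)
        assert est.intercept == pytest.approx(0.01, rel=1e-10)

    def test_proportional_data_zero_intercept(self):
        h = make_hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], 0.01)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.5, rel=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self, hset_3snp):
        flipped = make_hset([-0.1, 0.2, -0.3], [-0.03, 0.05, -0.07], 0.01)
        a, b = mr_egger(hset_3snp), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_zero_slope_variance_errors(self):
        h = make_hset([0.1, 0.1, 0.1], [0.02, 0.03, 0.04], 0.01)
        with pytest.raises(AnalysisError, match="unidentifiable"):
            mr_egger(h)

    def test_too_few_snps_errors(self, hset_2snp):
        with pytest.raises(AnalysisError, match="k ≥ 3"):
            mr_egger(hset_2snp)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_wls_with_intercept_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = _random_hset(rng)
        bx = np.abs(h.bx)
        by = h.beta_outcome * np.sign(h.bx)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / h.se_outcome**2).fit()
        est = mr_egger(h)
        assert est.intercept == pytest.approx(fit.params[0], rel=1e-9, abs=1e-12)
        assert est.beta == pytest.approx(fit.params[1], rel=1e-9)

    def test_zero_intercept_oracle_refit_reproduces_ivw(self):
        """Constraining the Egger intercept to 0 must give the IVW slope."""
        rng = np.random.default_rng(42)
        h = _random_hset(rng)
        fit = sm.WLS(h.beta_outcome, h.bx, weights=1.0 / h.se_outcome**2).fit()
        assert fit.params[0] == pytest.approx(ivw(h, "fixed").beta, rel=1e-10)


class TestWeightedMedian:
    def test_equal_weights_symmetric(self):
        assert weighted_median_point(np.array([0.1, 0.2, 0.3]),
                                     np.ones(3) / 3) == pytest.approx(0.2, rel=1e-12)

    def test_unequal_weight_interpolation(self):
        # p-positions (0.3, 0.7, 0.9); interpolate at 0.5 → 0.15
        assert weighted_median_point(np.array([0.1, 0.2, 0.3]),
                                     np.array([0.6, 0.2, 0.2])) == pytest.approx(0.15, rel=1e-12)

    def test_degenerate_distribution(self):
        h = make_hset([0.1, 0.2, 0.3], [0.02, 0.04, 0.06], 1e-8, se_bx=1e-10)
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, rel=1e-10)
        assert est.se < 1e-6  # bootstrap variance vanishes with the SEs

    def test_requires_seed(self, hset_3snp):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(hset_3snp, n_boot=10)

    def test_seeded_bootstrap_reproducible(self, hset_3snp):
        a = weighted_median(hset_3snp, n_boot=100, seed=7)
        b = weighted_median(hset_3snp, n_boot=100, seed=7)
        assert a.se == b.se

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        h = _random_hset(rng)
        perm = rng.permutation(h.k)
        a = weighted_median(h, n_boot=1, seed=3)
        b = weighted_median(h.subset(perm), n_boot=1, seed=3)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)


class TestEstimateScales:
    def test_exponentiated_ci_brackets_point(self, hset_2snp):
        est = ivw(hset_2snp)
        assert est.or_low < est.or_point < est.or_high
        assert est.or_point == pytest.approx(np.exp(est.beta), rel=1e-15)


class TestSimulationRecovery:
    def test_null_and_nonnull_parameter_recovery(self):
        """Mean IVW estimate over replicates recovers the true causal effect."""
        for truth in (0.0, 0.1):
            estimates = []
            for s in range(60):
                cfg = SimulationConfig(j_snps=50, j_snps_mediator=0, theta_xm=0.0,
                                       theta_my=0.0, theta_xy_direct=truth, seed=10_000 + s)
                trip = simulate_triplet(cfg)
                inst = select_instruments(trip.exposure, one_per_block=True)
                h = harmonize(inst, trip.outcome)
                estimates.append(ivw(h).beta)
            mean = np.mean(estimates)
            mc = 3 * np.std(estimates, ddof=1) / np.sqrt(len(estimates))
            assert abs(mean - truth) < max(mc, 0.005)
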