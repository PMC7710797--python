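import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_h
from mr2s import (DataError, EstimationError, Pleiotropy, SyntheticTruth,
                  generate_harmonized, ivw, max_likelihood, mr_egger, mr_raps,
                  wald_ratio, weighted_median)


def _flip(h, mask):
    """Re-orient a subset of SNPs: negate both effects (allele relabelling)."""
    h2 = h.subset(np.ones(h.k, dtype=bool))
    sign = np.where(mask, -1.0, 1.0)
    h2.gamma = h.gamma * sign
    h2.Gamma = h.Gamma * sign
    return h2


class TestWaldRatio:
    def test_arithmetic(self):
        h = make_h(gamma=[0.1], Gamma=[0.02], sigma_y=0.01)
        r = wald_ratio(h)
        assert r.beta[0] == pytest.approx(0.2)
        assert r.se[0] == pytest.approx(0.1)
        assert r.w[0] == pytest.approx(100.0)

    def test_zero_outcome_effect(self):
        h = make_h(gamma=[0.1], Gamma=[0.0])
        assert wald_ratio(h).beta[0] == 0.0

    def test_orientation_flip_leaves_ratio_unchanged(self):
        h = make_h(gamma=[-0.1], Gamma=[0.02])
        assert wald_ratio(h).beta[0] == pytest.approx(-0.2)
        h2 = make_h(gamma=[0.1], Gamma=[-0.02])
        assert wald_ratio(h2).beta[0] == pytest.approx(wald_ratio(h).beta[0])

    def test_zero_gamma_excluded_with_warning(self):
        h = make_h(gamma=[0.1, 0.0], Gamma=[0.02, 0.01])
        with pytest.warns(UserWarning):
            r = wald_ratio(h)
        assert len(r.beta) == 1


class TestIVW:
    def test_closed_form_weighted_mean(self, toy3):
        est = ivw(toy3)
        assert est.beta == pytest.approx(0.65 / 3, abs=1e-9)
        # Q/(k-1) < 1 so the multiplicative scale floors at 1 (fixed SE)
        assert est.se == pytest.approx(300 ** -0.5, abs=1e-9)
        assert est.extra["se_scale"] == 1.0

    def test_identical_ratios_return_that_ratio(self):
        h = make_h(gamma=[0.1, 0.2, 0.4], Gamma=[0.03, 0.06, 0.12])
        est = ivw(h)
        assert est.beta == pytest.approx(0.3)
        assert est.extra["Q"] == pytest.approx(0.0, abs=1e-12)

    def test_two_identical_snps_equal_common_ratio(self):
        h = make_h(gamma=[0.1, 0.1], Gamma=[0.02, 0.02])
        assert ivw(h).beta == pytest.approx(0.2)

    def test_single_snp_rejected(self):
        h = make_h(gamma=[0.1], Gamma=[0.02])
        with pytest.raises(DataError, match="Wald"):
            ivw(h)

    def test_multiplicative_se_never_below_fixed(self):
        h = generate_harmonized(SyntheticTruth(beta_true=0.1, seed=42,
                                               pleiotropy=Pleiotropy("balanced", tau=0.02)))
        assert ivw(h, "multiplicative").se >= ivw(h, "fixed").se

    def test_equals_wls_through_origin(self):
        """IVW is algebraically weighted least squares of Γ on γ through the
        origin with weights 1/σ_Y² (checked numerically)."""
        h = generate_harmonized(SyntheticTruth(beta_true=0.2, seed=9))
        w = 1.0 / h.sigma_y**2
        wls = float(np.sum(w * h.gamma * h.Gamma) / np.sum(w * h.gamma**2))
        assert ivw(h).beta == pytest.approx(wls, rel=1e-12)


class TestEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.1, 0.15, 0.2, 0.25])
        h = make_h(gamma=g, Gamma=0.01 + 0.3 * g)
        est, pl = mr_egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-9)
        assert pl.intercept == pytest.approx(0.01, abs=1e-9)

    def test_through_origin_hook_reproduces_ivw(self):
        g = np.array([0.1, 0.15, 0.2, 0.25])
        h = make_h(gamma=g, Gamma=[0.02, 0.05, 0.05, 0.08])
        est, _ = mr_egger(h, _fit_intercept=False)
        assert est.beta == pytest.approx(ivw(h, re_mode="fixed").beta, rel=1e-12)

    def test_singular_design_raises(self, toy3):
        with pytest.raises(EstimationError):
            mr_egger(toy3)  # all gamma identical: slope/intercept unidentifiable

    def test_directional_pleiotropy_intercept_recovery(self):
        """Over replicates with mean direct effect 0.02, the intercept's mean
        estimate recovers 0.02 within Monte-Carlo error."""
        intercepts = []
        for s in range(500):
            truth = SyntheticTruth(beta_true=0.2, seed=20_000 + s,
                                   pleiotropy=Pleiotropy("directional", mu=0.02,
                                                         tau=0.01))
            intercepts.append(mr_egger(generate_harmonized(truth))[1].intercept)
        b0 = np.asarray(intercepts)
        mcse = b0.std(ddof=1) / math.sqrt(len(b0))
        assert abs(b0.mean() - 0.02) < 3 * mcse


class TestWeightedMedian:
    def test_equal_weight_interpolation_grid(self, toy3):
        # ordered ratios (0.2, 0.2, 0.25) at cumulative weights (1/6, 1/2, 5/6):
        # p = 0.5 lands exactly on the middle order statistic
        est = weighted_median(toy3, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_all_equal_ratios(self):
        h = make_h(gamma=[0.1, 0.2, 0.4], Gamma=[0.03, 0.06, 0.12],
                   sigma_x=1e-8, sigma_y=1e-7)
        est = weighted_median(h, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 1e-4

    def test_robust_to_minority_invalid_instruments(self):
        """With 4 of 10 instruments carrying large (sign-mixed) direct
        effects, the weighted median stays near the truth while IVW on the
        same dataset is pulled away."""
        truth = SyntheticTruth(
            beta_true=0.2, k=10, seed=77,
            pleiotropy=Pleiotropy("outlier", indices=(0, 1, 2, 3),
                                  magnitudes=(0.1, -0.1, 0.12, -0.08)))
        h = generate_harmonized(truth)
        wm = weighted_median(h, seed=2)
        est_ivw = ivw(h)
        assert abs(wm.beta - 0.2) < abs(est_ivw.beta - 0.2)
        assert abs(wm.beta - 0.2) < 3 * wm.se

    def test_bootstrap_se_reproducible(self, toy3):
        a = weighted_median(toy3, seed=11)
        b = weighted_median(toy3, seed=11)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_exact_recovery_noise_free(self):
        g = np.array([0.1, 0.15, 0.2])
        h = make_h(gamma=g, Gamma=0.3 * g, sigma_x=1e-8, sigma_y=0.01)
        assert max_likelihood(h).beta == pytest.approx(0.3, abs=1e-6)

    def test_sigma_x_zero_limit_equals_ivw(self):
        h = generate_harmonized(SyntheticTruth(beta_true=0.2, seed=5))
        h.sigma_x = np.full(h.k, 1e-6)
        assert max_likelihood(h).beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-5)

    def test_against_grid_search_oracle(self, toy3):
        def neg2ll(beta):
            v = toy3.sigma_y**2 + beta**2 * toy3.sigma_x**2
            return float(np.sum((toy3.Gamma - beta * toy3.gamma) ** 2 / v))

        grid = np.linspace(0.1, 0.35, 20001)
        oracle = grid[np.argmin([neg2ll(b) for b in grid])]
        est = max_likelihood(toy3)
        assert est.beta == pytest.approx(oracle, abs=1e-3)
        assert abs(est.beta - 0.65 / 3) < 0.01


class TestRaps:
    def test_sigma_x_zero_equals_ivw(self, toy3):
        assert mr_raps(toy3).beta == pytest.approx(ivw(toy3, "fixed").beta, abs=1e-7)

    def test_exact_fit(self):
        g = np.array([0.1, 0.15, 0.2])
        h = make_h(gamma=g, Gamma=0.3 * g, sigma_x=1e-8)
        est = mr_raps(h, overdispersion=True)
        assert est.beta == pytest.approx(0.3, abs=1e-6)
        assert est.extra["tau2"] == pytest.approx(0.0, abs=1e-8)

    def test_less_biased_than_ivw_with_weak_instruments(self):
        """Mean F ≈ 15–25: exposure measurement error attenuates IVW toward
        zero; the profile score corrects it."""
        est_i, est_r = [], []
        for s in range(300):
            truth = SyntheticTruth(beta_true=0.1, seed=40_000 + s,
                                   gamma_sd=0.045, f_floor=5)
            h = generate_harmonized(truth)
            est_i.append(ivw(h).beta)
            est_r.append(mr_raps(h).beta)
        assert abs(np.mean(est_r) - 0.1) < abs(np.mean(est_i) - 0.1)
        mcse = np.std(est_r, ddof=1) / math.sqrt(len(est_r))
        assert abs(np.mean(est_r) - 0.1) < 3 * mcse


class TestSharedContracts:
    def test_or_and_ci_derive_from_beta_and_se(self, toy3):
        for est in (ivw(toy3), weighted_median(toy3, seed=3), mr_raps(toy3),
                    max_likelihood(toy3)):
            assert est.or_ == pytest.approx(math.exp(est.beta), rel=1e-12)
            assert est.ci_low < est.or_ < est.ci_high

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**20))
    def test_orientation_flip_invariance(self, seed):
        h = generate_harmonized(SyntheticTruth(beta_true=0.15, k=8, seed=seed % 9973))
        rng = np.random.default_rng(seed)
        mask = rng.random(h.k) < 0.5
        h2 = _flip(h, mask)
        assert ivw(h2).beta == pytest.approx(ivw(h).beta, rel=1e-9)
        assert mr_raps(h2).beta == pytest.approx(mr_raps(h).beta, rel=1e-6)
        assert max_likelihood(h2).beta == pytest.approx(max_likelihood(h).beta, abs=1e-6)
        # Egger canonicalizes orientation internally
        assert mr_egger(h2)[0].beta == pytest.approx(mr_egger(h)[0].beta, rel=1e-9)
        assert weighted_median(h2, seed=1).beta == pytest.approx(
            weighted_median(h, seed=1).beta, rel=1e-9)

    def test_estimators_agree_on_clean_strong_data(self):
        h = generate_harmonized(SyntheticTruth(beta_true=0.2, seed=314))
        ests = [ivw(h), mr_egger(h)[0], weighted_median(h, seed=4),
                max_likelihood(h), mr_raps(h)]
        for a in ests:
            for b in ests:
                assert abs(a.beta - b.beta) <= 2 * max(a.se, b.se)
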