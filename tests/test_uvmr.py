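"""Univariable estimators: algebraic identities, oracles and conversions."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate, stats as sps

from mrmediate.estimators import (
    beta_to_or,
    egger,
    ivw,
    mode_estimators,
    p_from_z,
    run_all_methods,
    se_from_ci,
    wald_ratio,
    weighted_median,
)
from mrmediate.instruments import InsufficientInstrumentsError
from mrmediate.simulate import ChainSimConfig, simulate_chain

from conftest import harmonize_all, make_h, random_h


class TestWaldRatio:
    def test_direct_arithmetic(self):
        est = wald_ratio(0.1, 0.02, 0.2, 0.05)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_null_numerator(self):
        est = wald_ratio(0.1, 0.02, 0.0, 0.05)
        assert est.beta == 0.0 and est.pvalue == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.02, 0.2, 0.05)

    @pytest.mark.parametrize("bx,sx,by,sy", [
        (1.0, 0.05, 0.5, 0.1), (0.2, 0.015, 0.1, 0.03), (-0.5, 0.04, 0.15, 0.06)])
    def test_first_order_se_close_to_second_order(self, bx, sx, by, sy):
        """With |beta_x|/se_x > 10 the simple SE is within 5% of the delta rule."""
        assert abs(bx) / sx > 10
        first = wald_ratio(bx, sx, by, sy).se
        second = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        assert abs(first - second) / second < 0.05


class TestIVW:
    def test_requires_two_instruments(self):
        h = make_h([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)

    def test_symmetric_two_snp_case(self):
        h = make_h([0.1, 0.1], [0.01, 0.01], [0.1, 0.3], [0.05, 0.05])
        assert ivw(h, model="fixed").beta == pytest.approx(2.0, rel=1e-12)

    def test_matches_wls_oracle(self):
        h = random_h(20, seed=2)
        est = ivw(h, model="fixed")
        fit = sm.WLS(h.beta_y, h.beta_x[:, None], weights=1.0 / h.se_y**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), abs=1e-10)

    def test_equals_weighted_mean_of_wald_ratios(self):
        """Fixed IVW == inverse-variance mean of ratios with weights bx²/se_y²."""
        h = random_h(25, seed=3)
        theta = h.beta_y / h.beta_x
        w = h.beta_x**2 / h.se_y**2
        assert ivw(h, model="fixed").beta == pytest.approx(
            float(np.sum(w * theta) / np.sum(w)), abs=1e-10)

    def test_random_effects_never_deflate(self):
        h = random_h(15, seed=4)
        assert ivw(h, model="multiplicative_random_effects").se >= \
            ivw(h, model="fixed").se

    def test_auto_switches_under_heterogeneity(self):
        rng = np.random.default_rng(6)
        bx = rng.uniform(0.1, 0.3, 12)
        by = 0.5 * bx + rng.normal(0, 0.2, 12)  # gross extra scatter
        h = make_h(bx, np.full(12, 0.01), by, np.full(12, 0.01))
        assert ivw(h).model_note == "multiplicative_random_effects"


class TestEgger:
    def test_matches_wls_oracle(self):
        h = random_h(20, seed=7)
        est = egger(h)
        sign = np.where(h.beta_x < 0, -1.0, 1.0)
        X = sm.add_constant(sign * h.beta_x)
        fit = sm.WLS(sign * h.beta_y, X, weights=1.0 / h.se_y**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_outcome_shift_moves_intercept_only(self):
        h = random_h(15, seed=8)
        h_pos = h.subset(h.beta_x > 0)  # orientation is identity here
        shifted = make_h(h_pos.beta_x, h_pos.se_x, h_pos.beta_y + 0.07, h_pos.se_y)
        a, b = egger(h_pos), egger(shifted)
        assert b.beta == pytest.approx(a.beta, abs=1e-10)
        assert b.extra["intercept"] == pytest.approx(
            a.extra["intercept"] + 0.07, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_h([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        h = make_h([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.9], [0.05] * 3)
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(2.0)

    def test_seed_reproducibility(self):
        h = random_h(10, seed=9)
        a = weighted_median(h, n_boot=200, seed=5)
        b = weighted_median(h, n_boot=200, seed=5)
        assert a.se == b.se

    def test_robust_to_minority_invalid_instruments(self):
        """With 30% grossly pleiotropic SNPs the median beats IVW most of the time."""
        wins = 0
        reps = 60
        for s in range(reps):
            cfg = ChainSimConfig(n_snps=30, n_mediator_snps=0, prop_invalid=0.3,
                                 pleiotropy_mean=0.2, pleiotropy_sd=0.05,
                                 seed=5000 + s)
            exposure, _, outcome, truth = simulate_chain(cfg)
            h = harmonize_all(exposure, outcome)
            err_med = abs(weighted_median(h, n_boot=50, seed=s).beta
                          - truth.beta_total_true)
            err_ivw = abs(ivw(h, model="fixed").beta - truth.beta_total_true)
            wins += err_med < err_ivw
        assert wins / reps >= 0.8


class TestModeEstimators:
    def test_point_mass(self):
        h = make_h([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.02] * 3)
        for variant in ("simple", "weighted"):
            est = mode_estimators(h, variant, n_boot=50, seed=2)
            assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_majority_cluster_beats_outlier(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.1, 0.3, 15)
        by = 2.0 * bx + rng.normal(0, 0.005, 15)
        by[0] = 50.0 * bx[0]
        h = make_h(bx, np.full(15, 0.005), by, np.full(15, 0.005))
        for variant in ("simple", "weighted"):
            est = mode_estimators(h, variant, n_boot=50, seed=7)
            assert abs(est.beta - 2.0) < 0.2

    def test_seed_reproducibility(self):
        h = random_h(10, seed=10)
        assert mode_estimators(h, "weighted", n_boot=100, seed=3).se == \
            mode_estimators(h, "weighted", n_boot=100, seed=3).se


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [2.0, 0.5, -1.5])
    def test_all_estimators_rescale(self, c):
        h = random_h(12, seed=12)
        hs = make_h(c * h.beta_x, abs(c) * h.se_x, h.beta_y, h.se_y)
        assert ivw(hs, model="fixed").beta == pytest.approx(
            ivw(h, model="fixed").beta / c, rel=1e-9)
        assert weighted_median(hs, n_boot=10, seed=1).beta == pytest.approx(
            weighted_median(h, n_boot=10, seed=1).beta / c, rel=1e-9)
        if c > 0:  # orientation makes egger invariant only up to sign handling
            assert egger(hs).beta == pytest.approx(egger(h).beta / c, rel=1e-9)


class TestConversions:
    @pytest.mark.parametrize("beta,se,or_str,lo_str,hi_str", [
        (-1.046, 0.338, "0.35", "0.18", "0.68"),
        (0.0, 1.0, "1.00", "0.14", "7.10"),
    ])
    def test_or_ci_display(self, beta, se, or_str, lo_str, hi_str):
        or_v, lo, hi = beta_to_or(beta, se)
        assert f"{or_v:.2f}" == or_str
        assert f"{lo:.2f}" == lo_str and f"{hi:.2f}" == hi_str

    def test_p_from_z_reported_value(self):
        assert p_from_z(-1.046, 0.338) == pytest.approx(1.97e-3, rel=5e-3)
        assert p_from_z(0.0, 1.0) == 1.0

    def test_p_from_z_matches_quadrature(self):
        for z in (0.5, 1.96, 3.1):
            tail, _ = integrate.quad(sps.norm.pdf, z, np.inf)
            assert p_from_z(z, 1.0) == pytest.approx(2 * tail, abs=1e-10)

    def test_se_from_ci_values(self):
        assert se_from_ci(0.002, 0.426) == pytest.approx(0.424 / 3.92, rel=1e-12)
        assert se_from_ci(-1.96, 1.96) == pytest.approx(1.0, rel=1e-12)

    def test_or_ci_inverts_to_se(self):
        _, lo, hi = beta_to_or(0.37, 0.121)
        assert se_from_ci(np.log(lo), np.log(hi)) == pytest.approx(0.121, abs=1e-12)


class TestRunAllMethods:
    def test_single_snp_uses_wald(self):
        h = make_h([0.1], [0.01], [0.05], [0.02])
        out = run_all_methods(h)
        assert [e.method for e in out] == ["wald_ratio"]

    def test_five_methods_consistent_signs_on_valid_data(self):
        cfg = ChainSimConfig(n_snps=50, n_mediator_snps=0, seed=3)
        exposure, _, outcome, _ = simulate_chain(cfg)
        h = harmonize_all(exposure, outcome)
        out = run_all_methods(h, seed=3)
        assert [e.method for e in out] == \
            ["ivw", "egger", "weighted_median", "weighted_mode", "simple_mode"]
        assert len({np.sign(e.beta) for e in out}) == 1

    def test_deterministic_given_seed(self):
        h = random_h(10, seed=14)
        a = run_all_methods(h, seed=9)
        b = run_all_methods(h, seed=9)
        assert [(e.method, e.beta, e.se) for e in a] == \
            [(e.method, e.beta, e.se) for e in b]
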