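"""Multivariable MR and the two-step mediation decomposition."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrmediate.estimators import ivw
from mrmediate.instruments import (
    InstrumentSet,
    InsufficientInstrumentsError,
    select_by_pvalue,
)
from mrmediate.mvmr import (
    CollinearityError,
    MVHarmonizedSet,
    TwoStepConfig,
    mediation_decompose,
    mvmr_egger,
    mvmr_harmonize,
    mvmr_ivw,
    mvmr_median,
    run_two_step,
)
from mrmediate.simulate import ChainSimConfig, simulate_chain

from conftest import make_h


def _mv(k=30, m=2, seed=0, coefs=(0.3, -0.5), contaminate=0.0):
    """Direct matrix-level MVMR fixture with known coefficients."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.3, (k, m)) * rng.choice([-1, 1], (k, m))
    sx = np.full((k, m), 0.005)
    sy = rng.uniform(0.01, 0.03, k)
    by = bx @ np.asarray(coefs[:m]) + rng.normal(0, sy)
    if contaminate:
        n_bad = int(round(contaminate * k))
        by[:n_bad] += 1.0
    return MVHarmonizedSet("outcome", [f"exp{i}" for i in range(m)],
                           np.array([f"rs{i+1}" for i in range(k)], dtype=object),
                           bx, sx, by, sy)


class TestMVMRHarmonize:
    def _chain(self, seed=61, **kw):
        cfg = ChainSimConfig(n_snps=10, n_mediator_snps=10, **kw, seed=seed)
        return simulate_chain(cfg)

    def test_union_of_disjoint_instrument_sets(self):
        exposure, mediator, outcome, truth = self._chain()
        inst_x = InstrumentSet("exposure", exposure.records.iloc[:10], {})
        inst_z = InstrumentSet("mediator", mediator.records.iloc[10:], {})
        mv = mvmr_harmonize({"exposure": inst_x, "mediator": inst_z},
                            [exposure, mediator], outcome)
        assert mv.k == 20 and mv.m == 2
        assert mv.exposure_names == ["exposure", "mediator"]

    def test_snp_missing_from_one_dataset_dropped(self):
        exposure, mediator, outcome, _ = self._chain()
        mediator_short = mediator.subset([v for v in mediator.records.variant_id
                                          if v != "rs3"])
        inst_x = InstrumentSet("exposure", exposure.records.iloc[:10], {})
        inst_z = InstrumentSet("mediator", mediator.records.iloc[10:], {})
        mv = mvmr_harmonize({"exposure": inst_x, "mediator": inst_z},
                            [exposure, mediator_short], outcome)
        assert "rs3" not in set(mv.variant_id) and mv.k == 19

    def test_palindromes_dropped(self):
        exposure, mediator, outcome, _ = self._chain(seed=62, palindrome_frac=0.2)
        inst_x = InstrumentSet("exposure", exposure.records.iloc[:10], {})
        inst_z = InstrumentSet("mediator", mediator.records.iloc[10:], {})
        mv = mvmr_harmonize({"exposure": inst_x, "mediator": inst_z},
                            [exposure, mediator], outcome)
        assert mv.k == 20 - round(0.2 * 20)


class TestMVMRIVW:
    def test_matches_wls_oracle(self):
        mv = _mv(seed=1)
        res = mvmr_ivw(mv)
        fit = sm.WLS(mv.beta_y, mv.beta_x, weights=1.0 / mv.se_y**2).fit()
        for i, name in enumerate(mv.exposure_names):
            assert res.estimates[name].beta == pytest.approx(fit.params[i], abs=1e-10)

    def test_reduces_to_univariable_ivw_when_m_is_one(self):
        mv = _mv(m=1, seed=2, coefs=(0.4,))
        h = make_h(mv.beta_x[:, 0], mv.se_x[:, 0], mv.beta_y, mv.se_y)
        assert mvmr_ivw(mv).estimates["exp0"].beta == pytest.approx(
            ivw(h, model="fixed").beta, abs=1e-12)

    def test_collinear_design_rejected(self):
        mv = _mv(seed=3)
        mv.beta_x[:, 1] = 2.0 * mv.beta_x[:, 0]
        with pytest.raises(CollinearityError):
            mvmr_ivw(mv)

    def test_recovers_direct_effects_with_no_direct_exposure_path(self):
        """With tau = 0 the mediator keeps delta and the exposure drops to 0."""
        deltas, taus = [], []
        for s in range(100):
            cfg = ChainSimConfig(theta_direct=0.0, n_snps=50, n_mediator_snps=50,
                                 seed=7000 + s)
            exposure, mediator, outcome, truth = simulate_chain(cfg)
            inst_x = select_by_pvalue(exposure, 1e-5)
            inst_z = select_by_pvalue(mediator, 1e-5)
            mv = mvmr_harmonize({"exposure": inst_x, "mediator": inst_z},
                                [exposure, mediator], outcome)
            res = mvmr_ivw(mv)
            deltas.append(res.estimates["mediator"].beta)
            taus.append(res.estimates["exposure"].beta)
        for values, target in [(deltas, -0.5), (taus, 0.0)]:
            values = np.array(values)
            mc_sd = values.std(ddof=1) / np.sqrt(len(values))
            assert abs(values.mean() - target) < 3 * mc_sd


class TestMVMREgger:
    def test_matches_wls_oracle(self):
        mv = _mv(seed=4)
        res = mvmr_egger(mv)
        sign = np.where(mv.beta_x[:, 0] < 0, -1.0, 1.0)
        X = sm.add_constant(mv.beta_x * sign[:, None])
        fit = sm.WLS(mv.beta_y * sign, X, weights=1.0 / mv.se_y**2).fit()
        assert res.intercept["intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        for i, name in enumerate(mv.exposure_names):
            assert res.estimates[name].beta == pytest.approx(
                fit.params[i + 1], abs=1e-10)

    def test_intercept_near_zero_without_pleiotropy(self):
        intercepts = []
        for s in range(60):
            mv = _mv(k=40, seed=100 + s)
            intercepts.append(mvmr_egger(mv).intercept["intercept"])
        intercepts = np.array(intercepts)
        mc_sd = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean()) < 3 * mc_sd

    def test_allele_flip_invariance(self):
        """Flipping a SNP's reported alleles (negating its betas) changes nothing."""
        mv = _mv(seed=5)
        flipped = MVHarmonizedSet(mv.outcome_name, mv.exposure_names,
                                  mv.variant_id, mv.beta_x.copy(), mv.se_x,
                                  mv.beta_y.copy(), mv.se_y)
        flipped.beta_x[::2] *= -1.0
        flipped.beta_y[::2] *= -1.0
        a, b = mvmr_egger(mv), mvmr_egger(flipped)
        for name in mv.exposure_names:
            assert b.estimates[name].beta == pytest.approx(
                a.estimates[name].beta, abs=1e-10)


class TestMVMRMedian:
    def test_agrees_with_ivw_on_clean_data(self):
        mv = _mv(k=50, seed=21)
        med = mvmr_median(mv, n_boot=200, seed=21)
        res_ivw = mvmr_ivw(mv)
        for name in mv.exposure_names:
            assert abs(med.estimates[name].beta - res_ivw.estimates[name].beta) \
                < 2 * med.estimates[name].se

    def test_robust_to_contaminated_outcome_betas(self):
        wins = 0
        reps = 60
        for s in range(reps):
            mv = _mv(k=40, seed=300 + s, contaminate=0.3)
            med = mvmr_median(mv, n_boot=10, seed=s)
            res_ivw = mvmr_ivw(mv)
            err_med = abs(med.estimates["exp1"].beta + 0.5)
            err_ivw = abs(res_ivw.estimates["exp1"].beta + 0.5)
            wins += err_med < err_ivw
        assert wins / reps >= 0.7

    def test_seed_reproducibility(self):
        mv = _mv(seed=6)
        a = mvmr_median(mv, n_boot=100, seed=8)
        b = mvmr_median(mv, n_boot=100, seed=8)
        assert a.estimates["exp0"].se == b.estimates["exp0"].se


class TestMediationDecompose:
    @pytest.mark.parametrize("total,xz,zy,effect,pct", [
        (-1.065, 0.214, -1.046, -0.224, 21.02),
        (0.354, -0.091, -0.291, 0.026, 7.48),
    ])
    def test_reported_style_examples(self, total, xz, zy, effect, pct):
        res = mediation_decompose(total, xz, zy)
        assert res.mediated_effect == pytest.approx(effect, abs=5e-4)
        assert 100 * res.proportion_mediated == pytest.approx(pct, abs=5e-3)
        assert res.direction_consistent

    def test_zero_mediated_effect_inconsistent(self):
        res = mediation_decompose(0.5, 0.0, -0.3)
        assert res.mediated_effect == 0.0
        assert res.proportion_mediated == 0.0
        assert not res.direction_consistent

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mediation_decompose(0.0, 0.1, 0.1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(total=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-6),
           xz=st.floats(-5, 5), zy=st.floats(-5, 5))
    def test_identities_hold_exactly(self, total, xz, zy):
        res = mediation_decompose(total, xz, zy)
        assert res.mediated_effect == xz * zy
        assert res.proportion_mediated == (xz * zy) / total
        assert res.direction_consistent == (
            np.sign(res.mediated_effect) == np.sign(total)
            and res.mediated_effect != 0)


class TestRunTwoStep:
    def test_recovers_chain_decomposition(self):
        cfg = ChainSimConfig(seed=17)
        exposure, mediator, outcome, truth = simulate_chain(cfg)
        res = run_two_step(exposure, mediator, outcome,
                           TwoStepConfig(run_sensitivity=False))
        expected = truth.theta_xz * truth.theta_zy / truth.beta_total_true
        assert res.mediation.proportion_mediated == pytest.approx(expected, abs=0.02)
        assert res.mediation.direction_consistent

    def test_deterministic(self):
        cfg = ChainSimConfig(n_snps=40, n_mediator_snps=40, seed=19)
        exposure, mediator, outcome, _ = simulate_chain(cfg)
        a = run_two_step(exposure, mediator, outcome)
        b = run_two_step(exposure, mediator, outcome)
        assert a.mediation == b.mediation

    def test_null_first_step_gives_tiny_inconsistent_proportion(self):
        cfg = ChainSimConfig(theta_xz=0.0, theta_direct=-0.3, seed=23)
        exposure, mediator, outcome, _ = simulate_chain(cfg)
        res = run_two_step(exposure, mediator, outcome,
                           TwoStepConfig(run_sensitivity=False))
        assert abs(res.mediation.proportion_mediated) < 0.05

    def test_insufficient_instruments_names_stage(self):
        cfg = ChainSimConfig(n_snps=5, n_mediator_snps=5,
                             exposure_effect_sd=1e-6, n_exposure=1000, seed=29)
        exposure, mediator, outcome, _ = simulate_chain(cfg)
        with pytest.raises(InsufficientInstrumentsError, match="exposure->outcome"):
            run_two_step(exposure, mediator, outcome,
                         TwoStepConfig(run_sensitivity=False))
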