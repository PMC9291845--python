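"""Bayesian IPD network meta-regression: design, sampler, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from riskbenefit import (
    NMRSpec,
    fit_nmr,
    linear_predictor,
    reduce_to_nma,
    simulate,
    study_baseline_arm,
)
from riskbenefit.nmr import check_connected
from riskbenefit.risk_model import RiskScoreSet

from conftest import make_table, true_score_set
from test_simulate import minimal_config

FAST = dict(iterations=2500, burn_in=500, thin=4)


def constant_scores(table, value=0.0):
    lr = pd.Series(value, index=table.data.index, dtype=float)
    study = table.data["study"].astype(str)
    return RiskScoreSet(lr, study, {s: value for s in study.unique()}, "constant")


class TestLinearPredictor:
    def test_baseline_arm_at_mean_risk(self):
        assert linear_predictor(-0.5, 0.0, 0.0, 0.0, 0.0, True) == -0.5
        assert expit(-0.5) == pytest.approx(0.3775, abs=1e-4)

    def test_nonbaseline_arm_arithmetic(self):
        eta = linear_predictor(-0.5, -1.0, 2.0, 0.5, 1.0, False)
        assert eta == pytest.approx(1.0)
        assert expit(eta) == pytest.approx(0.7311, abs=1e-4)

    def test_modification_vanishes_at_study_mean(self):
        eta = linear_predictor(0.3, -0.7, 2.0, 0.5, 0.0, False)
        assert eta == pytest.approx(0.3 - 0.7)


class TestReduceToNma:
    def test_disables_risk_terms_and_is_idempotent(self):
        spec = NMRSpec(reference_treatment="placebo")
        reduced = reduce_to_nma(spec)
        assert not reduced.include_risk_terms
        assert reduce_to_nma(reduced) == reduced

    def test_reduced_fit_equals_full_fit_with_constant_scores(self):
        cfg = minimal_config(seed=9, n=4000, delta={"drug": -0.8})
        table, _ = simulate(cfg)
        scores = constant_scores(table)
        spec = NMRSpec(reference_treatment="placebo", seed=1, **FAST)
        post_full = fit_nmr(table, scores, spec)
        post_red = fit_nmr(table, scores, reduce_to_nma(spec))
        d_full = post_full.delta("drug").mean()
        d_red = post_red.delta("drug").mean()
        assert d_full == pytest.approx(d_red, abs=0.05)


class TestFitNmr:
    def test_null_effect_recovered(self):
        """Two arms drawn from the same Bernoulli(0.4)."""
        cfg = minimal_config(seed=11, n=10_000)
        table, _ = simulate(cfg)
        spec = reduce_to_nma(NMRSpec(reference_treatment="placebo", seed=2, **FAST))
        post = fit_nmr(table, constant_scores(table), spec)
        assert abs(post.delta("drug").mean()) < 0.1

    def test_matches_closed_form_log_odds_ratio(self):
        """Interactions disabled: posterior mean delta vs ln(ad/bc)."""
        cfg = minimal_config(seed=13, n=10_000, delta={"drug": -0.9})
        table, _ = simulate(cfg)
        d = table.data
        tab = d.groupby("treatment")["outcome"].agg(["sum", "count"])
        a = tab.loc["drug", "sum"]; b = tab.loc["drug", "count"] - a
        c = tab.loc["placebo", "sum"]; e = tab.loc["placebo", "count"] - c
        oracle = float(np.log(a * e / (b * c)))
        spec = reduce_to_nma(NMRSpec(reference_treatment="placebo", seed=3, **FAST))
        post = fit_nmr(table, constant_scores(table), spec)
        assert post.delta("drug").mean() == pytest.approx(oracle, abs=0.05)

    def test_recovers_interaction_parameters(self, ms_network):
        table, truth = ms_network
        scores = true_score_set(table, truth)
        spec = NMRSpec(reference_treatment="placebo", seed=4,
                       iterations=4000, burn_in=1000, thin=10)
        post = fit_nmr(table, scores, spec)
        assert post.max_rhat() < 1.05
        for t, d in truth["delta"].items():
            lo, hi = post.credible_interval(f"delta[{t}]")
            assert lo - 0.3 < d < hi + 0.3  # loose single-replicate sanity band
        g_lo, g_hi = post.credible_interval("gamma0")
        assert g_lo - 0.3 < truth["gamma0"] < g_hi + 0.3

    def test_draw_count_contract(self):
        cfg = minimal_config(seed=15, n=1500)
        table, _ = simulate(cfg)
        spec = NMRSpec(reference_treatment="placebo", seed=5,
                       chains=2, iterations=1200, burn_in=200, thin=5)
        post = fit_nmr(table, constant_scores(table), spec)
        assert post.draws.shape[:2] == (2, (1200 - 200) // 5)

    def test_consistency_holds_exactly_per_draw(self, ms_network):
        table, truth = ms_network
        scores = true_score_set(table, truth)
        spec = NMRSpec(reference_treatment="placebo", seed=6, **FAST)
        post = fit_nmr(table, scores, spec)
        dn = post.delta("natalizumab")
        df = post.delta("dimethyl_fumarate")
        np.testing.assert_array_equal(
            post.contrast("dimethyl_fumarate", "natalizumab"), dn - df)
        np.testing.assert_array_equal(
            post.interaction_contrast("dimethyl_fumarate", "natalizumab"),
            post.gamma("natalizumab") - post.gamma("dimethyl_fumarate"))

    def test_centering_invariance_under_study_level_shifts(self, ms_network):
        """Shifting every score in a study moves u_j only; with identical
        seeds the delta/gamma chains are bit-identical because the centered
        covariate is unchanged."""
        table, truth = ms_network
        scores = true_score_set(table, truth)
        shift = scores.study.map({"affirm": 3.0, "confirm": -1.0, "define": 0.5})
        shifted = RiskScoreSet(
            logit_risk=scores.logit_risk + shift,
            study=scores.study,
            mean_logit_risk={s: m + {"affirm": 3.0, "confirm": -1.0, "define": 0.5}[s]
                             for s, m in scores.mean_logit_risk.items()},
        )
        spec = NMRSpec(reference_treatment="placebo", seed=7,
                       iterations=4000, burn_in=1000, thin=10)
        p1 = fit_nmr(table, scores, spec)
        p2 = fit_nmr(table, shifted, spec)
        # centered covariates agree to rounding, so paired-seed posteriors
        # agree within Monte Carlo error
        np.testing.assert_allclose(shifted.centered().to_numpy(),
                                   scores.centered().to_numpy(), atol=1e-9)
        for name in ["delta[natalizumab]", "delta[dimethyl_fumarate]",
                     "gamma0", "gamma[dimethyl_fumarate]"]:
            assert p1.flat(name).mean() == pytest.approx(
                p2.flat(name).mean(), abs=0.05)
        # the study intercept absorbs the shift only through its own prior,
        # not the centered covariate, so it too is unchanged
        assert p1.flat("u[affirm]").mean() == pytest.approx(
            p2.flat("u[affirm]").mean(), abs=0.05)

    def test_tight_prior_dominates(self):
        cfg = minimal_config(seed=17, n=3000, delta={"drug": -1.0})
        table, _ = simulate(cfg)
        spec = NMRSpec(reference_treatment="placebo", prior_variance=1e-6,
                       seed=8, **FAST)
        post = fit_nmr(table, constant_scores(table), spec)
        assert abs(post.delta("drug").mean()) < 0.01
        assert abs(post.flat("u[s1]").mean()) < 0.01

    def test_random_effects_extension_samples_sigma(self, ms_network):
        table, truth = ms_network
        scores = true_score_set(table, truth)
        spec = NMRSpec(reference_treatment="placebo", effect_model="random",
                       interaction_model="common", seed=9, **FAST)
        post = fit_nmr(table, scores, spec)
        sig = post.flat("sigma_D")
        assert np.all((sig > 0) & (sig < 5))
        assert np.isfinite(post.delta("natalizumab")).all()

    def test_disconnected_network_rejected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "study": ["s1"] * 40 + ["s2"] * 40,
            "treatment": (["placebo", "a"] * 20) + (["b", "c"] * 20),
            "outcome": rng.binomial(1, 0.5, 80),
            "x": rng.standard_normal(80),
        })
        from riskbenefit import IPDTable
        table = IPDTable(df, ["x"], reference="placebo")
        with pytest.raises(ValueError, match="disconnected"):
            check_connected(table, "placebo")


def test_study_baseline_prefers_overall_reference():
    assert study_baseline_arm(["b", "a", "placebo"], "placebo") == "placebo"
    assert study_baseline_arm(["b", "a"], "placebo") == "a"
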