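"""Absolute risk predictions, strata summaries and numbers needed to treat."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from riskbenefit import (
    IPDTable,
    NMRPosterior,
    NMRSpec,
    ReferenceAnchor,
    benefit_summary,
    estimate_anchor,
    nnt,
    odds_ratio_draws,
    predict_patient,
)
from riskbenefit.risk_model import RiskScoreSet


def fixed_posterior(values: dict, n_draws=50, treatments=("placebo", "df", "n")):
    """Degenerate posterior with every draw equal to the supplied values."""
    names = list(values)
    draws = np.tile(np.array([values[k] for k in names]), (1, n_draws, 1))
    spec = NMRSpec(reference_treatment="placebo", iterations=2, burn_in=1, thin=1)
    return NMRPosterior(param_names=names, draws=draws, spec=spec,
                        treatments=list(treatments), studies=["s"])


def make_scores(logit_risks):
    lr = pd.Series(np.asarray(logit_risks, dtype=float))
    study = pd.Series(["pool"] * len(lr))
    return RiskScoreSet(lr, study, {"pool": float(lr.mean())}, "test")


class TestEstimateAnchor:
    def _ref_table(self, y, score_value=0.2):
        df = pd.DataFrame({"x": 1.0, "study": "ext", "treatment": "placebo",
                           "outcome": y})
        table = IPDTable(df, ["x"], reference="placebo", single_arm_ok=True)
        lr = pd.Series(score_value, index=df.index, dtype=float)
        scores = RiskScoreSet(lr, df["study"], {"ext": score_value}, "test")
        return table, scores

    def test_constant_scores_give_logit_event_rate(self):
        y = [1] * 44 + [0] * 56
        table, scores = self._ref_table(y, score_value=0.2)
        anchor = estimate_anchor(table, scores)
        assert anchor.alpha == pytest.approx(logit(0.44), abs=1e-9)
        assert anchor.alpha == pytest.approx(-0.2412, abs=1e-4)
        assert anchor.mean_logit_risk == pytest.approx(0.2)

    def test_duplicating_the_population_changes_nothing(self):
        rng = np.random.default_rng(0)
        n = 400
        lr = rng.normal(-0.5, 0.8, n)
        y = rng.binomial(1, expit(lr))
        df = pd.DataFrame({"x": lr, "study": "ext", "treatment": "placebo", "outcome": y})
        table = IPDTable(df, ["x"], reference="placebo", single_arm_ok=True)
        scores = RiskScoreSet(pd.Series(lr), df["study"],
                              {"ext": float(lr.mean())}, "test")
        a1 = estimate_anchor(table, scores)
        df2 = pd.concat([df, df], ignore_index=True)
        table2 = IPDTable(df2, ["x"], reference="placebo", single_arm_ok=True)
        scores2 = RiskScoreSet(pd.Series(np.r_[lr, lr]), df2["study"],
                               {"ext": float(lr.mean())}, "test")
        a2 = estimate_anchor(table2, scores2)
        assert a1.alpha == pytest.approx(a2.alpha, abs=1e-8)
        assert a1.mean_logit_risk == pytest.approx(a2.mean_logit_risk)

    def test_recovers_generating_intercept(self):
        """With well-calibrated scores, alpha estimates the log-odds at mean risk."""
        rng = np.random.default_rng(1)
        n = 20_000
        lr = rng.normal(-0.3, 0.9, n)
        y = rng.binomial(1, expit(lr))
        df = pd.DataFrame({"x": lr, "study": "ext", "treatment": "placebo", "outcome": y})
        table = IPDTable(df, ["x"], reference="placebo", single_arm_ok=True)
        scores = RiskScoreSet(pd.Series(lr), df["study"], {"ext": float(lr.mean())}, "t")
        anchor = estimate_anchor(table, scores)
        assert anchor.alpha == pytest.approx(lr.mean(), abs=0.05)

    def test_mixed_treatments_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0], "study": "ext",
                           "treatment": ["placebo", "drug"], "outcome": [0, 1]})
        table = IPDTable(df, ["x"], reference="placebo")
        scores = RiskScoreSet(pd.Series([0.0, 0.0]), df["study"], {"ext": 0.0}, "t")
        with pytest.raises(ValueError, match="only"):
            estimate_anchor(table, scores)


class TestPredictPatient:
    def test_reference_at_mean_risk_collapses_to_alpha(self):
        post = fixed_posterior({"delta[df]": -0.9, "delta[n]": -1.2,
                                "gamma0": 1.3, "gamma[df]": 0.2, "gamma[n]": -0.3})
        anchor = ReferenceAnchor(alpha=-0.5322, mean_logit_risk=-0.4)
        pred = predict_patient(-0.4, "placebo", anchor, post)
        assert pred["probability"] == pytest.approx(expit(-0.5322), abs=1e-12)
        assert pred["ci_2.5"] == pytest.approx(pred["probability"], rel=1e-12)
        assert pred["ci_97.5"] == pytest.approx(pred["probability"], rel=1e-12)

    def test_plug_in_point_prediction(self):
        """Natalizumab at the population mean risk with plug-in means."""
        post = fixed_posterior({"delta[df]": -0.89, "delta[n]": -1.22,
                                "gamma0": 1.26, "gamma[df]": 0.25, "gamma[n]": -0.26})
        anchor = ReferenceAnchor(alpha=float(logit(0.37)), mean_logit_risk=0.0)
        pred = predict_patient(0.0, "n", anchor, post)
        assert pred["probability"] == pytest.approx(0.1478, abs=2e-4)

    def test_monotone_in_risk_when_modified_slope_positive(self):
        post = fixed_posterior({"delta[df]": -0.9, "delta[n]": -1.2,
                                "gamma0": 1.3, "gamma[df]": 0.2, "gamma[n]": -0.3})
        anchor = ReferenceAnchor(alpha=-0.5, mean_logit_risk=0.0)
        # gamma0 + gamma_df = 1.5 > 0 in every draw
        probs = [predict_patient(r, "df", anchor, post)["probability"]
                 for r in (-1.0, 0.0, 1.0, 2.0)]
        assert probs == sorted(probs)

    def test_unknown_treatment_rejected(self):
        post = fixed_posterior({"delta[df]": -0.9, "delta[n]": -1.2,
                                "gamma0": 1.3, "gamma[df]": 0.2, "gamma[n]": -0.3})
        anchor = ReferenceAnchor(alpha=-0.5, mean_logit_risk=0.0)
        with pytest.raises(ValueError, match="unknown"):
            predict_patient(0.0, "mystery", anchor, post)


class TestNNT:
    @pytest.mark.parametrize("ra, rb, expected", [
        (0.84, 0.69, 7),
        (0.93, 0.82, 10),
        (0.5, 0.25, 4),
    ])
    def test_ceiling_convention(self, ra, rb, expected):
        assert nnt(ra, rb) == expected

    def test_zero_or_negative_difference_rejected(self):
        with pytest.raises(ValueError):
            nnt(0.5, 0.5)
        with pytest.raises(ValueError):
            nnt(0.3, 0.5)

    @given(ra=st.floats(0.011, 0.999), diff=st.floats(0.01, 0.5))
    @settings(derandomize=True)
    def test_at_least_one_patient(self, ra, diff):
        rb = ra - diff
        if rb > 0:
            n = nnt(ra, rb)
            assert n >= 1 and (n - 1) * diff <= 1.0 + 1e-9


class TestOddsRatioIdentity:
    def test_or_equals_exp_delta_plus_gamma_c(self):
        post = fixed_posterior({"delta[df]": -0.89, "delta[n]": -1.22,
                                "gamma0": 1.26, "gamma[df]": 0.25, "gamma[n]": -0.26})
        anchor = ReferenceAnchor(alpha=-0.5, mean_logit_risk=0.3)
        for c in (0.0, 1.0):
            p_t = predict_patient(0.3 + c, "n", anchor, post)["draws"]
            p_ref = predict_patient(0.3 + c, "placebo", anchor, post)["draws"]
            or_from_probs = (p_t / (1 - p_t)) / (p_ref / (1 - p_ref))
            np.testing.assert_allclose(
                or_from_probs, np.exp(-1.22 + (-0.26) * c), rtol=1e-10)
            np.testing.assert_allclose(
                odds_ratio_draws(post, "n", c), np.exp(-1.22 - 0.26 * c), rtol=1e-12)


class TestBenefitSummary:
    def _post_and_anchor(self):
        post = fixed_posterior({"delta[df]": -0.89, "delta[n]": -1.22,
                                "gamma0": 1.26, "gamma[df]": 0.25, "gamma[n]": -0.26})
        anchor = ReferenceAnchor(alpha=float(logit(0.44)), mean_logit_risk=-0.3)
        return post, anchor

    def test_single_patient_degenerates_to_predict_patient(self):
        post, anchor = self._post_and_anchor()
        scores = make_scores([0.1])
        table = benefit_summary(scores, ["placebo", "n"], anchor, post)
        row = table.probabilities.query("group == 'all' and treatment == 'n'")
        direct = predict_patient(0.1, "n", anchor, post)
        assert row["probability"].iloc[0] == pytest.approx(direct["probability"])

    def test_identical_posteriors_give_null_benefits(self):
        post = fixed_posterior({"delta[df]": 0.0, "delta[n]": 0.0,
                                "gamma0": 1.0, "gamma[df]": 0.0, "gamma[n]": 0.0})
        anchor = ReferenceAnchor(alpha=-0.2, mean_logit_risk=0.0)
        table = benefit_summary(make_scores([-1.0, 0.0, 1.0]),
                                ["placebo", "df", "n"], anchor, post)
        assert np.allclose(table.pairwise["risk_difference_pp"], 0.0)
        assert np.allclose(table.pairwise["odds_ratio"], 1.0)
        assert table.pairwise["nnt"].isna().all()

    def test_permutation_invariance_in_patient_order(self):
        post, anchor = self._post_and_anchor()
        lrs = [-2.0, -0.5, 0.3, 1.5, 0.9]
        t1 = benefit_summary(make_scores(lrs), ["placebo", "n"], anchor, post)
        t2 = benefit_summary(make_scores(lrs[::-1]), ["placebo", "n"], anchor, post)
        pd.testing.assert_frame_equal(t1.probabilities, t2.probabilities)

    def test_stratum_membership_and_empty_stratum_omitted(self):
        post, anchor = self._post_and_anchor()
        # all three patients below 30% baseline risk -> no high-risk rows
        lrs = [float(logit(0.1)), float(logit(0.2)), float(logit(0.25))]
        table = benefit_summary(make_scores(lrs), ["placebo", "n"], anchor, post)
        groups = set(table.probabilities["group"])
        assert groups == {"all", "risk<0.3"}

    def test_nnt_reported_only_for_positive_differences(self):
        post, anchor = self._post_and_anchor()
        table = benefit_summary(make_scores([1.5]), ["placebo", "n"], anchor, post)
        pw = table.pairwise.query("group == 'all'").set_index(["comparator", "treatment"])
        assert pw.loc[("placebo", "n"), "nnt"] >= 1       # n lowers risk
        assert pd.isna(pw.loc[("n", "placebo"), "nnt"])   # reverse undefined
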