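"""Absolute risk predictions per treatment, risk-stratum benefits and NNTs.

Predictions for a new patient anchor the network's relative effects to an
external reference population (for instance pooled placebo arms): ``alpha``
is the logit outcome probability on the reference treatment for a patient
at the population mean logit risk, and for a patient with logit risk ``r``
on treatment ``t`` each posterior draw gives

    logit(p) = alpha + delta_t + (gamma0 + gamma_t) * (r - mean_logit_risk)

with ``delta_ref = gamma_ref = 0``.  Group summaries average patient-level
probabilities within a baseline-risk stratum; pairwise results are absolute
risk differences in percentage points, odds ratios, and numbers needed to
treat (ceiling of the reciprocal risk difference).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit as logit_fn

from .data import IPDTable, TREATMENT_COL
from .nmr import NMRPosterior
from .risk_model import RiskScoreSet


@dataclass
class ReferenceAnchor:
    """Anchoring constants estimated from a reference population."""

    alpha: float
    mean_logit_risk: float
    source: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceAnchor":
        return cls(**json.loads(Path(path).read_text()))


def estimate_anchor(reference_table: IPDTable, scores: RiskScoreSet,
                    source: str = "") -> ReferenceAnchor:
    """Estimate ``alpha`` and the mean logit risk from reference-arm data.

    ``alpha`` is the intercept of a logistic regression of the observed
    outcomes on the centered logit risk, i.e. the log-odds of the outcome
    for a reference-treated patient at the population mean risk score.
    """
    df = reference_table.data
    if len(df) == 0:
        raise ValueError("reference table is empty")
    arms = set(df[TREATMENT_COL].astype(str).unique())
    if arms != {reference_table.reference}:
        raise ValueError(
            f"reference table must contain only {reference_table.reference!r}; found {sorted(arms)}"
        )
    y = df["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("reference outcomes have a single class")
    lr = scores.logit_risk.to_numpy(dtype=float)
    mean_lr = float(lr.mean())
    centered = lr - mean_lr
    if np.ptp(centered) == 0:
        alpha = float(logit_fn(y.mean()))
    else:
        res = sm.Logit(y, sm.add_constant(centered)).fit(disp=0)
        alpha = float(res.params[0])
    return ReferenceAnchor(alpha=alpha, mean_logit_risk=mean_lr, source=source)


def _probability_draws(logit_risk: float, treatment: str,
                       anchor: ReferenceAnchor, posterior: NMRPosterior) -> np.ndarray:
    ref = posterior.spec.reference_treatment
    if treatment != ref and treatment not in posterior.treatments:
        raise ValueError(f"unknown treatment {treatment!r}")
    c = logit_risk - anchor.mean_logit_risk
    eta = anchor.alpha + posterior.delta(treatment) + (posterior.gamma0() + posterior.gamma(treatment)) * c
    return expit(eta)


def predict_patient(logit_risk: float, treatment: str,
                    anchor: ReferenceAnchor, posterior: NMRPosterior) -> dict:
    """Posterior predicted outcome probability for one patient and treatment."""
    p = _probability_draws(logit_risk, treatment, anchor, posterior)
    lo, hi = np.percentile(p, [2.5, 97.5])
    return {
        "treatment": treatment,
        "logit_risk": float(logit_risk),
        "probability": float(p.mean()),
        "ci_2.5": float(lo),
        "ci_97.5": float(hi),
        "draws": p,
    }


def nnt(risk_a: float, risk_b: float) -> int:
    """Number needed to treat: ceil(1 / (risk_a - risk_b)).

    ``risk_a`` is the outcome risk under the comparator, ``risk_b`` under
    the preferred treatment; only a positive risk difference is defined.
    """
    diff = risk_a - risk_b
    if diff <= 0:
        raise ValueError("NNT undefined: risk_a must exceed risk_b")
    return math.ceil(1.0 / diff)


def odds_ratio_draws(posterior: NMRPosterior, treatment: str,
                     centered_logit_risk: float = 0.0) -> np.ndarray:
    """Per-draw OR of ``treatment`` vs the reference at a centered risk value.

    Algebraic identity of the prediction equation:
    ``OR = exp(delta_t + gamma_t * c)``.
    """
    return np.exp(posterior.delta(treatment)
                  + posterior.gamma(treatment) * centered_logit_risk)


@dataclass
class BenefitTable:
    """Per-stratum predicted risks and pairwise benefit summaries."""

    probabilities: pd.DataFrame  # group x treatment: mean, ci bounds, n patients
    pairwise: pd.DataFrame       # group x (treatment pair): diff pp, OR, NNT
    strata: tuple[float, float]
    reference: str

    def to_csv(self, prob_path: str | Path, pairwise_path: str | Path) -> None:
        self.probabilities.to_csv(prob_path, index=False)
        self.pairwise.to_csv(pairwise_path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "strata": list(self.strata),
            "reference": self.reference,
            "probabilities": self.probabilities.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }, indent=2))


def benefit_summary(
    patients: RiskScoreSet,
    treatments: list[str],
    anchor: ReferenceAnchor,
    posterior: NMRPosterior,
    strata: tuple[float, float] = (0.30, 0.50),
) -> BenefitTable:
    """Summarize predicted risks and benefits by baseline-risk stratum.

    Groups are ``all`` patients, ``low`` (baseline risk below the first
    cutpoint) and ``high`` (above the second); empty strata are omitted.
    The group probability is the average over patients of the per-draw
    probabilities, i.e. a marginal group risk per posterior draw; pairwise
    ORs divide the group-level odds per draw.
    """
    lr = patients.logit_risk.to_numpy(dtype=float)
    if len(lr) == 0:
        raise ValueError("no patients to summarize")
    risk = expit(lr)
    low_cut, high_cut = strata
    groups = {"all": np.ones(len(lr), dtype=bool),
              f"risk<{low_cut:g}": risk < low_cut,
              f"risk>{high_cut:g}": risk > high_cut}

    prob_rows = []
    pair_rows = []
    for gname, mask in groups.items():
        if not mask.any():
            continue
        # draws x patients probability matrix per treatment, averaged over patients
        group_draws = {}
        for t in treatments:
            mat = np.stack([_probability_draws(r, t, anchor, posterior)
                            for r in lr[mask]], axis=1)
            group_draws[t] = mat.mean(axis=1)
        for t in treatments:
            d = group_draws[t]
            lo, hi = np.percentile(d, [2.5, 97.5])
            prob_rows.append({
                "group": gname, "treatment": t, "n_patients": int(mask.sum()),
                "probability": float(d.mean()),
                "ci_2.5": float(lo), "ci_97.5": float(hi),
            })
        for a in treatments:
            for b in treatments:
                if a == b:
                    continue
                diff = group_draws[a] - group_draws[b]
                or_draws = (group_draws[b] / (1 - group_draws[b])) / (
                    group_draws[a] / (1 - group_draws[a]))
                mean_a = float(group_draws[a].mean())
                mean_b = float(group_draws[b].mean())
                row = {
                    "group": gname, "comparator": a, "treatment": b,
                    "risk_difference_pp": float(diff.mean() * 100),
                    "odds_ratio": float(or_draws.mean()),
                    "nnt": nnt(mean_a, mean_b) if mean_a > mean_b else None,
                }
                pair_rows.append(row)

    return BenefitTable(
        probabilities=pd.DataFrame(prob_rows),
        pairwise=pd.DataFrame(pair_rows),
        strata=strata,
        reference=posterior.spec.reference_treatment,
    )
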