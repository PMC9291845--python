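"""Internal validation of stage-1 risk models.

Discrimination is the c-statistic (probability that a random event patient
outscores a random non-event patient, ties counting one half), calibration
is the slope of a logistic refit of outcomes on predicted logits, and
optimism is estimated by the bootstrap: the whole fitting procedure —
including any variable selection — is rerun in each resample, each
bootstrap model is evaluated both on its own resample and on the original
sample, and the average performance drop is subtracted from the apparent
performance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

from .data import IPDTable
from .risk_model import RiskModelFit, score


@dataclass
class ValidationReport:
    apparent_c: float
    apparent_slope: float
    optimism_c: float
    optimism_slope: float
    corrected_c: float
    corrected_slope: float
    n_bootstrap: int
    seed: int
    n_redraws: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def c_statistic(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance probability (AUC) with ties counted 0.5."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    return float((ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def calibration_slope(logit_scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Slope of a logistic regression of outcomes on predicted logits."""
    logit_scores = np.asarray(logit_scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if not np.isfinite(logit_scores).all():
        raise ValueError("logit scores must be finite")
    if len(np.unique(outcomes)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(logit_scores) == 0:
        return 0.0  # constant predictor carries no slope information
    if logit_scores[outcomes == 1].min() > logit_scores[outcomes == 0].max():
        warnings.warn("separation in calibration refit; slope reported as +inf")
        return float("inf")
    Z = sm.add_constant(logit_scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(outcomes, Z).fit(disp=0, maxiter=200)
        except Exception:
            warnings.warn("separation in calibration refit; slope reported as +inf")
            return float("inf")
    slope = float(res.params[1])
    if abs(slope) > 50:
        warnings.warn("separation in calibration refit; slope reported as +inf")
        return float("inf")
    return slope


def _performance(fit: RiskModelFit, table: IPDTable) -> tuple[float, float]:
    s = score(table, fit)
    y = table.outcome
    return c_statistic(s.logit_risk.to_numpy(), y), calibration_slope(s.logit_risk.to_numpy(), y)


def bootstrap_validate(
    table: IPDTable,
    fitter: Callable[[IPDTable], RiskModelFit],
    B: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Bootstrap optimism correction of the c-statistic and calibration slope.

    ``fitter`` must be the complete stage-1 procedure (selection plus
    estimation); anything less leaks optimism.  Resampling is at the patient
    level.  A resample with a single outcome class is redrawn (up to 10
    attempts) so that exactly ``B`` resamples contribute.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    apparent_fit = fitter(table)
    app_c, app_slope = _performance(apparent_fit, table)

    opt_c = np.empty(B)
    opt_slope = np.empty(B)
    n = table.n
    n_redraws = 0
    for b in range(B):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            boot = table.replace(data=table.data.iloc[idx].reset_index(drop=True))
            if len(np.unique(boot.outcome)) == 2:
                break
            n_redraws += 1
        else:
            raise ValueError("could not draw a two-class bootstrap sample in 10 attempts")
        fit_b = fitter(boot)
        c_boot, s_boot = _performance(fit_b, boot)
        c_orig, s_orig = _performance(fit_b, table)
        opt_c[b] = c_boot - c_orig
        opt_slope[b] = s_boot - s_orig

    o_c = float(opt_c.mean())
    o_s = float(opt_slope.mean())
    return ValidationReport(
        apparent_c=app_c,
        apparent_slope=app_slope,
        optimism_c=o_c,
        optimism_slope=o_s,
        corrected_c=app_c - o_c,
        corrected_slope=app_slope - o_s,
        n_bootstrap=B,
        seed=seed,
        n_redraws=n_redraws,
    )
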