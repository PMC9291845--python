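"""Stage 1: baseline-risk logistic models and per-patient risk scores.

Two routes are provided, both fitted on all trial arms pooled and blinded
to treatment assignment:

* ``fit_lasso`` — L1-penalized logistic regression over a decreasing
  penalty grid; the penalty is chosen by stratified K-fold cross-validation
  maximizing AUC with the one-standard-error rule (largest penalty whose
  mean CV AUC is within one SE of the best).
* ``fit_prespecified`` — a fixed set of covariates estimated by ridge-type
  penalized maximum likelihood; the penalty is chosen along a trace as the
  value maximizing a modified AIC (likelihood-ratio chi-squared minus twice
  the effective degrees of freedom).

Covariates are standardized internally before penalization (the intercept
is never penalized) and coefficients are reported on the original scale.
``score`` turns a fit into per-patient logit risks with per-study means,
the quantity carried into stage 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import IPDTable, STUDY_COL


@dataclass
class RiskModelFit:
    """A fitted baseline-risk logistic model."""

    route: str  # "lasso" | "prespecified"
    intercept: float
    coefficients: dict[str, float]
    penalty: float
    selection_meta: dict = field(default_factory=dict)
    training_prevalence: float | None = None
    standard_errors: dict[str, float] | None = None
    coefficient_pooling: str = "common"  # per-study variants reserved

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            lp += beta * X[name].to_numpy(dtype=float)
        return lp

    def to_dict(self) -> dict:
        return {
            "route": self.route,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "penalty": self.penalty,
            "selection_meta": self.selection_meta,
            "training_prevalence": self.training_prevalence,
            "standard_errors": self.standard_errors,
            "coefficient_pooling": self.coefficient_pooling,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModelFit":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RiskScoreSet:
    """Per-patient logit baseline risks plus per-study means."""

    logit_risk: pd.Series  # indexed like the scored table
    study: pd.Series
    mean_logit_risk: dict[str, float]
    provenance: str = ""

    @property
    def risk(self) -> pd.Series:
        return pd.Series(expit(self.logit_risk.to_numpy()), index=self.logit_risk.index)

    def centered(self) -> pd.Series:
        """Logit risk minus the patient's study mean (stage-2 covariate)."""
        means = self.study.map(self.mean_logit_risk)
        return self.logit_risk - means


def _design(table: IPDTable, variables: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = list(variables) if variables is not None else list(table.covariates)
    missing = [v for v in names if v not in table.data.columns]
    if missing:
        raise ValueError(f"covariate(s) not in table: {missing}")
    X = table.data[names].to_numpy(dtype=float)
    y = table.data["outcome"].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("table is not complete-case; run complete_case() first")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    return X, y, names


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate constant covariate")
    return (X - mu) / sd, mu, sd


def lasso_lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every L1 slope is exactly zero.

    Uses the mean-log-likelihood parametrization: the objective is
    ``(1/n) * deviance/2 + lam * ||slopes||_1`` with standardized covariates.
    """
    n = len(y)
    return float(np.max(np.abs(X_std.T @ (y - y.mean()))) / n)


def _fit_l1(X_std: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """L1-penalized logistic fit at one penalty (standardized scale)."""
    if lam <= 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
        clf.fit(X_std, y)
        return float(clf.intercept_[0]), clf.coef_[0].astype(float)
    # liblinear penalizes the intercept unless intercept_scaling is large
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="liblinear",
        intercept_scaling=1000.0, max_iter=2000, tol=1e-7, random_state=0,
    )
    clf.fit(X_std, y)
    return float(clf.intercept_[0]), clf.coef_[0].astype(float)


def fit_lasso(
    table: IPDTable,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> RiskModelFit:
    """LASSO route: CV-tuned L1 logistic regression with the one-SE rule.

    The penalty grid is log-spaced from the analytic ``lambda_max`` (null
    model) down to ``lambda_min_ratio * lambda_max``.  Folds are stratified
    by outcome and derived from ``seed``, so the fit is reproducible.
    """
    X, y, names = _design(table)
    X_std, mu, sd = _standardize(X)
    lam_max = lasso_lambda_max(X_std, y)
    grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = np.empty((folds, n_lambda))
    for f, (tr, te) in enumerate(skf.split(X_std, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError(f"fold {f} has a single outcome class")
        Xtr_std, mtr, str_ = _standardize(X[tr])
        Xte_std = (X[te] - mtr) / str_
        for i, lam in enumerate(grid):
            b0, b = _fit_l1(Xtr_std, y[tr], lam)
            lp = b0 + Xte_std @ b
            aucs[f, i] = 0.5 if np.ptp(lp) == 0 else roc_auc_score(y[te], lp)

    mean_auc = aucs.mean(axis=0)
    se_auc = aucs.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmax(mean_auc))
    cutoff = mean_auc[best] - se_auc[best]
    # grid is decreasing; the first index meeting the cutoff is the largest
    # (most parsimonious) penalty within one SE of the best AUC
    chosen = int(np.nonzero(mean_auc >= cutoff)[0][0])
    lam = float(grid[chosen])

    b0_std, b_std = _fit_l1(X_std, y, lam)
    beta = b_std / sd
    intercept = b0_std - float(mu @ beta)
    return RiskModelFit(
        route="lasso",
        intercept=float(intercept),
        coefficients={name: float(v) for name, v in zip(names, beta)},
        penalty=lam,
        selection_meta={
            "folds": folds,
            "seed": seed,
            "lambda_grid": grid.tolist(),
            "cv_auc_mean": mean_auc.tolist(),
            "cv_auc_se": se_auc.tolist(),
            "lambda_best": float(grid[best]),
            "one_se_cutoff": float(cutoff),
        },
        training_prevalence=float(y.mean()),
    )


# ---------------------------------------------------------------------------
# prespecified route: ridge-type penalized maximum likelihood
# ---------------------------------------------------------------------------

def _penalized_newton(
    X_std: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-10, max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximize sum log-lik minus (lam/2)*||slopes||^2 on the standardized scale.

    Returns the coefficient vector (intercept first), the unpenalized
    information matrix at the optimum and the penalized information.
    """
    n, p = X_std.shape
    Z = np.column_stack([np.ones(n), X_std])
    pen = np.zeros(p + 1)
    pen[1:] = lam
    theta = np.zeros(p + 1)
    theta[0] = np.log(y.mean() / (1 - y.mean()))
    for it in range(max_iter):
        eta = Z @ theta
        mu = expit(eta)
        grad = Z.T @ (y - mu) - pen * theta
        W = mu * (1 - mu)
        info = Z.T @ (Z * W[:, None])
        H = info + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # near-separation flattens the information; damp and continue
            step = np.linalg.solve(H + 1e-6 * np.eye(p + 1), grad)
        theta = theta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        if lam == 0:
            warnings.warn("unpenalized fit did not converge (possible separation)")
    eta = Z @ theta
    W = expit(eta) * (1 - expit(eta))
    info = Z.T @ (Z * W[:, None])
    return theta, info, info + np.diag(pen)


def _loglik(X_std: np.ndarray, y: np.ndarray, theta: np.ndarray) -> float:
    eta = theta[0] + X_std @ theta[1:]
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


DEFAULT_PENALTY_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)


def fit_prespecified(
    table: IPDTable,
    variables: Sequence[str],
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
) -> RiskModelFit:
    """Prespecified route: penalized ML over a penalty trace.

    For each penalty the model maximizes ``loglik - (lam/2) * sum(beta_k^2)``
    with slopes standardized and the intercept free.  The modified AIC is
    ``LR chi2(lam) - 2 * edf(lam)`` where the likelihood-ratio chi-squared
    uses the unpenalized log-likelihood at the penalized estimate and
    ``edf = trace(I (I + P)^-1)`` (intercept included, contributing ~1).
    The reported penalty maximizes the modified AIC.
    """
    X, y, names = _design(table, variables)
    X_std, mu, sd = _standardize(X)
    ll_null = float(len(y) * (y.mean() * np.log(y.mean()) + (1 - y.mean()) * np.log(1 - y.mean())))

    trace = []
    fits = {}
    for lam in penalty_grid:
        theta, info, pinfo = _penalized_newton(X_std, y, lam)
        lr_chi2 = 2.0 * (_loglik(X_std, y, theta) - ll_null)
        edf = float(np.trace(info @ np.linalg.inv(pinfo)))
        trace.append({"penalty": float(lam), "lr_chi2": lr_chi2, "edf": edf,
                      "modified_aic": lr_chi2 - 2.0 * edf})
        fits[lam] = (theta, info, pinfo)

    best = max(trace, key=lambda row: row["modified_aic"])
    lam = best["penalty"]
    theta, info, pinfo = fits[lam]

    # back-transform to the original covariate scale
    beta = theta[1:] / sd
    intercept = theta[0] - float(mu @ beta)
    pinv = np.linalg.inv(pinfo)
    cov_std = pinv @ info @ pinv  # sandwich covariance for penalized ML
    se = np.sqrt(np.diag(cov_std))[1:] / sd

    return RiskModelFit(
        route="prespecified",
        intercept=float(intercept),
        coefficients={name: float(v) for name, v in zip(names, beta)},
        penalty=float(lam),
        selection_meta={"penalty_trace": trace},
        training_prevalence=float(y.mean()),
        standard_errors={name: float(v) for name, v in zip(names, se)},
    )


def score(table: IPDTable, fit: RiskModelFit) -> RiskScoreSet:
    """Apply a stage-1 fit: per-patient logit risk and per-study means."""
    needed = [n for n in fit.coefficients if n not in table.data.columns]
    if needed:
        raise ValueError(f"table lacks covariate(s) required by the fit: {needed}")
    sub = table.data[list(fit.coefficients)]
    if sub.isna().any().any():
        raise ValueError("missing covariate values; score requires complete cases")
    lp = pd.Series(fit.linear_predictor(table.data), index=table.data.index)
    study = table.data[STUDY_COL].astype(str)
    means = lp.groupby(study).mean().to_dict()
    return RiskScoreSet(
        logit_risk=lp,
        study=study,
        mean_logit_risk={str(k): float(v) for k, v in means.items()},
        provenance=fit.route,
    )
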