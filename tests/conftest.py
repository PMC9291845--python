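"""Shared fixtures: small hand-built tables and seeded synthetic networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riskbenefit import IPDTable, default_ms_like_config, simulate
from riskbenefit.risk_model import RiskScoreSet


def make_table(
    X: np.ndarray,
    y: np.ndarray,
    covariates: list[str] | None = None,
    study: np.ndarray | str = "s1",
    treatment: np.ndarray | None = None,
    reference: str = "ctrl",
    single_arm_ok: bool = False,
) -> IPDTable:
    """Assemble an IPDTable from raw arrays (two alternating arms by default)."""
    n = len(y)
    covariates = covariates or [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=covariates)
    df["study"] = study
    df["treatment"] = (np.array(["ctrl", "trt"])[np.arange(n) % 2]
                       if treatment is None else treatment)
    df["outcome"] = y
    return IPDTable(df, covariates, reference=reference, single_arm_ok=single_arm_ok)


def true_score_set(table: IPDTable, truth: dict) -> RiskScoreSet:
    """Risk scores computed from the generating stage-1 coefficients."""
    lp = np.full(table.n, truth["beta0"])
    for name, b in truth["beta"].items():
        lp += b * table.data[name].to_numpy(dtype=float)
    lr = pd.Series(lp, index=table.data.index)
    study = table.data["study"].astype(str)
    return RiskScoreSet(
        logit_risk=lr,
        study=study,
        mean_logit_risk=lr.groupby(study).mean().to_dict(),
        provenance="generating-model",
    )


@pytest.fixture(scope="session")
def ms_network():
    """One seeded draw of the packaged three-trial synthetic network."""
    table, truth = simulate(default_ms_like_config(seed=42))
    return table, truth


@pytest.fixture(scope="session")
def logistic_sample():
    """Single-study logistic data with three true signals and two nulls."""
    rng = np.random.default_rng(5)
    n = 2000
    X = rng.standard_normal((n, 5))
    beta = np.array([0.8, -0.5, 0.3, 0.0, 0.0])
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-(0.2 + X @ beta))))
    return make_table(X, y), beta
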