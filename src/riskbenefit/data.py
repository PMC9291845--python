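"""Individual-patient-data tables and pre-modelling filters.

The container is a plain :class:`pandas.DataFrame` with three reserved
columns (``study``, ``treatment``, ``outcome``) plus one numeric column per
covariate, wrapped in :class:`IPDTable` which tracks the covariate names and
the designated overall reference treatment.

Filters implement the usual curation steps for pooled randomized-trial data:
dropping covariates with excessive missingness, pruning highly correlated
covariates, and complete-case restriction.  Each returns a
:class:`PreprocessReport` describing exactly what was removed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STUDY_COL = "study"
TREATMENT_COL = "treatment"
OUTCOME_COL = "outcome"
_RESERVED = (STUDY_COL, TREATMENT_COL, OUTCOME_COL)


class IPDError(ValueError):
    """Raised when a table violates the IPD contract."""


@dataclass
class IPDTable:
    """Patient-level records from one or more randomized trials.

    Parameters
    ----------
    data
        One row per patient with columns ``study``, ``treatment``,
        ``outcome`` (0/1, NaN allowed before complete-case filtering) and
        the covariates.
    covariates
        Names of the covariate columns, in order.
    reference
        Label of the overall reference treatment (e.g. placebo).
    single_arm_ok
        Allow studies with a single arm; used for external reference
        populations (e.g. pooled placebo arms) that anchor predictions.
    """

    data: pd.DataFrame
    covariates: list[str]
    reference: str = "ref"
    single_arm_ok: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in (*_RESERVED, *self.covariates) if c not in self.data.columns]
        if missing:
            raise IPDError(f"missing required column(s): {missing}")
        out = self.data[OUTCOME_COL]
        bad = out.dropna()[~out.dropna().isin((0, 1))]
        if len(bad):
            raise IPDError(f"outcome must be binary 0/1; found values {sorted(bad.unique())}")
        if not self.single_arm_ok:
            arm_counts = self.data.groupby(STUDY_COL, observed=True)[TREATMENT_COL].nunique()
            single = arm_counts[arm_counts < 2]
            if len(single):
                raise IPDError(
                    f"studies with <2 arms: {list(single.index)}; "
                    "set single_arm_ok=True for external reference data"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def studies(self) -> list[str]:
        return sorted(self.data[STUDY_COL].astype(str).unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data[TREATMENT_COL].astype(str).unique())

    def covariate_matrix(self) -> np.ndarray:
        return self.data[self.covariates].to_numpy(dtype=float)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[OUTCOME_COL].to_numpy(dtype=float)

    def replace(self, data: pd.DataFrame | None = None,
                covariates: list[str] | None = None) -> "IPDTable":
        return IPDTable(
            data=self.data if data is None else data,
            covariates=list(self.covariates) if covariates is None else covariates,
            reference=self.reference,
            single_arm_ok=self.single_arm_ok,
        )


@dataclass
class PreprocessReport:
    """What a filtering step removed, for the audit trail."""

    dropped_missing: list[tuple[str, float]] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0

    def to_dict(self) -> dict:
        return {
            "dropped_missing": [[name, frac] for name, frac in self.dropped_missing],
            "dropped_correlated": [[k, d, r] for k, d, r in self.dropped_correlated],
            "n_before": self.n_before,
            "n_after": self.n_after,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def read_ipd(path: str | Path, config: Mapping) -> IPDTable:
    """Read a delimited IPD file using a column-role configuration.

    ``config`` maps roles to column names: keys ``study``, ``treatment``,
    ``outcome``, ``covariates`` (list), and optionally ``categorical``
    (subset of covariates to expand into indicator columns), ``treatments``
    (allowed treatment labels), ``reference`` (overall reference label) and
    ``transforms`` (covariate -> "log" | "identity").

    Categorical covariates are expanded deterministically: levels sorted
    alphabetically, the first level is the baseline, and each remaining
    level ``v`` becomes an indicator column ``"{name}={v}"``.
    """
    for key in ("study", "treatment", "outcome", "covariates"):
        if key not in config:
            raise IPDError(f"config missing required key {key!r}")
    df = pd.read_csv(path)
    wanted = [config["study"], config["treatment"], config["outcome"], *config["covariates"]]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise IPDError(f"input file lacks column(s): {missing}")

    out = pd.DataFrame({
        STUDY_COL: df[config["study"]].astype(str),
        TREATMENT_COL: df[config["treatment"]].astype(str),
        OUTCOME_COL: pd.to_numeric(df[config["outcome"]], errors="raise"),
    })
    allowed = config.get("treatments")
    if allowed is not None:
        unknown = sorted(set(out[TREATMENT_COL].unique()) - set(map(str, allowed)))
        if unknown:
            raise IPDError(f"treatment label(s) {unknown} absent from config's treatment set")

    categorical = set(config.get("categorical", ()))
    transforms = dict(config.get("transforms", {}))
    covariates: list[str] = []
    for name in config["covariates"]:
        col = df[name]
        if name in categorical:
            levels = sorted(col.dropna().astype(str).unique())
            for level in levels[1:]:  # first (alphabetical) level is the baseline
                indicator = f"{name}={level}"
                vals = (col.astype(str) == level).astype(float)
                vals[col.isna()] = np.nan
                out[indicator] = vals
                covariates.append(indicator)
        else:
            vals = pd.to_numeric(col, errors="raise").astype(float)
            if transforms.get(name, "identity") == "log":
                vals = np.log(vals)
            out[name] = vals
            covariates.append(name)

    return IPDTable(
        data=out,
        covariates=covariates,
        reference=str(config.get("reference", "ref")),
        single_arm_ok=bool(config.get("single_arm_ok", False)),
    )


def filter_missing(table: IPDTable, max_missing: float = 0.5) -> tuple[IPDTable, PreprocessReport]:
    """Drop covariates whose missing fraction strictly exceeds ``max_missing``."""
    if not table.covariates:
        raise IPDError("table has no covariates")
    report = PreprocessReport(n_before=table.n, n_after=table.n)
    kept: list[str] = []
    for name in table.covariates:
        frac = float(table.data[name].isna().mean())
        if frac > max_missing:
            report.dropped_missing.append((name, frac))
        else:
            kept.append(name)
    keep_cols = [c for c in table.data.columns if c in (*_RESERVED, *kept)]
    return table.replace(data=table.data[keep_cols], covariates=kept), report


def prune_correlated(
    table: IPDTable,
    threshold: float = 0.7,
    keep_priority: Sequence[str] | None = None,
) -> tuple[IPDTable, PreprocessReport]:
    """Drop the lower-priority member of every covariate pair with |r| > threshold.

    Pearson correlations use pairwise-complete observations.  ``keep_priority``
    orders covariates from most to least preferred (default: column order,
    standing in for the subject-matter judgement used when curating real
    trial data).  Covariates are visited in priority order; each surviving
    covariate eliminates all later ones it is too correlated with.
    """
    report = PreprocessReport(n_before=table.n, n_after=table.n)
    if len(table.covariates) < 2:
        return table, report
    priority = list(keep_priority) if keep_priority is not None else list(table.covariates)
    corr = table.data[table.covariates].corr(method="pearson")

    flagged = {
        (a, b)
        for a, b in itertools.combinations(table.covariates, 2)
        if np.isfinite(corr.loc[a, b]) and abs(corr.loc[a, b]) > threshold
    }
    in_flagged = {name for pair in flagged for name in pair}
    outside = sorted(in_flagged - set(priority))
    if outside:
        raise IPDError(f"keep_priority omits covariate(s) in a correlated pair: {outside}")

    dropped: set[str] = set()
    for i, keep in enumerate(priority):
        if keep in dropped:
            continue
        for other in priority[i + 1:]:
            if other in dropped:
                continue
            pair = (keep, other) if (keep, other) in flagged else (other, keep)
            if pair in flagged:
                dropped.add(other)
                report.dropped_correlated.append((keep, other, float(corr.loc[keep, other])))

    kept = [c for c in table.covariates if c not in dropped]
    keep_cols = [c for c in table.data.columns if c not in dropped]
    return table.replace(data=table.data[keep_cols], covariates=kept), report


def complete_case(table: IPDTable) -> tuple[IPDTable, PreprocessReport]:
    """Restrict to records with no missing covariate or outcome values."""
    mask = table.data[[OUTCOME_COL, *table.covariates]].notna().all(axis=1)
    report = PreprocessReport(n_before=table.n, n_after=int(mask.sum()))
    if report.n_after == 0:
        raise IPDError("complete-case filtering removed every record")
    data = table.data.loc[mask].reset_index(drop=True)
    data[OUTCOME_COL] = data[OUTCOME_COL].astype(int)
    return table.replace(data=data), report


def preprocess(
    table: IPDTable,
    max_missing: float = 0.5,
    corr_threshold: float = 0.7,
    keep_priority: Sequence[str] | None = None,
) -> tuple[IPDTable, dict[str, PreprocessReport]]:
    """Run the full filter pipeline: missingness -> correlation -> complete case."""
    t1, rep_miss = filter_missing(table, max_missing)
    t2, rep_corr = prune_correlated(t1, corr_threshold, keep_priority)
    t3, rep_cc = complete_case(t2)
    return t3, {"missing": rep_miss, "correlated": rep_corr, "complete_case": rep_cc}
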