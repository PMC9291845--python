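"""Pre-modelling adequacy checks for a binary-outcome prediction model.

Implements events-per-variable (EPV) and the Riley minimum-sample-size
criteria for developing a logistic prediction model:

1. shrinkage: ``n1 = P / ((S-1) ln(1 - R2_cs/S))`` targets a global
   shrinkage factor of at least ``S`` (default 0.9);
2. small optimism in apparent fit: the same formula evaluated at
   ``S2 = R2_cs / (R2_cs + 0.05 * R2_max)``, which bounds the apparent
   minus adjusted Nagelkerke R-squared by 0.05;
3. precise mean risk: ``n3 = (z / margin)^2 * phi (1 - phi)`` pins the
   intercept (outcome prevalence ``phi``) to ``margin`` (default 0.05)
   with 95% confidence.

The required size is the maximum of the per-criterion ceilings.  The
anticipated Cox-Snell R-squared may be given directly or derived from an
anticipated Nagelkerke R-squared via the prevalence-dependent maximum
``R2_max = 1 - exp(2 (phi ln phi + (1-phi) ln(1-phi)))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path


def compute_epv(events: int, model_df: int) -> float:
    """Events per candidate model parameter, reported to one decimal."""
    if model_df < 1:
        raise ValueError("model_df must be >= 1")
    if events < 0:
        raise ValueError("events must be >= 0")
    return round(events / model_df, 1)


def cox_snell_max_r2(prevalence: float) -> float:
    """Largest attainable Cox-Snell R-squared for a binary outcome."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    p = prevalence
    return 1.0 - math.exp(2.0 * (p * math.log(p) + (1 - p) * math.log(1 - p)))


def nagelkerke_to_cox_snell(r2_nagelkerke: float, prevalence: float) -> float:
    """Convert an anticipated Nagelkerke R-squared to the Cox-Snell scale."""
    if not 0 < r2_nagelkerke < 1:
        raise ValueError("r2_nagelkerke must be in (0, 1)")
    return r2_nagelkerke * cox_snell_max_r2(prevalence)


@dataclass
class SampleSizeReport:
    """Outcome of the minimum-sample-size calculation."""

    model_df: int
    r2_cs: float
    shrinkage: float
    prevalence: float
    intercept_margin: float
    n_required: int
    criterion_values: dict[str, int] = field(default_factory=dict)
    events_required: int = 0
    n_available: int | None = None
    events_available: int | None = None
    epv: float | None = None

    @property
    def adequate(self) -> bool | None:
        if self.n_available is None:
            return None
        return self.n_available >= self.n_required

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"Minimum sample size for a {self.model_df}-parameter logistic model",
            f"  anticipated Cox-Snell R2 = {self.r2_cs:.4f}, shrinkage target = {self.shrinkage}",
            f"  outcome prevalence = {self.prevalence:.4f}",
        ]
        for name, val in self.criterion_values.items():
            lines.append(f"  {name}: n >= {val}")
        lines.append(f"  required: n >= {self.n_required} ({self.events_required} events)")
        if self.n_available is not None:
            verdict = "adequate" if self.adequate else "NOT adequate"
            lines.append(f"  available: n = {self.n_available} -> {verdict}")
        return "\n".join(lines)


def _shrinkage_n(model_df: int, r2_cs: float, s: float) -> float:
    return model_df / ((s - 1.0) * math.log(1.0 - r2_cs / s))


def riley_min_n(
    model_df: int,
    r2_cs: float | None = None,
    shrinkage: float = 0.9,
    prevalence: float = 0.5,
    intercept_margin: float = 0.05,
    r2_nagelkerke: float | None = None,
    n_available: int | None = None,
    events_available: int | None = None,
) -> SampleSizeReport:
    """Riley minimum sample size for developing a binary-outcome model.

    Exactly one of ``r2_cs`` (Cox-Snell) or ``r2_nagelkerke`` must be given;
    the latter is converted using the prevalence-dependent maximum.
    """
    if (r2_cs is None) == (r2_nagelkerke is None):
        raise ValueError("give exactly one of r2_cs or r2_nagelkerke")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if r2_nagelkerke is not None:
        r2_cs = nagelkerke_to_cox_snell(r2_nagelkerke, prevalence)
    assert r2_cs is not None
    if not 0 < r2_cs < shrinkage < 1:
        raise ValueError("need 0 < r2_cs < shrinkage < 1")
    if model_df < 1:
        raise ValueError("model_df must be >= 1")

    n1 = _shrinkage_n(model_df, r2_cs, shrinkage)
    s2 = r2_cs / (r2_cs + 0.05 * cox_snell_max_r2(prevalence))
    n2 = _shrinkage_n(model_df, r2_cs, s2)
    n3 = (1.96 / intercept_margin) ** 2 * prevalence * (1.0 - prevalence)

    criteria = {
        "shrinkage": math.ceil(n1),
        "r2_optimism": math.ceil(n2),
        "intercept_precision": math.ceil(n3),
    }
    n_required = max(criteria.values())
    report = SampleSizeReport(
        model_df=model_df,
        r2_cs=r2_cs,
        shrinkage=shrinkage,
        prevalence=prevalence,
        intercept_margin=intercept_margin,
        n_required=n_required,
        criterion_values=criteria,
        events_required=math.ceil(n_required * prevalence),
        n_available=n_available,
        events_available=events_available,
    )
    if events_available is not None:
        report.epv = compute_epv(events_available, model_df)
    return report
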