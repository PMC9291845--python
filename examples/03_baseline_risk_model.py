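"""Stage 1: fit and internally validate a baseline-risk model.

Fits both routes on synthetic trial data pooled over arms (blinded to
treatment): the LASSO route with cross-validated penalty selection, and a
prespecified-variable route with ridge-type penalized maximum likelihood.
Internal validation bootstrap-corrects the c-statistic and calibration
slope for optimism.
"""

import functools

from riskbenefit import (
    bootstrap_validate,
    default_ms_like_config,
    fit_lasso,
    fit_prespecified,
    score,
    simulate,
)

table, truth = simulate(default_ms_like_config(seed=1))

lasso = fit_lasso(table, folds=10, seed=1, n_lambda=40)
print(f"LASSO route: penalty {lasso.penalty:.4f} "
      f"({sum(v != 0 for v in lasso.coefficients.values())} of "
      f"{len(lasso.coefficients)} covariates kept)")

prespec_vars = ["age", "edss", "prior_relapses", "sf36_pcs", "prior_treatment"]
prespec = fit_prespecified(table, prespec_vars)
print(f"Prespecified route: ridge penalty {prespec.penalty:g} chosen by modified AIC")
for name, b in prespec.coefficients.items():
    se = prespec.standard_errors[name]
    print(f"  {name:16s} {b:+.4f} (SE {se:.4f})")

scores = score(table, prespec)
print(f"\nMean predicted risk {scores.risk.mean():.3f} "
      f"vs observed prevalence {table.outcome.mean():.3f}")

fitter = functools.partial(fit_prespecified, variables=prespec_vars)
report = bootstrap_validate(table, fitter, B=50, seed=1)
print(f"\nInternal validation ({report.n_bootstrap} bootstrap resamples):")
print(f"  c-statistic: apparent {report.apparent_c:.3f}, "
      f"optimism-corrected {report.corrected_c:.3f}")
print(f"  calibration slope: apparent {report.apparent_slope:.3f}, "
      f"corrected {report.corrected_slope:.3f}")
print("\nWithout variable selection and at this sample size the optimism is")
print("tiny, so corrected and apparent performance nearly coincide; modest")
print("discrimination (c around 0.6-0.7) is often enough baseline-risk signal")
print("to detect risk-based treatment-effect modification downstream.")
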