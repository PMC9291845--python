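"""Is a dataset big enough to develop a baseline-risk model?

Uses the published design of a 2-year relapse model: 2000 complete-case
patients with 742 events, anticipated Nagelkerke R-squared 0.15, shrinkage
target 0.9.  Compares a 45-parameter candidate set against a prespecified
14-parameter set.
"""

from riskbenefit import compute_epv, riley_min_n

for model_df in (45, 14):
    report = riley_min_n(
        model_df=model_df,
        r2_nagelkerke=0.15,
        shrinkage=0.9,
        prevalence=742 / 2000,
        n_available=2000,
        events_available=742,
    )
    print(report)
    print(f"  events per variable: {compute_epv(742, model_df)}")
    print()

print("A model with many candidate parameters needs a far larger development")
print("sample to keep overfitting (shrinkage) in check; the 14-parameter")
print("prespecified model is supported by 2000 patients, the 45-parameter")
print("selection problem is not.")
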