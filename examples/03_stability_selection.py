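"""Nominate candidate biomarkers by LASSO / elastic-net stability selection.

Repeats 50 times: draw a stratified 75/25 split, tune the penalty by
10-fold cross-validation on the training part, refit, and record which
features keep nonzero coefficients.  Features whose appearance
frequency exceeds the upper quartile of all frequencies are selected,
separately for LASSO (alpha=1) and elastic net (alpha=0.5), then
combined by union.
"""

from traumapanel import SelectionConfig, generate_cohort, stability_select, study_spec
from traumapanel.preprocess import preprocess_table

spec = study_spec(seed=7)
cohort, truth = generate_cohort(spec)
t1 = cohort.split_by_timepoint()[0]
table, _ = preprocess_table(t1)
immune = table.subset_features(table.features(role="immune"))

config = SelectionConfig(n_iterations=50, seed=1)
result = stability_select(immune, config)

for alpha in config.alphas:
    freqs = result.frequencies[alpha]
    top = freqs.sort_values(ascending=False).head(5)
    label = "LASSO" if alpha == 1.0 else f"EN(alpha={alpha:g})"
    print(f"{label}: threshold {result.thresholds[alpha]:.1f} appearances "
          f"out of {result.n_iterations}")
    for name, f in top.items():
        mark = " <- planted" if name in truth.markers else ""
        print(f"   {name}: {int(f)}{mark}")
print(f"combined panel ({result.combine_rule}): {result.combined}")
print(f"planted markers at this time point: "
      f"{[m for m in truth.markers if m.endswith('_t1')]}")
# frequencies near n_iterations mean a feature survives the penalty in
# almost every subsample - the stability-selection notion of a robust marker
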