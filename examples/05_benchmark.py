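"""Run the full benchmarking protocol on one synthetic cohort.

Index tests are evaluated prospectively on the whole cohort at their fixed
cutoffs; each machine-learning method runs under stratified ten-fold CV with
nested validation-based tuning.  Per-fold accuracies feed pairwise two-tailed
Wilcoxon signed-rank comparisons.
"""

from vestibench import GeneratorConfig, generate_cohort
from vestibench.evaluate import compare_models, run_benchmark

cohort = generate_cohort(GeneratorConfig(seed=1))
report = run_benchmark(cohort, k=10, seed=0)

print("Index tests (full cohort, fixed cutoff + cutoff-sweep AUC):")
for name, res in report.index_tests.items():
    print(f"  {name:6s} accuracy {res['accuracy']:.3f}  F1 {res['f1']:.3f}  "
          f"AUC {res['auc']:.3f}")

print("\nCV medians per machine-learning method:")
print(report.aggregates().round(3).to_string())

p = compare_models(report, "MultiGMC", "LR")
print(f"\nWilcoxon signed-rank on per-fold accuracies, MultiGMC vs LR: "
      f"p = {p:.3f}")
print("Small p-values flag a systematic per-fold accuracy difference; at "
      "n = 108 with 10 folds, only large gaps reach p < 0.05.")
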