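"""Fit the classical baselines (elastic-net LR, random forest, MLP) on one
stratified fold and inspect the forest's feature importances.
"""

import numpy as np

from vestibench import GeneratorConfig, generate_cohort, roc_auc
from vestibench.baselines import default_grid, fit, predict_posterior, tune
from vestibench.evaluate import fit_full_cohort_rf, make_folds, mdi_ranking

cohort = generate_cohort(GeneratorConfig(seed=1))
fold = make_folds(cohort, k=10, seed=0)[0]
train = cohort.subset(list(fold.train_ids))
val = cohort.subset(list(fold.val_ids))
test = cohort.subset(list(fold.test_ids))

for kind in ("lr", "rf", "ann"):
    best, _ = tune(default_grid(kind, seed=0), train, val)
    model = fit(best, train)
    post, _ = predict_posterior(model, test)
    print(f"{kind.upper():3s} tuned {best.params}  "
          f"test AUC {roc_auc(post, test.y()):.3f}")

rf = fit_full_cohort_rf(cohort, seed=0)
ranking = mdi_ranking(rf, cohort.schema)
print("\nTop-5 MDI features (full-cohort forest):")
print(ranking.head(5).to_string())
feats = list(ranking["feature"])
print(f"\naggregated vHIT rating ranks {feats.index('vhit_pathological') + 1} "
      f"of {len(feats)} on this cohort")
print("\nOculomotor (VOG) features fill the whole top of the ranking; which "
      "of them leads fluctuates from cohort to cohort because the planted "
      "signals are redundant, but the aggregated vHIT rating sits in the "
      "top 3 for most seeds.")
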