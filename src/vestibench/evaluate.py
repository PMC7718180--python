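"""The benchmarking protocol: stratified CV, model comparison, explanations.

Machine-learning methods are evaluated under stratified k-fold (default
ten-fold) cross-validation with a 90/10 train/test split per fold and a
further 10% of the training part withheld as a validation set for
hyper-parameter tuning and early stopping.  The clinical index tests HINTS
and ABCD² are instead evaluated prospectively on the entire cohort at their
fixed cutoffs (their parameters are not learned), and are flagged as such in
reports.

Model pairs are compared with a two-tailed Wilcoxon signed-rank test on
per-fold accuracies (exact distribution for up to 25 non-zero differences,
normal approximation above).  Random-forest feature importance uses the mean
decrease in impurity (MDI); univariate follow-up per feature uses the
Chi-square test for binary features and the two-sided Mann–Whitney U test
for continuous ones.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from . import baselines, gmc
from .cohort import Cohort, LABEL_NEURITIS, LABEL_STROKE
from .metrics import ConfusionCounts, UndefinedAUCError, accuracy, f1_score, roc_auc
from .schema import FeatureSchema
from .scores import score_cohort, score_roc
from ._rng import derive_seed

log = logging.getLogger(__name__)

ML_METHODS = ("LR", "RF", "ANN", "SingleGMC", "MultiGMC")
INDEX_TESTS = ("HINTS", "ABCD2")
ALL_METHODS = INDEX_TESTS + ML_METHODS


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: disjoint train/validation/test id sets."""

    fold: int
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    stratification: dict = field(default_factory=dict)

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("fold parts are not disjoint")


def make_folds(cohort: Cohort, k: int = 10, seed: int = 0,
               val_fraction: float = 0.1, stratified: bool = True) -> list:
    """Stratified k-fold splits with a nested validation part.

    Test folds partition the cohort with per-fold class proportions within one
    patient of the global proportions; the validation set is drawn stratified
    from each fold's training part (about ``val_fraction`` of it).  The same
    seed reproduces identical splits.  ``stratified=False`` relaxes to plain
    K-fold (e.g. for leave-one-out).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = cohort.y()
    ids = np.array(cohort.patient_ids)
    if stratified and min((y == 0).sum(), (y == 1).sum()) < k:
        raise ValueError(f"each class must have at least k={k} members for "
                         "stratified folds")

    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids, y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids)

    folds = []
    for f, (train_pool, test) in enumerate(split_iter):
        pool_ids, pool_y = ids[train_pool], y[train_pool]
        strat = pool_y if stratified and min(np.bincount(pool_y)) >= 2 else None
        n_val = max(2, int(round(val_fraction * len(pool_ids))))
        tr, va = train_test_split(np.arange(len(pool_ids)), test_size=n_val,
                                  random_state=derive_seed(seed, f"val-{f}"),
                                  stratify=strat)
        counts = {
            "train": {LABEL_STROKE: int(pool_y[tr].sum()),
                      LABEL_NEURITIS: int((pool_y[tr] == 0).sum())},
            "val": {LABEL_STROKE: int(pool_y[va].sum()),
                    LABEL_NEURITIS: int((pool_y[va] == 0).sum())},
            "test": {LABEL_STROKE: int(y[test].sum()),
                     LABEL_NEURITIS: int((y[test] == 0).sum())},
        }
        folds.append(FoldSplit(f, tuple(pool_ids[tr]), tuple(pool_ids[va]),
                               tuple(ids[test]), counts))
    return folds


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (exact midrank enumeration / normal approximation)
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x, y, exact_limit: int = 25):
    """Two-tailed paired Wilcoxon signed-rank test.

    Zero differences are dropped.  With at most ``exact_limit`` non-zero
    differences the p-value comes from the exact null distribution of the
    positive-rank sum (midranks; enumerated by dynamic programming over all
    2^n sign assignments); above that, a tie-corrected normal approximation
    is used.  Returns ``(W_plus, p_value)``; all-zero differences give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("paired samples contain NaN (incomplete fold metrics)")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_limit:
        # integer grid: twice the midranks are integers
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        # dp[s] = number of sign assignments with positive-rank sum s (in 2x units)
        dp = np.zeros(total + 1, dtype=float)
        dp[0] = 1.0
        for r in r2:
            dp[r:] = dp[r:] + dp[:-r or None]
        dp /= 2.0 ** n
        w2 = int(round(2 * w_plus))
        cdf = float(dp[: w2 + 1].sum())
        sf = float(dp[w2:].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
        return w_plus, p

    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var == 0:
        return w_plus, 1.0
    z = (w_plus - mn) / np.sqrt(var)
    return w_plus, float(2.0 * stats.norm.sf(abs(z)))


def compare_models(report: "EvalReport", method_a: str, method_b: str) -> float:
    """Two-tailed Wilcoxon signed-rank p-value on per-fold accuracies."""
    acc_a = report.fold_metric(method_a, "accuracy")
    acc_b = report.fold_metric(method_b, "accuracy")
    _, p = wilcoxon_signed_rank(acc_a, acc_b)
    return p


# ---------------------------------------------------------------------------
# Feature importance and univariate follow-up
# ---------------------------------------------------------------------------

def mdi_ranking(fitted, schema: FeatureSchema) -> pd.DataFrame:
    """Mean-decrease-in-impurity feature ranking from a fitted random forest.

    Importances are the sklearn MDI values (impurity decrease per split,
    weighted by node sample fraction, averaged over trees), normalized to sum
    to 1; ordering is descending with a stable tie-break by schema order.
    """
    est = fitted.estimator if isinstance(fitted, baselines.FittedModel) else fitted
    if not isinstance(est, RandomForestClassifier):
        raise TypeError("mdi_ranking requires a random-forest model")
    try:
        imp = np.asarray(est.feature_importances_, float)
    except Exception as exc:
        raise ValueError("forest is not fitted") from exc
    if imp.sum() > 0:
        imp = imp / imp.sum()
    order = np.argsort(-imp, kind="stable")
    return pd.DataFrame({
        "rank": np.arange(1, len(imp) + 1),
        "feature": [schema.names[i] for i in order],
        "importance": imp[order],
    }).set_index("rank")


def fit_full_cohort_rf(cohort: Cohort, n_trees: int = 50, seed: int = 0):
    """Forest fitted on the full labeled cohort, for the MDI ranking."""
    spec = baselines.ModelSpec("rf", {"n_trees": n_trees}, seed=seed)
    return baselines.fit(spec, cohort)


def univariate_table(cohort: Cohort, features=None) -> pd.DataFrame:
    """Per-feature class comparison (neuritis vs. stroke).

    Binary features: 2×2 Chi-square test without continuity correction;
    continuous/ordinal features: two-sided Mann–Whitney U with tie-corrected
    normal approximation.  Summaries are % for binary and mean ± sd
    otherwise, over observed values.  No multiple-testing correction is
    applied (noted in the output).
    """
    if cohort.labels is None:
        raise ValueError("univariate_table requires a labeled cohort")
    features = list(features) if features is not None else list(cohort.schema.names)
    y = cohort.y()
    rows = []
    for name in features:
        kind = cohort.schema.kind(name)
        col = cohort.values[name].to_numpy(float)
        g0 = col[(y == 0) & ~np.isnan(col)]
        g1 = col[(y == 1) & ~np.isnan(col)]
        row = {"feature": name, "kind": kind, "note": ""}
        if kind == "binary":
            row["test"] = "chi2"
            row["neuritis"] = float(g0.mean()) if len(g0) else np.nan
            row["stroke"] = float(g1.mean()) if len(g1) else np.nan
            table = np.array([[(g0 == 1).sum(), (g0 == 0).sum()],
                              [(g1 == 1).sum(), (g1 == 0).sum()]], float)
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                row["statistic"], row["p_value"] = 0.0, 1.0
                row["note"] = "degenerate 2x2 table"
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                row["statistic"], row["p_value"] = float(chi2), float(p)
        else:
            row["test"] = "mannwhitney"
            row["neuritis"] = float(g0.mean()) if len(g0) else np.nan
            row["neuritis_sd"] = float(g0.std(ddof=1)) if len(g0) > 1 else 0.0
            row["stroke"] = float(g1.mean()) if len(g1) else np.nan
            row["stroke_sd"] = float(g1.std(ddof=1)) if len(g1) > 1 else 0.0
            pooled = np.concatenate([g0, g1])
            if len(g0) == 0 or len(g1) == 0 or np.all(pooled == pooled[0]):
                row["statistic"], row["p_value"] = np.nan, 1.0
                row["note"] = "zero variance in both classes"
            else:
                u, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
                row["statistic"], row["p_value"] = float(u), float(p)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("feature")
    df.attrs["note"] = "no multiple-testing correction applied"
    return df


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-fold and aggregate results of a benchmark run."""

    per_fold: pd.DataFrame            # method, fold, accuracy, f1, auc
    index_tests: dict                 # method -> metrics on the full cohort
    n_folds: int
    seed: int
    fold_stratification: list
    failures: list = field(default_factory=list)
    notes: tuple = (
        "index tests evaluated prospectively on the full cohort, not under CV",
    )

    def fold_metric(self, method: str, metric: str) -> np.ndarray:
        sel = self.per_fold[self.per_fold["method"] == method]
        if sel.empty:
            raise KeyError(f"no per-fold results for method {method!r}")
        return sel.sort_values("fold")[metric].to_numpy(float)

    def aggregates(self) -> pd.DataFrame:
        """Median per-method metrics over folds (the default aggregate)."""
        agg = self.per_fold.groupby("method")[["accuracy", "f1", "auc"]].median()
        return agg.sort_index()

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "notes": list(self.notes),
            "index_tests": self.index_tests,
            "per_fold": self.per_fold.to_dict(orient="records"),
            "aggregates_median": {
                m: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for m, row in self.aggregates().iterrows()
            },
            "fold_stratification": self.fold_stratification,
            "failures": self.failures,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _posterior_metrics(y_true, posteriors):
    from .metrics import binarize

    decisions = binarize(np.asarray(posteriors, float))
    c = ConfusionCounts.from_predictions(y_true, decisions)
    try:
        auc = roc_auc(posteriors, y_true)
    except UndefinedAUCError:
        auc = np.nan
    return accuracy(c), f1_score(c), auc


def _index_test_results(cohort: Cohort) -> dict:
    table = score_cohort(cohort, missing_policy="conservative")
    y = cohort.y()
    out = {}
    for method, score_col, dec_col in (("HINTS", "hints", "hints_stroke"),
                                       ("ABCD2", "abcd2", "abcd2_stroke")):
        c = ConfusionCounts.from_predictions(y, table[dec_col].to_numpy(int))
        *_, auc = score_roc(table[score_col].to_numpy(float), y)
        out[method] = {"accuracy": accuracy(c), "f1": f1_score(c), "auc": auc,
                       "evaluated_on": "full_cohort"}
    return out


def run_benchmark(cohort: Cohort, methods=ALL_METHODS, k: int = 10, seed: int = 0,
                  folds=None, grids=None, gmc_config=None) -> EvalReport:
    """Benchmark index tests and ML methods on one cohort.

    Index tests are scored once on the full cohort at their fixed cutoffs
    plus a cutoff-sweep AUC.  Each ML method is tuned on the fold's
    validation part (grid search for the baselines, early stopping for the
    completion models) and evaluated on the fold's test part.  A method
    failing on a fold is recorded and skipped, not fatal.
    """
    methods = list(methods)
    unknown = [m for m in methods if m not in ALL_METHODS]
    if unknown:
        raise ValueError(f"unknown method {unknown[0]!r}; choose from {ALL_METHODS}")
    grids = grids or {}
    folds = folds if folds is not None else make_folds(cohort, k=k, seed=seed)

    index_tests = {}
    for m in [m for m in methods if m in INDEX_TESTS]:
        index_tests[m] = _index_test_results(cohort)[m]

    ml_methods = [m for m in methods if m in ML_METHODS]
    graphs = {}
    if any(m in ("SingleGMC", "MultiGMC") for m in ml_methods):
        g_age = gmc.build_similarity_graph(cohort, "age")
        g_abcd2 = gmc.build_similarity_graph(cohort, "abcd2")
        graphs["SingleGMC"] = [gmc.sum_graphs(g_age, g_abcd2)]
        graphs["MultiGMC"] = [g_age, g_abcd2]

    rows, failures = [], []
    for split in folds:
        test = cohort.subset(list(split.test_ids))
        y_test = test.y()
        train = cohort.subset(list(split.train_ids))
        val = cohort.subset(list(split.val_ids))
        for method in ml_methods:
            try:
                if method in ("SingleGMC", "MultiGMC"):
                    cfg = gmc_config or gmc.GmcConfig()
                    cfg = gmc.GmcConfig(**{**cfg.__dict__,
                                           "seed": derive_seed(seed, f"{method}-{split.fold}")})
                    problem = gmc.CompletionProblem(
                        cohort, graphs[method], split.train_ids,
                        split.val_ids, split.test_ids)
                    model = gmc.fit_gmc(problem, cfg)
                    post, _ = gmc.predict_gmc(model, problem, list(split.test_ids))
                else:
                    kind = method.lower()
                    grid = grids.get(method) or baselines.default_grid(
                        kind, seed=derive_seed(seed, f"{method}-{split.fold}"))
                    best, _ = baselines.tune(grid, train, val)
                    fitted = baselines.fit(best, train)
                    post, _ = baselines.predict_posterior(fitted, test)
                acc, f1, auc = _posterior_metrics(y_test, post)
                rows.append({"method": method, "fold": split.fold,
                             "accuracy": acc, "f1": f1, "auc": auc})
            except Exception as exc:  # noqa: BLE001 - per-fold failures are recorded
                log.warning("method %s failed on fold %d: %s", method, split.fold, exc)
                failures.append({"method": method, "fold": split.fold, "error": str(exc)})
                rows.append({"method": method, "fold": split.fold,
                             "accuracy": np.nan, "f1": np.nan, "auc": np.nan})

    per_fold = pd.DataFrame(rows, columns=["method", "fold", "accuracy", "f1", "auc"])
    return EvalReport(per_fold=per_fold, index_tests=index_tests,
                      n_folds=len(folds), seed=seed,
                      fold_stratification=[f.stratification for f in folds],
                      failures=failures)
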