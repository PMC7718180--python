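"""Classical classifiers: elastic-net logistic regression, random forest, MLP.

All three are scikit-learn estimators wrapped with a shared preprocessing
contract: missing features are imputed with per-feature training-set means
(continuous) or modes (binary), and inputs are z-scored by training statistics
for the logistic regression and the neural network (the forest sees unscaled
values).  The architectures and hyper-parameter ranges are fixed by the study
design: LR combines L1 and L2 penalties with the balance tuned as a
hyper-parameter; the forest size is tuned within 5–50 trees; the MLP maps the
305 inputs through hidden layers of 128 and 64 neurons to a 2-class
probabilistic output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .cohort import Cohort
from .metrics import binarize, roc_auc

log = logging.getLogger(__name__)

KINDS = ("lr", "rf", "ann")
RF_TREE_RANGE = (5, 50)
ANN_HIDDEN = (128, 64)


@dataclass(frozen=True)
class ModelSpec:
    """A model family member: kind plus its hyper-parameters.

    ``params`` keys by kind — lr: ``l1_ratio``, ``C``; rf: ``n_trees``;
    ann: ``learning_rate``, ``max_epochs``.
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "rf":
            n = self.params.get("n_trees", 50)
            if not RF_TREE_RANGE[0] <= n <= RF_TREE_RANGE[1]:
                raise ValueError(f"n_trees must lie in {RF_TREE_RANGE}, got {n}")
        if self.kind == "lr":
            r = self.params.get("l1_ratio", 0.5)
            if not 0 <= r <= 1:
                raise ValueError(f"l1_ratio must lie in [0, 1], got {r}")

    def __hash__(self):
        return hash((self.kind, tuple(sorted(self.params.items())), self.seed))

    def capacity_key(self):
        """Sort key so that ties in tuning resolve to the simplest model."""
        if self.kind == "rf":
            return (self.params.get("n_trees", 50),)
        if self.kind == "lr":
            # smaller C = stronger regularization = simpler
            return (self.params.get("C", 1.0), self.params.get("l1_ratio", 0.5))
        return (self.params.get("max_epochs", 200), self.params.get("learning_rate", 1e-3))


def default_grid(kind: str, seed: int = 0) -> list:
    """The declared hyper-parameter grid per model family."""
    if kind == "lr":
        return [ModelSpec("lr", {"l1_ratio": r, "C": c}, seed)
                for c in (0.1, 1.0) for r in (0.0, 0.5, 1.0)]
    if kind == "rf":
        return [ModelSpec("rf", {"n_trees": n}, seed) for n in (5, 15, 30, 50)]
    if kind == "ann":
        return [ModelSpec("ann", {"learning_rate": 1e-3, "max_epochs": 200}, seed)]
    raise ValueError(f"unknown model kind {kind!r}")


def _build_estimator(spec: ModelSpec):
    if spec.kind == "lr":
        return LogisticRegression(
            penalty="elasticnet", solver="saga",
            l1_ratio=spec.params.get("l1_ratio", 0.5),
            C=spec.params.get("C", 1.0),
            max_iter=3000, tol=1e-4, random_state=spec.seed,
        )
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=spec.params.get("n_trees", 50), random_state=spec.seed
        )
    return MLPClassifier(
        hidden_layer_sizes=ANN_HIDDEN, activation="relu", solver="adam",
        learning_rate_init=spec.params.get("learning_rate", 1e-3),
        max_iter=spec.params.get("max_epochs", 200),
        random_state=spec.seed,
    )


class FittedModel:
    """A fitted classifier plus its frozen preprocessing statistics."""

    def __init__(self, spec, estimator, feature_names, impute_values,
                 scale_mean=None, scale_std=None, metadata=None):
        self.spec = spec
        self.estimator = estimator
        self.feature_names = list(feature_names)
        self.impute_values = np.asarray(impute_values, float)
        self.scale_mean = scale_mean
        self.scale_std = scale_std
        self.metadata = metadata or {}
        self._stroke_col = int(np.argmax(estimator.classes_ == 1))

    def transform(self, cohort: Cohort) -> np.ndarray:
        if list(cohort.schema.names) != self.feature_names:
            extra = set(cohort.schema.names) ^ set(self.feature_names)
            name = sorted(extra)[0] if extra else "feature order"
            raise ValueError(f"schema mismatch on {name!r}")
        X = cohort.values.to_numpy(float)
        miss = np.isnan(X)
        X = np.where(miss, np.broadcast_to(self.impute_values, X.shape), X)
        if self.scale_mean is not None:
            X = (X - self.scale_mean) / self.scale_std
        return X


def fit(spec: ModelSpec, train: Cohort) -> FittedModel:
    """Fit a baseline model on a labeled cohort (deterministic given seed)."""
    y = train.y()
    if len(set(y.tolist())) < 2:
        raise ValueError("training cohort must contain both classes")
    X = train.values.to_numpy(float)

    impute = np.empty(X.shape[1])
    binary = set(train.schema.binary_names())
    for j, name in enumerate(train.schema.names):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0:
            impute[j] = 0.0
        elif name in binary:
            impute[j] = float(np.round(obs.mean()))  # mode of a 0/1 column
        else:
            impute[j] = float(obs.mean())
    Xf = np.where(np.isnan(X), np.broadcast_to(impute, X.shape), X)

    scale_mean = scale_std = None
    if spec.kind in ("lr", "ann"):
        scale_mean = Xf.mean(axis=0)
        scale_std = Xf.std(axis=0)
        scale_std = np.where(scale_std == 0, 1.0, scale_std)
        Xf = (Xf - scale_mean) / scale_std

    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings at small epoch caps
        est.fit(Xf, y)
    meta = {"n_train": len(y), "class_counts": train.class_counts()}
    return FittedModel(spec, est, train.schema.names, impute, scale_mean, scale_std, meta)


def predict_posterior(model: FittedModel, test: Cohort):
    """Posterior probability of stroke per patient, with binarized decisions.

    Returns ``(posteriors, decisions)`` aligned with ``test.patient_ids``.
    """
    if len(test) == 0:
        return np.array([]), np.array([], int)
    X = model.transform(test)
    post = model.estimator.predict_proba(X)[:, model._stroke_col]
    return post, binarize(post)


def tune(grid, train: Cohort, validation: Cohort):
    """Pick the grid spec with the best validation AUC.

    Ties resolve to the smallest-capacity spec; specs that fail to fit are
    skipped with a logged warning.  Returns ``(best_spec, results)`` where
    ``results`` maps each evaluated spec to its validation AUC.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    overlap = set(train.patient_ids) & set(validation.patient_ids)
    if overlap:
        raise ValueError(f"validation overlaps training: {sorted(overlap)[:3]}")

    y_val = validation.y()
    best_spec, best_auc, results = None, -np.inf, {}
    for spec in sorted(grid, key=lambda s: s.capacity_key()):
        try:
            model = fit(spec, train)
            post, _ = predict_posterior(model, validation)
            auc = roc_auc(post, y_val)
        except Exception as exc:  # noqa: BLE001 - tuning must survive bad specs
            log.warning("tuning: spec %s failed (%s); skipped", spec, exc)
            continue
        results[spec] = auc
        if auc > best_auc:
            best_spec, best_auc = spec, auc
    if best_spec is None:
        raise ValueError("every spec in the grid failed")
    return best_spec, results
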