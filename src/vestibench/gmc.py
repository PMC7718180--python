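"""Geometric matrix completion on patient-similarity graphs.

Patients are nodes of one or more population graphs built from meta-features:
two patients are connected if their ages differ by at most 5 years (age graph)
or their ABCD² scores by at most 1 point (ABCD² graph).  The single-graph
variant (SingleGMC) sums the two criteria into one graph with weights
{0, 1, 2}; the multi-graph variant (MultiGMC) keeps them separate, learns one
spectral convolutional layer per graph, and fuses the per-graph patient
representations by self-attention before the classification head.

The model completes a masked patients × (features + label) matrix
transductively: all patients are graph nodes, feature entries are observed
where measured, and the label column is observed only for training patients.
The loss is a masked sum — cross-entropy on observed training labels plus
``mu`` times the squared reconstruction error on observed feature entries —
so masked entries (missing features, held-out labels) are never read.

Spectral filtering uses Chebyshev polynomials of the symmetric-normalized
Laplacian rescaled with the λ_max = 2 bound (L~ = L − I); a degree-0 node has
an identity Laplacian row, so an edgeless graph reduces the filter to a
graph-independent linear map.  Since the Chebyshev propagation T_k(L~)X of the
fixed input is precomputed per graph, training is plain dense linear algebra;
gradients are computed analytically and optimised full-batch with
adaptive-moment (Adam) updates or plain gradient descent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
import numpy as np

from .cohort import Cohort
from .metrics import roc_auc
from .scores import abcd2_score

log = logging.getLogger(__name__)

AGE_THRESHOLD_YEARS = 5.0
ABCD2_THRESHOLD_POINTS = 1.0


# ---------------------------------------------------------------------------
# Population graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationGraph:
    """Symmetric, non-negative weighted adjacency over a fixed patient order."""

    patient_ids: tuple
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.shape != (len(self.patient_ids),) * 2:
            raise ValueError("adjacency shape does not match patient count")
        if not np.allclose(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if np.any(w < 0):
            raise ValueError("adjacency weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def normalized_laplacian(self) -> np.ndarray:
        """Symmetric-normalized Laplacian; identity row for degree-0 nodes."""
        w = self.weights
        deg = w.sum(axis=1)
        dinv = np.zeros_like(deg)
        nz = deg > 0
        dinv[nz] = 1.0 / np.sqrt(deg[nz])
        return np.eye(self.n) - (dinv[:, None] * w) * dinv[None, :]

    def scaled_laplacian(self) -> np.ndarray:
        """L~ = L − I, rescaling the spectrum with the λ_max = 2 bound."""
        return self.normalized_laplacian() - np.eye(self.n)

    def edge_list(self):
        """Upper-triangular (i, j, weight) tuples of the non-zero edges."""
        iu, ju = np.triu_indices(self.n, k=1)
        sel = self.weights[iu, ju] > 0
        return [(int(i), int(j), float(self.weights[i, j]))
                for i, j in zip(iu[sel], ju[sel])]


def _abcd2_meta_scores(cohort: Cohort) -> np.ndarray:
    """ABCD² score per patient; NaN when any component input is missing."""
    out = np.full(len(cohort), np.nan)
    for i, rec in enumerate(cohort.iter_records()):
        c = rec.abcd2_components()
        if any(v is None for v in c.values()):
            continue
        out[i] = abcd2_score(c["age"], c["sbp"], c["dbp"], c["unilateral_weakness"],
                             c["speech_impairment_wo_weakness"], c["duration_minutes"],
                             c["diabetes"]).score
    return out


def build_similarity_graph(cohort: Cohort, criterion: str) -> PopulationGraph:
    """Binary similarity graph over a cohort for one meta-feature criterion.

    ``criterion='age'`` connects patients whose ages differ by at most
    5 years; ``criterion='abcd2'`` connects patients whose ABCD² scores differ
    by at most 1 point.  A patient with a missing meta-feature gets no edges
    under that criterion (conservative choice, logged).
    """
    if criterion == "age":
        meta = cohort.values["age"].to_numpy(float)
        thr = AGE_THRESHOLD_YEARS
    elif criterion == "abcd2":
        meta = _abcd2_meta_scores(cohort)
        thr = ABCD2_THRESHOLD_POINTS
    else:
        raise ValueError(f"unknown similarity criterion {criterion!r}")

    n_missing = int(np.isnan(meta).sum())
    if n_missing:
        log.info("similarity graph %r: %d patients with missing meta-feature "
                 "left unconnected", criterion, n_missing)
    diff = np.abs(meta[:, None] - meta[None, :])
    w = (diff <= thr).astype(float)
    w[np.isnan(diff)] = 0.0
    np.fill_diagonal(w, 0.0)
    return PopulationGraph(tuple(cohort.patient_ids), w, provenance=criterion)


def sum_graphs(g_age: PopulationGraph, g_abcd2: PopulationGraph) -> PopulationGraph:
    """Element-wise sum of two graphs over the same patient ordering."""
    if g_age.patient_ids != g_abcd2.patient_ids:
        raise ValueError("graphs are over different patient orderings")
    return PopulationGraph(g_age.patient_ids, g_age.weights + g_abcd2.weights,
                           provenance=f"{g_age.provenance}+{g_abcd2.provenance}")


# ---------------------------------------------------------------------------
# Spectral filtering and attention primitives
# ---------------------------------------------------------------------------

def chebyshev_basis(graph: PopulationGraph, signal: np.ndarray, order: int) -> list:
    """[T_0(L~)X, ..., T_K(L~)X] via the Chebyshev recurrence."""
    lt = graph.scaled_laplacian()
    basis = [np.asarray(signal, float)]
    if order >= 1:
        basis.append(lt @ basis[0])
    for _ in range(2, order + 1):
        basis.append(2.0 * (lt @ basis[-1]) - basis[-2])
    return basis


def spectral_convolve(graph: PopulationGraph, signal: np.ndarray, coefficients) -> np.ndarray:
    """Chebyshev spectral graph convolution.

    ``coefficients`` is a sequence of K+1 (C_in × C_out) filter matrices; the
    output is ``sum_k T_k(L~) X theta_k``.  With K = 0 this is a per-channel
    linear map of the input, independent of the graph.
    """
    coefficients = [np.atleast_2d(np.asarray(c, float)) for c in coefficients]
    basis = chebyshev_basis(graph, signal, len(coefficients) - 1)
    out = basis[0] @ coefficients[0]
    for t, theta in zip(basis[1:], coefficients[1:]):
        out = out + t @ theta
    return out


def attention_weights(scores: np.ndarray) -> np.ndarray:
    """Softmax across the graph axis (last axis) of raw attention scores."""
    s = np.asarray(scores, float)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def self_attention_fuse(embeddings, attn_vector=None, attn_bias=None):
    """Convex per-patient combination of per-graph embeddings.

    Each graph g gets a scalar score per patient from a learned linear
    functional of its embedding, ``s_g = H_g @ a + b_g``; the weights are the
    softmax of these scores across graphs and sum to 1 per patient.  Returns
    ``(fused, weights)``.  A single graph fuses to itself with weight 1.
    """
    embeddings = [np.asarray(h, float) for h in embeddings]
    if not embeddings:
        raise ValueError("at least one graph embedding is required")
    widths = {h.shape for h in embeddings}
    if len(widths) != 1:
        raise ValueError(f"embedding shape mismatch: {sorted(widths)}")
    n, h = embeddings[0].shape
    g = len(embeddings)
    a = np.zeros(h) if attn_vector is None else np.asarray(attn_vector, float)
    b = np.zeros(g) if attn_bias is None else np.asarray(attn_bias, float)
    scores = np.stack([emb @ a + b[k] for k, emb in enumerate(embeddings)], axis=-1)
    alpha = attention_weights(scores)
    fused = sum(alpha[:, k:k + 1] * emb for k, emb in enumerate(embeddings))
    return fused, alpha


# ---------------------------------------------------------------------------
# Completion problem
# ---------------------------------------------------------------------------

class CompletionProblem:
    """Masked patients × (features + label) matrix plus its graphs.

    ``X`` holds the feature columns and one final label column (+1 stroke,
    −1 neuritis at the input; the loss uses 0/1 targets); ``mask`` is True for
    entries the loss and the model input may read: observed features, and the
    label only for training patients.
    """

    def __init__(self, cohort: Cohort, graphs, train_ids, val_ids=(), test_ids=()):
        ids = cohort.patient_ids
        for gph in graphs:
            if tuple(gph.patient_ids) != tuple(ids):
                raise ValueError("graph patient ordering does not match cohort")
        pos = {pid: i for i, pid in enumerate(ids)}
        missing = [p for p in list(train_ids) + list(val_ids) + list(test_ids)
                   if p not in pos]
        if missing:
            raise ValueError(f"patient {missing[0]!r} absent from the graphs")

        self.cohort = cohort
        self.graphs = list(graphs)
        self.train_idx = np.array([pos[p] for p in train_ids], int)
        self.val_idx = np.array([pos[p] for p in val_ids], int)
        self.test_idx = np.array([pos[p] for p in test_ids], int)
        if len(self.train_idx) == 0:
            raise ValueError("no observed training labels")

        feats = cohort.values.to_numpy(float)
        y = cohort.y().astype(float)
        self.n, self.d = feats.shape
        self.X = np.concatenate([feats, y[:, None]], axis=1)
        fmask = ~np.isnan(feats)
        lmask = np.zeros((self.n, 1), bool)
        lmask[self.train_idx] = True
        self.mask = np.concatenate([fmask, lmask], axis=1)

    def labels01(self, idx) -> np.ndarray:
        return self.X[idx, -1].astype(int)

    def model_input(self, col_mean, col_std) -> np.ndarray:
        """Standardized, zero-filled input; reads only unmasked entries.

        Feature columns are z-scored by the supplied per-column statistics;
        the label column is mapped to ±1 with 0 for hidden labels.
        """
        feats = np.where(self.mask[:, :-1], self.X[:, :-1], np.nan)
        z = (feats - col_mean) / col_std
        z = np.where(np.isnan(z), 0.0, z)
        lab = np.zeros((self.n, 1))
        lab[self.train_idx, 0] = 2.0 * self.X[self.train_idx, -1] - 1.0
        return np.concatenate([z, lab], axis=1)

    def observed_feature_stats(self):
        feats = np.where(self.mask[:, :-1], self.X[:, :-1], np.nan)
        mean = np.nanmean(feats, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        std = np.nanstd(feats, axis=0)
        std = np.where((std == 0) | np.isnan(std), 1.0, std)
        return mean, std


# ---------------------------------------------------------------------------
# Model, loss, training
# ---------------------------------------------------------------------------

@dataclass
class GmcConfig:
    """Hyper-parameters of the completion model.

    ``order`` is the Chebyshev order K (one spectral layer per graph),
    ``hidden`` the embedding width, ``mu`` the weight of the feature
    reconstruction term relative to the label cross-entropy, ``optimizer``
    'adam' or 'gd', and ``patience`` the early-stopping patience in epochs on
    validation AUC (0 disables early stopping).
    """

    order: int = 3
    hidden: int = 32
    mu: float = 1.0
    learning_rate: float = 0.02
    epochs: int = 300
    patience: int = 40
    optimizer: str = "adam"
    seed: int = 0


class GmcModel:
    """A fitted geometric matrix-completion model (parameters + provenance)."""

    def __init__(self, config: GmcConfig, params: dict, col_mean, col_std,
                 n_graphs: int, loss_history=None, attention=None):
        self.config = config
        self.params = params
        self.col_mean = np.asarray(col_mean, float)
        self.col_std = np.asarray(col_std, float)
        self.n_graphs = n_graphs
        self.loss_history = list(loss_history or [])
        self.attention = attention

    def to_json(self) -> str:
        blob = {
            "config": asdict(self.config),
            "n_graphs": self.n_graphs,
            "col_mean": self.col_mean.tolist(),
            "col_std": self.col_std.tolist(),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        return json.dumps(blob, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GmcModel":
        blob = json.loads(text)
        params = {k: np.asarray(v, float) for k, v in blob["params"].items()}
        return cls(GmcConfig(**blob["config"]), params, blob["col_mean"],
                   blob["col_std"], blob["n_graphs"])


def _init_params(rng, n_graphs, d_in, hidden, d_feat, order):
    params = {}
    fan_in = d_in * (order + 1)
    for g in range(n_graphs):
        params[f"theta_{g}"] = rng.normal(0, np.sqrt(2.0 / (fan_in + hidden)),
                                          (fan_in, hidden))
        params[f"btheta_{g}"] = np.zeros(hidden)
    params["attn_a"] = rng.normal(0, 1.0 / np.sqrt(hidden), hidden)
    params["attn_b"] = np.zeros(n_graphs)
    params["W_c"] = rng.normal(0, np.sqrt(2.0 / (hidden + 2)), (hidden, 2))
    params["b_c"] = np.zeros(2)
    params["W_r"] = rng.normal(0, np.sqrt(2.0 / (hidden + d_feat)), (hidden, d_feat))
    params["b_r"] = np.zeros(d_feat)
    return params


def _forward(params, S_list, problem, target_z, fmask, train_idx, mu):
    """Forward pass; returns (loss, cache).  Reads X only through S/targets."""
    G = len(S_list)
    Z, H = [], []
    for g in range(G):
        z = S_list[g] @ params[f"theta_{g}"] + params[f"btheta_{g}"]
        Z.append(z)
        H.append(np.maximum(z, 0.0))
    if G == 1:
        alpha = np.ones((H[0].shape[0], 1))
        fused = H[0]
    else:
        scores = np.stack([h @ params["attn_a"] + params["attn_b"][g]
                           for g, h in enumerate(H)], axis=-1)
        alpha = attention_weights(scores)
        fused = sum(alpha[:, g:g + 1] * H[g] for g in range(G))

    logits = fused @ params["W_c"] + params["b_c"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1)) + logits.max(axis=1)
    logp = logits - logsumexp[:, None]
    y_tr = problem.labels01(train_idx)
    ce = -logp[train_idx, y_tr].mean()

    recon = fused @ params["W_r"] + params["b_r"]
    n_obs = max(int(fmask.sum()), 1)
    resid = np.where(fmask, recon - target_z, 0.0)
    rec = (resid ** 2).sum() / n_obs

    loss = ce + mu * rec
    cache = dict(Z=Z, H=H, alpha=alpha, fused=fused, logits=logits, logp=logp,
                 recon=recon, resid=resid, n_obs=n_obs, y_tr=y_tr)
    return loss, cache


def _backward(params, S_list, cache, train_idx, mu):
    G = len(S_list)
    H, alpha, fused = cache["H"], cache["alpha"], cache["fused"]
    n = fused.shape[0]
    grads = {}

    # cross-entropy head
    p = np.exp(cache["logp"])
    dlogits = np.zeros_like(p)
    dlogits[train_idx] = p[train_idx]
    dlogits[train_idx, cache["y_tr"]] -= 1.0
    dlogits /= max(len(train_idx), 1)
    grads["W_c"] = fused.T @ dlogits
    grads["b_c"] = dlogits.sum(axis=0)
    dfused = dlogits @ params["W_c"].T

    # reconstruction head
    drecon = 2.0 * mu * cache["resid"] / cache["n_obs"]
    grads["W_r"] = fused.T @ drecon
    grads["b_r"] = drecon.sum(axis=0)
    dfused = dfused + drecon @ params["W_r"].T

    # attention fusion
    dH = [alpha[:, g:g + 1] * dfused for g in range(G)]
    if G > 1:
        dalpha = np.stack([(dfused * H[g]).sum(axis=1) for g in range(G)], axis=-1)
        dscores = alpha * (dalpha - (alpha * dalpha).sum(axis=-1, keepdims=True))
        grads["attn_a"] = sum(H[g].T @ dscores[:, g] for g in range(G))
        grads["attn_b"] = dscores.sum(axis=0)
        for g in range(G):
            dH[g] = dH[g] + np.outer(dscores[:, g], params["attn_a"])
    else:
        grads["attn_a"] = np.zeros_like(params["attn_a"])
        grads["attn_b"] = np.zeros_like(params["attn_b"])

    for g in range(G):
        dZ = dH[g] * (cache["Z"][g] > 0)
        grads[f"theta_{g}"] = S_list[g].T @ dZ
        grads[f"btheta_{g}"] = dZ.sum(axis=0)
    return grads


def gmc_loss(params, problem: CompletionProblem, config: GmcConfig,
             col_stats=None) -> float:
    """Masked training loss at the given parameters (no gradient step).

    Exposed so that loss hygiene — zero sensitivity to masked entries of X —
    can be checked numerically.
    """
    col_mean, col_std = col_stats or problem.observed_feature_stats()
    x_in = problem.model_input(col_mean, col_std)
    S_list = [_stack_basis(g, x_in, config.order) for g in problem.graphs]
    fmask = problem.mask[:, :-1]
    target_z = np.where(fmask, (problem.X[:, :-1] - col_mean) / col_std, 0.0)
    loss, _ = _forward(params, S_list, problem, target_z, fmask,
                       problem.train_idx, config.mu)
    return float(loss)


def _stack_basis(graph, signal, order):
    return np.concatenate(chebyshev_basis(graph, signal, order), axis=1)


def fit_gmc(problem: CompletionProblem, config: GmcConfig = None) -> GmcModel:
    """Train the completion model on a problem (deterministic given seed).

    Minimizes cross-entropy on observed training labels plus ``mu`` times the
    masked feature-reconstruction error.  If the problem carries a validation
    index set and ``patience > 0``, training early-stops on validation AUC and
    the best-validation parameters are returned.
    """
    config = config or GmcConfig()
    rng = np.random.default_rng(config.seed)

    col_mean, col_std = problem.observed_feature_stats()
    x_in = problem.model_input(col_mean, col_std)
    S_list = [_stack_basis(g, x_in, config.order) for g in problem.graphs]
    fmask = problem.mask[:, :-1]
    target_z = np.where(fmask, (problem.X[:, :-1] - col_mean) / col_std, 0.0)

    d_in = x_in.shape[1]
    params = _init_params(rng, len(S_list), d_in, config.hidden,
                          problem.d, config.order)

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8

    use_val = config.patience > 0 and len(problem.val_idx) > 0
    y_val = problem.labels01(problem.val_idx) if use_val else None
    if use_val and len(set(y_val.tolist())) < 2:
        use_val = False
    best_auc, best_params, stall = -np.inf, None, 0
    history = []

    for epoch in range(1, config.epochs + 1):
        loss, cache = _forward(params, S_list, problem, target_z, fmask,
                               problem.train_idx, config.mu)
        history.append(float(loss))
        grads = _backward(params, S_list, cache, problem.train_idx, config.mu)
        if config.optimizer == "adam":
            for k in params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mh = m[k] / (1 - b1 ** epoch)
                vh = v[k] / (1 - b2 ** epoch)
                params[k] = params[k] - config.learning_rate * mh / (np.sqrt(vh) + eps)
        elif config.optimizer == "gd":
            for k in params:
                params[k] = params[k] - config.learning_rate * grads[k]
        else:
            raise ValueError(f"unknown optimizer {config.optimizer!r}")

        if use_val:
            post = _posterior(params, S_list)
            try:
                auc = roc_auc(post[problem.val_idx], y_val)
            except ValueError:
                auc = 0.5
            if auc > best_auc + 1e-12:
                best_auc, best_params, stall = auc, {k: p.copy() for k, p in params.items()}, 0
            else:
                stall += 1
                if stall >= config.patience:
                    break

    if use_val and best_params is not None:
        params = best_params

    _, cache = _forward(params, S_list, problem, target_z, fmask,
                        problem.train_idx, config.mu)
    return GmcModel(config, params, col_mean, col_std, len(S_list),
                    loss_history=history, attention=cache["alpha"])


def _posterior(params, S_list):
    G = len(S_list)
    H = [np.maximum(S_list[g] @ params[f"theta_{g}"] + params[f"btheta_{g}"], 0.0)
         for g in range(G)]
    if G == 1:
        fused = H[0]
    else:
        fused, _ = self_attention_fuse(H, params["attn_a"], params["attn_b"])
    logits = fused @ params["W_c"] + params["b_c"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return (e[:, 1] / e.sum(axis=1))


def predict_gmc(model: GmcModel, problem: CompletionProblem, patient_ids=None):
    """Posterior probability of stroke for the requested patients.

    The setting is transductive: every requested patient must be a node of the
    problem's graphs.  Test labels are masked in the problem and are never
    read.  Returns ``(posteriors, decisions)``.
    """
    from .metrics import binarize

    if model.n_graphs != len(problem.graphs):
        raise ValueError("model/problem graph count mismatch")
    x_in = problem.model_input(model.col_mean, model.col_std)
    S_list = [_stack_basis(g, x_in, model.config.order) for g in problem.graphs]
    post = _posterior(model.params, S_list)

    ids = list(problem.cohort.patient_ids)
    if patient_ids is None:
        sel = np.arange(len(ids))
    else:
        pos = {p: i for i, p in enumerate(ids)}
        missing = [p for p in patient_ids if p not in pos]
        if missing:
            raise ValueError(f"patient {missing[0]!r} absent from the graphs")
        sel = np.array([pos[p] for p in patient_ids], int)
    p = post[sel]
    return p, binarize(p)
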