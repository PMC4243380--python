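"""Reference Distance Estimators: semi-supervised linear classifiers.

An RDE with reference feature ``r`` scores an example ``x`` as

    f(x, r) = sum_j (P(r|j) - P(r)) x_j

where ``x_j`` is Boolean feature presence and the probabilities come
from unlabeled co-occurrence counts.  When ``r`` is both discriminative
for the class label and nearly independent of the other features, the
score approximates a classifier trained on label-scale data.

The semi-supervised pipeline (SeRDE):

1. rank candidate reference features by
   ``(1/|I(r)|) * sum_j P(j) |P(j,r)/(P(j)P(r)) - 1|`` ascending, where
   ``I(r) = P(r,y) - alpha P(r,ybar) P(r)`` is counted on labeled data,
   and keep the top k;
2. build one RDE per selected reference;
3. prune from each RDE the features whose dependence ratio deviation
   ``|P(j,r)/(P(j)P(r)) - 1|`` exceeds a threshold ``t``;
4. use the k RDE decision scores as features of a small supervised
   meta-classifier (logistic regression or random forest).

SuRDE is the supervised counterpart: the reference feature is the gold
label itself and probabilities are counted on labeled data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2 as sklearn_chi2
from sklearn.linear_model import LogisticRegression

from goseed.cooc_stats import DEFAULT_EPSILON, CoocStats

STRATEGY_BOUND = "bound"
STRATEGY_CHI_SQUARE = "chi_square"
STRATEGY_FREQUENCY = "frequency"

META_LOGISTIC = "logistic_regression"
META_RANDOM_FOREST = "random_forest"


@dataclass
class RDEConfig:
    """Knobs of the SeRDE pipeline.

    ``k``: number of reference features (ensemble width).
    ``alpha``: weight of the false-positive penalty inside ``I(r)``.
    ``t``: pruning threshold on the dependence-ratio deviation.
    ``strategy``: reference selection — 'bound' (theory-derived ranking),
    'chi_square' (label association) or 'frequency' (most frequent
    unlabeled features).
    ``epsilon``: add-eps smoothing used for every unlabeled probability.
    ``min_candidate_freq``: unlabeled document-frequency floor for the
    candidate reference pool; reference features must be frequent for
    their joint probabilities to be well estimated.
    ``i_floor``: candidates with ``|I(r)|`` below this are dropped from
    bound-strategy ranking to avoid division blow-up.
    """

    k: int = 200
    alpha: float = 1.0
    t: float = 10.0
    strategy: str = STRATEGY_BOUND
    epsilon: float = DEFAULT_EPSILON
    min_candidate_freq: int = 100
    i_floor: float = 1e-6
    meta: str = META_LOGISTIC
    rf_trees: int = 500
    seed: Optional[int] = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class RDEModel:
    """One reference feature with its weight map ``j -> P(r|j) - P(r)``."""

    r: int
    weights: np.ndarray
    pruned: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("RDE weights must be finite")


def build_rde(stats: CoocStats, r: int, eps: float = DEFAULT_EPSILON) -> RDEModel:
    """Construct the RDE for reference ``r`` from unlabeled counts."""
    weights = stats.p_r_given_j_all(r, eps) - stats.p_r(r, eps)
    return RDEModel(r=int(r), weights=weights)


def score_rde(model: RDEModel, x: np.ndarray) -> float:
    """f(x, r) = sum over active features of (P(r|j) - P(r)); 0 for empty x.

    Ids outside the model's vocabulary are ignored.
    """
    ids = np.asarray(x, dtype=np.int64)
    ids = ids[(ids >= 0) & (ids < len(model.weights))]
    return float(model.weights[np.unique(ids)].sum())


def dependence_deviation(stats: CoocStats, r: int,
                         eps: float = DEFAULT_EPSILON) -> np.ndarray:
    """|P(j,r)/(P(j)P(r)) - 1| for every vocabulary feature j."""
    p_j = stats.p_j_all(eps)
    p_r = stats.p_r(r, eps)
    p_jr = stats.p_jr_all(r, eps)
    if eps == 0 and (p_r == 0 or np.any(p_j == 0)):
        raise ZeroDivisionError("zero marginal probability with smoothing off")
    return np.abs(p_jr / (p_j * p_r) - 1.0)


def dependency_expectation(stats: CoocStats, r: int,
                           eps: float = DEFAULT_EPSILON) -> float:
    """Expected dependence of reference ``r`` on the rest of the vocabulary.

    ``sum_j P(j) |P(j,r)/(P(j)P(r)) - 1|`` — zero iff ``r`` is exactly
    independent of every feature.  Low values make good references.
    """
    p_j = stats.p_j_all(eps)
    return float((p_j * dependence_deviation(stats, r, eps)).sum())


def precision_indicator(
    X: sparse.spmatrix, y: Sequence[int], r: int, alpha: float = 1.0
) -> float:
    """I(r) = P(r, y) - alpha * P(r, ybar) * P(r), counted on labeled data.

    High when the reference feature fires mostly inside the positive
    class; the indicator is closely related to the precision of ``r``
    as a one-feature predictor of the class.
    """
    y = np.asarray(y)
    n = len(y)
    if n == 0:
        raise ValueError("no labeled examples")
    col = np.asarray((X[:, r] != 0).todense()).ravel() if sparse.issparse(X) \
        else np.asarray(X)[:, r] != 0
    p_r = col.sum() / n
    p_r_y = (col & (y == 1)).sum() / n
    p_r_ybar = (col & (y == 0)).sum() / n
    return float(p_r_y - alpha * p_r_ybar * p_r)


def select_references(
    stats: CoocStats,
    cfg: RDEConfig,
    labeled: Optional[tuple[sparse.spmatrix, Sequence[int]]] = None,
    candidates: Optional[Sequence[int]] = None,
) -> list[int]:
    """Rank candidate reference features and return the top ``cfg.k`` ids.

    Strategies: 'bound' ranks ascending by
    ``(1/|I(r)|) * dependency_expectation``; 'chi_square' descending by
    chi-square association with the label; 'frequency' descending by
    unlabeled document frequency.  Ties break lexicographically on the
    feature id.  Raises if fewer than k candidates have a defined score.
    """
    if candidates is None:
        candidates = [int(r) for r in stats.ref_ids]
    candidates = sorted(set(int(c) for c in candidates))

    if cfg.strategy == STRATEGY_FREQUENCY:
        scored = [(-stats.count_j(r), r) for r in candidates]
    elif cfg.strategy == STRATEGY_BOUND:
        if labeled is None:
            raise ValueError("bound strategy needs labeled data for I(r)")
        X, y = labeled
        scored = []
        for r in candidates:
            i_r = precision_indicator(X, y, r, cfg.alpha)
            if abs(i_r) < cfg.i_floor:
                continue
            scored.append((dependency_expectation(stats, r, cfg.epsilon) / abs(i_r), r))
    elif cfg.strategy == STRATEGY_CHI_SQUARE:
        if labeled is None:
            raise ValueError("chi_square strategy needs labeled data")
        X, y = labeled
        chi, _ = sklearn_chi2(X, np.asarray(y))
        scored = [(-chi[r], r) for r in candidates if np.isfinite(chi[r])]
    else:
        raise ValueError(f"unknown strategy: {cfg.strategy!r}")

    if cfg.k > len(scored):
        raise ValueError(
            f"k={cfg.k} exceeds the {len(scored)} candidates with a defined score"
        )
    scored.sort()
    return [r for _, r in scored[:cfg.k]]


def prune(model: RDEModel, stats: CoocStats, t: float,
          eps: float = DEFAULT_EPSILON) -> RDEModel:
    """Zero out features whose dependence-ratio deviation exceeds ``t``.

    Strongly ``r``-dependent features violate the independence
    assumption behind the RDE weight estimate, so they are removed from
    the weight map.
    """
    deviation = dependence_deviation(stats, model.r, eps)
    weights = np.where(deviation <= t, model.weights, 0.0)
    return RDEModel(r=model.r, weights=weights, pruned=True)


def transform(X: sparse.spmatrix | Sequence[np.ndarray],
              rdes: Sequence[RDEModel]) -> np.ndarray:
    """Example-by-RDE decision-score matrix (the learned feature set)."""
    W = np.stack([m.weights for m in rdes], axis=1)
    if sparse.issparse(X):
        if X.shape[1] != W.shape[0]:
            raise ValueError("matrix width does not match RDE vocabulary")
        return np.asarray(X @ W)
    return np.array([[score_rde(m, x) for m in rdes] for x in X])


def train_surde(X: sparse.spmatrix, y: Sequence[int]) -> RDEModel:
    """Supervised RDE: the reference feature is the gold label itself.

    Weights are ``P(y|j) - P(y)`` counted on labeled data.  The model's
    ``r`` is set to -1 since the label is not a vocabulary feature.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("SuRDE needs both classes in the training data")
    Xb = (X != 0).astype(np.int64)
    n = Xb.shape[0]
    n_j = np.asarray(Xb.sum(axis=0)).ravel()
    n_jy = np.asarray(Xb[y == 1].sum(axis=0)).ravel()
    p_y = (y == 1).sum() / n
    with np.errstate(invalid="ignore", divide="ignore"):
        p_y_given_j = np.where(n_j > 0, n_jy / np.maximum(n_j, 1), p_y)
    return RDEModel(r=-1, weights=p_y_given_j - p_y)


@dataclass
class EnsembleModel:
    """Meta-classifier over k RDE decision scores plus a tuned cutoff."""

    rdes: list
    meta: object
    meta_kind: str
    threshold: float = 0.0

    def decision_scores(self, X) -> np.ndarray:
        Z = transform(X, self.rdes)
        return meta_scores(self.meta, self.meta_kind, Z)

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(np.int64)


def meta_scores(meta, meta_kind: str, Z: np.ndarray) -> np.ndarray:
    if meta_kind == META_LOGISTIC:
        return meta.decision_function(Z)
    return meta.predict_proba(Z)[:, 1]


def _f1(tp: int, n_pred: int, n_gold: int) -> float:
    if n_pred == 0 or n_gold == 0 or tp == 0:
        return 0.0
    p, r = tp / n_pred, tp / n_gold
    return 2 * p * r / (p + r)


def tune_threshold(scores: np.ndarray, labels: Sequence[int]) -> tuple[float, float]:
    """F1-maximizing cutoff over the grid of observed scores.

    Returns ``(threshold, f1_at_threshold)``; predictions are positive
    at ``score >= threshold``.  Ties in F1 go to the higher threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    best_t, best_f1 = math.inf, _f1(0, 0, int((labels == 1).sum()))
    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    n_gold = int((labels == 1).sum())
    tp = 0
    for i in range(len(s_sorted)):
        tp += int(l_sorted[i] == 1)
        if i + 1 < len(s_sorted) and s_sorted[i + 1] == s_sorted[i]:
            continue
        f1 = _f1(tp, i + 1, n_gold)
        if f1 > best_f1:
            best_f1, best_t = f1, float(s_sorted[i])
    return best_t, best_f1


def train_ensemble(
    Z_train: np.ndarray,
    y_train: Sequence[int],
    rdes: Sequence[RDEModel],
    Z_dev: np.ndarray,
    y_dev: Sequence[int],
    meta: str = META_LOGISTIC,
    seed: Optional[int] = None,
    rf_trees: int = 500,
) -> EnsembleModel:
    """Fit the meta-classifier on RDE scores; tune the cutoff on the dev split."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("meta-classifier needs both classes in training labels")
    if meta == META_LOGISTIC:
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif meta == META_RANDOM_FOREST:
        clf = RandomForestClassifier(n_estimators=rf_trees, random_state=seed)
    else:
        raise ValueError(f"unknown meta-classifier: {meta!r}")
    clf.fit(Z_train, y_train)
    dev_scores = meta_scores(clf, meta, Z_dev)
    threshold, _ = tune_threshold(dev_scores, y_dev)
    return EnsembleModel(rdes=list(rdes), meta=clf, meta_kind=meta,
                         threshold=threshold)


def rescale_minmax(scores: np.ndarray,
                   reference: Optional[np.ndarray] = None) -> np.ndarray:
    """Min-max rescale to [0, 1] using the reference (e.g. dev) score range."""
    scores = np.asarray(scores, dtype=np.float64)
    ref = scores if reference is None else np.asarray(reference, dtype=np.float64)
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        return np.full_like(scores, 0.5)
    return np.clip((scores - lo) / (hi - lo), 0.0, 1.0)


def combine_mean(score_lists: Sequence[np.ndarray]) -> np.ndarray:
    """Per-example arithmetic mean of aligned, already-rescaled score lists."""
    if not score_lists:
        raise ValueError("no score lists to combine")
    arrays = [np.asarray(s, dtype=np.float64) for s in score_lists]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("score lists must have equal length")
    return np.mean(arrays, axis=0)


# ---------------------------------------------------------------------------
# High-level convenience pipeline


def candidate_pool(stats_n_j: np.ndarray, min_freq: int) -> list[int]:
    """Vocabulary ids frequent enough in unlabeled data to be references."""
    return np.nonzero(np.asarray(stats_n_j) >= min_freq)[0].tolist()


def fit_serde(
    X_train: sparse.spmatrix,
    y_train: Sequence[int],
    X_unlabeled: sparse.spmatrix,
    cfg: RDEConfig,
    X_dev: Optional[sparse.spmatrix] = None,
    y_dev: Optional[Sequence[int]] = None,
) -> EnsembleModel:
    """End-to-end SeRDE: pool -> select -> build -> prune -> ensemble.

    When the candidate pool holds fewer than ``cfg.k`` scored features
    (small unlabeled corpora), the ensemble width shrinks to what is
    available rather than failing.  Without a dev split the threshold
    is tuned on the training scores.
    """
    from goseed import cooc_stats as cs

    n_features = X_unlabeled.shape[1]
    n_j = np.asarray((X_unlabeled != 0).sum(axis=0)).ravel()
    pool = candidate_pool(n_j, cfg.min_candidate_freq)
    if not pool:
        raise ValueError("empty candidate reference pool; lower min_candidate_freq")
    stats = cs.accumulate(X_unlabeled, pool, n_features)

    labeled = (X_train, y_train)
    k = cfg.k
    while True:
        try:
            refs = select_references(
                stats, RDEConfig(**{**cfg.__dict__, "k": k}), labeled=labeled,
                candidates=pool,
            )
            break
        except ValueError:
            if k == 1:
                raise
            k = max(1, k // 2)

    rdes = [prune(build_rde(stats, r, cfg.epsilon), stats, cfg.t, cfg.epsilon)
            for r in refs]
    Z_train = transform(X_train, rdes)
    if X_dev is not None and y_dev is not None:
        Z_dev, yd = transform(X_dev, rdes), y_dev
    else:
        Z_dev, yd = Z_train, y_train
    return train_ensemble(Z_train, y_train, rdes, Z_dev, yd,
                          meta=cfg.meta, seed=cfg.seed, rf_trees=cfg.rf_trees)


# ---------------------------------------------------------------------------
# Serialization


def save_rdes(rdes: Sequence[RDEModel], path) -> None:
    records = []
    for m in rdes:
        nz = np.nonzero(m.weights)[0]
        records.append({
            "r": int(m.r), "pruned": bool(m.pruned),
            "n_features": int(len(m.weights)),
            "weights": {int(j): float(m.weights[j]) for j in nz},
        })
    Path(path).write_text(json.dumps(records))


def load_rdes(path) -> list[RDEModel]:
    records = json.loads(Path(path).read_text())
    models = []
    for rec in records:
        weights = np.zeros(rec["n_features"])
        for j, w in rec["weights"].items():
            weights[int(j)] = w
        models.append(RDEModel(r=rec["r"], weights=weights, pruned=rec["pruned"]))
    return models
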