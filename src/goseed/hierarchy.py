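"""High-level GO-class filtering of retrieval predictions.

The GO concept tree has three roots (biological process, molecular
function, cellular component); their direct ``is_a`` children form the
second level.  A 12-way bank of binary classifiers — one for each of
the 11 level-2 classes most frequent in the training annotations plus
an OTHER class — scores each sentence, and a retrieval prediction is
kept only when its own level-2 class falls among the sentence's top-n
classes.  The filter can only remove predictions, trading recall for
precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from goseed.goretrieval import AnnotationPrediction, GOTerm
from goseed.rde import RDEModel, train_surde, transform

OTHER_CLASS = "OTHER"
N_CLASSES = 12


def roots(terms: dict[str, GOTerm]) -> set[str]:
    """Terms with no is_a parents: the three namespace roots."""
    return {go_id for go_id, t in terms.items() if not t.parents}


def level2_terms(terms: dict[str, GOTerm]) -> set[str]:
    """Direct is_a children of the roots."""
    top = roots(terms)
    return {go_id for go_id, t in terms.items()
            if t.parents and t.parents <= top and go_id not in top}


def ancestors(go_id: str, terms: dict[str, GOTerm]) -> set[str]:
    """All is_a ancestors of a term (excluding the term itself)."""
    if go_id not in terms:
        raise KeyError(f"unknown GO id: {go_id}")
    seen: set[str] = set()
    frontier = list(terms[go_id].parents)
    while frontier:
        parent = frontier.pop()
        if parent in seen or parent not in terms:
            continue
        seen.add(parent)
        frontier.extend(terms[parent].parents)
    return seen


def level2_classes(go_id: str, terms: dict[str, GOTerm]) -> set[str]:
    """All level-2 ancestors of a term (the term itself if it is level-2).

    Empty only for the roots.  A term below two different level-2
    branches maps to both classes.
    """
    level2 = level2_terms(terms)
    if go_id in level2:
        return {go_id}
    return ancestors(go_id, terms) & level2


@dataclass
class FilterConfig:
    """Filtering threshold ``n`` and the 12-member class set (11 + OTHER)."""

    n: int
    class_set: tuple

    def __post_init__(self):
        if not 0 <= self.n <= N_CLASSES:
            raise ValueError("n must be in [0, 12]")
        if len(self.class_set) != N_CLASSES:
            raise ValueError("class_set must have exactly 12 members")
        if OTHER_CLASS not in self.class_set:
            raise ValueError("class_set must include OTHER")


def select_top_classes(
    gold_go_ids: Iterable[Iterable[str]],
    terms: dict[str, GOTerm],
    n_named: int = N_CLASSES - 1,
) -> tuple:
    """The ``n_named`` level-2 classes most frequent in training gold, + OTHER.

    Frequency is the number of training sentences mapping into the
    class; ties break lexicographically on the GO id.
    """
    counts: Counter = Counter()
    for gos in gold_go_ids:
        mapped: set[str] = set()
        for go_id in gos:
            mapped |= level2_classes(go_id, terms)
        counts.update(mapped)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    named = tuple(go_id for go_id, _ in ranked[:n_named])
    if len(named) < n_named:
        raise ValueError(
            f"training gold maps into only {len(named)} level-2 classes; "
            f"{n_named} needed"
        )
    return named + (OTHER_CLASS,)


def make_class_labels(
    gold_go_ids: Sequence[Iterable[str]],
    class_set: Sequence[str],
    terms: dict[str, GOTerm],
) -> dict[str, np.ndarray]:
    """Per-class binary label vectors over sentences.

    A sentence is positive for class ``c`` iff any of its gold terms
    maps to ``c`` through :func:`level2_classes`; positive for OTHER
    iff none of its gold terms maps into the 11 named classes.
    """
    named = [c for c in class_set if c != OTHER_CLASS]
    labels = {c: np.zeros(len(gold_go_ids), dtype=np.int64) for c in class_set}
    for i, gos in enumerate(gold_go_ids):
        mapped: set[str] = set()
        for go_id in gos:
            mapped |= level2_classes(go_id, terms)
        hit = False
        for c in named:
            if c in mapped:
                labels[c][i] = 1
                hit = True
        if not hit:
            labels[OTHER_CLASS][i] = 1
    return labels


@dataclass
class ClassBank:
    """12 binary one-vs-rest classifiers over sentence features.

    Each class classifier is a supervised RDE (reference = the class
    membership label) whose decision score is calibrated by a logistic
    regression, mirroring the configuration used at annotation time.
    Classes whose training labels are single-class fall back to a
    constant score equal to the class prior.
    """

    class_set: tuple
    surdes: dict
    calibrators: dict
    class_freq: dict

    def class_scores(self, X: sparse.spmatrix) -> dict[str, np.ndarray]:
        scores = {}
        for c in self.class_set:
            surde = self.surdes[c]
            if surde is None:
                scores[c] = np.full(X.shape[0], self.class_freq[c], dtype=float)
                continue
            z = transform(X, [surde])
            calibrator = self.calibrators[c]
            scores[c] = calibrator.predict_proba(z)[:, 1]
        return scores

    def rank_classes(self, X: sparse.spmatrix) -> list[list[str]]:
        """Per-sentence class ranking, best first; ties break by class frequency."""
        scores = self.class_scores(X)
        rankings = []
        for i in range(X.shape[0]):
            order = sorted(
                self.class_set,
                key=lambda c: (-scores[c][i], -self.class_freq[c], str(c)),
            )
            rankings.append(order)
        return rankings


def train_class_bank(
    X: sparse.spmatrix,
    gold_go_ids: Sequence[Iterable[str]],
    terms: dict[str, GOTerm],
    class_set: Optional[tuple] = None,
    seed: Optional[int] = None,
) -> ClassBank:
    """Train the 12 binary class classifiers on labeled sentences."""
    if class_set is None:
        class_set = select_top_classes(gold_go_ids, terms)
    labels = make_class_labels(gold_go_ids, class_set, terms)
    surdes: dict = {}
    calibrators: dict = {}
    class_freq = {c: int(labels[c].sum()) for c in class_set}
    for c in class_set:
        y = labels[c]
        if len(np.unique(y)) < 2:
            surdes[c] = None
            calibrators[c] = None
            continue
        surde = train_surde(X, y)
        z = transform(X, [surde])
        calibrator = LogisticRegression(max_iter=2000, random_state=seed)
        calibrator.fit(z, y)
        surdes[c] = surde
        calibrators[c] = calibrator
    return ClassBank(class_set=tuple(class_set), surdes=surdes,
                     calibrators=calibrators, class_freq=class_freq)


def filter_prediction(
    prediction: AnnotationPrediction,
    ranked_classes: Sequence[str],
    cfg: FilterConfig,
    terms: dict[str, GOTerm],
) -> bool:
    """Keep a prediction iff its level-2 class is among the top-n classes.

    ``n = 12`` keeps everything; ``n = 0`` drops everything.
    """
    if cfg.n >= N_CLASSES:
        return True
    if cfg.n == 0:
        return False
    top = set(ranked_classes[:cfg.n])
    pred_classes = level2_classes(prediction.go_id, terms)
    if not pred_classes & set(cfg.class_set):
        pred_classes = {OTHER_CLASS}
    return bool(pred_classes & top)


def save_bank(bank: ClassBank, directory) -> None:
    """Serialize a class bank as JSON (SuRDE weights + calibrator params)."""
    import json
    from pathlib import Path

    record = {"class_set": list(bank.class_set), "class_freq": bank.class_freq,
              "classes": {}}
    for c in bank.class_set:
        surde = bank.surdes[c]
        if surde is None:
            record["classes"][str(c)] = None
            continue
        nz = np.nonzero(surde.weights)[0]
        cal = bank.calibrators[c]
        record["classes"][str(c)] = {
            "n_features": int(len(surde.weights)),
            "weights": {int(j): float(surde.weights[j]) for j in nz},
            "coef": cal.coef_.ravel().tolist(),
            "intercept": cal.intercept_.tolist(),
        }
    path = Path(directory)
    path.mkdir(parents=True, exist_ok=True)
    (path / "bank.json").write_text(json.dumps(record))


def load_bank(directory) -> ClassBank:
    import json
    from pathlib import Path

    record = json.loads((Path(directory) / "bank.json").read_text())
    class_set = tuple(record["class_set"])
    surdes: dict = {}
    calibrators: dict = {}
    for c in class_set:
        data = record["classes"][str(c)]
        if data is None:
            surdes[c], calibrators[c] = None, None
            continue
        weights = np.zeros(data["n_features"])
        for j, w in data["weights"].items():
            weights[int(j)] = w
        surdes[c] = RDEModel(r=-1, weights=weights)
        cal = LogisticRegression()
        cal.coef_ = np.array([data["coef"]])
        cal.intercept_ = np.array(data["intercept"])
        cal.classes_ = np.array([0, 1])
        calibrators[c] = cal
    class_freq = {c: record["class_freq"][str(c)] if str(c) in record["class_freq"]
                  else record["class_freq"][c] for c in class_set}
    return ClassBank(class_set=class_set, surdes=surdes,
                     calibrators=calibrators, class_freq=class_freq)


def filter_predictions(
    predictions: Sequence[AnnotationPrediction],
    X: sparse.spmatrix,
    bank: ClassBank,
    cfg: FilterConfig,
    terms: dict[str, GOTerm],
) -> list[AnnotationPrediction]:
    """Apply the level-2 filter; row i of X is prediction i's sentence."""
    if X.shape[0] != len(predictions):
        raise ValueError("one feature row per prediction required")
    rankings = bank.rank_classes(X)
    return [p for p, ranked in zip(predictions, rankings)
            if filter_prediction(p, ranked, cfg, terms)]
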