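"""Evaluation metrics: exact/relaxed sentence P/R/F1, GO-term F1,
hierarchy F1 and AUC.

Sentence-level records are ``(doc_id, char_start, char_end, gene_id)``
tuples: *exact* scoring requires the identical sentence span for the
same gene, *relaxed* scoring credits any character-span overlap with a
gold span for the same gene.  GO-level records are ``(doc_id, gene_id,
go_id)``; *hierarchy* scoring replaces each side's GO terms by their
is_a ancestor closures (the three roots excluded) before micro
precision/recall, crediting near-miss predictions.

All P/R/F1 are micro-averaged over the whole prediction/gold sets; an
empty denominator yields 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from goseed.goretrieval import GOTerm
from goseed.hierarchy import ancestors, roots

MODE_EXACT = "exact"
MODE_RELAXED = "relaxed"
MODE_BINARY = "binary"
MODE_HIERARCHY = "hierarchy"


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    mode: str
    auc: Optional[float] = None


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _result(tp_pred: int, n_pred: int, tp_gold: int, n_gold: int,
            mode: str) -> EvalResult:
    precision = tp_pred / n_pred if n_pred else 0.0
    recall = tp_gold / n_gold if n_gold else 0.0
    return EvalResult(precision=precision, recall=recall,
                      f1=_f1(precision, recall), mode=mode)


def _check_sentence_record(record) -> tuple:
    doc_id, start, end, gene_id = record
    start, end = int(start), int(end)
    if end < start:
        raise ValueError(f"malformed span in record {record!r}")
    return (str(doc_id), start, end, str(gene_id))


def prf_sentences(
    preds: Iterable[tuple], gold: Iterable[tuple], mode: str = MODE_EXACT
) -> EvalResult:
    """Micro P/R/F1 over (doc_id, char_start, char_end, gene_id) records."""
    P = {_check_sentence_record(r) for r in preds}
    G = {_check_sentence_record(r) for r in gold}
    if mode == MODE_EXACT:
        tp = len(P & G)
        return _result(tp, len(P), tp, len(G), mode)
    if mode != MODE_RELAXED:
        raise ValueError(f"unknown sentence mode: {mode!r}")

    def overlaps(a, b) -> bool:
        return (a[0] == b[0] and a[3] == b[3]
                and a[1] < b[2] and b[1] < a[2])

    tp_pred = sum(1 for p in P if any(overlaps(p, g) for g in G))
    tp_gold = sum(1 for g in G if any(overlaps(p, g) for p in P))
    return _result(tp_pred, len(P), tp_gold, len(G), mode)


def _closure(record: tuple, terms: dict[str, GOTerm], top: set) -> set:
    doc_id, gene_id, go_id = record
    if go_id not in terms:
        raise KeyError(f"GO id {go_id!r} absent from ontology")
    closure = ({go_id} | ancestors(go_id, terms)) - top
    return {(doc_id, gene_id, a) for a in closure}


def prf_go(
    preds: Iterable[tuple],
    gold: Iterable[tuple],
    mode: str = MODE_EXACT,
    terms: Optional[dict] = None,
) -> EvalResult:
    """Micro P/R/F1 over (doc_id, gene_id, go_id) records.

    In hierarchy mode both sides are replaced by their ancestor
    closures (roots excluded) before set comparison; requires the
    ontology.
    """
    P = {(str(d), str(g), str(go)) for d, g, go in preds}
    G = {(str(d), str(g), str(go)) for d, g, go in gold}
    if mode == MODE_EXACT:
        tp = len(P & G)
        return _result(tp, len(P), tp, len(G), mode)
    if mode != MODE_HIERARCHY:
        raise ValueError(f"unknown GO mode: {mode!r}")
    if terms is None:
        raise ValueError("hierarchy mode requires the ontology")
    top = roots(terms)
    P_closed = set().union(*(_closure(r, terms, top) for r in P)) if P else set()
    G_closed = set().union(*(_closure(r, terms, top) for r in G)) if G else set()
    tp = len(P_closed & G_closed)
    return _result(tp, len(P_closed), tp, len(G_closed), mode)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative),
    ties counted 1/2.  Raises when only one class is present."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
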