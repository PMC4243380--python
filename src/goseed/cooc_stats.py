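"""Presence/co-occurrence counting over an unlabeled example stream.

Everything an RDE needs is a handful of counts over unlabeled examples:
the number of examples ``N``, per-feature presence counts ``n_j``,
reference-feature counts ``n_r`` and joint counts ``n_jr``.  Counting
is a single pass and associative, so stats accumulated over stream
partitions merge exactly into the stats of the full stream — which is
what makes the approach practical on arbitrarily large corpora.

Probabilities are estimated from the stored counts at query time with
optional add-``eps`` smoothing (never baked into the counts):

    P(j)    = (n_j + eps)  / (N + 2 eps)
    P(r|j)  = (n_jr + eps) / (n_j + 2 eps)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from scipy import sparse

DEFAULT_EPSILON = 0.5

StreamLike = Union[sparse.spmatrix, Iterable[np.ndarray]]


@dataclass
class CoocStats:
    """Counts from unlabeled data: N, n_j, n_r, n_jr.

    ``n_jr`` is a dense ``(len(ref_ids), n_features)`` array; reference
    sets are small (hundreds) so this stays modest even for large
    vocabularies.
    """

    n_examples: int
    n_j: np.ndarray
    ref_ids: np.ndarray
    n_jr: np.ndarray

    def __post_init__(self):
        self.n_j = np.asarray(self.n_j, dtype=np.int64)
        self.ref_ids = np.asarray(self.ref_ids, dtype=np.int64)
        self.n_jr = np.asarray(self.n_jr, dtype=np.int64)
        if self.n_jr.shape != (len(self.ref_ids), len(self.n_j)):
            raise ValueError("n_jr shape mismatch")
        self._ref_pos = {int(r): i for i, r in enumerate(self.ref_ids)}

    # -- raw counts ---------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.n_j)

    def count_j(self, j: int) -> int:
        return int(self.n_j[j])

    def count_r(self, r: int) -> int:
        return int(self.n_j[r])

    def count_jr(self, j: int, r: int) -> int:
        return int(self.n_jr[self._ref_pos[int(r)], j])

    # -- probabilities ------------------------------------------------------

    def p_j(self, j: int, eps: float = DEFAULT_EPSILON) -> float:
        return _ratio(self.count_j(j) + eps, self.n_examples + 2 * eps)

    def p_r(self, r: int, eps: float = DEFAULT_EPSILON) -> float:
        return self.p_j(r, eps)

    def p_jr(self, j: int, r: int, eps: float = DEFAULT_EPSILON) -> float:
        return _ratio(self.count_jr(j, r) + eps, self.n_examples + 2 * eps)

    def p_r_given_j(self, j: int, r: int, eps: float = DEFAULT_EPSILON) -> float:
        """(n_jr + eps) / (n_j + 2 eps); raises if n_j == 0 and eps == 0."""
        return _ratio(self.count_jr(j, r) + eps, self.count_j(j) + 2 * eps)

    # Vectorized forms over the whole vocabulary, used by the RDE module.

    def p_j_all(self, eps: float = DEFAULT_EPSILON) -> np.ndarray:
        return (self.n_j + eps) / _denom(self.n_examples + 2 * eps)

    def p_jr_all(self, r: int, eps: float = DEFAULT_EPSILON) -> np.ndarray:
        row = self.n_jr[self._ref_pos[int(r)]]
        return (row + eps) / _denom(self.n_examples + 2 * eps)

    def p_r_given_j_all(self, r: int, eps: float = DEFAULT_EPSILON) -> np.ndarray:
        row = self.n_jr[self._ref_pos[int(r)]]
        denom = self.n_j + 2 * eps
        if eps == 0 and np.any(denom == 0):
            raise ZeroDivisionError("n_j == 0 for some feature with smoothing off")
        return (row + eps) / denom


def _denom(x: float) -> float:
    if x == 0:
        raise ZeroDivisionError("probability denominator is zero (smoothing off?)")
    return x


def _ratio(num: float, den: float) -> float:
    return num / _denom(den)


def accumulate(
    stream: StreamLike,
    candidate_refs: Sequence[int],
    n_features: int,
) -> CoocStats:
    """Single-pass exact presence counts over an unlabeled stream.

    ``stream`` is either a sparse Boolean example-by-feature matrix or
    an iterable of sorted active-id arrays (visited once).  Raises on a
    vector referencing an id outside ``[0, n_features)``.
    """
    ref_ids = np.array(sorted(int(r) for r in set(candidate_refs)), dtype=np.int64)
    if len(ref_ids) and (ref_ids[0] < 0 or ref_ids[-1] >= n_features):
        raise IndexError("candidate reference id outside the vocabulary")

    if sparse.issparse(stream):
        X = stream.tocsr()
        if X.shape[1] != n_features:
            raise IndexError("stream matrix width does not match n_features")
        X = (X != 0).astype(np.int64)
        n_j = np.asarray(X.sum(axis=0)).ravel().astype(np.int64)
        if len(ref_ids):
            n_jr = np.asarray((X[:, ref_ids].T @ X).todense(), dtype=np.int64)
        else:
            n_jr = np.zeros((0, n_features), dtype=np.int64)
        return CoocStats(n_examples=X.shape[0], n_j=n_j, ref_ids=ref_ids, n_jr=n_jr)

    ref_set = set(int(r) for r in ref_ids)
    ref_pos = {int(r): i for i, r in enumerate(ref_ids)}
    n = 0
    n_j = np.zeros(n_features, dtype=np.int64)
    n_jr = np.zeros((len(ref_ids), n_features), dtype=np.int64)
    for vector in stream:
        ids = np.asarray(vector, dtype=np.int64)
        if len(ids) and (ids.min() < 0 or ids.max() >= n_features):
            raise IndexError("feature id outside the vocabulary")
        ids = np.unique(ids)
        n += 1
        n_j[ids] += 1
        for r in ref_set.intersection(ids.tolist()):
            n_jr[ref_pos[r], ids] += 1
    return CoocStats(n_examples=n, n_j=n_j, ref_ids=ref_ids, n_jr=n_jr)


def merge(a: CoocStats, b: CoocStats) -> CoocStats:
    """Exact merge of stats from two sub-streams (counting is associative)."""
    if a.n_features != b.n_features:
        raise ValueError("cannot merge stats over different vocabularies")
    if not np.array_equal(a.ref_ids, b.ref_ids):
        raise ValueError("cannot merge stats with different reference sets")
    return CoocStats(
        n_examples=a.n_examples + b.n_examples,
        n_j=a.n_j + b.n_j,
        ref_ids=a.ref_ids.copy(),
        n_jr=a.n_jr + b.n_jr,
    )


# ---------------------------------------------------------------------------
# Serialization: three TSV tables plus a header carrying N.


def save(stats: CoocStats, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "header.tsv").write_text(
        f"n_examples\t{stats.n_examples}\nn_features\t{stats.n_features}\n"
    )
    with open(directory / "marginals.tsv", "w") as fh:
        for j, c in enumerate(stats.n_j):
            if c:
                fh.write(f"{j}\t{int(c)}\n")
    with open(directory / "ref_marginals.tsv", "w") as fh:
        for r in stats.ref_ids:
            fh.write(f"{int(r)}\t{stats.count_r(int(r))}\n")
    with open(directory / "joint.tsv", "w") as fh:
        for i, r in enumerate(stats.ref_ids):
            row = stats.n_jr[i]
            for j in np.nonzero(row)[0]:
                fh.write(f"{int(j)}\t{int(r)}\t{int(row[j])}\n")


def load(directory) -> CoocStats:
    directory = Path(directory)
    header = dict(
        line.split("\t")
        for line in (directory / "header.tsv").read_text().splitlines()
        if line
    )
    n_examples = int(header["n_examples"])
    n_features = int(header["n_features"])
    n_j = np.zeros(n_features, dtype=np.int64)
    for line in (directory / "marginals.tsv").read_text().splitlines():
        j, c = line.split("\t")
        n_j[int(j)] = int(c)
    ref_ids = []
    for line in (directory / "ref_marginals.tsv").read_text().splitlines():
        r, _ = line.split("\t")
        ref_ids.append(int(r))
    ref_ids = np.array(sorted(ref_ids), dtype=np.int64)
    ref_pos = {int(r): i for i, r in enumerate(ref_ids)}
    n_jr = np.zeros((len(ref_ids), n_features), dtype=np.int64)
    for line in (directory / "joint.tsv").read_text().splitlines():
        j, r, c = line.split("\t")
        n_jr[ref_pos[int(r)], int(j)] = int(c)
    return CoocStats(n_examples=n_examples, n_j=n_j, ref_ids=ref_ids, n_jr=n_jr)
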