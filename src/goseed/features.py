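"""Boolean bag-of-words / bag-of-bigrams feature extraction.

Four feature regimes are supported: unigrams or bigrams drawn from the
sentence alone or from the sentence plus its enclosing paragraph.
Features are strictly Boolean presence indicators.  Paragraph-scope
features live in their own namespace (prefixed ``ctx::``) so that the
same word occurring in the sentence and in the surrounding context
yields two distinct features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from goseed.corpus import Example

SCOPE_SENTENCE = "sentence"
SCOPE_SENTENCE_PARAGRAPH = "sentence+paragraph"
ORDER_UNIGRAM = "unigram"
ORDER_BIGRAM = "bigram"

PARAGRAPH_PREFIX = "ctx::"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric tokens; punctuation acts as a separator."""
    return _TOKEN_RE.findall(text.lower())


def _ngram_features(tokens: Sequence[str], order: str) -> list[str]:
    if order == ORDER_UNIGRAM:
        return list(tokens)
    if order == ORDER_BIGRAM:
        return [f"{a}_{b}" for a, b in zip(tokens, tokens[1:])]
    raise ValueError(f"unknown order: {order!r}")


def example_features(example: Example, scope: str, order: str) -> set[str]:
    """The set of feature names active in an example under a regime."""
    feats = set(_ngram_features(tokenize(example.sentence.text), order))
    if scope == SCOPE_SENTENCE_PARAGRAPH:
        context = _ngram_features(tokenize(example.paragraph_text), order)
        feats.update(PARAGRAPH_PREFIX + f for f in context)
    elif scope != SCOPE_SENTENCE:
        raise ValueError(f"unknown scope: {scope!r}")
    return feats


@dataclass
class Vocabulary:
    """Bijective feature <-> integer id map with document frequencies.

    Ids are assigned deterministically: document frequency descending,
    then lexicographic.  A vocabulary remembers the (scope, order)
    regime it was built under and refuses vectors from another regime.
    """

    index: dict
    doc_frequency: np.ndarray
    scope: str = SCOPE_SENTENCE
    order: str = ORDER_UNIGRAM

    def __post_init__(self):
        if len(self.index) != len(self.doc_frequency):
            raise ValueError("index/doc_frequency size mismatch")

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, feature: str) -> bool:
        return feature in self.index

    @property
    def features(self) -> list[str]:
        names = [""] * len(self.index)
        for feat, i in self.index.items():
            names[i] = feat
        return names

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#scope={self.scope}\torder={self.order}\n")
            for feat, i in sorted(self.index.items(), key=lambda kv: kv[1]):
                fh.write(f"{feat}\t{i}\t{int(self.doc_frequency[i])}\n")

    @classmethod
    def from_tsv(cls, path) -> "Vocabulary":
        index, freqs = {}, []
        scope, order = SCOPE_SENTENCE, ORDER_UNIGRAM
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, value = part.partition("=")
                        if key == "scope":
                            scope = value
                        elif key == "order":
                            order = value
                    continue
                feat, fid, df = line.split("\t")
                index[feat] = int(fid)
                freqs.append((int(fid), int(df)))
        doc_frequency = np.zeros(len(index), dtype=np.int64)
        for fid, df in freqs:
            doc_frequency[fid] = df
        return cls(index=index, doc_frequency=doc_frequency, scope=scope, order=order)


def build_vocabulary(
    examples: Iterable[Example],
    scope: str = SCOPE_SENTENCE,
    order: str = ORDER_UNIGRAM,
    min_df: int = 1,
) -> Vocabulary:
    """Vocabulary of all features with document frequency >= ``min_df``."""
    counts: dict[str, int] = {}
    for example in examples:
        for feat in example_features(example, scope, order):
            counts[feat] = counts.get(feat, 0) + 1
    kept = [(f, c) for f, c in counts.items() if c >= min_df]
    kept.sort(key=lambda fc: (-fc[1], fc[0]))
    index = {f: i for i, (f, _) in enumerate(kept)}
    doc_frequency = np.array([c for _, c in kept], dtype=np.int64)
    return Vocabulary(index=index, doc_frequency=doc_frequency,
                      scope=scope, order=order)


def extract_features(
    example: Example, scope: str, order: str, vocab: Vocabulary
) -> np.ndarray:
    """Sorted active feature ids of an example (Boolean presence).

    Features unseen by the vocabulary are ignored (predict-time
    contract).  Raises on a (scope, order) regime mismatch.
    """
    if (scope, order) != (vocab.scope, vocab.order):
        raise ValueError(
            f"vocabulary regime ({vocab.scope}, {vocab.order}) does not match "
            f"requested ({scope}, {order})"
        )
    ids = {vocab.index[f] for f in example_features(example, scope, order)
           if f in vocab.index}
    return np.fromiter(sorted(ids), dtype=np.int64, count=len(ids))


def featurize(
    examples: Sequence[Example], vocab: Vocabulary
) -> sparse.csr_matrix:
    """Sparse Boolean example-by-feature matrix under the vocabulary's regime."""
    indptr = [0]
    indices: list[int] = []
    for example in examples:
        ids = extract_features(example, vocab.scope, vocab.order, vocab)
        indices.extend(ids.tolist())
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.float64)
    return sparse.csr_matrix(
        (data, np.array(indices, dtype=np.int64), np.array(indptr, dtype=np.int64)),
        shape=(len(examples), len(vocab)),
    )


def vectors_from_matrix(matrix: sparse.csr_matrix) -> list[np.ndarray]:
    """Row-wise active-id arrays of a sparse Boolean matrix."""
    csr = matrix.tocsr()
    return [csr.indices[csr.indptr[i]:csr.indptr[i + 1]].astype(np.int64)
            for i in range(csr.shape[0])]
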