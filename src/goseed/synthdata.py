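"""Synthetic corpora, ontologies and annotation counts with known truth.

The generator emulates the statistical structure the RDE method relies
on, so that recovery can be checked against a known answer:

* each sentence has a latent binary label (evidence / non-evidence)
  drawn from a class prior;
* *planted reference words* appear with explicit class-conditional
  probabilities ``P(r|y)`` and ``P(r|ybar)`` — strong, nearly
  independent label indicators;
* a fraction of the remaining vocabulary is *weakly informative*: each
  such word's Zipfian base rate is tilted up in one class and down in
  the other by a random factor, all words mutually independent given
  the label (exactly the regime in which an RDE aggregates many weak
  signals through its reference feature);
* the rest of the vocabulary is pure filler, independent of the label;
* one gene name from a generated lexicon is appended to every sentence.

The toy ontology has the GO shape that matters here: 3 roots, a second
level (at least 5 terms per root), leaves below, and per-term
annotation-document counts drawn from a discrete power law — mirroring
the heavy-tailed term usage observed in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse

from goseed.corpus import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    LABEL_UNKNOWN,
    Example,
    GeneLexicon,
    Sentence,
)
from goseed.goretrieval import GOTerm


@dataclass
class GenSpec:
    """Generator parameters; the defaults are the benchmark conditions.

    ``p_r_given_y``/``p_r_given_noty`` apply to every planted reference
    word.  ``informative_fraction`` of the non-planted vocabulary gets
    a class tilt drawn log-uniformly from ``[tilt_min, tilt_max]`` with
    a random direction.  ``mean_sentence_length`` scales the Zipfian
    word base rates.
    """

    seed: int = 0
    n_labeled: int = 500
    n_dev: int = 250
    n_test: int = 1000
    n_unlabeled: int = 100_000
    vocab_size: int = 1000
    n_reference_words: int = 1
    p_r_given_y: float = 0.8
    p_r_given_noty: float = 0.2
    class_prior: float = 0.3
    mean_sentence_length: float = 12.0
    informative_fraction: float = 0.3
    tilt_min: float = 1.3
    tilt_max: float = 3.0
    zipf_exponent: float = 1.1
    min_word_rate: float = 0.004
    n_go_terms: int = 60
    powerlaw_exponent: float = 2.0
    n_genes: int = 50

    def __post_init__(self):
        for p in (self.p_r_given_y, self.p_r_given_noty, self.class_prior,
                  self.informative_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_reference_words and self.p_r_given_y <= self.p_r_given_noty:
            raise ValueError(
                "planted references must satisfy p_r_given_y > p_r_given_noty"
            )
        if self.n_reference_words + 1 >= self.vocab_size:
            raise ValueError("vocabulary too small for the planted references")
        if self.n_go_terms < 15:
            raise ValueError("n_go_terms must be >= 15 (3 roots x 5 level-2)")


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery tests."""

    class_prior: float
    words: list
    reference_words: list
    reference_ids: np.ndarray
    informative_ids: np.ndarray
    p_word_given_y: np.ndarray
    p_word_given_noty: np.ndarray
    labels_unlabeled: np.ndarray


def _word(i: int) -> str:
    return f"w{i:05d}"


def gen_lexicon(spec: GenSpec) -> GeneLexicon:
    """gene0..geneN-1, each its own ID."""
    return GeneLexicon({f"gene{i}": f"G{i}" for i in range(spec.n_genes)})


def _conditional_rates(spec: GenSpec, rng: np.random.Generator):
    """Per-word P(word|y), P(word|ybar) under the planted design."""
    V = spec.vocab_size
    ranks = np.arange(V, dtype=np.float64)
    base = 1.0 / (ranks + 25.0) ** spec.zipf_exponent
    base *= spec.mean_sentence_length / base.sum()
    # Words below the rate floor are both hard to estimate from the
    # unlabeled stream and unlikely to enter a labeled-corpus
    # vocabulary, so the marginal distribution is floored there.
    base = np.clip(base, spec.min_word_rate, 0.6)

    p_y = base.copy()
    p_n = base.copy()

    ref_ids = np.arange(spec.n_reference_words)
    p_y[ref_ids] = spec.p_r_given_y
    p_n[ref_ids] = spec.p_r_given_noty

    rest = np.arange(spec.n_reference_words, V)
    n_info = int(round(spec.informative_fraction * len(rest)))
    info_ids = rng.choice(rest, size=n_info, replace=False)
    info_ids.sort()
    tilt = np.exp(rng.uniform(np.log(spec.tilt_min), np.log(spec.tilt_max),
                              size=n_info))
    direction = rng.random(n_info) < 0.5
    up = np.where(direction, tilt, 1.0 / tilt)
    p_y[info_ids] = np.clip(base[info_ids] * up, 1e-6, 0.9)
    p_n[info_ids] = np.clip(base[info_ids] / up, 1e-6, 0.9)
    return p_y, p_n, ref_ids, info_ids


def _sample_presence(
    p_y: np.ndarray, p_n: np.ndarray, labels: np.ndarray,
    rng: np.random.Generator, chunk: int = 10_000,
) -> sparse.csr_matrix:
    """Sparse presence matrix: word w active in sentence i w.p. P(w|label_i)."""
    V = len(p_y)
    blocks = []
    for start in range(0, len(labels), chunk):
        lab = labels[start:start + chunk]
        probs = np.where(lab[:, None] == 1, p_y[None, :], p_n[None, :])
        blocks.append(sparse.csr_matrix(rng.random((len(lab), V)) < probs))
    X = sparse.vstack(blocks, format="csr") if blocks else \
        sparse.csr_matrix((0, V))
    return X.astype(np.int8)


def _render_sentences(
    X: sparse.csr_matrix,
    words: Sequence[str],
    gene_names: Sequence[str],
    labels: Optional[np.ndarray],
    rng: np.random.Generator,
    doc_prefix: str,
) -> list[Example]:
    """Turn presence rows into Example objects with shuffled word order."""
    examples = []
    indptr, indices = X.indptr, X.indices
    gene_pick = rng.integers(0, len(gene_names), size=X.shape[0])
    for i in range(X.shape[0]):
        active = indices[indptr[i]:indptr[i + 1]]
        toks = [words[j] for j in active]
        rng.shuffle(toks)
        gene = gene_names[gene_pick[i]]
        text = " ".join(toks + [gene]) + "."
        sentence = Sentence(doc_id=f"{doc_prefix}{i}", section="Body",
                            index=0, text=text, char_start=0,
                            char_end=len(text))
        if labels is None:
            label = LABEL_UNKNOWN
        else:
            label = LABEL_POSITIVE if labels[i] == 1 else LABEL_NEGATIVE
        examples.append(Example(sentence=sentence,
                                gene_ids=frozenset({f"G{gene_pick[i]}"}),
                                label=label))
    return examples


def gen_corpus(
    spec: GenSpec, render_text: bool = True
) -> tuple[list[Example], list[Example], GroundTruth]:
    """Labeled and unlabeled example sets plus the generating parameters.

    The labeled list concatenates the train, dev and test splits
    (sizes ``n_labeled``, ``n_dev``, ``n_test``); all splits and the
    unlabeled stream are sampled i.i.d. from the same planted
    conditionals.  ``truth.splits`` maps split name to the index range
    within the labeled list.

    With ``render_text=False`` no Example objects are built and the
    presence matrices are attached to the returned ground truth as
    ``X_labeled`` / ``X_unlabeled`` (word id = column id), for callers
    that featurize directly.
    """
    rng = np.random.default_rng(spec.seed)
    p_y, p_n, ref_ids, info_ids = _conditional_rates(spec, rng)
    words = [_word(i) for i in range(spec.vocab_size)]
    gene_names = [f"gene{i}" for i in range(spec.n_genes)]

    n_lab = spec.n_labeled + spec.n_dev + spec.n_test
    y_lab = (rng.random(n_lab) < spec.class_prior).astype(np.int64)
    y_unl = (rng.random(spec.n_unlabeled) < spec.class_prior).astype(np.int64)
    X_lab = _sample_presence(p_y, p_n, y_lab, rng)
    X_unl = _sample_presence(p_y, p_n, y_unl, rng)

    truth = GroundTruth(
        class_prior=spec.class_prior,
        words=words,
        reference_words=[words[i] for i in ref_ids],
        reference_ids=ref_ids,
        informative_ids=info_ids,
        p_word_given_y=p_y,
        p_word_given_noty=p_n,
        labels_unlabeled=y_unl,
    )
    truth.labels_labeled = y_lab         # type: ignore[attr-defined]
    truth.splits = {                     # type: ignore[attr-defined]
        "train": (0, spec.n_labeled),
        "dev": (spec.n_labeled, spec.n_labeled + spec.n_dev),
        "test": (spec.n_labeled + spec.n_dev, n_lab),
    }
    if render_text:
        labeled = _render_sentences(X_lab, words, gene_names, y_lab, rng, "L")
        unlabeled = _render_sentences(X_unl, words, gene_names, None, rng, "U")
    else:
        labeled = []
        unlabeled = []
        truth.X_labeled = X_lab          # type: ignore[attr-defined]
        truth.X_unlabeled = X_unl        # type: ignore[attr-defined]
    return labeled, unlabeled, truth


@dataclass
class CorpusSplits:
    """Rendered train/dev/test/unlabeled splits of one generated corpus."""

    train: list
    dev: list
    test: list
    unlabeled: list
    truth: GroundTruth

    def labels(self, split: str) -> np.ndarray:
        lo, hi = self.truth.splits[split]  # type: ignore[attr-defined]
        return self.truth.labels_labeled[lo:hi]  # type: ignore[attr-defined]


def gen_splits(spec: GenSpec) -> CorpusSplits:
    """Generate a corpus and slice the labeled part into named splits."""
    labeled, unlabeled, truth = gen_corpus(spec)
    s = truth.splits  # type: ignore[attr-defined]
    return CorpusSplits(
        train=labeled[s["train"][0]:s["train"][1]],
        dev=labeled[s["dev"][0]:s["dev"][1]],
        test=labeled[s["test"][0]:s["test"][1]],
        unlabeled=unlabeled,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Toy ontology + annotation counts


def gen_ontology(
    spec: GenSpec,
) -> tuple[dict[str, GOTerm], dict[str, int]]:
    """A 3-root toy ontology with power-law annotation counts.

    ``n_go_terms`` counts non-root terms: 5 level-2 terms per root come
    first, the remainder are leaves attached to a random level-2 parent
    (one in ten leaves gets a second level-2 parent from the same
    namespace, exercising multi-parent paths).  Term names are drawn
    from the corpus vocabulary so that generated sentences and term
    bags share tokens.  Counts follow a discrete power law with tail
    exponent ``powerlaw_exponent``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    words = [_word(i) for i in range(spec.vocab_size)]

    def go(n: int) -> str:
        return f"GO:{n:07d}"

    terms: dict[str, GOTerm] = {}
    next_id = 1
    root_ids = []
    for namespace in ("biological_process", "molecular_function",
                      "cellular_component"):
        gid = go(next_id); next_id += 1
        root_ids.append(gid)
        terms[gid] = GOTerm(go_id=gid, name=namespace.replace("_", " "),
                            namespace=namespace)

    def sample_name() -> str:
        n_words = int(rng.integers(2, 4))
        picks = rng.choice(len(words), size=n_words, replace=False)
        return " ".join(words[i] for i in picks)

    level2_by_root: dict[str, list[str]] = {r: [] for r in root_ids}
    n_level2 = 15
    for i in range(n_level2):
        root = root_ids[i % 3]
        gid = go(next_id); next_id += 1
        terms[gid] = GOTerm(go_id=gid, name=sample_name(),
                            namespace=terms[root].namespace,
                            parents=frozenset({root}))
        level2_by_root[root].append(gid)

    n_leaves = spec.n_go_terms - n_level2
    for i in range(n_leaves):
        root = root_ids[int(rng.integers(0, 3))]
        pool = level2_by_root[root]
        parents = {pool[int(rng.integers(0, len(pool)))]}
        if len(pool) > 1 and rng.random() < 0.1:
            second = pool[int(rng.integers(0, len(pool)))]
            parents.add(second)
        gid = go(next_id); next_id += 1
        terms[gid] = GOTerm(go_id=gid, name=sample_name(),
                            namespace=terms[root].namespace,
                            parents=frozenset(parents))

    counts = {}
    non_roots = [g for g in terms if g not in root_ids]
    draws = sample_powerlaw_counts(len(non_roots), spec.powerlaw_exponent, rng)
    for gid, c in zip(non_roots, draws):
        counts[gid] = int(c)
    return terms, counts


def sample_powerlaw_counts(
    n: int, exponent: float, rng: np.random.Generator,
    x_min: int = 2, cap: int = 100_000,
) -> np.ndarray:
    """Discrete power-law draws: P(X >= x) ~ x^-(exponent-1), x >= x_min."""
    if exponent <= 1.0:
        raise ValueError("power-law exponent must exceed 1")
    u = rng.random(n)
    x = np.floor(x_min * u ** (-1.0 / (exponent - 1.0)))
    return np.minimum(x, cap).astype(np.int64)


def gen_annotated_sentences(
    spec: GenSpec,
    terms: dict[str, GOTerm],
    counts: dict[str, int],
    n_sentences: int = 200,
    n_term_tokens: int = 2,
    n_noise_tokens: int = 6,
) -> tuple[list[Example], list[list[str]]]:
    """Sentences with known gold GO terms, for retrieval/filter benchmarks.

    Each sentence takes ``n_term_tokens`` tokens from its gold term's
    name plus Zipfian noise words, and carries one gene.  Gold terms
    are drawn with probability proportional to their annotation count,
    matching how frequent terms dominate real annotation data.
    """
    rng = np.random.default_rng(spec.seed + 2)
    words = [_word(i) for i in range(spec.vocab_size)]
    candidates = [g for g in sorted(counts) if counts[g] >= 1]
    weights = np.array([counts[g] for g in candidates], dtype=np.float64)
    weights /= weights.sum()

    examples, gold = [], []
    for i in range(n_sentences):
        gid = candidates[int(rng.choice(len(candidates), p=weights))]
        name_tokens = terms[gid].name.split()
        take = min(n_term_tokens, len(name_tokens))
        picked = list(rng.choice(name_tokens, size=take, replace=False))
        noise = [words[int(rng.integers(0, spec.vocab_size))]
                 for _ in range(n_noise_tokens)]
        toks = picked + noise
        rng.shuffle(toks)
        gene = int(rng.integers(0, spec.n_genes))
        text = " ".join(toks + [f"gene{gene}"]) + "."
        sentence = Sentence(doc_id=f"A{i}", section="Body", index=0,
                            text=text, char_start=0, char_end=len(text))
        examples.append(Example(sentence=sentence,
                                gene_ids=frozenset({f"G{gene}"}),
                                label=LABEL_POSITIVE))
        gold.append([gid])
    return examples, gold


# ---------------------------------------------------------------------------
# File emission (OBO 1.2 / GAF 2.2 / lexicon TSV)


def write_obo(terms: dict[str, GOTerm], path) -> None:
    lines = ["format-version: 1.2", "ontology: go-toy", ""]
    for gid in sorted(terms):
        t = terms[gid]
        lines.append("[Term]")
        lines.append(f"id: {t.go_id}")
        lines.append(f"name: {t.name}")
        lines.append(f"namespace: {t.namespace}")
        for syn in t.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        if t.definition:
            lines.append(f'def: "{t.definition}" []')
        for parent in sorted(t.parents):
            lines.append(f"is_a: {parent} ! {terms[parent].name}"
                         if parent in terms else f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gaf(counts: dict[str, int], path, db: str = "TOY") -> None:
    """One GAF 2.2 row per (term, distinct reference document)."""
    pmid = 1
    rows = ["!gaf-version: 2.2"]
    for gid in sorted(counts):
        for _ in range(counts[gid]):
            fields = [db, f"P{pmid:07d}", f"gene{pmid % 97}", "", gid,
                      f"PMID:{pmid}", "IDA", "", "P", "", "", "protein",
                      "taxon:9606", "20140101", db, "", ""]
            rows.append("\t".join(fields))
            pmid += 1
    Path(path).write_text("\n".join(rows) + "\n")


def write_lexicon(lexicon_size: int, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(lexicon_size):
            fh.write(f"gene{i}\tG{i}\n")
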