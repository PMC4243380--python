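"""Shared fixtures: a hand-built toy ontology and small corpora."""

import numpy as np
import pytest

from goseed.corpus import Example, GeneLexicon, Sentence
from goseed.goretrieval import GOTerm


def make_example(text, label="unknown", doc_id="d1", index=0, paragraph=""):
    sentence = Sentence(doc_id=doc_id, section="Body", index=index, text=text,
                        char_start=0, char_end=len(text))
    return Example(sentence=sentence, gene_ids=frozenset({"G1"}), label=label,
                   paragraph_text=paragraph)


@pytest.fixture
def lexicon():
    return GeneLexicon({"BRCA1": "672", "TP53": "7157", "p53": "7157"})


@pytest.fixture
def toy_terms():
    """3 roots, 5 level-2 terms, leaves (one with two level-2 parents)."""

    def term(gid, name, ns, parents=()):
        return GOTerm(go_id=gid, name=name, namespace=ns,
                      parents=frozenset(parents))

    bp, mf, cc = "biological_process", "molecular_function", "cellular_component"
    terms = {
        "GO:0000001": term("GO:0000001", "biological process", bp),
        "GO:0000002": term("GO:0000002", "molecular function", mf),
        "GO:0000003": term("GO:0000003", "cellular component", cc),
        "GO:0000011": term("GO:0000011", "cell growth", bp, ["GO:0000001"]),
        "GO:0000012": term("GO:0000012", "signal transduction", bp, ["GO:0000001"]),
        "GO:0000021": term("GO:0000021", "kinase activity", mf, ["GO:0000002"]),
        "GO:0000022": term("GO:0000022", "dna binding", mf, ["GO:0000002"]),
        "GO:0000031": term("GO:0000031", "nucleus", cc, ["GO:0000003"]),
        "GO:0000111": term("GO:0000111", "positive regulation of cell growth",
                           bp, ["GO:0000011"]),
        "GO:0000112": term("GO:0000112", "growth factor signaling", bp,
                           ["GO:0000011", "GO:0000012"]),
        "GO:0000121": term("GO:0000121", "protein kinase activity", mf,
                           ["GO:0000021"]),
        "GO:0000211": term("GO:0000211", "rapid cell growth control", bp,
                           ["GO:0000111"]),
    }
    return terms


@pytest.fixture
def toy_obo_text(toy_terms):
    from goseed.synthdata import write_obo
    import io, tempfile, os
    lines = ["format-version: 1.2", ""]
    for gid in sorted(toy_terms):
        t = toy_terms[gid]
        lines.append("[Term]")
        lines.append(f"id: {t.go_id}")
        lines.append(f"name: {t.name}")
        lines.append(f"namespace: {t.namespace}")
        for p in sorted(t.parents):
            lines.append(f"is_a: {p}")
        lines.append("")
    return "\n".join(lines)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
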