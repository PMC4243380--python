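"""OBO/GAF loading, GORank scoring and top-term retrieval."""

import math

import pytest

from goseed import goretrieval as gr

TOY_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: biological process
namespace: biological_process

[Term]
id: GO:0000011
name: cell growth
namespace: biological_process
is_a: GO:0000001 ! biological process

[Term]
id: GO:0000012
name: kinase activity
namespace: molecular_function
synonym: "phosphotransferase action" EXACT []
is_a: GO:0000001 ! biological process
is_a: GO:0000011 ! cell growth

[Term]
id: GO:0000013
name: gone term
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture
def toy_obo_path(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


class TestLoadObo:
    def test_parses_terms_and_parents(self, toy_obo_path):
        terms = gr.load_obo(toy_obo_path)
        assert set(terms) == {"GO:0000001", "GO:0000011", "GO:0000012"}
        assert terms["GO:0000011"].parents == {"GO:0000001"}
        assert terms["GO:0000011"].name == "cell growth"

    def test_obsolete_excluded(self, toy_obo_path):
        assert "GO:0000013" not in gr.load_obo(toy_obo_path)

    def test_multiple_parents_retained(self, toy_obo_path):
        terms = gr.load_obo(toy_obo_path)
        assert terms["GO:0000012"].parents == {"GO:0000001", "GO:0000011"}

    def test_synonyms_unquoted(self, toy_obo_path):
        terms = gr.load_obo(toy_obo_path)
        assert terms["GO:0000012"].synonyms == ("phosphotransferase action",)


class TestLoadGafCounts:
    def _gaf(self, tmp_path, rows):
        lines = ["!gaf-version: 2.2"]
        for go_id, ref in rows:
            fields = ["DB", "P1", "g", "", go_id, ref, "IDA", "", "P", "",
                      "", "protein", "taxon:9606", "20140101", "DB", "", ""]
            lines.append("\t".join(fields))
        path = tmp_path / "toy.gaf"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_distinct_documents_counted(self, tmp_path):
        path = self._gaf(tmp_path, [
            ("GO:0000001", "PMID:1"), ("GO:0000001", "PMID:2"),
            ("GO:0000001", "PMID:1"), ("GO:0000002", "PMID:9"),
        ])
        counts = gr.load_gaf_counts(path)
        assert counts == {"GO:0000001": 2, "GO:0000002": 1}

    def test_empty_gaf(self, tmp_path):
        path = tmp_path / "empty.gaf"
        path.write_text("!gaf-version: 2.2\n")
        assert gr.load_gaf_counts(path) == {}

    def test_duplicate_rows_counted_once(self, tmp_path):
        path = self._gaf(tmp_path, [("GO:0000001", "PMID:1")] * 3)
        assert gr.load_gaf_counts(path) == {"GO:0000001": 1}

    def test_short_row_raises(self, tmp_path):
        path = tmp_path / "bad.gaf"
        path.write_text("DB\tP1\tg\tGO:0000001\n")
        with pytest.raises(ValueError):
            gr.load_gaf_counts(path)


class TestGorank:
    def test_no_common_tokens_zero(self):
        assert gr.gorank({"a", "b"}, {"c"}, 1000) == 0.0

    def test_count_one_zero_regardless_of_overlap(self):
        assert gr.gorank({"kinase"}, {"kinase"}, 1) == 0.0

    def test_worked_value(self):
        # query of 4 tokens vs a 2-token term, 2 common, count 1000:
        # (2 / sqrt(8)) * ln 1000 = 4.885
        score = gr.gorank({"kinase", "activity", "regulates", "growth"},
                          {"kinase", "activity"}, 1000)
        assert score == pytest.approx((2 / math.sqrt(8)) * math.log(1000),
                                      abs=1e-12)
        assert score == pytest.approx(4.885, abs=1e-3)

    def test_unsqrt_variant_smaller(self):
        q, g = {"a", "b", "c"}, {"a", "b"}
        assert gr.gorank(q, g, 100, sqrt_denominator=False) < gr.gorank(q, g, 100)

    def test_monotone_in_count(self):
        q, g = {"a", "x"}, {"a", "y"}
        scores = [gr.gorank(q, g, c) for c in (2, 10, 100, 10_000)]
        assert scores == sorted(scores) and len(set(scores)) == len(scores)

    def test_monotone_in_overlap(self):
        g = {"a", "b", "c", "d"}
        s1 = gr.gorank({"a", "x", "y", "z"}, g, 50)
        s2 = gr.gorank({"a", "b", "y", "z"}, g, 50)
        s3 = gr.gorank({"a", "b", "c", "z"}, g, 50)
        assert s1 < s2 < s3

    def test_duplicate_tokens_irrelevant(self):
        assert gr.gorank(["a", "a", "b"], ["a", "c"], 10) == \
            gr.gorank({"a", "b"}, {"a", "c"}, 10)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            gr.gorank(set(), {"a"}, 10)
        with pytest.raises(ValueError):
            gr.gorank({"a"}, set(), 10)
        with pytest.raises(ValueError):
            gr.gorank({"a"}, {"a"}, 0)


def brute_force_top(query_tokens, index):
    """Independent argmax with the documented tie-breaks."""
    best = None
    for go_id, bag in index.token_bags.items():
        score = gr.gorank(set(query_tokens), bag, index.counts[go_id])
        if score <= 0:
            continue
        key = (score, index.counts[go_id], [-ord(c) for c in go_id])
        if best is None or key > best[0]:
            best = (key, go_id, score)
    return best


class TestRetrieveTop:
    def _index(self, spec_counts):
        terms, bags, counts = {}, {}, {}
        for i, (name, count) in enumerate(spec_counts, start=1):
            gid = f"GO:{i:07d}"
            terms[gid] = gr.GOTerm(go_id=gid, name=name,
                                   namespace="biological_process")
            bags[gid] = frozenset(name.split())
            counts[gid] = count
        return gr.GOIndex(terms=terms, token_bags=bags, counts=counts)

    def test_single_overlapping_term(self):
        index = self._index([("cell growth", 100)])
        p = gr.retrieve_top("rapid cell growth", index)
        assert p is not None and p.go_id == "GO:0000001"

    def test_count_breaks_equal_cosine(self):
        index = self._index([("cell growth", 100), ("cell cycle", 1000)])
        p = gr.retrieve_top("the cell responds", index)
        assert p.go_id == "GO:0000002"  # same overlap, higher count wins

    def test_no_shared_tokens_returns_none(self):
        index = self._index([("kinase activity", 500)])
        assert gr.retrieve_top("unrelated words entirely", index) is None

    def test_matches_brute_force_on_random_index(self, rng):
        words = [f"t{i}" for i in range(30)]
        entries = []
        for _ in range(200):
            name = " ".join(rng.choice(words, size=3, replace=False))
            entries.append((name, int(rng.integers(2, 5000))))
        index = self._index(entries)
        for _ in range(25):
            query = [words[i] for i in rng.choice(30, size=5, replace=False)]
            expected = brute_force_top(query, index)
            got = gr.retrieve_top(" ".join(query), index)
            if expected is None:
                assert got is None
            else:
                assert got.go_id == expected[1]
                assert got.score == pytest.approx(expected[2], abs=1e-12)


class TestFrequencyThreshold:
    def test_strictly_over(self):
        terms = {f"GO:{i:07d}": gr.GOTerm(go_id=f"GO:{i:07d}", name=f"n{i}",
                                          namespace="biological_process")
                 for i in range(1, 4)}
        counts = dict(zip(sorted(terms), [1999, 2000, 2001]))
        index = gr.build_index(terms, counts)
        filtered = gr.apply_frequency_threshold(index, 2000)
        assert list(filtered.terms) == ["GO:0000003"]

    def test_zero_threshold_keeps_all_counted(self):
        terms = {"GO:0000001": gr.GOTerm(go_id="GO:0000001", name="x",
                                         namespace="biological_process")}
        index = gr.build_index(terms, {"GO:0000001": 5})
        assert len(gr.apply_frequency_threshold(index, 0).terms) == 1

    def test_threshold_above_max_empties_index(self):
        terms = {"GO:0000001": gr.GOTerm(go_id="GO:0000001", name="word",
                                         namespace="biological_process")}
        index = gr.build_index(terms, {"GO:0000001": 5})
        filtered = gr.apply_frequency_threshold(index, 10)
        assert gr.retrieve_top("word", filtered) is None
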