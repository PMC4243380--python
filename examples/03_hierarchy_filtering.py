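"""Pruning retrieval predictions with the 12-way level-2 class filter.

Trains the class bank on annotated synthetic sentences, retrieves a GO
term for each fresh sentence, and sweeps the filtering threshold n:
small n keeps only predictions whose level-2 GO class agrees with the
sentence classifiers, trading recall for precision.
"""

from goseed import evaluation, features, goretrieval, hierarchy, synthdata
from goseed.synthdata import GenSpec

spec = GenSpec(seed=7, n_go_terms=60, vocab_size=300)
terms, counts = synthdata.gen_ontology(spec)
train_ex, train_gold = synthdata.gen_annotated_sentences(
    spec, terms, counts, n_sentences=400)
test_ex, test_gold = synthdata.gen_annotated_sentences(
    GenSpec(seed=8, n_go_terms=60, vocab_size=300), terms, counts,
    n_sentences=200)

vocab = features.build_vocabulary(train_ex)
bank = hierarchy.train_class_bank(
    features.featurize(train_ex, vocab), train_gold, terms, seed=0)

index = goretrieval.build_index(terms, counts)
preds, rows, gold = [], [], set()
for e, gs in zip(test_ex, test_gold):
    gold.add((e.sentence.doc_id, "G1", gs[0]))
    p = goretrieval.retrieve_top(e.sentence, index, gene_id="G1")
    if p is not None:
        preds.append(goretrieval.AnnotationPrediction(
            doc_id=e.sentence.doc_id, sentence_index=0, gene_id="G1",
            go_id=p.go_id, score=p.score))
        rows.append(e)
X_pred = features.featurize(rows, vocab)

print(" n   kept   precision   recall    F1")
for n in (0, 1, 2, 4, 6, 8, 12):
    cfg = hierarchy.FilterConfig(n=n, class_set=bank.class_set)
    kept = hierarchy.filter_predictions(preds, X_pred, bank, cfg, terms)
    records = {(p.doc_id, p.gene_id, p.go_id) for p in kept}
    r = evaluation.prf_go(records, gold)
    print(f"{n:2d}  {len(kept):5d}   {r.precision:9.3f}  {r.recall:7.3f}  "
          f"{r.f1:6.3f}")
print()
print("n=12 is the unfiltered identity; decreasing n removes predictions")
print("whose level-2 GO class disagrees with the sentence classifiers,")
print("raising precision at the cost of recall.")
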