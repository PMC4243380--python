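"""GO-term retrieval with GORank on a toy ontology.

Builds a small synthetic ontology with power-law annotation counts,
then ranks GO terms against a query sentence.  GORank multiplies the
token-set cosine similarity by log(count), so among equally similar
terms the one with the larger annotation footprint wins.
"""

from goseed import goretrieval
from goseed.synthdata import GenSpec, gen_ontology

spec = GenSpec(seed=4, n_go_terms=40, vocab_size=200)
terms, counts = gen_ontology(spec)
index = goretrieval.build_index(terms, counts)

# a query built from one indexed term's name plus noise words
target = sorted(index.terms)[5]
query = terms[target].name + " w00003 w00017 unrelated tokens"

print(f"query sentence: {query!r}")
print(f"gold term:      {target} ({terms[target].name!r}, "
      f"count {counts[target]})")
print()
print("top 5 by GORank (cosine x log count):")
ranked = goretrieval.rank_terms(goretrieval.tokenize(query), index)
for go_id, score in ranked[:5]:
    print(f"  {go_id}  score={score:6.3f}  count={index.counts[go_id]:6d}  "
          f"name={terms[go_id].name!r}")

worked = goretrieval.gorank({"kinase", "activity", "regulates", "growth"},
                            {"kinase", "activity"}, 1000)
print()
print(f"worked example: 4-token query vs 2-token term, 2 shared, count 1000")
print(f"  (2/sqrt(8)) * ln(1000) = {worked:.3f}")
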