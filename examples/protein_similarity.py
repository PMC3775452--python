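"""Gene-product functional similarity on a seeded synthetic corpus.

Generates a 40-term random ontology and a 12-protein corpus, then scores
protein pairs with the topological-position measure combined by its
canonical best-match-average (BMA) strategy, alongside the three other
combination strategies for one pair.
"""

import itertools

from gosim import MeasureContext, combine, pairwise_matrix, protein_similarity
from gosim.fixtures import DagSpec, random_corpus, random_dag

graph = random_dag(DagSpec(n_terms=40, seed=42))
corpus = random_corpus(graph, n_proteins=12, mean_terms_per_protein=3, seed=42)
ctx = MeasureContext(graph, "universal", corpus)

print("pairwise functional similarity (universal + BMA):")
proteins = corpus.proteins[:5]
for p1, p2 in itertools.combinations(proteins, 2):
    r = protein_similarity(ctx, p1, p2, "universal", "toy", "default")
    print(f"  {p1}  {p2}  {r.score:.4f}")

p1, p2 = proteins[0], proteins[1]
m = pairwise_matrix(
    ctx, corpus.terms_of(p1, graph, "toy"), corpus.terms_of(p2, graph, "toy"),
    "universal",
)
print(f"\nterm-level matrix for ({p1}, {p2}) is {m.shape[0]}x{m.shape[1]};")
for strategy in ("avg", "max", "bma", "abm"):
    print(f"  {strategy}: {combine(m, strategy):.4f}")

print()
print("avg is dragged down by unrelated term pairs and max ignores all but")
print("the best match; bma/abm average only each term's best partner and sit")
print("between the two, which is why they are the recommended defaults.")
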