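"""Compute term specificity under all four models on the diamond fixture.

The diamond DAG has a root r, two intermediate terms a and b, a shared
child c and a leaf d; the companion corpus annotates P1 to d, P2 to c and
P3 to a.  Higher IC / semantic value means a more specific term.
"""

from gosim import compute_ic, wang_svalues
from gosim.fixtures import fixture_diamond

graph, corpus = fixture_diamond()

annotation = compute_ic(graph, "annotation", corpus)
zhang = compute_ic(graph, "zhang")
universal = compute_ic(graph, "universal")

print(f"{'term':<6}{'annotation':>12}{'zhang':>10}{'universal':>11}{'wang SV':>9}")
for term in sorted(graph.terms):
    sv = wang_svalues(graph, term).sv
    print(
        f"{term:<6}{annotation.get(term):>12.6f}{zhang.get(term):>10.6f}"
        f"{universal.get(term):>11.6f}{sv:>9.4f}"
    )

print()
print("The root always scores 0 (it carries no information); the leaf d is")
print("the most specific term under every model.  The annotation model gives")
print("a IC 0 because every protein in the corpus falls under a.")
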