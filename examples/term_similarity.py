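"""Score one term pair under a spread of registered similarity measures.

Uses the diamond fixture's pair (c, d): d is the only child of c, so the
pair is closely related and every normalized measure should score it well
above unrelated siblings such as (a, b).
"""

from gosim import MeasureContext, measure
from gosim.fixtures import fixture_diamond

graph, corpus = fixture_diamond()

contexts = {
    "annotation": MeasureContext(graph, "annotation", corpus),
    "zhang": MeasureContext(graph, "zhang"),
    "universal": MeasureContext(graph, "universal"),
    "wang": MeasureContext(graph, "wang"),
}

rows = [
    ("resnik_raw", "annotation"),
    ("resnik_nmax", "annotation"),
    ("resnik_nunif", "annotation"),
    ("resnik_nunivers", "annotation"),
    ("lin", "annotation"),
    ("relevance", "annotation"),
    ("li", "annotation"),
    ("xgrasm_lin", "annotation"),
    ("jc_distance", "annotation"),
    ("jc_couto", "annotation"),
    ("zhang", "zhang"),
    ("universal", "universal"),
    ("wang", "wang"),
    ("wu_palmer", "universal"),
    ("edge_based", "universal"),
]

print(f"{'measure':<18}{'IC model':<12}{'sim(c,d)':>10}{'sim(a,b)':>10}")
for name, model in rows:
    ctx = contexts[model]
    print(
        f"{name:<18}{model:<12}"
        f"{measure(name, 'c', 'd', ctx):>10.6f}"
        f"{measure(name, 'a', 'b', ctx):>10.6f}"
    )

print()
print("(c, d) share an informative ancestor, so all measures score them > 0;")
print("(a, b) share only the root, so every IC-based similarity is 0.")
print("resnik_raw and jc_distance are unnormalized (an IC and a distance).")
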