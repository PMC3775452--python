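# gosim

Information-content models and a unified semantic-similarity framework for
the Gene Ontology (or any rooted `is_a`/`part_of` DAG), with gene-product
functional similarity on top.

Semantic similarity between GO terms is the workhorse behind functional
comparison of gene products: protein function prediction, interaction-network
denoising, cluster annotation. Dozens of published measures differ only in
(i) how a term's *specificity* is scored and (ii) how the specificity of the
ancestors two terms share is turned into a similarity. `gosim` implements
both layers explicitly and exposes the single formula that generates all the
IC-based measures, so published measures become parameter rows rather than
separate code paths.

## The model

**Term specificity.** For a term `x` with ancestor closure `T_x` (the
true-path closure, `x` included):

- *annotation IC*: `IC(x) = -ln f(x)/f(root)`, where `f(x)` counts the
  distinct gene products annotated to `x` or any descendant in a corpus;
  corpus-unused ("orphan") terms are *undefined*, not zero;
- *Zhang et al.*: same form with topological counts `f(leaf) = 1`,
  `f(x) = sum of children's f` (path multiplicity intended);
- *GO-universal* (topological position): `p(root) = 1`,
  `p(x) = prod over parents w of p(w)/|children(w)|`, `IC = -ln p`;
- *Wang et al.*: S-values `S_x(x) = 1`,
  `S_x(t) = max over children t' in T_x of w_e S_x(t')`
  (`w_e` = 0.8 for `is_a`, 0.6 for `part_of`), with semantic value
  `SV(x) = sum of S_x over T_x`.

**Term similarity.** With `mu_inf` = max specificity in a term set and
`mu_1` = summed specificity, every IC-based measure is an instance of

```
              eps * mu_p(T_a & T_b)
S(a,b) = --------------------------------------------------------
         alpha*mu_p(T_a & T_b) + beta*mu_p(T_a) + gamma*mu_p(T_b)
```

with `eps in (0,1]` a commonality-overestimation correction and
`alpha, beta, gamma >= 0`, `alpha+beta+gamma >= 1`, which keeps the score in
[0, 1]. Lin is `(p=inf, alpha=0, beta=gamma=1/2, eps=1)`; Relevance and the
Li et al. information coefficient put `eps = 1 - e^{-IC(c)}` and
`eps = 1 - (1+IC(c))^{-1}` (`c` = most informative common ancestor, MICA);
GraSM averages the IC of the *disjunctive* common ancestors (independent
paths to both terms) and XGraSM of *all informative* common ancestors;
Wang is the `p = 1` row. The raw Resnik score `IC(c)` is normalized by
`max IC` (Nmax), `log2 N` (Nunif) or `max(IC(a), IC(b))` (Nunivers), and the
Jiang–Conrath distance `IC(a)+IC(b)-2 IC(c)` with its canonical
normalization recovers Lin exactly. Depth-based Wu–Palmer and
edge-counting measures are included for completeness.

**Gene-product similarity.** The term-level matrix between two annotation
sets is collapsed by Avg, Max, BMA (best-match average) or ABM (average
best matches); defaults follow the originating schemes (BMA for the
GO-universal and annotation measures, ABM for Wang, Avg for Zhang).

## Worked example

```python
from gosim import MeasureContext, measure, compute_ic
from gosim.fixtures import fixture_diamond

graph, corpus = fixture_diamond()      # r -> {a,b} -> c -> d, 3 proteins
ctx = MeasureContext(graph, "annotation", corpus)
print(round(compute_ic(graph, "annotation", corpus)["d"], 6))  # 1.098612
print(round(measure("lin", "c", "d", ctx), 6))                 # 0.539155
print(round(measure("resnik_nunivers", "c", "d", ctx), 6))     # 0.369070
```

`IC(d) = -ln(1/3)`: one of three proteins is annotated under `d`. The pair
(c, d) shares an ancestor of IC `ln(3/2) = 0.405465`, giving Lin
`2*0.405465/(0.405465+1.098612) = 0.539155`; dividing instead by the larger
endpoint IC gives the Nunivers score `0.369070`.

The same computations are available from a shell:

```bash
gosim fixtures --name diamond --out-dir /tmp/fx
printf 'c\td\n' > /tmp/fx/pairs.tsv
gosim termsim --obo /tmp/fx/diamond.obo --gaf /tmp/fx/diamond.gaf \
      --ic annotation --measure lin --pairs /tmp/fx/pairs.tsv
# c   d   lin   0.539155
```

See `examples/` for narrative scripts covering each capability
(specificity models, the measure registry, disjunctive-ancestor
corrections, gene-level combination).

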