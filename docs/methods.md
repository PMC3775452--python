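# Methods

This note documents the models `gosim` implements, the conventions chosen
where definitions in the literature are loose, and what the synthetic
fixtures do and do not establish.

## Ontology model

An ontology is a set of disjoint rooted DAGs, one per namespace. Only
`is_a` and `part_of` edges carry topology; other relationship types
(`regulates`, ...) are biological cross-links and are dropped at parse time
with a logged count. Edges are stored parent → child; "ancestor" means
toward the root; the root sits at depth 0. Obsolete terms are retained for
id resolution but stripped of edges and excluded from closures, roots and
depth tables. Validation is strict: cycles, cross-namespace edges,
multiple roots per namespace and terms unreachable from their root are
hard errors, because every downstream quantity assumes a rooted DAG.

Annotation corpora hold *direct* protein → term links (GAF 2.x; `NOT`
rows excluded, alternate ids resolved, unresolvable rows counted and
skipped, duplicate protein–term rows collapsed, every evidence code kept
unless an allow-list is given). True-path propagation happens in the IC
layer, never in the corpus.

## Term specificity

Four models, all per namespace:

**Annotation IC.** `f(x)` = number of *distinct* gene products annotated
to `x` or any descendant; `p(x) = f(x)/f(root)`; `IC = -ln p`. A
frequently cited shortcut computes `f` as the term's own count plus its
direct children's counts; on any diamond-shaped region that either
double-counts proteins or undercounts deep contributions and can make a
parent rarer than its child. The distinct-protein union over the full
descendant closure is the only reading under which `p` is a true
cumulative probability and IC is monotone along edges, so it is the
default; the literal children-sum is available behind
`literal_children_sum=True` for comparison. Terms with `f = 0` (orphans)
have *undefined* IC — not 0, which would mean "root-like, maximally
general". Any similarity touching an orphan is NaN, and NaN propagates
through gene-level aggregation unless explicitly skipped.

**Zhang counts.** `f(leaf) = 1`, `f(x) = sum of children's f`, exactly as
published — a term reached by several paths from a leaf is counted once
per path. This is intentional (the published recursion is self-consistent)
and is cross-checked in the tests against brute-force path enumeration.

**GO-universal (topological position).** `p(root) = 1`,
`p(x) = prod over parents w of p(w)/|Ch(w)|`. Implemented in log space
(`ic(x) = sum over parents of ic(w) + ln|Ch(w)|`) because the probability
product underflows on multi-parent DAGs long before IC becomes large; the
two forms are algebraically identical. Every term gets a value, and each
factor being ≤ 1 makes IC monotone along edges by induction.

**Wang S-values.** Within the focus term's closure `T_x`: `S_x(x) = 1`,
`S_x(t) = max{w_e · S_x(t') : t' ∈ Ch(t) ∩ T_x}` with contribution
factors 0.8 (`is_a`) and 0.6 (`part_of`), and `SV(x) = Σ S_x`. When both
an `is_a` and a `part_of` edge connect the same pair, the pair collapses
to `is_a` (the larger factor) at graph construction.

## Term similarity

The engine evaluates
`S = eps·mu_p(∩) / (alpha·mu_p(∩) + beta·mu_p(T_a) + gamma·mu_p(T_b))`
literally from enumerated closures: `mu_inf` is the max specificity in the
set, `mu_1` the sum. For the three `-ln p` models the specificity is IC;
for Wang the commonality term sums `S_a(t) + S_b(t)` over the shared
ancestors while each description term is the semantic value. Every
registered closed form with an engine parameter row is verified to agree
with the engine to 1e-12 on random-DAG ensembles; the closed forms are
what the registry dispatches (they are cheaper), the engine is the
specification.

Conventions where the published material is loose:

- **MICA tie-break.** Among common ancestors of maximal IC, the
  lexicographically smallest id wins — except a self pair, whose MICA is
  the term itself even when an ancestor ties (IC ties are routine under
  the Zhang model, where a single-child parent has its child's count).
  Scores depending only on `IC(c)` are unaffected; determinism matters for
  the disjunctive-ancestor list.
- **Disjunctive common ancestors.** `u, v` are disjunctive for the pair
  `(a, b)` iff for each target there are paths from `u` and from `v` such
  that `u`'s path avoids `v` and vice versa (reachability in the graph
  with the other node deleted). Selection is greedy: start from the MICA,
  visit candidates in decreasing IC, keep a candidate iff disjunctive
  from everything kept. Candidates are restricted to *informative*
  (IC > 0) ancestors: the correction factor `eps = mean(IC of list)/IC(c)`
  is only meaningful over informative ancestors, and without the
  restriction the root — almost always disjunctive — would drag every
  corrected score toward 0 and the "reduces to the MICA measure when
  there is nothing else" contract would fail.
- **eps at an uninformative MICA.** If `IC(c) = 0` the similarity is
  already 0; `eps` is defined as 1 so it stays in (0, 1].
- **Degenerate pairs.** A pair whose description measure is 0 (two roots)
  scores 0 by convention: no information is shared.
- **Zhang's measure.** The published parameter table lists
  `beta = gamma = 1` next to a closed form `2·IC(c)/(IC(a)+IC(b))`; the
  two are inconsistent and the closed form governs (the engine row uses
  `beta = gamma = 1/2`).
- **Wu–Palmer / edge-based depths.** Longest-path ("maximum depth")
  semantics throughout. As printed in the source formulation, the
  Wu–Palmer denominator uses the *global* depths of `a` and `b`, not the
  depths routed through the selected common ancestor; consequence: a self
  pair scores 0.5, not 1. The edge-based measure picks the deepest common
  ancestor (ties to smallest id) and uses longest ancestor→descendant
  path lengths.
- **Identity axiom.** `sim(x,x) = 1` is a theorem only for the measures
  whose `eps = 1` and whose denominator reduces to the commonality on a
  self pair (lin, zhang, universal, wang, nunivers, grasm_lin,
  grasm_nunivers, the Jiang–Conrath-derived similarities, edge_based).
  Relevance/Li multiply by `eps < 1`; XGraSM averages over all
  informative ancestors of the self pair; Nmax/Nunif divide by a global
  constant; Wu–Palmer scores 0.5 as above. The registry records the
  guarantee per measure and the tests assert exactly it.
- **Corpus-scaled measures.** Nunif, the `t0` and the uniform
  Jiang–Conrath normalizations divide by corpus-wide scales (`log2 N`,
  `IC(t0)`), which only bound the score for annotation IC; they are
  registered for the annotation model only. `t0` is the
  lexicographically smallest term used exactly once (IC `ln N`); if none
  exists the maximum IC is used instead, with a warning.
- **Non-canonical combinations.** Lin/Relevance/Li/GraSM were proposed for
  annotation IC but are well defined for any `-ln p` model; the registry
  permits them there (its `canonical_ic` field records the original
  pairing, and cross-checks default to the canonical model).

## Gene-product similarity

Avg, Max, BMA = `(mean of row maxima + mean of column maxima)/2` and
ABM = `(Σ row maxima + Σ column maxima)/(m+n)`. These acronyms are used
in the literature more often than they are written down; the formulas
here are the standard best-match definitions, symmetrized, and BMA = ABM
exactly when `m = n`. Functional similarity is always computed within one
namespace — annotation sets are filtered first and namespaces are never
pooled. Defaults per measure: BMA for the GO-universal and all
annotation-family measures, ABM for Wang, Avg for Zhang; all overridable.

## Synthetic fixtures and generators

- The **diamond** fixture (r → {a,b} → c → d with three proteins) is the
  smallest graph exercising multi-parent closure; every IC and similarity
  value on it is hand-derivable and frozen in the tests to 1e-12.
- The **chain** fixture demonstrates the raw-Resnik inconsistency: the
  score between a term and increasingly specific cousins is constant
  (their MICA never changes) while the Nunivers normalization strictly
  decreases. The chain carries a sibling branch at each step: under the
  topological-position model a single child inherits its parent's
  probability unchanged, so an unbranched chain would make the property
  degenerate (all ICs equal) rather than strict.
- The **helicase** fixture is a *synthetic* reconstruction of a
  molecular-function neighbourhood (term ids borrow the corresponding GO
  accessions; the wiring is hand-chosen). It pins down the
  two-disjunctive-ancestor scenario exactly: `eps(GraSM) = 0.75`,
  `eps(XGraSM) = 2/3` under the topological-position IC.
- The **random generators** produce rooted DAGs by giving each term
  1..max_parents parents among earlier terms in a topological layout
  (defaults n_terms = 40, max_parents = 3, part_of fraction 0.2 — sparse
  multi-parent graphs of GO-like shallowness) and corpora by uniform
  direct annotation over non-root terms (default 3 terms/protein,
  Poisson-spread). They emulate GO's *shape*, not its term-usage
  statistics: term frequencies in real corpora are heavy-tailed and
  biased toward well-studied processes, so passing tests establish
  structural correctness, not performance on real annotation data.
  Problem sizes in the tests and the acceptance script (20–60-term DAGs,
  ensembles of 10–100, 1,000 sampled pairs) are chosen to enumerate all
  pairs exhaustively in seconds while exercising every diamond/tie/orphan
  configuration the small fixtures cannot.

## Known limitations

- **Wang SV is not monotone along edges.** For a single-parent child,
  `SV(child) = 1 + w·SV(parent)`, which *decreases* once
  `SV(parent) > 1/(1-w)` (5 for `is_a`, 2.5 for `part_of`). Rich
  multi-parent DAGs exceed that threshold routinely (about 9% of edges in
  the random ensemble). The often-repeated claim that the semantic value
  is strictly increasing in specificity holds only near the root or on
  tree-like regions; the corresponding test states the strict property
  and reports the violations rather than weakening it. The three `-ln p`
  models are provably monotone and test clean.
- GraSM's pairwise path-avoidance test deletes one node at a time; like
  the original formulation it does not detect higher-order overlap among
  three or more ancestors. Its cost is quadratic in the number of
  informative common ancestors per pair (with per-pair caching), which is
  fine at fixture scale and is the reason XGraSM exists at corpus scale.
- Relationship types beyond `is_a`/`part_of` are dropped rather than
  reasoned over; OWL inputs and GO-slim mapping are out of scope.
- The annotation model normalizes per namespace (`f(root)`), while `N`
  in Nunif is the corpus-wide protein count; a protein annotated in
  several namespaces counts once in `N` but contributes to each
  namespace's `f(root)` it appears under.
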