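"""Unified term-level semantic similarity.

Every information-content-based similarity between two ontology terms
``a`` and ``b`` with ancestor closures ``T_a``, ``T_b`` can be written as

    S(a, b) = eps * mu_p(T_a & T_b)
              -----------------------------------------------
              alpha * mu_p(T_a & T_b) + beta * mu_p(T_a) + gamma * mu_p(T_b)

where ``mu_inf`` of a term set is the maximum specificity it contains and
``mu_1`` the sum; ``eps`` in (0, 1] is a correction factor for the
overestimation of commonality (possibly built from the common ancestors),
and ``alpha, beta, gamma >= 0`` with ``alpha + beta + gamma >= 1`` are free
parameters.  Under those constraints the score always lies in [0, 1].

Instantiations (the measure registry):

===================  =========================================================
name                 definition
===================  =========================================================
resnik_raw           IC(c), c the most informative common ancestor (MICA)
resnik_nmax          IC(c) / IC_max
resnik_nunif         IC(c) / log2(N)
resnik_nunivers      IC(c) / max(IC(a), IC(b))
lin                  2 IC(c) / (IC(a) + IC(b))
relevance            (1 - e^{-IC(c)}) * lin
li                   (1 - (1 + IC(c))^{-1}) * lin
grasm_<base>         eps_DCA * base,  base in {lin, nmax, nunif, nunivers}
xgrasm_<base>        eps_ICA * base
zhang                2 IC(c) / (IC(a) + IC(b)) with the Zhang topology IC
universal            IC(c) / max(IC(a), IC(b)) with the topological-position IC
wang                 sum_{t in T_a & T_b} (S_a(t) + S_b(t)) / (SV(a) + SV(b))
jc_distance          IC(a) + IC(b) - 2 IC(c)   (a distance, not in [0,1])
jc_couto             1 / (1 + jc_distance)
jc_t0                1 - min(1, jc_distance / IC(t0)), t0 a once-used term
jc_pesquita          1 - (ICu(a) + ICu(b))/2 + ICu(c),  ICu = IC / log2(N)
jc_canonical         1 - jc_distance / (IC(a) + IC(b))  (identically lin)
wu_palmer            2 len(r,c) / (len(r,a) + len(r,b) + 2 len(r,c))
edge_based           len(r,c) / (len(r,c) + len(c,a) + len(c,b))
===================  =========================================================

The GraSM correction averages the IC of the *disjunctive* common ancestors
(ancestors reaching both terms through mutually independent paths); the
XGraSM correction averages over *all* informative common ancestors.  Both
corrections equal mean(IC of list) / IC(c) and reduce to 1 when the list is
just the MICA.

Under the corpus ("annotation") IC model, orphan terms have undefined IC;
any similarity touching one is NaN, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Callable, Mapping

import networkx as nx

from .ic import (
    DEFAULT_WANG_WEIGHTS,
    ICTable,
    WangProfile,
    compute_ic,
    wang_svalues,
)
from .ontology import (
    AnnotationCorpus,
    DepthTable,
    OntologyError,
    OntologyGraph,
    longest_depths,
)

INF = math.inf


# -- parameters and context ----------------------------------------------


@dataclass(frozen=True)
class SimilarityParams:
    """The (p, alpha, beta, gamma, eps-rule) tuple of the unified formula.

    ``p`` selects the set functional (math.inf -> max, 1 -> sum).
    ``select_max=True`` replaces the fixed (beta, gamma) with (1, 0) or
    (0, 1) on whichever term has the larger description measure, yielding
    a max(...) denominator.
    """

    p: float = INF
    alpha: float = 0.0
    beta: float = 0.5
    gamma: float = 0.5
    epsilon_rule: str = "one"  # one | relevance | li | grasm | xgrasm
    select_max: bool = False

    def __post_init__(self) -> None:
        if self.p not in (1, INF):
            raise ValueError("p must be 1 or math.inf")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")
        if self.alpha + self.beta + self.gamma < 1 and not self.select_max:
            raise ValueError("alpha + beta + gamma must be >= 1")


@dataclass
class NormalizationContext:
    """Corpus-level scales used by the Resnik normalizations.

    ``ic_max`` maps each namespace to the largest defined IC in it;
    ``n_proteins`` is the number of annotated gene products N;
    ``t0_ic`` maps a namespace to the IC of a term used exactly once
    (falls back to ic_max when no such term exists).
    """

    ic_max: dict[str, float] = field(default_factory=dict)
    n_proteins: int | None = None
    t0_ic: dict[str, float] = field(default_factory=dict)


class MeasureContext:
    """Everything a measure evaluation needs: graph, IC model, corpus scales.

    Build once per (graph, IC model, corpus) and reuse across pairs; Wang
    profiles, ancestor summaries and depth tables are cached internally.
    """

    def __init__(
        self,
        graph: OntologyGraph,
        ic_model: str = "universal",
        corpus: AnnotationCorpus | None = None,
        ic_table: ICTable | None = None,
        wang_weights: Mapping[str, float] | None = None,
    ):
        if ic_model not in ("annotation", "zhang", "universal", "wang"):
            raise OntologyError(f"unknown IC model {ic_model!r}")
        self.graph = graph
        self.ic_model = ic_model
        self.corpus = corpus
        self.wang_weights = dict(DEFAULT_WANG_WEIGHTS if wang_weights is None else wang_weights)
        if ic_model == "wang":
            self.ic: ICTable | None = None
        else:
            self.ic = ic_table if ic_table is not None else compute_ic(graph, ic_model, corpus)
        self._wang_cache: dict[str, WangProfile] = {}
        self._depths: DepthTable | None = None
        self._norm: NormalizationContext | None = None
        # symmetric per-pair caches (keyed on the sorted pair)
        self._mica_cache: dict[tuple[str, str], tuple[str, float]] = {}
        self._dca_cache: dict[tuple[str, str], tuple[str, ...]] = {}
        self._ica_cache: dict[tuple[str, str], tuple[str, ...]] = {}

    # cached helpers

    def wang_profile(self, term: str) -> WangProfile:
        prof = self._wang_cache.get(term)
        if prof is None:
            prof = wang_svalues(self.graph, term, self.wang_weights)
            self._wang_cache[term] = prof
        return prof

    @property
    def depths(self) -> DepthTable:
        if self._depths is None:
            self._depths = longest_depths(self.graph)
        return self._depths

    @property
    def norm(self) -> NormalizationContext:
        if self._norm is None:
            ctx = NormalizationContext()
            if self.ic is not None:
                for ns in self.graph.roots:
                    vals = [
                        v
                        for t, v in self.ic.ic.items()
                        if self.graph.namespace_of(t) == ns
                    ]
                    if vals:
                        ctx.ic_max[ns] = max(vals)
            if self.corpus is not None:
                ctx.n_proteins = self.corpus.protein_count
            if (
                self.ic is not None
                and self.ic.substrate is not None
                and self.ic.model == "annotation"
            ):
                counts = self.ic.substrate.counts
                for ns in self.graph.roots:
                    once = sorted(
                        t
                        for t, f in counts.items()
                        if f == 1 and self.graph.namespace_of(t) == ns
                    )
                    if once:
                        ctx.t0_ic[ns] = self.ic[once[0]]
                    elif ns in ctx.ic_max:
                        ctx.t0_ic[ns] = ctx.ic_max[ns]
            self._norm = ctx
        return self._norm

    def _check_pair(self, a: str, b: str) -> str:
        ns_a, ns_b = self.graph.namespace_of(a), self.graph.namespace_of(b)
        if ns_a != ns_b:
            raise OntologyError(
                f"terms {a!r} ({ns_a}) and {b!r} ({ns_b}) are in different namespaces"
            )
        return ns_a

    def defined(self, term: str) -> bool:
        return self.ic is None or self.ic.defined(term)


# -- mu functionals -------------------------------------------------------


def mu(term_set, delta, p: float) -> float:
    """Description measure of a term set: max (p=inf) or sum (p=1) of
    specificities ``delta(t)``.  NaN specificities propagate; an empty set
    is an error.
    """
    if not term_set:
        raise OntologyError("mu of an empty term set is undefined")
    getter = delta.get if hasattr(delta, "get") else delta
    values = [getter(t) for t in term_set]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
        return math.nan
    return max(values) if p == INF else sum(values)


# -- common-ancestor machinery -------------------------------------------


@dataclass
class CommonAncestorSummary:
    """MICA, disjunctive and informative common ancestors for a term pair.

    ``dca`` and ``ica`` are ordered by increasing IC with the MICA last.
    """

    a: str
    b: str
    common: frozenset[str]
    mica: str
    mica_ic: float
    dca: tuple[str, ...] = ()
    ica: tuple[str, ...] = ()


def common_ancestors(graph: OntologyGraph, a: str, b: str) -> frozenset[str]:
    """T_a & T_b (both closures are reflexive, so never empty in a namespace)."""
    return graph.ancestors(a) & graph.ancestors(b)


def mica(ctx: MeasureContext, a: str, b: str) -> tuple[str, float]:
    """Most informative common ancestor; ties broken to the smallest term id."""
    if ctx.ic is None:
        raise OntologyError("MICA requires a single-valued IC model, not Wang")
    ctx._check_pair(a, b)
    key = (a, b) if a <= b else (b, a)
    hit = ctx._mica_cache.get(key)
    if hit is not None:
        return hit
    common = common_ancestors(ctx.graph, a, b)
    if not (ctx.defined(a) and ctx.defined(b)):
        out = min(common), math.nan
    elif a == b:
        out = a, ctx.ic[a]  # a self pair is its own most informative ancestor
    else:
        best_ic = max(ctx.ic[t] for t in common)
        best = min(t for t in common if ctx.ic[t] == best_ic)
        out = best, best_ic
    ctx._mica_cache[key] = out
    return out


def _has_path_avoiding(g: nx.DiGraph, src: str, dst: str, avoid: str) -> bool:
    if dst == avoid or src == avoid:
        return False
    if src == dst:
        return True
    sub = g.subgraph(n for n in g if n != avoid)
    return nx.has_path(sub, src, dst)


def _pairwise_disjunctive(
    graph: OntologyGraph, u: str, v: str, a: str, b: str
) -> bool:
    """True if ancestors u, v reach each of a and b via mutually independent
    paths (u's path avoids v and v's path avoids u)."""
    g = graph.nx_graph
    for target in (a, b):
        if not _has_path_avoiding(g, u, target, v):
            return False
        if not _has_path_avoiding(g, v, target, u):
            return False
    return True


def informative_common_ancestors(
    ctx: MeasureContext, a: str, b: str
) -> tuple[str, ...]:
    """All common ancestors with IC > 0, ordered by increasing IC, MICA last."""
    if ctx.ic is None:
        raise OntologyError("ICA requires a single-valued IC model, not Wang")
    ctx._check_pair(a, b)
    key = (a, b) if a <= b else (b, a)
    hit = ctx._ica_cache.get(key)
    if hit is not None:
        return hit
    common = common_ancestors(ctx.graph, a, b)
    informative = [
        t for t in common if ctx.ic.defined(t) and ctx.ic[t] > 0
    ]
    informative.sort(key=lambda t: (-ctx.ic[t], t))
    out = tuple(reversed(informative))
    ctx._ica_cache[key] = out
    return out


def disjunctive_common_ancestors(
    ctx: MeasureContext, a: str, b: str
) -> tuple[str, ...]:
    """Greedy GraSM selection of disjunctive common ancestors.

    Candidates are the informative (IC > 0) common ancestors, visited in
    decreasing IC order starting from the MICA; a candidate is kept iff it
    is pairwise disjunctive from every ancestor kept so far.  Returned in
    increasing IC order with the MICA last.
    """
    key = (a, b) if a <= b else (b, a)
    hit = ctx._dca_cache.get(key)
    if hit is not None:
        return hit
    ordered = informative_common_ancestors(ctx, a, b)
    if not ordered:
        out: tuple[str, ...] = ()
    else:
        # the greedy selection starts from the MICA (the list's last entry
        # by contract), then admits candidates in decreasing IC order
        c, _ = mica(ctx, a, b)
        kept = [c]
        for t in reversed(ordered):  # decreasing IC
            if t == c:
                continue
            if all(_pairwise_disjunctive(ctx.graph, t, u, a, b) for u in kept):
                kept.append(t)
        out = tuple(reversed(kept))
    ctx._dca_cache[key] = out
    return out


def ancestor_summary(
    ctx: MeasureContext,
    a: str,
    b: str,
    with_dca: bool = False,
    with_ica: bool = False,
) -> CommonAncestorSummary:
    """Bundle MICA (and optionally DCA / ICA lists) for a pair."""
    c, ic_c = mica(ctx, a, b)
    return CommonAncestorSummary(
        a=a,
        b=b,
        common=common_ancestors(ctx.graph, a, b),
        mica=c,
        mica_ic=ic_c,
        dca=disjunctive_common_ancestors(ctx, a, b) if with_dca else (),
        ica=informative_common_ancestors(ctx, a, b) if with_ica else (),
    )


# -- correction factor ----------------------------------------------------


def epsilon(ctx: MeasureContext, rule: str, a: str, b: str) -> float:
    """Correction factor eps in (0, 1] for the pair (a, b).

    When IC(MICA) = 0 the whole similarity is already 0, and eps is
    defined as 1 by convention.
    """
    if rule == "one":
        return 1.0
    _, ic_c = mica(ctx, a, b)
    if math.isnan(ic_c):
        return math.nan
    if ic_c <= 0:
        return 1.0
    if rule == "relevance":
        return 1.0 - math.exp(-ic_c)
    if rule == "li":
        return 1.0 - 1.0 / (1.0 + ic_c)
    if rule in ("grasm", "xgrasm"):
        lst = (
            disjunctive_common_ancestors(ctx, a, b)
            if rule == "grasm"
            else informative_common_ancestors(ctx, a, b)
        )
        if not lst:
            return 1.0
        return fmean(ctx.ic[t] for t in lst) / ic_c
    raise OntologyError(f"unknown epsilon rule {rule!r}")


# -- the unified engine ---------------------------------------------------


def unified_similarity(
    ctx: MeasureContext, a: str, b: str, params: SimilarityParams
) -> float:
    """Evaluate the fundamental formula directly from the ancestor closures.

    For the three -ln p IC models the specificity delta(t) is IC(t).  For
    the Wang model the description measures are profile sums: the
    commonality uses S_a(t) + S_b(t) over the shared ancestors while each
    term's own description is its semantic value SV.
    """
    ctx._check_pair(a, b)
    graph = ctx.graph
    Ta, Tb = graph.ancestors(a), graph.ancestors(b)
    common = Ta & Tb
    if ctx.ic_model == "wang":
        Sa, Sb = ctx.wang_profile(a).svalues, ctx.wang_profile(b).svalues
        mu_common = mu(common, lambda t: Sa[t] + Sb[t], params.p)
        mu_a = mu(Ta, Sa, params.p)
        mu_b = mu(Tb, Sb, params.p)
    else:
        assert ctx.ic is not None
        if not (ctx.defined(a) and ctx.defined(b)):
            return math.nan
        mu_common = mu(common, ctx.ic.ic, params.p)
        mu_a = mu(Ta, ctx.ic.ic, params.p)
        mu_b = mu(Tb, ctx.ic.ic, params.p)
    eps = epsilon(ctx, params.epsilon_rule, a, b)
    if math.isnan(eps):
        return math.nan
    beta, gamma = params.beta, params.gamma
    if params.select_max:
        beta, gamma = (1.0, 0.0) if mu_a >= mu_b else (0.0, 1.0)
    denom = params.alpha * mu_common + beta * mu_a + gamma * mu_b
    if denom == 0:
        return 0.0  # pair of roots: no information shared
    return eps * mu_common / denom


# -- closed forms ---------------------------------------------------------


def _pair_ics(ctx: MeasureContext, a: str, b: str) -> tuple[float, float, float]:
    """(IC(a), IC(b), IC(mica)); NaNs when either endpoint is undefined."""
    assert ctx.ic is not None
    if not (ctx.defined(a) and ctx.defined(b)):
        return math.nan, math.nan, math.nan
    _, ic_c = mica(ctx, a, b)
    return ctx.ic[a], ctx.ic[b], ic_c


def resnik_raw(ctx: MeasureContext, a: str, b: str) -> float:
    ctx._check_pair(a, b)
    return _pair_ics(ctx, a, b)[2]


def lin_similarity(ctx: MeasureContext, a: str, b: str) -> float:
    ctx._check_pair(a, b)
    ia, ib, ic_c = _pair_ics(ctx, a, b)
    if math.isnan(ic_c):
        return math.nan
    if ia + ib == 0:
        return 0.0
    return 2.0 * ic_c / (ia + ib)


def resnik_nunivers(ctx: MeasureContext, a: str, b: str) -> float:
    ctx._check_pair(a, b)
    ia, ib, ic_c = _pair_ics(ctx, a, b)
    if math.isnan(ic_c):
        return math.nan
    m = max(ia, ib)
    if m == 0:
        return 0.0
    return ic_c / m


def resnik_nmax(ctx: MeasureContext, a: str, b: str) -> float:
    ns = ctx._check_pair(a, b)
    ic_c = _pair_ics(ctx, a, b)[2]
    if math.isnan(ic_c):
        return math.nan
    ic_max = ctx.norm.ic_max.get(ns, 0.0)
    if ic_max <= 0:
        raise OntologyError(f"Nmax normalization needs ic_max > 0 in {ns!r}")
    return ic_c / ic_max


def resnik_nunif(ctx: MeasureContext, a: str, b: str) -> float:
    ctx._check_pair(a, b)
    ic_c = _pair_ics(ctx, a, b)[2]
    if math.isnan(ic_c):
        return math.nan
    n = ctx.norm.n_proteins
    if n is None or n <= 1:
        raise OntologyError("Nunif normalization needs a corpus with N > 1")
    return ic_c / math.log2(n)


def jc_distance(ctx: MeasureContext, a: str, b: str) -> float:
    """Jiang-Conrath distance IC(a) + IC(b) - 2 IC(c); 0 for a self pair."""
    ctx._check_pair(a, b)
    ia, ib, ic_c = _pair_ics(ctx, a, b)
    if math.isnan(ic_c):
        return math.nan
    return ia + ib - 2.0 * ic_c


def jc_couto(ctx: MeasureContext, a: str, b: str) -> float:
    d = jc_distance(ctx, a, b)
    return math.nan if math.isnan(d) else 1.0 / (1.0 + d)


def jc_t0(ctx: MeasureContext, a: str, b: str) -> float:
    ns = ctx._check_pair(a, b)
    d = jc_distance(ctx, a, b)
    if math.isnan(d):
        return math.nan
    t0 = ctx.norm.t0_ic.get(ns)
    if t0 is None or t0 <= 0:
        raise OntologyError("t0 normalization needs an annotation corpus")
    return 1.0 - min(1.0, d / t0)


def jc_pesquita(ctx: MeasureContext, a: str, b: str) -> float:
    ctx._check_pair(a, b)
    ia, ib, ic_c = _pair_ics(ctx, a, b)
    if math.isnan(ic_c):
        return math.nan
    n = ctx.norm.n_proteins
    if n is None or n <= 1:
        raise OntologyError("uniform JC normalization needs a corpus with N > 1")
    scale = math.log2(n)
    return 1.0 - (ia / scale + ib / scale) / 2.0 + ic_c / scale


def jc_canonical(ctx: MeasureContext, a: str, b: str) -> float:
    """1 - d_JC / (IC(a) + IC(b)); algebraically identical to lin."""
    ctx._check_pair(a, b)
    ia, ib, ic_c = _pair_ics(ctx, a, b)
    if math.isnan(ic_c):
        return math.nan
    if ia + ib == 0:
        return 0.0
    return 1.0 - (ia + ib - 2.0 * ic_c) / (ia + ib)


def wang_similarity(ctx: MeasureContext, a: str, b: str) -> float:
    """Wang et al.: shared S-value mass over total semantic values."""
    ctx._check_pair(a, b)
    pa, pb = ctx.wang_profile(a), ctx.wang_profile(b)
    common = set(pa.svalues) & set(pb.svalues)
    num = sum(pa.svalues[t] + pb.svalues[t] for t in common)
    den = pa.sv + pb.sv
    return num / den if den else 0.0


def wu_palmer(ctx: MeasureContext, a: str, b: str) -> float:
    """Depth-based similarity, with len(r, x) the longest-path depth of x
    and len(r, c) the maximum depth over all common ancestors (as printed
    in the source formulation: the denominator depths are global, not
    routed through the chosen common ancestor)."""
    ctx._check_pair(a, b)
    depths = ctx.depths
    common = common_ancestors(ctx.graph, a, b)
    l_c = max(depths.lengths[t] for t in common)
    l_a, l_b = depths.lengths[a], depths.lengths[b]
    den = l_a + l_b + 2.0 * l_c
    return 2.0 * l_c / den if den else 0.0


def edge_based(ctx: MeasureContext, a: str, b: str) -> float:
    """Longest-path edge-counting similarity len(r,c)/(len(r,c)+len(c,a)+len(c,b)).

    c is the deepest common ancestor (ties to the smallest term id).
    """
    ctx._check_pair(a, b)
    depths = ctx.depths
    common = common_ancestors(ctx.graph, a, b)
    deepest = max(depths.lengths[t] for t in common)
    c = min(t for t in common if depths.lengths[t] == deepest)
    l_c = depths.lengths[c]
    den = l_c + depths.pair_length(c, a) + depths.pair_length(c, b)
    return l_c / den if den else 0.0


def _corrected(rule: str, base: Callable[..., float]):
    def f(ctx: MeasureContext, a: str, b: str) -> float:
        s = base(ctx, a, b)
        if math.isnan(s):
            return math.nan
        return epsilon(ctx, rule, a, b) * s

    return f


def _relevance(ctx, a, b):
    s = lin_similarity(ctx, a, b)
    return s if math.isnan(s) else epsilon(ctx, "relevance", a, b) * s


def _li(ctx, a, b):
    s = lin_similarity(ctx, a, b)
    return s if math.isnan(s) else epsilon(ctx, "li", a, b) * s


# -- registry -------------------------------------------------------------

_LNP_MODELS = ("annotation", "zhang", "universal")


@dataclass(frozen=True)
class MeasureDef:
    """Registry entry: evaluator plus compatibility and contract metadata."""

    func: Callable[[MeasureContext, str, str], float]
    ic_models: tuple[str, ...]  # empty tuple = any context
    needs_corpus: bool = False
    normalized: bool = True  # score guaranteed in [0, 1]
    identity: bool = True  # sim(x, x) = 1 whenever x is informative
    engine_params: SimilarityParams | None = None
    canonical_ic: str | None = None  # the IC family the measure was proposed with


_P = SimilarityParams

REGISTRY: dict[str, MeasureDef] = {
    "resnik_raw": MeasureDef(resnik_raw, _LNP_MODELS, normalized=False, identity=False),
    "resnik_nmax": MeasureDef(resnik_nmax, _LNP_MODELS, identity=False,
                              canonical_ic="annotation"),
    "resnik_nunif": MeasureDef(resnik_nunif, ("annotation",), needs_corpus=True,
                               identity=False, canonical_ic="annotation"),
    "resnik_nunivers": MeasureDef(
        resnik_nunivers, _LNP_MODELS,
        engine_params=_P(INF, 0, 1, 0, "one", select_max=True),
    ),
    "lin": MeasureDef(lin_similarity, _LNP_MODELS,
                      engine_params=_P(INF, 0, 0.5, 0.5, "one"),
                      canonical_ic="annotation"),
    "relevance": MeasureDef(_relevance, _LNP_MODELS, identity=False,
                            engine_params=_P(INF, 0, 0.5, 0.5, "relevance"),
                            canonical_ic="annotation"),
    "li": MeasureDef(_li, _LNP_MODELS, identity=False,
                     engine_params=_P(INF, 0, 0.5, 0.5, "li"),
                     canonical_ic="annotation"),
    "zhang": MeasureDef(lin_similarity, ("zhang",),
                        engine_params=_P(INF, 0, 0.5, 0.5, "one")),
    "universal": MeasureDef(resnik_nunivers, ("universal",),
                            engine_params=_P(INF, 0, 1, 0, "one", select_max=True)),
    "wang": MeasureDef(wang_similarity, ("wang",),
                       engine_params=_P(1, 0, 1, 1, "one")),
    "jc_distance": MeasureDef(jc_distance, _LNP_MODELS, normalized=False,
                              identity=False, canonical_ic="annotation"),
    "jc_couto": MeasureDef(jc_couto, _LNP_MODELS, canonical_ic="annotation"),
    "jc_t0": MeasureDef(jc_t0, ("annotation",), needs_corpus=True,
                        canonical_ic="annotation"),
    "jc_pesquita": MeasureDef(jc_pesquita, ("annotation",), needs_corpus=True,
                              canonical_ic="annotation"),
    "jc_canonical": MeasureDef(jc_canonical, _LNP_MODELS, canonical_ic="annotation"),
    "wu_palmer": MeasureDef(wu_palmer, (), identity=False),
    "edge_based": MeasureDef(edge_based, ()),
}

for _base_name, _base_fn, _needs, _models in (
    ("lin", lin_similarity, False, _LNP_MODELS),
    ("nmax", resnik_nmax, False, _LNP_MODELS),
    ("nunif", resnik_nunif, True, ("annotation",)),
    ("nunivers", resnik_nunivers, False, _LNP_MODELS),
):
    for _rule in ("grasm", "xgrasm"):
        _identity = _base_name in ("lin", "nunivers") and _rule == "grasm"
        _engine = None
        if _base_name == "lin":
            _engine = _P(INF, 0, 0.5, 0.5, _rule)
        elif _base_name == "nunivers":
            _engine = _P(INF, 0, 1, 0, _rule, select_max=True)
        REGISTRY[f"{_rule}_{_base_name}"] = MeasureDef(
            _corrected(_rule, _base_fn),
            _models,
            needs_corpus=_needs,
            identity=_identity,
            engine_params=_engine,
            canonical_ic="annotation",
        )


def list_measures() -> list[str]:
    return sorted(REGISTRY)


def measure(name: str, a: str, b: str, ctx: MeasureContext) -> float:
    """Evaluate a registered measure for one term pair.

    Raises on an unknown name, on an incompatible (measure, IC model)
    combination, or when a corpus-scaled measure is asked for without a
    corpus.  Returns NaN when the pair touches a term with undefined IC.
    """
    try:
        mdef = REGISTRY[name]
    except KeyError:
        raise OntologyError(
            f"unknown measure {name!r}; available: {', '.join(list_measures())}"
        ) from None
    if mdef.ic_models and ctx.ic_model not in mdef.ic_models:
        raise OntologyError(
            f"measure {name!r} is incompatible with IC model {ctx.ic_model!r} "
            f"(allowed: {mdef.ic_models})"
        )
    if mdef.needs_corpus and ctx.corpus is None:
        raise OntologyError(f"measure {name!r} needs an annotation corpus")
    return mdef.func(ctx, a, b)
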