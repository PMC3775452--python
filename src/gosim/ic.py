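"""Term-specificity (information content) models.

Four models are provided:

``annotation``
    Corpus-based IC.  ``f(x)`` is the number of *distinct* gene products
    annotated to ``x`` or any of its descendants (the true-path rule:
    an annotation to a term implies annotations to all its ancestors),
    ``p(x) = f(x) / f(root)`` per namespace and ``IC(x) = -ln p(x)``.
    Terms never reached by any annotation ("orphans") have *undefined*
    IC, not zero, and any similarity touching one stays undefined.

``zhang``
    Topology-only IC.  ``f(leaf) = 1`` and ``f(x)`` is the sum of its
    children's counts; a term reachable from a leaf along several paths
    is counted once per path.  ``p`` (the D-value) and IC as above.

``universal``
    Topology-only IC using both parents and children: ``p(root) = 1`` and
    ``p(x)`` is the product over parents ``w`` of ``p(w) / |children(w)|``.
    Defined for every term; no orphans are possible.

``wang``
    Wang et al.'s S-value profile.  Within the ancestor closure T_x of a
    focus term x, ``S_x(x) = 1`` and ``S_x(t)`` is the maximum over
    children t' of t inside T_x of ``w_e * S_x(t')``, with the semantic
    contribution factor ``w_e`` 0.8 for is_a and 0.6 for part_of edges.
    The semantic value ``SV(x)`` is the sum of S-values over T_x and plays
    the role of the term's specificity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

from .ontology import AnnotationCorpus, OntologyGraph, OntologyError

logger = logging.getLogger(__name__)

#: Semantic contribution factors for the Wang model.
DEFAULT_WANG_WEIGHTS: Mapping[str, float] = {"is_a": 0.8, "part_of": 0.6}

IC_MODELS = ("annotation", "zhang", "universal", "wang")


@dataclass
class TermCountTable:
    """Per-term frequency substrate f(x) for the annotation or Zhang model."""

    model: str
    counts: dict[str, float]


@dataclass
class ICTable:
    """Per-term probability-like values and information content.

    ``ic`` holds only *defined* terms; orphans under the annotation model
    are absent and :meth:`defined` reports them.  ``get`` returns NaN for
    undefined terms so that arithmetic propagates undefinedness.
    """

    model: str
    p: dict[str, float]
    ic: dict[str, float]
    substrate: TermCountTable | None = None

    def defined(self, term: str) -> bool:
        return term in self.ic

    def get(self, term: str) -> float:
        return self.ic.get(term, math.nan)

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


@dataclass
class WangProfile:
    """S-values of one focus term over its ancestor closure."""

    term: str
    svalues: dict[str, float]
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WANG_WEIGHTS))

    @property
    def sv(self) -> float:
        """Semantic value SV(x) = sum of S-values over T_x."""
        return sum(self.svalues.values())


# -- annotation model -----------------------------------------------------


def annotation_counts(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    literal_children_sum: bool = False,
) -> TermCountTable:
    """True-path annotation frequency f(x) for every term.

    By default f(x) is the number of distinct proteins annotated to x or
    any descendant of x (no double counting through diamond paths), which
    is the only reading compatible with IC monotonicity along edges.
    ``literal_children_sum=True`` instead evaluates the naive recursion
    "own direct count plus the direct counts of the children", kept for
    comparison; it can double-count and is not monotone in general.
    """
    per_term = corpus.proteins_per_term()
    if not per_term:
        logger.warning("empty annotation corpus: all counts are 0")
    counts: dict[str, float] = {}
    if literal_children_sum:
        for tid, term in graph.terms.items():
            if term.obsolete:
                continue
            n = len(per_term.get(tid, ()))
            for child in graph.children(tid):
                n += len(per_term.get(child, ()))
            counts[tid] = float(n)
        return TermCountTable("annotation-literal", counts)

    # distinct-protein union over the term and its descendants, computed
    # bottom-up (reverse topological order) to avoid repeated closures
    sets: dict[str, set[str]] = {}
    for tid in reversed(graph.topological_order()):
        if graph.terms[tid].obsolete:
            continue
        s = set(per_term.get(tid, ()))
        for child in graph.children(tid):
            s |= sets[child]
        sets[tid] = s
        counts[tid] = float(len(s))
    return TermCountTable("annotation", counts)


def annotation_ic(counts: TermCountTable, graph: OntologyGraph) -> ICTable:
    """Corpus IC: p(x) = f(x)/f(root) per namespace, IC = -ln p.

    Terms with f(x) = 0 are orphans and carry no IC.  Raises if every
    namespace root has count 0 (nothing annotated at all).
    """
    root_counts = {ns: counts.counts.get(r, 0.0) for ns, r in graph.roots.items()}
    if all(c == 0 for c in root_counts.values()):
        raise OntologyError("annotation IC undefined: no namespace has annotations")
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for tid, f in counts.counts.items():
        ns = graph.namespace_of(tid)
        froot = root_counts[ns]
        if froot == 0 or f == 0:
            continue  # orphan: IC undefined, never 0
        p[tid] = f / froot
        ic[tid] = -math.log(p[tid]) + 0.0
    return ICTable("annotation", p, ic, substrate=counts)


# -- Zhang model ----------------------------------------------------------


def zhang_counts(graph: OntologyGraph) -> TermCountTable:
    """Zhang topological counts: f(leaf)=1, f(x)=sum of children's f.

    Double counting through multiple paths is part of the definition.
    """
    counts: dict[str, float] = {}
    for tid in reversed(graph.topological_order()):
        if graph.terms[tid].obsolete:
            continue
        kids = graph.children(tid)
        counts[tid] = 1.0 if not kids else float(sum(counts[c] for c in kids))
    return TermCountTable("zhang", counts)


def zhang_ic(counts: TermCountTable, graph: OntologyGraph) -> ICTable:
    """Zhang IC: D-value p(x) = f(x)/f(root) per namespace, IC = -ln p."""
    root_counts = {ns: counts.counts[r] for ns, r in graph.roots.items()}
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for tid, f in counts.counts.items():
        froot = root_counts[graph.namespace_of(tid)]
        p[tid] = f / froot
        ic[tid] = -math.log(p[tid]) + 0.0
    return ICTable("zhang", p, ic, substrate=counts)


# -- GO-universal model ---------------------------------------------------


def universal_ic(graph: OntologyGraph) -> ICTable:
    """Topological-position IC: p(root)=1, p(x) = prod over parents w of
    p(w)/|children(w)|, evaluated in topological order; IC = -ln p.

    Every term gets a value (no orphans possible); IC is non-decreasing
    along every parent -> child edge since each factor is <= 1.
    """
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    for tid in graph.topological_order():
        if graph.terms[tid].obsolete:
            continue
        # accumulate in log space: the product of parent probabilities can
        # underflow in deep multi-parent DAGs even though IC stays modest
        v = 0.0
        for w in graph.parents(tid):
            v += ic[w] + math.log(len(graph.children(w)))
        ic[tid] = v
        p[tid] = math.exp(-v)
    return ICTable("universal", p, ic)


# -- Wang model -----------------------------------------------------------


def wang_svalues(
    graph: OntologyGraph,
    term: str,
    weights: Mapping[str, float] | None = None,
) -> WangProfile:
    """S-value profile of ``term`` over its ancestor closure T_x.

    S_x(x) = 1; for an ancestor t, S_x(t) is the maximum over children t'
    of t that lie inside T_x of ``w_e(t -> t') * S_x(t')``.
    """
    w = dict(DEFAULT_WANG_WEIGHTS if weights is None else weights)
    closure = graph.ancestors(term)
    order = [t for t in graph.topological_order() if t in closure]
    svalues: dict[str, float] = {}
    for t in reversed(order):  # most specific first
        if t == term:
            svalues[t] = 1.0
            continue
        best = 0.0
        for child in graph.children(t):
            if child not in closure:
                continue
            rel = graph.relation(t, child)
            if rel not in w:
                raise OntologyError(f"no Wang weight for relation {rel!r}")
            best = max(best, w[rel] * svalues[child])
        svalues[t] = best
    return WangProfile(term, svalues, w)


# -- dispatcher -----------------------------------------------------------


def compute_ic(
    graph: OntologyGraph,
    model: str,
    corpus: AnnotationCorpus | None = None,
) -> ICTable:
    """Build the ICTable for one of the -ln p models.

    The Wang model has no single-number IC table; use
    :func:`wang_svalues` (or a similarity context) for it.
    """
    if model == "annotation":
        if corpus is None:
            raise OntologyError("annotation IC requires an annotation corpus")
        return annotation_ic(annotation_counts(graph, corpus), graph)
    if model == "zhang":
        return zhang_ic(zhang_counts(graph), graph)
    if model == "universal":
        return universal_ic(graph)
    raise OntologyError(
        f"unknown or table-less IC model {model!r}; expected one of "
        "('annotation', 'zhang', 'universal')"
    )
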