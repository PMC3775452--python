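"""Ontology DAG and annotation-corpus handling.

The Gene Ontology (and any ontology this package accepts) is a rooted
directed acyclic graph whose topology is carried by ``is_a`` and ``part_of``
edges only; other relationship types are biological annotations that do not
shape the hierarchy and are dropped at parse time.  Edges are stored
parent -> child, i.e. from the more general to the more specific term, and
"ancestor" always means toward the root.  The root sits at level 0.

Each namespace (e.g. the three GO sub-ontologies) is a disjoint rooted
sub-DAG with exactly one root; closures, depths and information content are
always computed per namespace.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relationship types that carry the DAG topology.
TOPOLOGY_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """A structural problem in an ontology or annotation input."""


class CycleError(OntologyError):
    """The term graph contains a directed cycle."""


@dataclass(frozen=True)
class Term:
    """A single ontology term."""

    id: str
    name: str = ""
    namespace: str = ""
    obsolete: bool = False
    alt_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Edge:
    """A typed parent -> child link between two terms."""

    parent: str
    child: str
    relation: str = "is_a"

    def __post_init__(self) -> None:
        if self.parent == self.child:
            raise OntologyError(f"self-edge on term {self.parent!r}")
        if self.relation not in TOPOLOGY_RELATIONS:
            raise OntologyError(
                f"relation {self.relation!r} is not a topology relation "
                f"{TOPOLOGY_RELATIONS}"
            )


class OntologyGraph:
    """A validated, immutable rooted DAG of terms.

    Parameters
    ----------
    terms:
        The term set; ids must be unique.
    edges:
        Typed parent -> child edges between non-obsolete terms of the same
        namespace.

    Raises
    ------
    CycleError
        If the edges contain a directed cycle (one cycle is named).
    OntologyError
        On duplicate ids, dangling edges, edges touching obsolete terms,
        cross-namespace edges, namespaces without a unique root, or terms
        unreachable from their namespace root.
    """

    def __init__(self, terms: Iterable[Term], edges: Iterable[Edge]):
        self.terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self.terms:
                raise OntologyError(f"duplicate term id {t.id!r}")
            self.terms[t.id] = t

        self._alt: dict[str, str] = {}
        for t in self.terms.values():
            for alt in t.alt_ids:
                if alt not in self.terms:
                    self._alt[alt] = t.id

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for e in edges:
            for endpoint in (e.parent, e.child):
                if endpoint not in self.terms:
                    raise OntologyError(f"edge endpoint {endpoint!r} not a term")
                if self.terms[endpoint].obsolete:
                    raise OntologyError(
                        f"edge touches obsolete term {endpoint!r}"
                    )
            p, c = self.terms[e.parent], self.terms[e.child]
            if p.namespace != c.namespace:
                raise OntologyError(
                    f"edge {e.parent}->{e.child} crosses namespaces "
                    f"{p.namespace!r}/{c.namespace!r}"
                )
            # duplicate (parent, child) pairs collapse; is_a wins over part_of
            if g.has_edge(e.parent, e.child):
                if e.relation == "is_a":
                    g[e.parent][e.child]["relation"] = "is_a"
            else:
                g.add_edge(e.parent, e.child, relation=e.relation)
        self._g = g

        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise CycleError(f"ontology contains a cycle: {path}")

        self.roots: dict[str, str] = {}
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            if g.in_degree(tid) == 0:
                ns = term.namespace
                if ns in self.roots:
                    raise OntologyError(
                        f"namespace {ns!r} has multiple roots: "
                        f"{self.roots[ns]!r} and {tid!r}"
                    )
                self.roots[ns] = tid
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            ns = term.namespace
            if ns not in self.roots:
                raise OntologyError(f"namespace {ns!r} has no root")
        # reachability from the namespace root
        for tid, term in self.terms.items():
            if term.obsolete or g.in_degree(tid) == 0:
                continue
            if self.roots[term.namespace] not in self.ancestors(tid):
                raise OntologyError(
                    f"term {tid!r} has no path to its namespace root"
                )

    # -- queries ---------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term: str) -> None:
        if term not in self.terms:
            raise OntologyError(f"unknown term {term!r}")

    def resolve(self, term: str) -> str | None:
        """Map a primary or alternate id to the primary id, else ``None``."""
        if term in self.terms:
            return term
        return self._alt.get(term)

    def namespace_of(self, term: str) -> str:
        self._require(term)
        return self.terms[term].namespace

    def relation(self, parent: str, child: str) -> str:
        """Relation type of the edge parent -> child."""
        return self._g[parent][child]["relation"]

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.predecessors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._g.successors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive ancestor closure T_x (includes ``term`` itself)."""
        self._require(term)
        cached = self._g.nodes[term].get("_anc")
        if cached is None:
            cached = frozenset(nx.ancestors(self._g, term)) | {term}
            self._g.nodes[term]["_anc"] = cached
        return cached

    def descendants(self, term: str) -> set[str]:
        """Strict descendant closure (excludes ``term`` itself)."""
        self._require(term)
        return set(nx.descendants(self._g, term))

    def leaves(self, namespace: str | None = None) -> set[str]:
        """Terms with no children (optionally within one namespace)."""
        out = set()
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            if namespace is not None and term.namespace != namespace:
                continue
            if self._g.out_degree(tid) == 0:
                out.add(tid)
        return out

    def edges(self) -> Iterator[Edge]:
        for p, c, data in self._g.edges(data=True):
            yield Edge(p, c, data["relation"])

    def namespace_terms(self, namespace: str) -> set[str]:
        return {
            tid
            for tid, t in self.terms.items()
            if t.namespace == namespace and not t.obsolete
        }

    def topological_order(self) -> list[str]:
        """Terms ordered so that every parent precedes its children."""
        return list(nx.topological_sort(self._g))

    @property
    def nx_graph(self) -> nx.DiGraph:
        """The underlying parent -> child :class:`networkx.DiGraph` (read-only use)."""
        return self._g


# -- depths --------------------------------------------------------------


@dataclass
class DepthTable:
    """Longest-path depths from each namespace root.

    ``lengths[x]`` is the maximum number of edges on any root-to-x path
    (root = 0).  :meth:`pair_length` gives the longest path between an
    ancestor and one of its descendants and is computed on demand.
    """

    lengths: dict[str, int]
    _graph: OntologyGraph = field(repr=False)
    _pair_cache: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def pair_length(self, ancestor: str, descendant: str) -> int:
        """Longest path (in edges) from ``ancestor`` down to ``descendant``.

        Defined only when ``descendant`` is in the descendant closure of
        ``ancestor`` (or the same term, length 0).
        """
        g = self._graph
        g._require(ancestor)
        g._require(descendant)
        table = self._pair_cache.get(ancestor)
        if table is None:
            # longest-path DP over the sub-DAG below `ancestor`
            reach = g.descendants(ancestor) | {ancestor}
            table = {ancestor: 0}
            for node in g.topological_order():
                if node not in reach or node == ancestor:
                    continue
                best = -1
                for p in g.parents(node):
                    if p in table:
                        best = max(best, table[p] + 1)
                if best >= 0:
                    table[node] = best
            self._pair_cache[ancestor] = table
        if descendant not in table:
            raise OntologyError(
                f"{descendant!r} is not a descendant of {ancestor!r}"
            )
        return table[descendant]


def longest_depths(graph: OntologyGraph) -> DepthTable:
    """Longest-path depth of every non-obsolete term from its namespace root."""
    lengths: dict[str, int] = {}
    for node in graph.topological_order():
        if graph.terms[node].obsolete:
            continue
        parents = graph.parents(node)
        if not parents:
            lengths[node] = 0
        else:
            lengths[node] = 1 + max(lengths[p] for p in parents)
    return DepthTable(lengths, graph)


# -- convenience wrappers (functional surface) ----------------------------


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Reflexive ancestor closure T_x of ``term``."""
    return graph.ancestors(term)


def descendants(graph: OntologyGraph, term: str) -> set[str]:
    """Strict descendant closure of ``term``."""
    return graph.descendants(term)


def children(graph: OntologyGraph, term: str) -> set[str]:
    return graph.children(term)


def leaves(graph: OntologyGraph, namespace: str | None = None) -> set[str]:
    return graph.leaves(namespace)


def roots(graph: OntologyGraph) -> dict[str, str]:
    return dict(graph.roots)


# -- annotation corpus ----------------------------------------------------


@dataclass
class GafReport:
    """Bookkeeping from a GAF parse."""

    n_rows: int = 0
    n_not_qualified: int = 0
    n_unresolvable: int = 0
    unresolvable_terms: Counter = field(default_factory=Counter)


@dataclass
class AnnotationCorpus:
    """Direct gene-product -> term annotations with evidence codes.

    Annotations are *direct*: true-path propagation to ancestors happens
    in the information-content layer, not here.
    """

    direct_annotations: dict[str, set[tuple[str, str]]]
    report: GafReport = field(default_factory=GafReport)

    @property
    def protein_count(self) -> int:
        """Number of distinct annotated gene products, N."""
        return len(self.direct_annotations)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.direct_annotations)

    def terms_of(
        self,
        protein: str,
        graph: OntologyGraph | None = None,
        namespace: str | None = None,
    ) -> set[str]:
        """Direct annotation terms of one protein, optionally one namespace."""
        if protein not in self.direct_annotations:
            raise OntologyError(f"protein {protein!r} not in corpus")
        terms = {t for t, _ in self.direct_annotations[protein]}
        if namespace is not None:
            if graph is None:
                raise ValueError("namespace filtering requires the graph")
            terms = {t for t in terms if graph.namespace_of(t) == namespace}
        return terms

    def proteins_per_term(self) -> dict[str, set[str]]:
        """Direct annotation sets A(x): term -> {proteins annotated to it}."""
        out: dict[str, set[str]] = {}
        for protein, anns in self.direct_annotations.items():
            for term, _ in anns:
                out.setdefault(term, set()).add(protein)
        return out


# -- OBO parsing ----------------------------------------------------------


def parse_obo(source: str | IO[str]) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into a validated :class:`OntologyGraph`.

    Obsolete terms are retained but stripped of any edges; relationship
    types other than ``is_a``/``part_of`` are dropped (a count is logged).
    """
    if isinstance(source, str) and "\n" in source:
        import io as _io

        source = _io.StringIO(source)
    multi = obonet.read_obo(source, ignore_obsolete=False)
    default_ns = ""
    ns_field = multi.graph.get("default-namespace")
    if ns_field:
        default_ns = ns_field[0] if isinstance(ns_field, list) else str(ns_field)

    terms: list[Term] = []
    obsolete_ids: set[str] = set()
    for tid, data in multi.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        if obsolete:
            obsolete_ids.add(tid)
        terms.append(
            Term(
                id=tid,
                name=data.get("name", ""),
                namespace=data.get("namespace", default_ns),
                obsolete=obsolete,
                alt_ids=frozenset(data.get("alt_id", [])),
            )
        )

    edges: list[Edge] = []
    dropped: Counter = Counter()
    # obonet stores edges child -> parent keyed by relation type
    for child, parent, relation in multi.edges(keys=True):
        if relation not in TOPOLOGY_RELATIONS:
            dropped[relation] += 1
            continue
        if child in obsolete_ids or parent in obsolete_ids:
            continue
        edges.append(Edge(parent=parent, child=child, relation=relation))
    if dropped:
        logger.info(
            "dropped %d non-topology relationship(s): %s",
            sum(dropped.values()),
            dict(dropped),
        )

    graph = OntologyGraph(terms, edges)
    graph.dropped_relations = dict(dropped)  # type: ignore[attr-defined]
    return graph


# -- GAF parsing ----------------------------------------------------------

_GAF_MIN_COLUMNS = 7


def parse_gaf(
    source: str | IO[str],
    graph: OntologyGraph,
    evidence_allow: set[str] | None = None,
) -> AnnotationCorpus:
    """Parse a GAF 2.x file against ``graph``.

    Column 2 is the gene-product id, column 5 the term accession and column
    7 the evidence code (1-based).  ``NOT``-qualified rows are excluded;
    term ids are resolved through alternate ids; rows whose term cannot be
    resolved are skipped and counted in the report.  All evidence codes are
    retained unless an allow-list is given.
    """
    if isinstance(source, str):
        import io as _io
        import os

        if os.path.exists(source):
            stream: IO[str] = open(source)
        else:
            stream = _io.StringIO(source)
    else:
        stream = source

    report = GafReport()
    direct: dict[str, set[tuple[str, str]]] = {}
    seen: set[tuple[str, str]] = set()  # duplicate (protein, term) rows collapse
    with stream:
        for line in stream:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < _GAF_MIN_COLUMNS:
                report.n_unresolvable += 1
                continue
            report.n_rows += 1
            protein, qualifier, term, evidence = cols[1], cols[3], cols[4], cols[6]
            if "NOT" in qualifier.split("|"):
                report.n_not_qualified += 1
                continue
            resolved = graph.resolve(term)
            if resolved is None or graph.terms[resolved].obsolete:
                report.n_unresolvable += 1
                report.unresolvable_terms[term] += 1
                continue
            if evidence_allow is not None and evidence not in evidence_allow:
                continue
            if (protein, resolved) in seen:
                continue
            seen.add((protein, resolved))
            direct.setdefault(protein, set()).add((resolved, evidence))
    if report.n_unresolvable:
        logger.warning(
            "skipped %d GAF row(s) with unresolvable terms", report.n_unresolvable
        )
    return AnnotationCorpus(direct, report)


# -- serialization --------------------------------------------------------


def to_obo(graph: OntologyGraph, ontology_name: str = "gosim-fixture") -> str:
    """Serialize a graph as a deterministic OBO 1.2 flat file."""
    lines = [
        "format-version: 1.2",
        f"ontology: {ontology_name}",
        "",
    ]
    by_child: dict[str, list[Edge]] = {}
    for e in graph.edges():
        by_child.setdefault(e.child, []).append(e)
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name or t.id}")
        if t.namespace:
            lines.append(f"namespace: {t.namespace}")
        for alt in sorted(t.alt_ids):
            lines.append(f"alt_id: {alt}")
        if t.obsolete:
            lines.append("is_obsolete: true")
        for e in sorted(by_child.get(tid, []), key=lambda e: e.parent):
            if e.relation == "is_a":
                lines.append(f"is_a: {e.parent}")
            else:
                lines.append(f"relationship: part_of {e.parent}")
        lines.append("")
    return "\n".join(lines)


def to_gaf(corpus: AnnotationCorpus, graph: OntologyGraph) -> str:
    """Serialize a corpus as a deterministic GAF 2.1 file."""
    lines = ["!gaf-version: 2.1"]
    for protein in sorted(corpus.direct_annotations):
        for term, evidence in sorted(corpus.direct_annotations[protein]):
            aspect = {"biological_process": "P", "molecular_function": "F",
                      "cellular_component": "C"}.get(graph.namespace_of(term), "F")
            lines.append(
                "\t".join(
                    [
                        "GOSIM", protein, protein, "", term, "GOSIM:0001",
                        evidence, "", aspect, "", "", "protein", "taxon:0000",
                        "20130101", "GOSIM", "", "",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def graph_summary(graph: OntologyGraph) -> str:
    """TSV summary: term id, namespace, n_parents, n_children, depth."""
    depths = longest_depths(graph)
    rows = ["term_id\tnamespace\tn_parents\tn_children\tdepth"]
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        depth = "" if t.obsolete else str(depths.lengths[tid])
        rows.append(
            f"{tid}\t{t.namespace}\t{len(graph.parents(tid))}"
            f"\t{len(graph.children(tid))}\t{depth}"
        )
    return "\n".join(rows) + "\n"
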