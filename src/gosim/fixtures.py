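"""Deterministic synthetic ontologies and annotation corpora.

Three hand-built fixtures with fully hand-checkable numbers, plus seeded
random DAG/corpus generators, so every measure in the package is testable
without downloading GO or GOA data.

``fixture_diamond``
    Five terms r, a, b, c, d with edges r->a, r->b, a->c, b->c, c->d (all
    is_a): the smallest DAG with a multi-parent diamond.  Ships with a toy
    corpus (P1 -> d, P2 -> c, P3 -> a) whose ICs under every model are
    hand-derivable.

``fixture_chain``
    A root with two children; one child ("n1") has children "n2" and "n3",
    and "n3" starts a three-step descendant chain with binary branching so
    that the topological-position IC strictly increases down the chain.
    This is the shape on which the raw Resnik score is constant between
    "n2" and every descendant of "n3" while the Nunivers normalization
    strictly decreases - the inconsistency the normalization repairs.

``fixture_helicase``
    A synthetic reconstruction of a molecular-function neighbourhood around
    helicase activity in which ATP-dependent helicase activity and DNA
    helicase activity share two *disjunctive* common ancestors (helicase
    activity and nucleoside-triphosphatase activity), while purine
    NTP-dependent helicase vs DNA helicase has only the MICA.  Term ids
    reuse the corresponding GO accessions, but the wiring is a synthetic
    stand-in chosen so the two-DCA scenario is exact and hand-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ontology import AnnotationCorpus, Edge, OntologyGraph, OntologyError, Term


@dataclass(frozen=True)
class DagSpec:
    """Parameters for the random-DAG generator."""

    n_terms: int = 40
    max_parents: int = 3
    part_of_fraction: float = 0.2
    seed: int = 0
    namespace: str = "toy"

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise OntologyError("need at least a root and one term")
        if not 1 <= self.max_parents < self.n_terms:
            raise OntologyError("max_parents must be in [1, n_terms)")
        if not 0.0 <= self.part_of_fraction <= 1.0:
            raise OntologyError("part_of_fraction must be in [0, 1]")


def _graph(term_ids, edges, namespace="toy", names=None):
    names = names or {}
    terms = [Term(t, name=names.get(t, t), namespace=namespace) for t in term_ids]
    return OntologyGraph(terms, [Edge(p, c, r) for p, c, r in edges])


def fixture_diamond() -> tuple[OntologyGraph, AnnotationCorpus]:
    """The diamond DAG and its three-protein corpus."""
    graph = _graph(
        ["r", "a", "b", "c", "d"],
        [
            ("r", "a", "is_a"),
            ("r", "b", "is_a"),
            ("a", "c", "is_a"),
            ("b", "c", "is_a"),
            ("c", "d", "is_a"),
        ],
    )
    corpus = AnnotationCorpus(
        {
            "P1": {("d", "IDA")},
            "P2": {("c", "IDA")},
            "P3": {("a", "IDA")},
        }
    )
    return graph, corpus


def fixture_chain() -> OntologyGraph:
    """Root with sibling branches and a strictly-IC-increasing chain.

    Edges: r -> n1, r -> s; n1 -> n2, n1 -> n3; then n3 -> n4 -> n5 -> n6
    with a leaf sibling at each chain step (n4x, n5x, n6x) so each chain
    node halves the topological-position probability of its parent.
    """
    edges = [
        ("r", "n1", "is_a"),
        ("r", "s", "is_a"),
        ("n1", "n2", "is_a"),
        ("n1", "n3", "is_a"),
        ("n3", "n4", "is_a"),
        ("n3", "n4x", "is_a"),
        ("n4", "n5", "is_a"),
        ("n4", "n5x", "is_a"),
        ("n5", "n6", "is_a"),
        ("n5", "n6x", "is_a"),
    ]
    ids = ["r", "s", "n1", "n2", "n3", "n4", "n4x", "n5", "n5x", "n6", "n6x"]
    return _graph(ids, edges)


#: Readable handles for the helicase fixture's GO-style accessions.
HELICASE_TERMS = {
    "root": "GO:0003674",            # molecular_function
    "catalytic": "GO:0003824",       # catalytic activity
    "hydrolase": "GO:0016787",       # sibling splitting the probability mass
    "helicase": "GO:0004386",        # helicase activity
    "ntpase": "GO:0017111",          # nucleoside-triphosphatase activity
    "atpase": "GO:0016887",          # ATP hydrolysis activity
    "atpase_coupled": "GO:0042623",  # ATPase activity, coupled
    "purine_helicase": "GO:0070035", # purine NTP-dependent helicase activity
    "atp_helicase": "GO:0008026",    # ATP-dependent helicase activity
    "dna_helicase": "GO:0003678",    # DNA helicase activity
}


def fixture_helicase() -> OntologyGraph:
    """Synthetic two-disjunctive-ancestor scenario (see module docstring).

    Under the topological-position IC: helicase activity has IC ln 4 and
    is the MICA of (ATP-dependent helicase, DNA helicase); NTPase activity
    (IC ln 2) is a second disjunctive common ancestor reached through the
    ATPase branch on one side and directly on the other.  Catalytic
    activity (IC ln 2) is informative but *not* disjunctive from the MICA.
    """
    T = HELICASE_TERMS
    edges = [
        (T["root"], T["catalytic"], "is_a"),
        (T["root"], T["ntpase"], "is_a"),
        (T["catalytic"], T["helicase"], "is_a"),
        (T["catalytic"], T["hydrolase"], "is_a"),
        (T["helicase"], T["purine_helicase"], "is_a"),
        (T["helicase"], T["dna_helicase"], "is_a"),
        (T["ntpase"], T["atpase"], "is_a"),
        (T["ntpase"], T["dna_helicase"], "is_a"),
        (T["atpase"], T["atpase_coupled"], "is_a"),
        (T["atpase_coupled"], T["atp_helicase"], "is_a"),
        (T["purine_helicase"], T["atp_helicase"], "is_a"),
    ]
    names = {v: k for k, v in T.items()}
    return _graph(
        list(T.values()), edges, namespace="molecular_function", names=names
    )


def random_dag(spec: DagSpec | None = None, **kwargs) -> OntologyGraph:
    """Seeded random rooted DAG.

    Terms are laid out in a topological order; each non-root term picks
    1..max_parents distinct parents among the earlier terms, so the graph
    is acyclic, single-rooted and fully reachable by construction.
    """
    spec = spec if spec is not None else DagSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    ids = [f"T:{i:07d}" for i in range(spec.n_terms)]
    edges: list[tuple[str, str, str]] = []
    for i in range(1, spec.n_terms):
        k = int(rng.integers(1, spec.max_parents + 1))
        parents = rng.choice(i, size=min(k, i), replace=False)
        for p in np.sort(parents):
            rel = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
            edges.append((ids[int(p)], ids[i], rel))
    return _graph(ids, edges, namespace=spec.namespace)


def random_corpus(
    graph: OntologyGraph,
    n_proteins: int = 20,
    mean_terms_per_protein: float = 3.0,
    seed: int = 0,
) -> AnnotationCorpus:
    """Seeded random corpus: direct annotations drawn uniformly over
    non-root, non-obsolete terms; every protein gets at least one term."""
    rng = np.random.default_rng(seed)
    root_ids = set(graph.roots.values())
    candidates = sorted(
        t for t, term in graph.terms.items()
        if t not in root_ids and not term.obsolete
    )
    if not candidates:
        raise OntologyError("graph has no non-root terms to annotate")
    direct: dict[str, set[tuple[str, str]]] = {}
    for i in range(n_proteins):
        n_terms = 1 + rng.poisson(max(mean_terms_per_protein - 1.0, 0.0))
        n_terms = min(int(n_terms), len(candidates))
        chosen = rng.choice(len(candidates), size=n_terms, replace=False)
        direct[f"P{i:04d}"] = {(candidates[int(j)], "IEA") for j in chosen}
    return AnnotationCorpus(direct)
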