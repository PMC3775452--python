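"""Gene-product (protein) functional similarity.

Two annotated gene products are compared within one namespace by building
the full matrix of term-level similarities between their direct annotation
sets and collapsing it with one of four strategies:

``avg``   mean of all entries,
``max``   largest entry,
``bma``   best-match average: mean of the row maxima and of the column
          maxima, averaged ( (mean_i max_j + mean_j max_i) / 2 ),
``abm``   average best matches: all row and column maxima pooled,
          (sum of row maxima + sum of column maxima) / (m + n).

``bma`` and ``abm`` coincide exactly when both proteins have the same
number of terms.  Per the originating schemes, the topological-position
measure defaults to BMA, Wang's measure to ABM, Zhang's to Avg, and all
annotation-based measures to BMA.

Undefined term-level scores (NaN, from orphan terms under the corpus IC)
propagate to the gene level unless ``skip_undefined`` drops them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ontology import OntologyError
from .similarity import MeasureContext, measure

STRATEGIES = ("avg", "max", "bma", "abm")

#: Gene-level combination each term measure was proposed with.
_MEASURE_DEFAULTS = {"universal": "bma", "wang": "abm", "zhang": "avg"}


def default_strategy(measure_name: str) -> str:
    """The combination strategy canonically paired with a term measure."""
    return _MEASURE_DEFAULTS.get(measure_name, "bma")


@dataclass
class ProteinPairScore:
    protein1: str
    protein2: str
    namespace: str
    measure: str
    strategy: str
    score: float  # NaN = undefined

    @property
    def defined(self) -> bool:
        return not math.isnan(self.score)


def pairwise_matrix(
    ctx: MeasureContext,
    terms_a,
    terms_b,
    measure_name: str,
) -> np.ndarray:
    """Full m x n matrix of term-level scores (rows: terms_a, sorted)."""
    rows, cols = sorted(terms_a), sorted(terms_b)
    if not rows or not cols:
        raise OntologyError("pairwise matrix needs non-empty term sets")
    out = np.empty((len(rows), len(cols)))
    for i, ta in enumerate(rows):
        for j, tb in enumerate(cols):
            out[i, j] = measure(measure_name, ta, tb, ctx)
    return out


def combine(matrix: np.ndarray, strategy: str, skip_undefined: bool = False) -> float:
    """Collapse a term-similarity matrix into one score.

    Any NaN entry makes the result NaN unless ``skip_undefined``; with
    skipping, rows/columns that are entirely undefined are dropped.
    """
    if strategy not in STRATEGIES:
        raise OntologyError(f"unknown strategy {strategy!r}; expected {STRATEGIES}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise OntologyError("matrix must be 2-D and non-empty")
    if np.isnan(m).any() and not skip_undefined:
        return math.nan
    if strategy == "avg":
        v = np.nanmean(m) if skip_undefined else np.mean(m)
        return float(v)
    if strategy == "max":
        v = np.nanmax(m) if skip_undefined else np.max(m)
        return float(v)
    with np.errstate(all="ignore"):
        row_max = np.nanmax(m, axis=1) if skip_undefined else np.max(m, axis=1)
        col_max = np.nanmax(m, axis=0) if skip_undefined else np.max(m, axis=0)
    row_max = row_max[~np.isnan(row_max)]
    col_max = col_max[~np.isnan(col_max)]
    if row_max.size == 0 or col_max.size == 0:
        return math.nan
    if strategy == "bma":
        return float((row_max.mean() + col_max.mean()) / 2.0)
    # abm
    return float((row_max.sum() + col_max.sum()) / (row_max.size + col_max.size))


def protein_similarity(
    ctx: MeasureContext,
    protein1: str,
    protein2: str,
    measure_name: str,
    namespace: str,
    strategy: str = "default",
    skip_undefined: bool = False,
) -> ProteinPairScore:
    """Functional similarity of two gene products in one namespace.

    ``strategy='default'`` resolves to the measure's canonical combination.
    Raises when a protein is absent from the corpus; yields an undefined
    score when a protein has no annotation in the namespace.
    """
    if ctx.corpus is None:
        raise OntologyError("protein similarity requires an annotation corpus")
    if strategy == "default":
        strategy = default_strategy(measure_name)
    terms_a = ctx.corpus.terms_of(protein1, ctx.graph, namespace)
    terms_b = ctx.corpus.terms_of(protein2, ctx.graph, namespace)
    if not terms_a or not terms_b:
        score = math.nan
    else:
        matrix = pairwise_matrix(ctx, terms_a, terms_b, measure_name)
        score = combine(matrix, strategy, skip_undefined)
    return ProteinPairScore(protein1, protein2, namespace, measure_name, strategy, score)
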