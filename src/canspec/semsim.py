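"""Information-content GO semantic similarity between genes.

Term information content (IC) is the negative log2 of a term's annotation
frequency under the true-path rule: IC(t) = -log2 p(t) with p(t) the
fraction of annotated genes annotated to t or any of its descendants.  The
root annotates everything, so IC(root) = 0, and IC can only grow from
parent to child.  Term-term similarity is Lin's normalization of the
Resnik most-informative-common-ancestor (MICA) score,

    sim(t1, t2) = 2 * IC(MICA) / (IC(t1) + IC(t2)),

bounded in [0, 1] (the log base cancels).  Gene-gene similarity is the mean
of term similarities over all ordered pairs of the two genes' *direct*
annotations; propagated annotations are used only for the frequencies —
all-pairs over propagated sets would degenerate toward 1 because every
gene carries the root.  Terms from different namespaces share no ancestor
and contribute 0.

The group contrast compares the pairwise similarity distributions within
the most specific and the most general scored genes: functionally coherent
groups (shared deep modules) score high, functionally scattered groups
score low.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass
from itertools import combinations, product
from math import log2

import numpy as np
import pandas as pd

from .io_formats import OntologyGraph
from .specificity import ScoreComparisonResult, rank_sum_compare

logger = logging.getLogger(__name__)

__all__ = [
    "term_ic",
    "term_similarity",
    "gene_similarity",
    "pairwise_similarities",
    "ExtremesComparison",
    "compare_extremes",
]


def term_ic(graph: OntologyGraph) -> dict[str, float]:
    """Information content per term from propagated annotation frequencies.

    Terms annotating no gene (even after propagation) are dropped with a
    logged count.
    """
    propagated = graph.propagated()
    if not propagated:
        raise ValueError("ontology has no annotated genes")
    total = len(propagated)
    counts: dict[str, int] = {}
    for terms in propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    dropped = len(graph.terms) - len(counts)
    if dropped:
        logger.info("%d terms with zero annotation frequency dropped", dropped)
    return {t: -log2(c / total) for t, c in counts.items()}


def term_similarity(
    t1: str, t2: str, ic: dict[str, float], graph: OntologyGraph
) -> float:
    """Lin similarity of two terms via their most informative common ancestor."""
    if t1 not in ic or t2 not in ic:
        raise KeyError("both terms must carry information content")
    if graph.namespace(t1) != graph.namespace(t2):
        logger.debug("terms %s and %s are in different namespaces", t1, t2)
        return 0.0
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:
        logger.debug("terms %s and %s share no ancestor", t1, t2)
        return 0.0
    mica_ic = max(ic.get(a, 0.0) for a in common)
    return 2.0 * mica_ic / denom


def gene_similarity(
    g1: str, g2: str, graph: OntologyGraph, ic: dict[str, float]
) -> float:
    """Mean Lin similarity over all ordered pairs of direct annotations."""
    terms1 = [t for t in graph.annotations.get(g1, ()) if t in ic]
    terms2 = [t for t in graph.annotations.get(g2, ()) if t in ic]
    if not terms1:
        raise ValueError(f"gene {g1!r} has no IC-bearing annotation")
    if not terms2:
        raise ValueError(f"gene {g2!r} has no IC-bearing annotation")
    sims = [term_similarity(a, b, ic, graph) for a, b in product(terms1, terms2)]
    return float(np.mean(sims))


def pairwise_similarities(
    genes: Sequence[str], graph: OntologyGraph, ic: dict[str, float]
) -> np.ndarray:
    """All C(n, 2) within-group gene similarities, in combination order."""
    return np.array(
        [gene_similarity(a, b, graph, ic) for a, b in combinations(genes, 2)]
    )


@dataclass(frozen=True)
class ExtremesComparison:
    specific_genes: tuple[str, ...]
    general_genes: tuple[str, ...]
    specific_similarities: np.ndarray
    general_similarities: np.ndarray
    comparison: ScoreComparisonResult


def compare_extremes(
    scores: pd.DataFrame,
    n_top: int,
    graph: OntologyGraph,
    ic: dict[str, float],
) -> ExtremesComparison:
    """Contrast pairwise similarity within the most specific vs most general genes.

    Takes the ``n_top`` lowest-ranked (most specific) and highest-ranked
    (most general) scored genes that carry at least one IC-bearing direct
    annotation, computes all within-group pairwise similarities, and
    compares the two similarity distributions with a two-sided rank-sum
    test.  Apply the study-count filter upstream if study bias is a
    concern.
    """
    if n_top < 3:
        raise ValueError("n_top must be >= 3")
    annotated = [
        g
        for g in scores.sort_values("rank").index
        if any(t in ic for t in graph.annotations.get(g, ()))
    ]
    if len(annotated) < 2 * n_top:
        raise ValueError(
            f"need >= {2 * n_top} annotated scored genes, have {len(annotated)}"
        )
    specific = tuple(annotated[:n_top])
    general = tuple(annotated[-n_top:])
    sim_s = pairwise_similarities(specific, graph, ic)
    sim_g = pairwise_similarities(general, graph, ic)
    cmp = rank_sum_compare(sim_s, sim_g, labels=("specific", "general"))
    return ExtremesComparison(specific, general, sim_s, sim_g, cmp)
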