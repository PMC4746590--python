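"""Expression breadth vs specificity, and expression/pathology agreement.

Two questions about healthy-tissue protein abundance: (1) are broadly
expressed (housekeeping-like) proteins involved in more cancer types?
Answered by correlating per-gene expression breadth (number of tissues
where the protein is detected) with the specificity score.  (2) Do highly
specific cancer genes at least show their strongest expression in the
tissue where they drive cancer?  Answered by matching each single-type
solid-tumor gene's argmax expression tissue against its cancer tissue
(direct) or a tissue adjacent to it, with a one-sided binomial test on the
number of matches.

Detection defaults to abundance strictly greater than the threshold
(threshold 0 = any nonzero signal); a pre-thresholded binary matrix can be
passed instead.  Ties at the expression argmax count as a match if any
argmax tissue qualifies, deliberately biasing toward agreement (i.e.
against the expected no-agreement outcome).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io_formats import TissueMap
from .specificity import correlate

logger = logging.getLogger(__name__)

__all__ = [
    "tissue_breadth",
    "breadth_specificity_correlation",
    "MatchResult",
    "top_tissue_match",
    "binomial_match_test",
]


def tissue_breadth(
    expr: pd.DataFrame, detect_threshold: float = 0.0
) -> pd.Series:
    """Number of tissues with abundance strictly above the threshold."""
    if detect_threshold < 0:
        raise ValueError("detect_threshold must be >= 0")
    return (expr > detect_threshold).sum(axis=1)


def breadth_specificity_correlation(
    breadth: pd.Series,
    scores: pd.DataFrame | pd.Series,
) -> tuple[float, float]:
    """Pearson r (Fisher-z p) between expression breadth and specificity.

    ``scores`` may be the ranked specificity table (its ``score`` column is
    used) or any per-gene series such as raw associated-tissue counts.
    """
    values = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    return correlate(breadth, values)


@dataclass(frozen=True)
class MatchResult:
    per_gene: dict[str, str]  # gene -> 'direct' | 'adjacent' | 'none'
    n_direct: int
    n_adjacent: int
    n_none: int

    @property
    def n_genes(self) -> int:
        return self.n_direct + self.n_adjacent + self.n_none


def top_tissue_match(
    cancer_tissues: Mapping[str, str],
    expr: pd.DataFrame,
    tmap: TissueMap,
) -> MatchResult:
    """Classify each gene's top expression tissue against its cancer tissue.

    ``cancer_tissues`` maps gene -> the tissue of its single associated
    (solid) cancer type.  'direct' if any argmax expression tissue equals
    the cancer tissue, 'adjacent' if any argmax tissue is adjacent to it,
    else 'none'.  Genes absent from the matrix or with cancer tissues not
    among the expression columns are excluded (logged).
    """
    per_gene: dict[str, str] = {}
    for gene, tissue in sorted(cancer_tissues.items()):
        if gene not in expr.index:
            logger.info("gene %s missing from expression matrix; excluded", gene)
            continue
        if tissue not in expr.columns:
            logger.info("tissue %s of gene %s not in expression matrix; excluded",
                        tissue, gene)
            continue
        row = expr.loc[gene]
        top = set(row.index[row == row.max()])
        if tissue in top:
            per_gene[gene] = "direct"
        elif top & tmap.adjacent(tissue):
            per_gene[gene] = "adjacent"
        else:
            per_gene[gene] = "none"
    labels = list(per_gene.values())
    return MatchResult(
        per_gene=per_gene,
        n_direct=labels.count("direct"),
        n_adjacent=labels.count("adjacent"),
        n_none=labels.count("none"),
    )


def binomial_match_test(n_matches: int, n_genes: int, p0: float) -> float:
    """One-sided upper-tail binomial p value: P(X >= n_matches | n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= n_matches <= n_genes:
        raise ValueError("need 0 <= n_matches <= n_genes")
    if n_matches == 0:
        return 1.0
    return float(stats.binom.sf(n_matches - 1, n_genes, p0))


def default_match_probability(
    cancer_tissues: Mapping[str, str], expr: pd.DataFrame, tmap: TissueMap
) -> float:
    """Chance probability of a direct-or-adjacent match under random argmax.

    (1 + # adjacent tissues present in the matrix) / (# expression
    tissues), averaged over genes.
    """
    n_tissues = expr.shape[1]
    probs = []
    for _, tissue in cancer_tissues.items():
        if tissue not in expr.columns:
            continue
        adj = len(tmap.adjacent(tissue) & set(expr.columns))
        probs.append((1 + adj) / n_tissues)
    if not probs:
        raise ValueError("no gene with a mappable cancer tissue")
    return float(sum(probs) / len(probs))
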