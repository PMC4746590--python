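"""Cancer-gene specificity scoring and score-distribution comparisons.

The specificity score S of a gene combines three quantities from a
pan-cancer mutation-significance analysis: ``mostQ`` (its smallest single
tumor-type q value), ``panQ`` (its q value in the pooled pan-cancer cohort)
and ``k`` (the number of tumor types in which it is significantly mutated,
i.e. q below a threshold tau).  A gene highly significant in one type but
unremarkable pan-cancer is tissue-specific; a gene significant pan-cancer
and in many types is general.  The default functional form is

    S = log10((mostQ + eps) / (panQ + eps)) + k

with eps = 1e-16 guarding exact zeros (supplementary significance tables do
contain q = 0).  Small S = specific, large S = general.  S is strictly
increasing in mostQ and k and strictly decreasing in panQ.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MutationSignificanceTable

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TAU",
    "DEFAULT_EPSILON",
    "ScoreComparisonResult",
    "compute_specificity",
    "rank_genes",
    "filter_by_study_count",
    "rank_sum_compare",
    "compare_score_groups",
    "correlate",
]

DEFAULT_TAU = 0.1
DEFAULT_EPSILON = 1e-16

#: columns of the ranked specificity table
SPECIFICITY_COLUMNS = ["mostQ", "panQ", "k", "score", "rank"]


def compute_specificity(
    most_q: float,
    pan_q: float,
    k: int,
    *,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Specificity score for one gene: log10 q-ratio plus breadth count."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if k == 0:
        logger.warning("k=0 for a gene entering the score; kept")
    return math.log10((most_q + epsilon) / (pan_q + epsilon)) + k


def rank_genes(
    table: MutationSignificanceTable,
    *,
    tau: float = DEFAULT_TAU,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Score and rank all genes; rank 1 = most tissue-specific.

    Ties in the score are broken by panQ descending (the more
    pan-significant, hence more general, gene ranks last) and then by
    gene id, so ranks are a deterministic permutation of 1..n regardless of
    input row order.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if len(table.genes) < 2:
        raise ValueError("need at least two genes to rank")
    most_q = table.most_q()
    k = table.n_significant(tau)
    score = np.log10((most_q + epsilon) / (table.pan_q + epsilon)) + k
    out = pd.DataFrame(
        {"mostQ": most_q, "panQ": table.pan_q, "k": k, "score": score}
    )
    out = _sorted_with_ties(out)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _sorted_with_ties(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["_gene"] = frame.index
    frame = frame.sort_values(
        by=["score", "panQ", "_gene"], ascending=[True, False, True]
    )
    return frame.drop(columns="_gene")


def filter_by_study_count(
    scores: pd.DataFrame,
    counts: Mapping[str, int] | pd.Series,
    max_studies: int = 500,
) -> pd.DataFrame:
    """Drop highly studied genes and recompute ranks on the survivors.

    Genes absent from ``counts`` count as never studied (0).  The study-bias
    control: aggregated annotation sources over-cover famous genes, so
    analyses sensitive to annotation depth are repeated on the subset
    studied at most ``max_studies`` times.
    """
    if max_studies < 0:
        raise ValueError("max_studies must be >= 0")
    counts = pd.Series(dict(counts)) if not isinstance(counts, pd.Series) else counts
    n = pd.to_numeric(counts.reindex(scores.index), errors="coerce").fillna(0)
    kept = scores[n <= max_studies].copy()
    if len(kept) < 2:
        raise ValueError("study-count filter left fewer than 2 genes")
    kept = _sorted_with_ties(kept.drop(columns="rank"))
    kept["rank"] = np.arange(1, len(kept) + 1)
    return kept


@dataclass(frozen=True)
class ScoreComparisonResult:
    """Two-group rank-sum comparison outcome."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float
    method: str  # 'exact' | 'asymptotic'


def rank_sum_compare(
    a: Iterable[float],
    b: Iterable[float],
    labels: tuple[str, str] = ("A", "B"),
) -> ScoreComparisonResult:
    """Two-sided Wilcoxon-Mann-Whitney test on two value samples.

    Exact when the smaller sample has <= 8 values: the classical exact
    null distribution without ties, full enumeration of group assignments
    (which remains valid under ties) when that is feasible.  Normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ScoreComparisonResult(
            labels[0], labels[1], len(a), len(b),
            statistic=len(a) * len(b) / 2.0, pvalue=1.0, method="degenerate",
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(len(a), len(b)) <= 8
    if small and not has_ties:
        method_arg: object = "exact"
        method = "exact"
    elif small and math.comb(len(pooled), len(a)) <= 100_000:
        # exact enumeration of all group assignments, valid under ties
        method_arg = stats.PermutationMethod(n_resamples=100_001)
        method = "exact"
    else:
        method_arg = "asymptotic"
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method_arg)
    return ScoreComparisonResult(
        labels[0], labels[1], len(a), len(b),
        statistic=float(res.statistic), pvalue=float(min(res.pvalue, 1.0)),
        method=method,
    )


def compare_score_groups(
    scores: pd.DataFrame | Mapping[str, float],
    group_a: Iterable[str],
    group_b: Iterable[str],
    labels: tuple[str, str] = ("A", "B"),
    allow_overlap: bool = False,
) -> ScoreComparisonResult:
    """Rank-sum comparison of specificity scores between two gene groups.

    Groups are intersected with the scored genes first; an overlap after
    intersection is an error unless ``allow_overlap`` (then shared genes
    contribute to both samples, logged).
    """
    if isinstance(scores, pd.DataFrame):
        score_of = scores["score"]
    else:
        score_of = pd.Series(dict(scores))
    set_a = set(group_a) & set(score_of.index)
    set_b = set(group_b) & set(score_of.index)
    shared = set_a & set_b
    if shared:
        if not allow_overlap:
            raise ValueError(f"groups overlap after scoring: {sorted(shared)}")
        logger.info("groups share %d genes; included in both", len(shared))
    return rank_sum_compare(
        score_of[sorted(set_a)], score_of[sorted(set_b)], labels
    )


def correlate(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
) -> tuple[float, float]:
    """Pearson r over the gene intersection, p via the Fisher z-transform.

    z = atanh(r) * sqrt(n - 3); two-sided normal tail.  Requires n >= 4 and
    non-degenerate variance in both vectors.
    """
    xs = pd.Series(dict(x)) if not isinstance(x, pd.Series) else x
    ys = pd.Series(dict(y)) if not isinstance(y, pd.Series) else y
    common = xs.index.intersection(ys.index)
    if len(common) < 4:
        raise ValueError("need >= 4 paired observations")
    xv = xs[common].to_numpy(dtype=float)
    yv = ys[common].to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(xv, yv)[0, 1])
    n = len(common)
    if abs(r) >= 1.0:
        return (r, 0.0)
    z = math.atanh(r) * math.sqrt(n - 3)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return (r, min(p, 1.0))
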