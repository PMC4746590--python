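"""DNA-repair pathway x tissue analyses and hallmark-class contrasts.

Cancer genes fall into three broad hallmark classes — oncogenes, tumor
suppressors and DNA-repair (stability) genes — and the repair genes further
into pathway classes: nucleotide-excision repair (NER), mismatch repair
(MM) and double-strand break repair (DSBR).  These three pathways respond
to different damage sources (UV crosslinks, replication mismatches,
double-strand breaks), so their cancer-gene members are expected to
distribute unevenly across tissues.  This module assigns pathway classes
from propagated ontology annotations (genes hitting more than one class
are 'multiple' and excluded from counts), tabulates uniquely assigned
genes per tissue, and provides the association tests around that table:
per-cell Fisher exact tests, the germline fold enrichment, the
germline-vs-somatic tissue-breadth comparison, and a PCA of tissues in
pathway space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OntologyGraph
from .specificity import ScoreComparisonResult, compare_score_groups, rank_sum_compare

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_REPAIR_TERMS",
    "assign_repair_pathways",
    "pathway_tissue_counts",
    "hallmark_specificity",
    "FisherResult",
    "pathway_tissue_fisher",
    "germline_fold_enrichment",
    "breadth_comparison",
    "PCAResult",
    "pca_tissues",
]

#: ontology classes defining the three DNA-repair pathways
DEFAULT_REPAIR_TERMS = {
    "NER": "GO:0006289",   # nucleotide-excision repair
    "MM": "GO:0006298",    # mismatch repair
    "DSBR": "GO:0006302",  # double-strand break repair
}

PATHWAYS = ("NER", "MM", "DSBR")


def assign_repair_pathways(
    catalog: pd.DataFrame,
    graph: OntologyGraph,
    terms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fill the catalog's ``repair_pathway`` column from ontology annotations.

    A gene annotated (with propagation) to exactly one of the three pathway
    classes gets that class; to more than one, 'multiple'; otherwise 'none'.
    Only unique assignments enter downstream counts.
    """
    terms = dict(terms or DEFAULT_REPAIR_TERMS)
    missing = [t for t in terms.values() if t not in graph.graph.nodes]
    if missing:
        raise ValueError(f"pathway class terms missing from ontology: {missing}")
    propagated = graph.propagated()
    out = catalog.copy()
    assigned = []
    for gene in out.index:
        hits = [name for name, term in terms.items() if term in propagated.get(gene, ())]
        if len(hits) == 1:
            assigned.append(hits[0])
        elif len(hits) > 1:
            assigned.append("multiple")
        else:
            assigned.append("none")
    out["repair_pathway"] = assigned
    n_multi = sum(a == "multiple" for a in assigned)
    if n_multi:
        logger.info("%d repair genes annotated to multiple classes; excluded "
                    "from pathway counts", n_multi)
    return out


def pathway_tissue_counts(catalog: pd.DataFrame) -> pd.DataFrame:
    """Tissue x pathway gene counts over uniquely assigned repair genes.

    A gene contributes one count to each of its associated tissues; genes
    with empty tissue sets are excluded (logged).
    """
    rows: dict[str, dict[str, int]] = {}
    n_untissued = 0
    for gene, row in catalog.iterrows():
        pathway = row["repair_pathway"]
        if pathway not in PATHWAYS:
            continue
        if not row["tissues"]:
            n_untissued += 1
            continue
        for tissue in row["tissues"]:
            rows.setdefault(tissue, {p: 0 for p in PATHWAYS})[pathway] += 1
    if n_untissued:
        logger.warning("%d uniquely assigned repair genes lack tissues", n_untissued)
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    counts = counts.reindex(columns=list(PATHWAYS), fill_value=0)
    return counts.sort_index()


def hallmark_specificity(
    scores: pd.DataFrame, catalog: pd.DataFrame
) -> dict[tuple[str, str], ScoreComparisonResult]:
    """Pairwise specificity contrasts among the three hallmark classes.

    Genes belonging to two classes are included in both samples (logged by
    the underlying comparison).
    """
    classes = ("oncogene", "tumor_suppressor", "dna_repair")
    members = {
        c: set(catalog.index[catalog["hallmark"] == c]) for c in classes
    }
    for c, genes in members.items():
        if len(genes & set(scores.index)) < 2:
            raise ValueError(f"hallmark class {c!r} has fewer than 2 scored genes")
    results = {}
    for c1, c2 in combinations(classes, 2):
        results[(c1, c2)] = compare_score_groups(
            scores, members[c1], members[c2], labels=(c1, c2), allow_overlap=True
        )
    return results


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float


def pathway_tissue_fisher(
    counts: pd.DataFrame, pathway: str, tissue: str
) -> FisherResult:
    """Fisher exact test: is ``pathway`` over-represented in ``tissue``?

    2x2 table over uniquely assigned repair genes: [pathway & tissue,
    pathway & other tissues; other pathways & tissue, other pathways &
    other tissues].  Two-sided p by the point-probability method.  An empty
    margin yields p = 1 (logged).
    """
    if counts.to_numpy().sum() < 1:
        raise ValueError("empty pathway x tissue count table")
    a = int(counts.loc[tissue, pathway])
    b = int(counts[pathway].sum() - a)
    c = int(counts.loc[tissue].sum() - a)
    d = int(counts.to_numpy().sum() - a - b - c)
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.info("empty margin in Fisher table for %s x %s", pathway, tissue)
        return FisherResult(table, float("nan"), 1.0)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return FisherResult(table, float(odds), float(p))


def germline_fold_enrichment(
    n_pathway_germline: int, n_germline: int, n_pathway: int, n_total: int
) -> float:
    """Fold enrichment of repair-pathway membership among germline genes.

    (n_pathway_germline / n_germline) / (n_pathway / n_total), reported to
    one decimal.
    """
    for name, v in (
        ("n_pathway_germline", n_pathway_germline),
        ("n_germline", n_germline),
        ("n_pathway", n_pathway),
        ("n_total", n_total),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if n_pathway_germline > min(n_germline, n_pathway):
        raise ValueError("n_pathway_germline exceeds a margin")
    fold = (n_pathway_germline / n_germline) / (n_pathway / n_total)
    return round(fold, 1)


def breadth_comparison(catalog: pd.DataFrame) -> ScoreComparisonResult:
    """Rank-sum comparison of per-gene tissue counts: germline vs somatic.

    Genes with mutation origin 'both' are excluded so curation-strategy
    differences between sources do not leak in.
    """
    germ = catalog[catalog["mutation_origin"] == "germline"]
    soma = catalog[catalog["mutation_origin"] == "somatic"]
    if len(germ) < 2 or len(soma) < 2:
        raise ValueError("each origin class needs >= 2 genes")
    breadth_g = [len(t) for t in germ["tissues"]]
    breadth_s = [len(t) for t in soma["tissues"]]
    return rank_sum_compare(breadth_g, breadth_s, labels=("germline", "somatic"))


@dataclass(frozen=True)
class PCAResult:
    coordinates: pd.DataFrame      # tissues x components
    loadings: pd.DataFrame         # components x pathways
    variance_fractions: np.ndarray


def pca_tissues(counts: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of tissues in DNA-repair pathway space (column-centered SVD).

    Components are ordered by explained variance; each loading vector's
    sign is fixed so its largest-magnitude entry is positive, making the
    projection reproducible across platforms.
    """
    if len(counts) < 3:
        raise ValueError("need >= 3 tissues for a tissue PCA")
    x = counts.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("count matrix has zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    var = s**2
    fractions = var / var.sum()
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        u[:, :k] * s[:k],
        index=counts.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        vt[:k],
        index=[f"PC{i + 1}" for i in range(k)],
        columns=counts.columns,
    )
    return PCAResult(coords, loadings, fractions)
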