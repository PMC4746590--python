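"""Enrichment of environmental interactors among tissue-specific cancer genes.

Two bipartite networks feed this module: chemical-gene associations
(toxicogenomics-style, with evidence counts and source-study sizes) and
virus-host protein-protein interactions (strain-level partners grouped
into species).  Bias-control filters come first: single-evidence edges and
approved cancer drugs are removed from the chemical network, and edges can
be restricted to large source studies (>= 30 chemical-gene interactions,
>= 500 host-virus PPIs) to guard against literature bias toward famous
cancer genes.

The chemical test asks, per (cancer type, chemical), whether the type's
specific genes (significant in exactly that one type) interact with the
chemical more often than the remaining specific-cancer genes do: Pearson
chi-square on the 2x2 table without continuity correction, with a Fisher
exact fallback (flagged) whenever an expected count drops below 5, and BH
correction across all pairs tested.  A row is "reportable" when q < alpha
AND the chemical covers at least 20% of the type's specific genes.

The virus analyses count distinct strains per gene (tropism breadth) and
profile each virus species' cancer-gene interactors across tissue groups.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BipartiteNetwork, MutationSignificanceTable, TissueMap
from .gsea import bh_adjust
from .specificity import DEFAULT_TAU, ScoreComparisonResult, rank_sum_compare

logger = logging.getLogger(__name__)

__all__ = [
    "filter_network",
    "specific_gene_sets",
    "chemical_enrichment",
    "pollutant_fraction",
    "strain_counts",
    "virus_strain_specificity",
    "virus_tissue_profile",
]

#: display rule from the published association table
DEFAULT_ALPHA = 0.01
DEFAULT_MIN_COVERAGE = 0.20
DEFAULT_MIN_GENES = 8


def filter_network(
    net: BipartiteNetwork,
    min_evidence: int = 1,
    exclude_drugs: bool = False,
    min_study_size: int = 0,
) -> BipartiteNetwork:
    """Apply the bias-control filters; order of application is irrelevant."""
    if min_evidence < 0 or min_study_size < 0:
        raise ValueError("filter thresholds must be >= 0")
    edges = net.edges
    kept = edges[
        (edges["evidence_count"] >= min_evidence)
        & (edges["study_size"] >= min_study_size)
    ]
    if exclude_drugs:
        drugs = set(net.partners.index[net.partners["is_drug"].astype(bool)])
        kept = kept[~kept["partner"].isin(drugs)]
    if kept.empty:
        raise ValueError(
            "no edges survive filters "
            f"(min_evidence={min_evidence}, exclude_drugs={exclude_drugs}, "
            f"min_study_size={min_study_size})"
        )
    return BipartiteNetwork(edges=kept.reset_index(drop=True), partners=net.partners)


def specific_gene_sets(
    table: MutationSignificanceTable,
    tissue_map: TissueMap,
    tau: float = DEFAULT_TAU,
    min_genes: int = DEFAULT_MIN_GENES,
    solid_only: bool = True,
) -> dict[str, frozenset[str]]:
    """Group genes significant in exactly one tumor type by that type.

    Types with fewer than ``min_genes`` such genes are dropped, as are
    non-solid types when ``solid_only``.
    """
    sig = table.significant_types(tau)
    by_type: dict[str, set[str]] = {}
    for gene, types in sig.items():
        if len(types) == 1:
            by_type.setdefault(next(iter(types)), set()).add(gene)
    out = {}
    for ctype, genes in sorted(by_type.items()):
        if solid_only and not tissue_map.is_solid(ctype):
            continue
        if len(genes) < min_genes:
            continue
        out[ctype] = frozenset(genes)
    if not out:
        raise ValueError("no cancer type retains enough specific genes")
    return out


def _chi2_or_fisher(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Pearson chi-square without continuity correction; Fisher fallback
    (flagged) when any expected count is below 5."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return (float("nan"), float(p), True)
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return (float(chi2), p, False)


def chemical_enrichment(
    sets: Mapping[str, frozenset[str]],
    net: BipartiteNetwork,
    alpha: float = DEFAULT_ALPHA,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per (cancer type, chemical) over-representation of interactions.

    The background universe is the union of all investigated types'
    specific genes.  Chemicals interacting with zero background genes are
    skipped (logged).  Returns all tested rows (not just reportable ones),
    sorted by (cancer_type, q, chemical).
    """
    background: set[str] = set().union(*sets.values())
    chem_edges = net.edges[net.edges["partner_kind"] == "chemical"]
    interactors = {
        chem: set(grp["gene"]) & background
        for chem, grp in chem_edges.groupby("partner")
    }
    rows = []
    for ctype, genes in sorted(sets.items()):
        genes = set(genes)
        rest = background - genes
        for chem in sorted(interactors):
            hits = interactors[chem]
            if not hits:
                logger.info("chemical %s hits no background gene; skipped", chem)
                continue
            a = len(hits & genes)
            b = len(genes) - a
            c = len(hits & rest)
            d = len(rest) - c
            chi2, p, fallback = _chi2_or_fisher(a, b, c, d)
            rows.append(
                {
                    "cancer_type": ctype,
                    "chemical": chem,
                    "n_interacting": a,
                    "coverage": a / len(genes),
                    "chi2": chi2,
                    "pvalue": p,
                    "fisher_fallback": fallback,
                }
            )
    if not rows:
        raise ValueError("no (type, chemical) pair could be tested")
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_adjust(out["pvalue"].clip(lower=np.nextafter(0, 1)))
    out["reportable"] = (out["qvalue"] < alpha) & (out["coverage"] >= min_coverage)
    return out.sort_values(["cancer_type", "qvalue", "chemical"]).reset_index(
        drop=True
    )


def pollutant_fraction(
    reportable_chemicals: Iterable[str],
    pollutant_flags: Mapping[str, bool],
    background_chemicals: Iterable[str],
) -> tuple[float, float]:
    """Fraction of air pollutants among a type's reportable chemicals.

    Fisher exact test against the background chemical universe (reportable
    chemicals vs the rest of the background).
    """
    reportable = sorted(set(reportable_chemicals))
    if not reportable:
        raise ValueError("no reportable chemicals")
    background = set(background_chemicals)
    if not background:
        raise ValueError("empty background chemical universe")
    rest = background - set(reportable)
    flagged = sum(bool(pollutant_flags.get(c, False)) for c in reportable)
    flagged_rest = sum(bool(pollutant_flags.get(c, False)) for c in rest)
    fraction = flagged / len(reportable)
    _, p = stats.fisher_exact(
        [[flagged, len(reportable) - flagged],
         [flagged_rest, len(rest) - flagged_rest]],
        alternative="two-sided",
    )
    return (fraction, float(p))


def strain_counts(net: BipartiteNetwork) -> pd.Series:
    """Distinct virus strains interacting with each gene (dedup by partner)."""
    virus = net.edges[net.edges["partner_kind"] == "virus_strain"]
    return virus.groupby("gene")["partner"].nunique()


def virus_strain_specificity(
    net: BipartiteNetwork, catalog: pd.DataFrame
) -> dict[str, ScoreComparisonResult]:
    """Tumor-type breadth of multi-strain vs at-most-one-strain interactors.

    Genes are partitioned by distinct-strain count (strains, not species):
    {<= 1} vs {> 1}, compared on per-gene tissue counts from the catalog.
    Also reports the control contrast of no-interaction vs exactly-one-
    strain genes.  Catalog genes without tissues are excluded.
    """
    counts = strain_counts(net)
    tissued = catalog[[len(t) > 0 for t in catalog["tissues"]]]
    breadth = pd.Series(
        {g: len(t) for g, t in tissued["tissues"].items()}, dtype=float
    )
    n_strains = counts.reindex(breadth.index).fillna(0).astype(int)
    few = breadth[n_strains <= 1]
    many = breadth[n_strains > 1]
    none = breadth[n_strains == 0]
    one = breadth[n_strains == 1]
    if len(few) < 2 or len(many) < 2:
        raise ValueError("a strain-count partition is (nearly) empty")
    out = {
        "le1_vs_gt1": rank_sum_compare(few, many, labels="le1 gt1".split()),
    }
    if len(none) >= 2 and len(one) >= 2:
        out["none_vs_one"] = rank_sum_compare(none, one, labels="none one".split())
    else:
        logger.warning("no-interaction vs one-strain control not computable")
    return out


def virus_tissue_profile(
    net: BipartiteNetwork,
    catalog: pd.DataFrame,
    viruses: Iterable[str],
    tissue_groups: TissueMap,
) -> pd.DataFrame:
    """Fraction of each virus species' interactors per tissue group.

    entry(v, t) = (# cancer-gene interactors of species v with tissue group
    t) / (# interactors of v with >= 1 tissue).  Multi-tissue genes count
    in each of their groups, so rows need not sum to 1.  Species with zero
    tissue-bearing interactors are dropped with a warning.
    """
    virus_edges = net.edges[net.edges["partner_kind"] == "virus_strain"]
    species_of = {
        p: net.species_of(p) for p in virus_edges["partner"].unique()
    }
    tissued = {
        g: {tissue_groups.group(t) for t in tset}
        for g, tset in catalog["tissues"].items()
        if tset
    }
    rows: dict[str, dict[str, float]] = {}
    for species in viruses:
        strains = {p for p, s in species_of.items() if s == species}
        genes = set(virus_edges[virus_edges["partner"].isin(strains)]["gene"])
        genes &= set(tissued)
        if not genes:
            logger.warning("virus %s has no tissue-annotated interactor; dropped",
                           species)
            continue
        counts: dict[str, int] = {}
        for g in genes:
            for grp in tissued[g]:
                counts[grp] = counts.get(grp, 0) + 1
        rows[species] = {grp: c / len(genes) for grp, c in counts.items()}
    if not rows:
        raise ValueError("no virus retained any interactor")
    profile = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return profile.sort_index().sort_index(axis=1)
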