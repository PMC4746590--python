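"""End-to-end pipeline: score -> gsea -> semsim -> repair -> chem -> virus -> expr.

Stages communicate only via files so each is independently re-runnable.
A YAML config names every input path and parameter; a fail-fast validation
pass checks all inputs before any stage runs.  The run writes one TSV per
stage plus ``manifest.json`` recording input hashes, parameters, seed and
package version — the manifest alone suffices to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import (
    expression_agreement,
    gsea,
    interaction_enrich,
    io_formats,
    repair_tissue,
    semsim,
    specificity,
)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_all", "DEFAULT_PARAMS"]

DEFAULT_PARAMS = {
    "tau": specificity.DEFAULT_TAU,
    "epsilon": specificity.DEFAULT_EPSILON,
    "max_studies": 500,
    "min_size": gsea.DEFAULT_MIN_SIZE,
    "n_perm": gsea.DEFAULT_N_PERM,
    "seed": 0,
    "n_top": 30,
    "min_evidence": 2,
    "chem_min_study_size": 0,
    "virus_min_study_size": 0,
    "alpha": interaction_enrich.DEFAULT_ALPHA,
    "min_genes": interaction_enrich.DEFAULT_MIN_GENES,
    "viruses": [],
    "detect_threshold": 0.0,
}

REQUIRED_INPUTS = [
    "mutation_table",
    "study_counts",
    "obo",
    "annotations",
    "gene_sets",
    "census",
    "hallmarks",
    "chem_edges",
    "chem_attributes",
    "virus_edges",
    "virus_attributes",
    "expression",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError("config must be a mapping with an 'inputs' section")
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_all(config: dict | str | Path, outdir) -> Path:
    """Run every stage on the configured inputs; returns the report dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    inputs = {k: Path(v) for k, v in config["inputs"].items()}
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    missing = [k for k in REQUIRED_INPUTS if k not in inputs]
    absent = [str(p) for k, p in inputs.items() if not p.exists()]
    if missing:
        raise ValueError(f"config missing inputs: {missing}")
    if absent:
        raise FileNotFoundError(f"input files not found: {absent}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tissue_map = io_formats.TissueMap.default()
    groups = io_formats.TissueMap.default_system_groups()

    # --- score
    table = io_formats.read_mutation_table(inputs["mutation_table"])
    counts = io_formats.read_study_counts(inputs["study_counts"])
    scores = specificity.rank_genes(
        table, tau=params["tau"], epsilon=params["epsilon"]
    )
    _write(scores.rename_axis("gene").reset_index(), outdir / "scores.tsv")
    filtered = specificity.filter_by_study_count(
        scores, counts, max_studies=params["max_studies"]
    )
    _write(
        filtered.rename_axis("gene").reset_index(), outdir / "scores_filtered.tsv"
    )
    logger.info("score: %d genes, %d after study filter", len(scores), len(filtered))

    # --- gsea
    sets = io_formats.read_gmt(inputs["gene_sets"])
    enrichment = gsea.run_gsea(
        scores,
        sets,
        min_size=params["min_size"],
        n_perm=params["n_perm"],
        seed=params["seed"],
    )
    _write(enrichment, outdir / "gsea.tsv")

    # --- semsim
    graph = io_formats.read_obo_lite(inputs["obo"], inputs["annotations"])
    ic = semsim.term_ic(graph)
    extremes = semsim.compare_extremes(filtered, params["n_top"], graph, ic)
    summary = pd.DataFrame(
        [
            {
                "group": "specific",
                "n_genes": len(extremes.specific_genes),
                "n_pairs": len(extremes.specific_similarities),
                "median_similarity": float(
                    pd.Series(extremes.specific_similarities).median()
                ),
            },
            {
                "group": "general",
                "n_genes": len(extremes.general_genes),
                "n_pairs": len(extremes.general_similarities),
                "median_similarity": float(
                    pd.Series(extremes.general_similarities).median()
                ),
            },
            {
                "group": "rank_sum_p",
                "n_genes": extremes.comparison.n_a + extremes.comparison.n_b,
                "n_pairs": 0,
                "median_similarity": extremes.comparison.pvalue,
            },
        ]
    )
    _write(summary, outdir / "semsim.tsv")

    # --- repair
    census = pd.read_csv(inputs["census"], sep="\t")
    hallmarks = pd.read_csv(inputs["hallmarks"], sep="\t")
    catalog = io_formats.build_ext_catalog(
        core_genes=scores.index,
        census_tables=[census],
        tissue_map=tissue_map,
        hallmarks=dict(zip(hallmarks["gene"], hallmarks["hallmark"])),
    )
    catalog = repair_tissue.assign_repair_pathways(catalog, graph)
    pcounts = repair_tissue.pathway_tissue_counts(catalog)
    _write(pcounts.rename_axis("tissue").reset_index(), outdir / "repair_counts.tsv")
    fisher_rows = []
    for tissue in pcounts.index:
        for pathway in pcounts.columns:
            res = repair_tissue.pathway_tissue_fisher(pcounts, pathway, tissue)
            fisher_rows.append(
                {
                    "tissue": tissue,
                    "pathway": pathway,
                    "odds_ratio": res.odds_ratio,
                    "pvalue": res.pvalue,
                }
            )
    _write(pd.DataFrame(fisher_rows), outdir / "repair_fisher.tsv")
    pca = repair_tissue.pca_tissues(pcounts)
    _write(
        pca.coordinates.rename_axis("tissue").reset_index(), outdir / "repair_pca.tsv"
    )
    breadth = repair_tissue.breadth_comparison(catalog)
    hallmark_cmp = repair_tissue.hallmark_specificity(scores, catalog)
    repair_summary = pd.DataFrame(
        [
            {
                "comparison": "germline_vs_somatic_breadth",
                "n_a": breadth.n_a,
                "n_b": breadth.n_b,
                "pvalue": breadth.pvalue,
            }
        ]
        + [
            {
                "comparison": f"{a}_vs_{b}_score",
                "n_a": r.n_a,
                "n_b": r.n_b,
                "pvalue": r.pvalue,
            }
            for (a, b), r in hallmark_cmp.items()
        ]
    )
    _write(repair_summary, outdir / "repair_summary.tsv")

    # --- chem
    chem_net = io_formats.read_network(
        inputs["chem_edges"], "chemical", inputs["chem_attributes"]
    )
    chem_net = interaction_enrich.filter_network(
        chem_net,
        min_evidence=params["min_evidence"],
        exclude_drugs=True,
        min_study_size=params["chem_min_study_size"],
    )
    sets_by_type = interaction_enrich.specific_gene_sets(
        table, tissue_map, tau=params["tau"], min_genes=params["min_genes"]
    )
    chem_rows = interaction_enrich.chemical_enrichment(
        sets_by_type, chem_net, alpha=params["alpha"]
    )
    _write(chem_rows, outdir / "chem.tsv")
    pollutant_flags = dict(
        chem_net.partners["is_air_pollutant"].astype(bool).items()
    )
    background = sorted(
        set(chem_rows["chemical"])
    )
    poll_rows = []
    for ctype, grp in chem_rows[chem_rows["reportable"]].groupby("cancer_type"):
        frac, p = interaction_enrich.pollutant_fraction(
            grp["chemical"], pollutant_flags, background
        )
        poll_rows.append(
            {"cancer_type": ctype, "pollutant_fraction": frac, "fisher_p": p}
        )
    _write(
        pd.DataFrame(poll_rows, columns=["cancer_type", "pollutant_fraction",
                                         "fisher_p"]),
        outdir / "chem_pollutants.tsv",
    )

    # --- virus
    virus_net = io_formats.read_network(
        inputs["virus_edges"], "virus_strain", inputs["virus_attributes"]
    )
    if params["virus_min_study_size"]:
        virus_net = interaction_enrich.filter_network(
            virus_net, min_study_size=params["virus_min_study_size"]
        )
    viruses = params["viruses"] or sorted(
        set(virus_net.partners["virus_species"]) - {""}
    )
    profile = interaction_enrich.virus_tissue_profile(
        virus_net, catalog, viruses, groups
    )
    _write(profile.rename_axis("virus").reset_index(), outdir / "virus_profile.tsv")
    tropism = interaction_enrich.virus_strain_specificity(virus_net, catalog)
    _write(
        pd.DataFrame(
            [
                {"comparison": name, "n_a": r.n_a, "n_b": r.n_b, "pvalue": r.pvalue}
                for name, r in tropism.items()
            ]
        ),
        outdir / "virus_summary.tsv",
    )

    # --- expr
    expr = io_formats.read_expression(inputs["expression"])
    breadth_counts = expression_agreement.tissue_breadth(
        expr, params["detect_threshold"]
    )
    r_score, p_score = expression_agreement.breadth_specificity_correlation(
        breadth_counts, scores
    )
    sig = table.significant_types(params["tau"])
    cancer_tissues = {
        g: tissue_map.tissue_of(next(iter(t)))
        for g, t in sig.items()
        if len(t) == 1 and tissue_map.is_solid(next(iter(t)))
    }
    match = expression_agreement.top_tissue_match(cancer_tissues, expr, tissue_map)
    p0 = expression_agreement.default_match_probability(
        cancer_tissues, expr, tissue_map
    )
    p_binom = expression_agreement.binomial_match_test(
        match.n_direct + match.n_adjacent, match.n_genes, p0
    )
    _write(
        pd.DataFrame(
            [
                {
                    "breadth_score_r": r_score,
                    "breadth_score_p": p_score,
                    "n_matched_genes": match.n_genes,
                    "n_direct": match.n_direct,
                    "n_adjacent": match.n_adjacent,
                    "binomial_p": p_binom,
                }
            ]
        ),
        outdir / "expr_summary.tsv",
    )

    manifest = {
        "package": "canspec 0.1.0",
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in
                   inputs.items()},
        "params": params,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return outdir
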