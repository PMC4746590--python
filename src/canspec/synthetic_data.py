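"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes —
planted tissue-specific and general genes in the mutation-significance
table, an ontology with a functional module shared by the general genes,
chemical and virus networks with planted tissue-directed enrichments, and
an expression matrix with planted expression/pathology matches — so the
entire pipeline is testable offline, with known ground truth.

Defaults mirror the study conditions: 224 genes across 21 tumor types;
58% of genes significant in exactly one type (about 130 of them in solid
types, as in the scored cohort), dealt across seven solid and four
hematological tumor types; planted chemical coverage 0.5 against a 3%
background interaction rate; and a study-count table in which 37 genes
exceed the 500-study threshold.

One top-level seed drives independent per-generator substreams (derived
from fixed stream tags), so adding a generator never perturbs the outputs
of the others, and the same seed is always bitwise-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import (
    BipartiteNetwork,
    MutationSignificanceTable,
    OntologyGraph,
    TissueMap,
)

__all__ = [
    "PlantedChemical",
    "PlantedVirus",
    "SyntheticSpec",
    "synthetic_tissue_map",
    "gen_truth",
    "gen_mutation_table",
    "gen_study_counts",
    "gen_ontology",
    "gen_catalog",
    "gen_chemical_network",
    "gen_virus_network",
    "gen_expression",
    "gen_bundle",
]

# stream tags: one fixed integer per generator substream
_STREAMS = {
    "truth": 1,
    "mutation": 2,
    "studies": 3,
    "ontology": 4,
    "catalog": 5,
    "chemical": 6,
    "virus": 7,
    "expression": 8,
}

# tumor types ordered so the types receiving planted specific genes come
# first: seven specific-gene-rich solid types, then the hematological ones
_TYPE_ORDER = [
    "LUAD", "BRCA", "CRC", "BLCA", "UCEC", "KIRC", "MEL",
    "LAML", "DLBCL", "CLL", "MM",
    "GBM", "HNSC", "LUSC", "OV", "PRAD", "THCA", "ESO", "MED",
    "NB", "RHAB",
]


@dataclass(frozen=True)
class PlantedChemical:
    chemical: str
    target_type: str
    coverage: float = 0.5
    is_air_pollutant: bool = False
    is_drug: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("planted coverage must lie in (0, 1]")


@dataclass(frozen=True)
class PlantedVirus:
    species: str
    n_strains: int = 2
    preferred_group: str | None = None
    #: probability that a sampled host partner comes from the preferred
    #: tissue group's gene pool (the rest are drawn from all genes)
    affinity: float = 0.85


@dataclass
class SyntheticSpec:
    """All knobs of the synthetic benchmark, with study-scale defaults."""

    seed: int = 0
    n_genes: int = 224
    n_tumor_types: int = 21
    # 130 of the 224 scored genes are significant in exactly one solid
    # tumor type; 0.58 reproduces that count at the default cohort size
    frac_specific: float = 0.58
    frac_general: float = 0.20
    n_specific_types: int = 11
    # q-value models (log-uniform ranges where the scale spans decades)
    specific_most_q: tuple[float, float] = (1e-12, 1e-8)
    specific_pan_q: tuple[float, float] = (0.1, 1.0)
    general_pan_q: tuple[float, float] = (1e-12, 1e-8)
    general_sig_q: tuple[float, float] = (1e-12, 0.05)
    general_k_min: int = 8
    background_q: tuple[float, float] = (0.1, 1.0)
    # study counts
    n_high_study: int = 37
    high_study_range: tuple[int, int] = (501, 3000)
    low_study_range: tuple[int, int] = (0, 400)
    # ontology shape
    ontology_depth: int = 4
    ontology_branching: int = 3
    n_annotations_per_gene: int = 3
    general_module_affinity: float = 0.8
    # repair-gene structure (38 repair genes, 11 multi-annotated -> 27 unique)
    n_repair_genes: int = 38
    n_repair_multi: int = 11
    n_oncogenes: int = 25
    n_tumor_suppressors: int = 18
    # chemical network
    planted_chemicals: tuple[PlantedChemical, ...] = (
        PlantedChemical("chem_planted_lung", "LUAD", 0.5, is_air_pollutant=True),
        PlantedChemical("chem_planted_breast", "BRCA", 0.5),
        PlantedChemical("chem_planted_colon", "CRC", 0.5),
    )
    n_background_chemicals: int = 30
    chemical_background_rate: float = 0.03
    background_pollutant_rate: float = 0.03
    frac_single_evidence: float = 0.5
    n_drug_chemicals: int = 2
    # virus network
    planted_viruses: tuple[PlantedVirus, ...] = (
        PlantedVirus("EBV_like", 4, "hematopoietic"),
        PlantedVirus("HPV_like", 3, "urogenital"),
        PlantedVirus("HIV_like", 2, None),
    )  # strongly tropic species plus one diffuse control
    virus_partners_per_strain: int = 30
    # expression
    n_expression_tissues: int = 60
    planted_direct_matches: int = 1
    planted_adjacent_matches: int = 3

    def __post_init__(self) -> None:
        if self.frac_specific + self.frac_general > 1:
            raise ValueError("frac_specific + frac_general must be <= 1")
        if not 2 <= self.n_tumor_types <= len(_TYPE_ORDER):
            raise ValueError(f"n_tumor_types must lie in [2, {len(_TYPE_ORDER)}]")
        if self.ontology_depth < 2:
            raise ValueError("ontology depth must be >= 2")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )

    @property
    def tumor_types(self) -> list[str]:
        return _TYPE_ORDER[: self.n_tumor_types]

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


def synthetic_tissue_map(spec: SyntheticSpec) -> TissueMap:
    """Tissue map restricted to the spec's tumor types, with adjacency."""
    base = TissueMap.default()
    c2t = {t: base.cancer_to_tissue[t] for t in spec.tumor_types}
    tissues = set(c2t.values())
    pairs = [tuple(p) for p in base.adjacency if p & tissues]
    return TissueMap.from_pairs(
        c2t, pairs, base.grouping, solid=set(c2t) & base.solid
    )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


# ---------------------------------------------------------------------------
# ground truth


def gen_truth(spec: SyntheticSpec) -> pd.DataFrame:
    """Planted per-gene labels: class, specific type, hallmark, repair, origin.

    Specific genes are dealt round-robin to the first ``n_specific_types``
    tumor types; repair genes get a pathway class (a planted subset
    multi-annotated); hallmark classes and mutation origins are drawn with
    repair genes biased toward germline origin.
    """
    rng = spec.rng("truth")
    genes = spec.genes
    n_spec = int(spec.frac_specific * spec.n_genes)
    n_gen = int(spec.frac_general * spec.n_genes)
    classes = (
        ["specific"] * n_spec
        + ["general"] * n_gen
        + ["background"] * (spec.n_genes - n_spec - n_gen)
    )
    order = rng.permutation(spec.n_genes)
    truth = pd.DataFrame(index=pd.Index(genes, name="gene"))
    truth["class"] = [classes[i] for i in np.argsort(order)]
    # round-robin assignment of specific genes to the specific-heavy types
    spec_types = spec.tumor_types[: spec.n_specific_types]
    spec_genes = list(truth.index[truth["class"] == "specific"])
    truth["specific_type"] = ""
    for i, g in enumerate(spec_genes):
        truth.loc[g, "specific_type"] = spec_types[i % len(spec_types)]

    # repair pathway labels
    truth["repair_class"] = ""
    n_repair = min(spec.n_repair_genes, spec.n_genes)
    repair_genes = rng.choice(genes, size=n_repair, replace=False)
    pathways = ["NER", "MM", "DSBR"]
    for i, g in enumerate(repair_genes):
        if i < spec.n_repair_multi:
            truth.loc[g, "repair_class"] = "multiple"
        else:
            truth.loc[g, "repair_class"] = pathways[i % 3]

    # hallmark classes: repair genes are dna_repair; oncogene/TSG drawn from
    # the remainder
    truth["hallmark"] = "other"
    truth.loc[repair_genes, "hallmark"] = "dna_repair"
    rest = [g for g in genes if g not in set(repair_genes)]
    picked = rng.choice(
        rest, size=min(spec.n_oncogenes + spec.n_tumor_suppressors, len(rest)),
        replace=False,
    )
    truth.loc[picked[: spec.n_oncogenes], "hallmark"] = "oncogene"
    truth.loc[picked[spec.n_oncogenes:], "hallmark"] = "tumor_suppressor"

    # mutation origin: repair genes mostly germline (18/5/5-style skew)
    origins = []
    for g in genes:
        if truth.loc[g, "repair_class"]:
            origins.append(
                rng.choice(["germline", "somatic", "both"], p=[0.64, 0.18, 0.18])
            )
        else:
            origins.append(
                rng.choice(["germline", "somatic", "both"], p=[0.08, 0.82, 0.10])
            )
    truth["origin"] = origins
    return truth


# ---------------------------------------------------------------------------
# mutation-significance table


def gen_mutation_table(
    spec: SyntheticSpec, truth: pd.DataFrame | None = None
) -> tuple[MutationSignificanceTable, pd.DataFrame]:
    """Planted mutation-significance q values.

    Specific genes: one type with q ~ log-uniform(1e-12, 1e-8), all other
    types and the pan-cancer column non-significant.  General genes: k >= 8
    significant types plus a highly significant pan-cancer q.  Background:
    everything non-significant.
    """
    if truth is None:
        truth = gen_truth(spec)
    rng = spec.rng("mutation")
    types = spec.tumor_types
    q = pd.DataFrame(
        rng.uniform(*spec.background_q, size=(spec.n_genes, len(types))),
        index=truth.index,
        columns=types,
    )
    pan = pd.Series(
        rng.uniform(*spec.background_q, size=spec.n_genes), index=truth.index
    )
    for gene, row in truth.iterrows():
        if row["class"] == "specific":
            q.loc[gene, row["specific_type"]] = _log_uniform(
                rng, *spec.specific_most_q
            )
            pan[gene] = rng.uniform(*spec.specific_pan_q)
        elif row["class"] == "general":
            k = int(rng.integers(spec.general_k_min, len(types) + 1))
            sig_types = rng.choice(types, size=k, replace=False)
            q.loc[gene, sig_types] = _log_uniform(rng, *spec.general_sig_q, size=k)
            pan[gene] = _log_uniform(rng, *spec.general_pan_q)
    pan.name = "pan_q"
    return MutationSignificanceTable(q=q, pan_q=pan), truth


def gen_study_counts(
    spec: SyntheticSpec, truth: pd.DataFrame | None = None
) -> pd.Series:
    """Publication counts with a planted number of highly studied genes."""
    if truth is None:
        truth = gen_truth(spec)
    rng = spec.rng("studies")
    counts = pd.Series(
        rng.integers(*spec.low_study_range, size=spec.n_genes, endpoint=True),
        index=truth.index,
        name="n_studies",
    )
    high = rng.choice(truth.index, size=min(spec.n_high_study, spec.n_genes),
                      replace=False)
    counts[high] = rng.integers(*spec.high_study_range, size=len(high),
                                endpoint=True)
    return counts


# ---------------------------------------------------------------------------
# ontology

REPAIR_TERM_NAMES = {
    "GO:0006289": "nucleotide-excision repair",
    "GO:0006298": "mismatch repair",
    "GO:0006302": "double-strand break repair",
}
_REPAIR_TERM = {"NER": "GO:0006289", "MM": "GO:0006298", "DSBR": "GO:0006302"}


def gen_ontology(
    spec: SyntheticSpec, truth: pd.DataFrame | None = None
) -> OntologyGraph:
    """Rooted tree ontology with a planted general-gene module.

    A complete tree of the stated depth and branching under a single root,
    plus the three DNA-repair pathway classes attached below the root.
    Every gene receives ``n_annotations_per_gene`` leaf annotations;
    general genes draw each annotation from the leaves of one fixed deep
    subtree (the "general module") with probability
    ``general_module_affinity``, giving them elevated annotation
    clustering, hence higher pairwise semantic similarity and a detectable
    gene-set signal.  Repair genes are additionally annotated to their
    pathway class (two classes for the multi-annotated ones).
    """
    if truth is None:
        truth = gen_truth(spec)
    rng = spec.rng("ontology")
    g = nx.DiGraph()
    ns = "biological_process"
    root = "SYN:0000000"
    g.add_node(root, name="root", namespace=ns)
    levels = [[root]]
    counter = 1
    for depth in range(1, spec.ontology_depth + 1):
        level = []
        for parent in levels[-1]:
            for _ in range(spec.ontology_branching):
                term = f"SYN:{counter:07d}"
                counter += 1
                g.add_node(term, name=f"term {counter}", namespace=ns)
                g.add_edge(term, parent)
                level.append(term)
        levels.append(level)
    leaves = levels[-1]
    # general module: all leaves under the first depth-1 subtree
    first_child = levels[1][0]
    graph_tmp = OntologyGraph(graph=g.copy(), annotations={})
    module_leaves = [lf for lf in leaves if first_child in graph_tmp.ancestors(lf)]
    other_leaves = [lf for lf in leaves if lf not in set(module_leaves)]

    for term, name in REPAIR_TERM_NAMES.items():
        g.add_node(term, name=name, namespace=ns)
        g.add_edge(term, root)

    annotations: dict[str, frozenset[str]] = {}
    for gene, row in truth.iterrows():
        terms: set[str] = set()
        for _ in range(spec.n_annotations_per_gene):
            if (
                row["class"] == "general"
                and rng.random() < spec.general_module_affinity
            ):
                terms.add(module_leaves[rng.integers(len(module_leaves))])
            else:
                terms.add(leaves[rng.integers(len(leaves))])
        rc = row["repair_class"]
        if rc == "multiple":
            pair = rng.choice(list(_REPAIR_TERM.values()), size=2, replace=False)
            terms.update(pair)
        elif rc:
            terms.add(_REPAIR_TERM[rc])
        annotations[gene] = frozenset(terms)
    return OntologyGraph(graph=g, annotations=annotations)


# ---------------------------------------------------------------------------
# catalog


def gen_catalog(
    spec: SyntheticSpec,
    truth: pd.DataFrame | None = None,
    tissue_map: TissueMap | None = None,
) -> pd.DataFrame:
    """Catalog rows (tissues, origin, hallmark) for every planted gene.

    Specific genes carry the tissue of their planted type; general genes
    2-4 tissues; background genes 1-2.  Repair pathway assignment is left
    to the ontology-driven stage (column initialized to 'none').
    """
    if truth is None:
        truth = gen_truth(spec)
    tissue_map = tissue_map or synthetic_tissue_map(spec)
    rng = spec.rng("catalog")
    pool = sorted(set(tissue_map.cancer_to_tissue.values()))
    rows = []
    for gene, row in truth.iterrows():
        if row["class"] == "specific":
            tissues = {tissue_map.tissue_of(row["specific_type"])}
        elif row["class"] == "general":
            n = int(rng.integers(2, min(5, len(pool) + 1)))
            tissues = set(rng.choice(pool, size=n, replace=False))
        else:
            n = int(rng.integers(1, 3))
            tissues = set(rng.choice(pool, size=n, replace=False))
        rows.append(
            (gene, frozenset(tissues), row["origin"], row["hallmark"], "none")
        )
    return pd.DataFrame(
        rows, columns=["gene", *io_formats.CATALOG_COLUMNS]
    ).set_index("gene")


# ---------------------------------------------------------------------------
# interaction networks


def _study_sizes(rng: np.random.Generator, n: int) -> np.ndarray:
    # mixture exercising the 30 / 500 study-size thresholds
    return rng.choice([10, 50, 600], size=n, p=[0.4, 0.3, 0.3])


def gen_chemical_network(
    spec: SyntheticSpec, truth: pd.DataFrame | None = None
) -> BipartiteNetwork:
    """Chemical-gene network with planted per-type enrichments.

    Each planted chemical interacts with ``coverage`` of its target type's
    specific genes (evidence 2, large source study, so it survives all
    filters); background chemicals hit genes Bernoulli at the background
    rate with mixed evidence counts and study sizes; drug-flagged
    chemicals exercise the drug filter.
    """
    if truth is None:
        truth = gen_truth(spec)
    rng = spec.rng("chemical")
    genes = list(truth.index)
    edges: list[tuple[str, str, int, int]] = []
    attrs: dict[str, dict] = {}

    for planted in spec.planted_chemicals:
        members = sorted(
            truth.index[
                (truth["class"] == "specific")
                & (truth["specific_type"] == planted.target_type)
            ]
        )
        if not members:
            raise ValueError(
                f"planted chemical targets type {planted.target_type!r} "
                "with no specific genes"
            )
        n_hit = int(round(planted.coverage * len(members)))
        hit = rng.choice(members, size=n_hit, replace=False)
        for g in hit:
            edges.append((g, planted.chemical, 2, 600))
        attrs[planted.chemical] = {
            "is_drug": planted.is_drug,
            "is_air_pollutant": planted.is_air_pollutant,
            "virus_species": "",
        }

    background = [f"chem_bg_{i:03d}" for i in range(spec.n_background_chemicals)]
    for chem in background:
        attrs[chem] = {
            "is_drug": False,
            "is_air_pollutant": bool(
                rng.random() < spec.background_pollutant_rate
            ),
            "virus_species": "",
        }
        mask = rng.random(len(genes)) < spec.chemical_background_rate
        sizes = _study_sizes(rng, int(mask.sum()))
        for g, size in zip(np.array(genes)[mask], sizes):
            evidence = 1 if rng.random() < spec.frac_single_evidence else 2
            edges.append((g, chem, evidence, int(size)))

    for i in range(spec.n_drug_chemicals):
        chem = f"chem_drug_{i}"
        attrs[chem] = {"is_drug": True, "is_air_pollutant": False,
                       "virus_species": ""}
        hit = rng.choice(genes, size=max(3, len(genes) // 20), replace=False)
        for g in hit:
            edges.append((g, chem, 2, 600))

    frame = pd.DataFrame(
        edges, columns=["gene", "partner", "evidence_count", "study_size"]
    ).assign(partner_kind="chemical")
    frame = frame.groupby(["gene", "partner"], as_index=False).agg(
        evidence_count=("evidence_count", "sum"),
        study_size=("study_size", "max"),
        partner_kind=("partner_kind", "first"),
    )
    partners = pd.DataFrame.from_dict(attrs, orient="index").rename_axis("partner")
    return BipartiteNetwork(edges=frame, partners=partners)


def gen_virus_network(
    spec: SyntheticSpec,
    truth: pd.DataFrame | None = None,
    catalog: pd.DataFrame | None = None,
    tissue_map: TissueMap | None = None,
    groups: TissueMap | None = None,
) -> BipartiteNetwork:
    """Virus-strain <-> gene network with planted tissue-group tropism.

    Each strain of a species samples its host partners with genes from the
    species' preferred tissue group up-weighted, so the species' interactor
    profile peaks in that group.
    """
    if truth is None:
        truth = gen_truth(spec)
    if catalog is None:
        catalog = gen_catalog(spec, truth, tissue_map)
    groups = groups or TissueMap.default_system_groups()
    rng = spec.rng("virus")
    tissued = catalog[[len(t) > 0 for t in catalog["tissues"]]]
    gene_groups = {
        g: {groups.group(t) for t in tset}
        for g, tset in tissued["tissues"].items()
    }
    genes = sorted(gene_groups)
    edges = []
    attrs: dict[str, dict] = {}
    for virus in spec.planted_viruses:
        pref = [
            g
            for g in genes
            if virus.preferred_group and virus.preferred_group in gene_groups[g]
        ]
        weights = np.full(len(genes), 1.0 / len(genes))
        if pref:
            is_pref = np.isin(genes, pref)
            weights = (1 - virus.affinity) / len(genes) + np.where(
                is_pref, virus.affinity / len(pref), 0.0
            )
        for s in range(virus.n_strains):
            strain = f"{virus.species}_strain{s}"
            attrs[strain] = {
                "is_drug": False,
                "is_air_pollutant": False,
                "virus_species": virus.species,
            }
            n = min(spec.virus_partners_per_strain, len(genes))
            partners = rng.choice(genes, size=n, replace=False, p=weights)
            sizes = _study_sizes(rng, n)
            for g, size in zip(partners, sizes):
                edges.append((g, strain, 1, int(size)))
    frame = pd.DataFrame(
        edges, columns=["gene", "partner", "evidence_count", "study_size"]
    ).assign(partner_kind="virus_strain")
    partners = pd.DataFrame.from_dict(attrs, orient="index").rename_axis("partner")
    return BipartiteNetwork(edges=frame, partners=partners)


# ---------------------------------------------------------------------------
# expression


def gen_expression(
    spec: SyntheticSpec,
    truth: pd.DataFrame | None = None,
    tissue_map: TissueMap | None = None,
) -> pd.DataFrame:
    """Expression matrix with planted expression/pathology matches.

    Tissue panel = mapped cancer tissues + their adjacency partners +
    filler tissues up to ``n_expression_tissues``.  Per-gene expression
    breadth is uniform over [1, n_tissues].  The first
    ``planted_direct_matches`` specific solid genes get their argmax in
    their cancer tissue, the next ``planted_adjacent_matches`` in an
    adjacent tissue; every other specific gene's argmax is forced into a
    filler tissue so planted match counts are exact.
    """
    if truth is None:
        truth = gen_truth(spec)
    tissue_map = tissue_map or synthetic_tissue_map(spec)
    rng = spec.rng("expression")
    mapped = sorted(set(tissue_map.cancer_to_tissue.values()))
    adjacent = sorted(
        {t for m in mapped for t in tissue_map.adjacent(m)} - set(mapped)
    )
    n_fill = spec.n_expression_tissues - len(mapped) - len(adjacent)
    if n_fill < 1:
        raise ValueError("n_expression_tissues too small for the tissue panel")
    fillers = [f"aux_{i:02d}" for i in range(n_fill)]
    tissues = mapped + adjacent + fillers
    n_t = len(tissues)

    mat = pd.DataFrame(0.0, index=truth.index, columns=tissues)
    for gene in truth.index:
        breadth = int(rng.integers(1, n_t + 1))
        where = rng.choice(n_t, size=breadth, replace=False)
        mat.iloc[mat.index.get_loc(gene), where] = rng.lognormal(
            mean=1.0, sigma=0.8, size=breadth
        )

    solid_specific = [
        g
        for g in truth.index
        if truth.loc[g, "class"] == "specific"
        and tissue_map.is_solid(truth.loc[g, "specific_type"])
    ]
    n_direct = spec.planted_direct_matches
    n_adj = spec.planted_adjacent_matches
    direct_genes = set(solid_specific[:n_direct])
    adjacent_eligible = [
        g
        for g in solid_specific[n_direct:]
        if tissue_map.adjacent(
            tissue_map.tissue_of(truth.loc[g, "specific_type"])
        ) & set(tissues)
    ]
    if len(adjacent_eligible) < n_adj:
        raise ValueError(
            "planted adjacent matches impossible: not enough specific genes "
            "whose cancer tissue has an adjacent tissue in the panel"
        )
    adjacent_genes = set(adjacent_eligible[:n_adj])
    for gene in solid_specific:
        target = tissue_map.tissue_of(truth.loc[gene, "specific_type"])
        peak = float(mat.loc[gene].max()) + 1.0
        if gene in direct_genes:
            mat.loc[gene, target] = peak
        elif gene in adjacent_genes:
            adj = sorted(tissue_map.adjacent(target) & set(tissues))
            mat.loc[gene, adj[0]] = peak
        else:
            # argmax forced away from the cancer tissue and its neighbors
            mat.loc[gene, target] = min(mat.loc[gene, target], peak - 1.5)
            for t in tissue_map.adjacent(target) & set(tissues):
                mat.loc[gene, t] = min(mat.loc[gene, t], peak - 1.5)
            filler = fillers[int(rng.integers(len(fillers)))]
            mat.loc[gene, filler] = peak
    return mat


# ---------------------------------------------------------------------------
# file bundle


def gen_bundle(spec: SyntheticSpec, outdir) -> dict[str, Path]:
    """Generate every input and write it in the pipeline's file formats.

    Returns a name -> path map covering the mutation table, study counts,
    ontology + annotations, gene sets (from propagated ontology terms),
    census-style catalog rows, hallmark labels, chemical and virus networks
    with partner attributes, the expression matrix, and the planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = gen_truth(spec)
    tissue_map = synthetic_tissue_map(spec)
    table, _ = gen_mutation_table(spec, truth)
    counts = gen_study_counts(spec, truth)
    graph = gen_ontology(spec, truth)
    catalog = gen_catalog(spec, truth, tissue_map)
    chem = gen_chemical_network(spec, truth)
    virus = gen_virus_network(spec, truth, catalog, tissue_map)
    expr = gen_expression(spec, truth, tissue_map)

    paths = {name: outdir / fname for name, fname in {
        "mutation_table": "mutation_table.tsv",
        "study_counts": "study_counts.tsv",
        "obo": "ontology.obo",
        "annotations": "annotations.tsv",
        "gene_sets": "gene_sets.gmt",
        "census": "census.tsv",
        "hallmarks": "hallmarks.tsv",
        "chem_edges": "chem_edges.tsv",
        "chem_attributes": "chem_attributes.tsv",
        "virus_edges": "virus_edges.tsv",
        "virus_attributes": "virus_attributes.tsv",
        "expression": "expression.tsv",
        "truth": "truth.tsv",
    }.items()}

    q = table.q.copy()
    q.insert(0, "gene", q.index)
    q["pan_q"] = table.pan_q
    q.to_csv(paths["mutation_table"], sep="\t", index=False)
    counts.rename_axis("gene").reset_index().to_csv(
        paths["study_counts"], sep="\t", index=False
    )
    io_formats.write_obo_lite(graph, paths["obo"])
    io_formats.write_annotations(graph.annotations, paths["annotations"])
    io_formats.write_gmt(
        io_formats.collection_from_ontology(graph), paths["gene_sets"]
    )
    census = pd.DataFrame(
        {
            "gene": catalog.index,
            "tissue": [";".join(sorted(t)) for t in catalog["tissues"]],
            "origin": catalog["mutation_origin"].to_numpy(),
        }
    )
    census.to_csv(paths["census"], sep="\t", index=False)
    pd.DataFrame(
        {"gene": catalog.index, "hallmark": catalog["hallmark"].to_numpy()}
    ).to_csv(paths["hallmarks"], sep="\t", index=False)
    for net, ekey, akey in (
        (chem, "chem_edges", "chem_attributes"),
        (virus, "virus_edges", "virus_attributes"),
    ):
        net.edges[["gene", "partner", "evidence_count", "study_size"]].to_csv(
            paths[ekey], sep="\t", index=False
        )
        net.partners.reset_index().to_csv(paths[akey], sep="\t", index=False)
    expr.rename_axis("gene").to_csv(paths["expression"], sep="\t")
    truth.reset_index().to_csv(paths["truth"], sep="\t", index=False)
    return paths
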