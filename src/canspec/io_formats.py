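"""Readers, writers and in-memory containers for the pipeline's input tables.

All tabular inputs are TSV with a header row; gene sets use the GMT format;
the ontology is an OBO 1.2 subset (``id``/``name``/``namespace``/``is_a``
only).  Gene identifiers are opaque, case-sensitive strings — any symbol
harmonization is the caller's job.  Column dialects are declared explicitly
(never sniffed): a silently mis-mapped q-value column is the worst possible
failure mode for everything downstream.

Containers
----------
``MutationSignificanceTable``
    Per-gene mutation-significance q values: one column per tumor type plus
    a pan-cancer column.  Source of ``mostQ`` (smallest per-type q), ``panQ``
    and ``k`` (number of types significant below a threshold).
``GeneSetCollection``
    Named gene sets (GMT-style), mapping set name -> (description, members).
``OntologyGraph``
    Rooted is_a DAG plus gene -> term annotations, with true-path
    propagation.
``BipartiteNetwork``
    Gene <-> partner (chemical or virus strain) edges with evidence counts
    and source-study sizes, plus partner attributes.
``TissueMap``
    Cancer-type -> tissue mapping, symmetric tissue adjacency, and a
    fine-label -> group-label map.

Catalogs (``CancerGeneCatalog``) and expression matrices are plain pandas
DataFrames with documented schemas (see :func:`build_ext_catalog` and
:func:`read_expression`).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationTableDialect",
    "MutationSignificanceTable",
    "GeneSet",
    "GeneSetCollection",
    "OntologyGraph",
    "BipartiteNetwork",
    "TissueMap",
    "read_mutation_table",
    "read_gmt",
    "write_gmt",
    "read_obo_lite",
    "read_annotations",
    "read_network",
    "read_expression",
    "read_study_counts",
    "build_ext_catalog",
    "collection_from_ontology",
    "write_obo_lite",
    "write_annotations",
]

HALLMARKS = ("oncogene", "tumor_suppressor", "dna_repair", "other")
ORIGINS = ("germline", "somatic", "both")


# ---------------------------------------------------------------------------
# mutation-significance tables


@dataclass(frozen=True)
class MutationTableDialect:
    """Column naming for a mutation-significance TSV.

    ``type_cols=None`` means every column other than the gene and pan-cancer
    columns is a tumor-type q-value column.
    """

    gene_col: str = "gene"
    pan_col: str = "pan_q"
    type_cols: tuple[str, ...] | None = None


@dataclass
class MutationSignificanceTable:
    """Per-gene q values: ``q`` is genes x tumor types, ``pan_q`` per gene."""

    q: pd.DataFrame
    pan_q: pd.Series

    def __post_init__(self) -> None:
        if self.q.index.has_duplicates:
            dup = self.q.index[self.q.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if self.q.shape[1] < 1:
            raise ValueError("need at least one tumor-type q column")
        if not self.pan_q.index.equals(self.q.index):
            self.pan_q = self.pan_q.reindex(self.q.index)
        if self.pan_q.isna().any():
            missing = list(self.pan_q.index[self.pan_q.isna()])
            raise ValueError(f"pan-cancer q missing for {missing}")
        for frame in (self.q, self.pan_q.to_frame()):
            bad = (frame < 0) | (frame > 1)
            if bad.to_numpy().any():
                raise ValueError("q values must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.q.index

    @property
    def tumor_types(self) -> list[str]:
        return list(self.q.columns)

    def most_q(self) -> pd.Series:
        """Smallest single-tumor-type q value per gene (mostQ)."""
        return self.q.min(axis=1)

    def n_significant(self, tau: float) -> pd.Series:
        """Number of tumor types with q < ``tau`` per gene (k)."""
        return (self.q < tau).sum(axis=1)

    def significant_types(self, tau: float) -> dict[str, frozenset[str]]:
        """Per gene, the set of tumor types with q < ``tau``."""
        mask = self.q < tau
        cols = self.q.columns
        return {
            gene: frozenset(cols[row.to_numpy()])
            for gene, row in mask.iterrows()
        }


def read_mutation_table(
    path, dialect: MutationTableDialect | None = None
) -> MutationSignificanceTable:
    """Read a per-gene mutation-significance TSV.

    Missing/empty q cells become 1.0 (least significant, logged); q values
    outside [0,1] or non-numeric are hard errors naming the offending row.
    """
    dialect = dialect or MutationTableDialect()
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect.gene_col not in raw.columns:
        raise ValueError(f"missing gene column {dialect.gene_col!r}")
    if dialect.pan_col not in raw.columns:
        raise ValueError(f"missing pan-cancer column {dialect.pan_col!r}")
    genes = raw[dialect.gene_col]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    if dialect.type_cols is None:
        type_cols = [
            c for c in raw.columns if c not in (dialect.gene_col, dialect.pan_col)
        ]
    else:
        type_cols = list(dialect.type_cols)
        missing = set(type_cols) - set(raw.columns)
        if missing:
            raise ValueError(f"missing tumor-type columns {sorted(missing)}")

    def parse_col(col: str) -> pd.Series:
        vals = []
        for i, cell in enumerate(raw[col]):
            if cell is None or pd.isna(cell) or str(cell).strip() == "":
                logger.warning(
                    "row %d gene %s: empty %s treated as q=1.0", i, genes.iloc[i], col
                )
                vals.append(1.0)
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric q {cell!r} in column {col!r} at row {i}"
                ) from exc
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"q={v} outside [0,1] in column {col!r} at row {i}"
                )
            vals.append(v)
        return pd.Series(vals, index=genes.to_numpy())

    q = pd.DataFrame({c: parse_col(c) for c in type_cols})
    q.index.name = "gene"
    pan = parse_col(dialect.pan_col)
    pan.name = "pan_q"
    return MutationSignificanceTable(q=q, pan_q=pan)


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


class GeneSetCollection(Mapping[str, GeneSet]):
    """Named gene sets with unique names; iteration order = insertion order."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return {n: (s.description, s.members) for n, s in self._sets.items()} == {
            n: (s.description, s.members) for n, s in other._sets.items()
        }


def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            coll.add(GeneSet(name, desc, frozenset(m for m in members if m)))
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.values():
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# ontology


@dataclass
class OntologyGraph:
    """Rooted is_a DAG with gene -> term annotations.

    ``graph`` is a :class:`networkx.DiGraph` with edges child -> parent; node
    attributes carry ``name`` and ``namespace``.  ``annotations`` are the
    direct (non-propagated) gene annotations; :meth:`propagated` applies the
    true-path rule (a gene annotated to a term is annotated to every
    ancestor).
    """

    graph: nx.DiGraph
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            edge = nx.find_cycle(self.graph)[0]
            raise ValueError(f"is_a cycle through edge {edge[0]} -> {edge[1]}")
        unknown = {
            t for terms in self.annotations.values() for t in terms
        } - set(self.graph.nodes)
        if unknown:
            raise ValueError(f"annotations to unknown terms: {sorted(unknown)}")
        self._ancestors: dict[str, frozenset[str]] = {}
        self._propagated: dict[str, frozenset[str]] | None = None

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def roots(self) -> dict[str, str]:
        """One root (no outgoing is_a) per namespace; error otherwise."""
        roots: dict[str, str] = {}
        for node in self.graph.nodes:
            if self.graph.out_degree(node) == 0:
                ns = self.namespace(node)
                if ns in roots:
                    raise ValueError(
                        f"namespace {ns!r} has multiple roots: {roots[ns]}, {node}"
                    )
                roots[ns] = node
        return roots

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` along is_a, including ``term`` itself."""
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    def propagated(self) -> dict[str, frozenset[str]]:
        """True-path-propagated annotations (idempotent)."""
        if self._propagated is None:
            self._propagated = {
                gene: frozenset().union(*(self.ancestors(t) for t in terms))
                for gene, terms in self.annotations.items()
                if terms
            }
        return self._propagated


def read_annotations(path) -> dict[str, frozenset[str]]:
    """Read a two-column (gene TAB term) annotation TSV without header."""
    pairs: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"annotation line {lineno}: need gene TAB term")
            pairs.setdefault(fields[0], set()).add(fields[1])
    return {g: frozenset(t) for g, t in pairs.items()}


def read_obo_lite(path_obo, path_annotations=None) -> OntologyGraph:
    """Read an OBO file (id/name/namespace/is_a subset) plus annotations.

    Relationship types other than is_a are dropped with a logged count.
    Cycles and annotations to unknown terms are hard errors.
    """
    multi = obonet.read_obo(path_obo)
    graph = nx.DiGraph()
    graph.add_nodes_from(
        (n, {"name": d.get("name", n), "namespace": d.get("namespace", "")})
        for n, d in multi.nodes(data=True)
    )
    dropped = 0
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
        else:
            dropped += 1
    if dropped:
        logger.info("ignored %d non-is_a ontology relationships", dropped)
    annotations = read_annotations(path_annotations) if path_annotations else {}
    return OntologyGraph(graph=graph, annotations=annotations)


def write_obo_lite(graph: OntologyGraph, path) -> None:
    """Write the id/name/namespace/is_a subset of OBO 1.2."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: canspec-lite\n")
        for term in sorted(graph.graph.nodes):
            data = graph.graph.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {data.get('name', term)}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for parent in sorted(graph.graph.successors(term)):
                fh.write(f"is_a: {parent}\n")


def write_annotations(annotations: Mapping[str, frozenset[str]], path) -> None:
    """Write gene TAB term annotation pairs (no header)."""
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def collection_from_ontology(
    graph: OntologyGraph, namespace: str | None = None
) -> GeneSetCollection:
    """Turn propagated term memberships into a gene-set collection.

    One set per term with >=1 annotated gene, named by term id; useful for
    feeding ontology classes into the gene-set enrichment stage.
    """
    members: dict[str, set[str]] = {}
    for gene, terms in graph.propagated().items():
        for t in terms:
            members.setdefault(t, set()).add(gene)
    coll = GeneSetCollection()
    for term in sorted(members):
        if namespace is not None and graph.namespace(term) != namespace:
            continue
        name = graph.graph.nodes[term].get("name", term)
        coll.add(GeneSet(term, name, frozenset(members[term])))
    return coll


# ---------------------------------------------------------------------------
# bipartite interaction networks


@dataclass
class BipartiteNetwork:
    """Gene <-> partner edges plus partner attributes.

    ``edges`` columns: gene, partner, partner_kind ('chemical' |
    'virus_strain'), evidence_count (>=1), study_size (largest source-study
    size supporting the edge).  ``partners`` is indexed by partner id with
    columns is_drug, is_air_pollutant, virus_species ('' for chemicals).
    """

    edges: pd.DataFrame
    partners: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.edges["evidence_count"] < 1).any():
            raise ValueError("evidence_count must be >= 1")
        kinds = self.edges.groupby("partner")["partner_kind"].nunique()
        if (kinds > 1).any():
            bad = kinds[kinds > 1].index[0]
            raise ValueError(f"partner {bad!r} has inconsistent partner_kind")
        kind_of = self.edges.drop_duplicates("partner").set_index("partner")[
            "partner_kind"
        ]
        for pid, kind in kind_of.items():
            species = ""
            if pid in self.partners.index:
                species = str(self.partners.loc[pid, "virus_species"] or "")
            if kind == "virus_strain" and not species:
                raise ValueError(f"virus strain {pid!r} has no virus_species")
            if kind == "chemical" and species:
                raise ValueError(f"chemical {pid!r} must not carry virus_species")

    def partner_flag(self, partner: str, flag: str) -> bool:
        if partner in self.partners.index:
            return bool(self.partners.loc[partner, flag])
        return False

    def species_of(self, partner: str) -> str:
        if partner in self.partners.index:
            return str(self.partners.loc[partner, "virus_species"] or "")
        return ""


_DEFAULT_ATTRS = {"is_drug": False, "is_air_pollutant": False, "virus_species": ""}


def read_network(path, partner_kind: str, attribute_path=None) -> BipartiteNetwork:
    """Read a TSV edge list (gene, partner, evidence_count, study_size).

    Duplicate (gene, partner) edges are merged: evidence counts summed,
    study sizes maxed.  Partners absent from the attribute table get default
    flags (logged); virus partners without a species are a hard error.
    """
    if partner_kind not in ("chemical", "virus_strain"):
        raise ValueError(f"unknown partner_kind {partner_kind!r}")
    edges = pd.read_csv(path, sep="\t")
    required = {"gene", "partner", "evidence_count", "study_size"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge list missing columns {sorted(missing)}")
    if (edges["evidence_count"] < 1).any():
        raise ValueError("evidence_count must be >= 1")
    edges = (
        edges.groupby(["gene", "partner"], as_index=False)
        .agg(evidence_count=("evidence_count", "sum"), study_size=("study_size", "max"))
        .assign(partner_kind=partner_kind)
    )
    if attribute_path is not None:
        attrs = pd.read_csv(attribute_path, sep="\t", dtype={"partner": str})
        attrs = attrs.set_index("partner")
        for col, default in _DEFAULT_ATTRS.items():
            if col not in attrs.columns:
                attrs[col] = default
        attrs["virus_species"] = attrs["virus_species"].fillna("")
        attrs[["is_drug", "is_air_pollutant"]] = attrs[
            ["is_drug", "is_air_pollutant"]
        ].fillna(False).astype(bool)
    else:
        attrs = pd.DataFrame(columns=list(_DEFAULT_ATTRS)).rename_axis("partner")
    unknown = set(edges["partner"]) - set(attrs.index)
    if unknown:
        logger.warning(
            "%d partners without attribute rows get default flags", len(unknown)
        )
        defaults = pd.DataFrame(
            {k: [v] * len(unknown) for k, v in _DEFAULT_ATTRS.items()},
            index=sorted(unknown),
        ).rename_axis("partner")
        attrs = pd.concat([attrs, defaults])
    return BipartiteNetwork(edges=edges, partners=attrs)


# ---------------------------------------------------------------------------
# expression matrices and study counts


def read_expression(path) -> pd.DataFrame:
    """Read a gene x tissue abundance TSV (first column = gene id).

    Abundances must be non-negative; tissue labels must be unique.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.columns.has_duplicates:
        raise ValueError("duplicate tissue labels in expression matrix")
    if (mat.to_numpy() < 0).any():
        raise ValueError("negative abundances in expression matrix")
    return mat


def read_study_counts(path) -> pd.Series:
    """Read a gene TAB publication-count TSV (header row: gene, n_studies)."""
    tbl = pd.read_csv(path, sep="\t")
    counts = tbl.set_index(tbl.columns[0])[tbl.columns[1]].astype(int)
    if (counts < 0).any():
        raise ValueError("publication counts must be non-negative")
    return counts


# ---------------------------------------------------------------------------
# tissue maps


@dataclass(frozen=True)
class TissueMap:
    """Cancer-type -> tissue mapping plus adjacency and label grouping."""

    cancer_to_tissue: Mapping[str, str]
    adjacency: frozenset[frozenset[str]] = frozenset()
    grouping: Mapping[str, str] = field(default_factory=dict)
    solid: frozenset[str] = frozenset()

    @classmethod
    def from_pairs(
        cls,
        cancer_to_tissue: Mapping[str, str],
        adjacency_pairs: Iterable[tuple[str, str]] = (),
        grouping: Mapping[str, str] | None = None,
        solid: Iterable[str] = (),
    ) -> "TissueMap":
        pairs = set()
        for a, b in adjacency_pairs:
            if a == b:
                raise ValueError(f"adjacency must be irreflexive: {a!r}")
            pairs.add(frozenset((a, b)))
        return cls(
            cancer_to_tissue=dict(cancer_to_tissue),
            adjacency=frozenset(pairs),
            grouping=dict(grouping or {}),
            solid=frozenset(solid),
        )

    def tissue_of(self, cancer_type: str) -> str:
        if cancer_type not in self.cancer_to_tissue:
            raise KeyError(f"no tissue mapping for cancer type {cancer_type!r}")
        return self.cancer_to_tissue[cancer_type]

    def is_solid(self, cancer_type: str) -> bool:
        return cancer_type in self.solid

    def adjacent(self, tissue: str) -> frozenset[str]:
        return frozenset(
            next(iter(pair - {tissue})) for pair in self.adjacency if tissue in pair
        )

    def group(self, label: str) -> str:
        return self.grouping.get(label, label)

    @classmethod
    def default(cls) -> "TissueMap":
        """Default map for the 21 tumor types of the pan-cancer analysis."""
        c2t = {
            "BLCA": "bladder", "BRCA": "breast", "CLL": "blood",
            "CRC": "colon", "DLBCL": "lymph", "ESO": "esophagus",
            "GBM": "brain", "HNSC": "head_neck", "KIRC": "kidney",
            "LAML": "blood", "LUAD": "lung", "LUSC": "lung",
            "MED": "brain", "MEL": "skin", "MM": "blood",
            "NB": "adrenal", "OV": "ovary", "PRAD": "prostate",
            "RHAB": "muscle", "THCA": "thyroid", "UCEC": "endometrium",
        }
        non_solid = {"CLL", "DLBCL", "LAML", "MM"}
        adjacency = [
            ("endometrium", "myometrium"), ("colon", "ileum"),
            ("kidney", "adrenal"), ("ovary", "endometrium"),
            ("lung", "bronchus"), ("skin", "esophagus"),
        ]
        grouping = {
            # census-style fine labels -> canonical tissue
            "melanoma": "skin", "skin basal cell": "skin",
            "skin squamous cell": "skin", "colorectal": "colon",
            "leukaemia": "blood", "leukemia": "blood", "lymphoma": "lymph",
            "uterus": "endometrium",
        }
        return cls.from_pairs(
            c2t, adjacency, grouping, solid=set(c2t) - non_solid
        )

    @classmethod
    def default_system_groups(cls) -> "TissueMap":
        """Grouping of tissues into organ systems (virus tissue profiles)."""
        grouping = {
            "blood": "hematopoietic", "lymph": "hematopoietic",
            "bone_marrow": "hematopoietic",
            "bladder": "urogenital", "kidney": "urogenital",
            "ovary": "urogenital", "endometrium": "urogenital",
            "myometrium": "urogenital", "prostate": "urogenital",
            "cervix": "urogenital",
            "colon": "digestive", "ileum": "digestive",
            "esophagus": "digestive", "stomach": "digestive",
        }
        return cls.from_pairs({}, (), grouping)


# ---------------------------------------------------------------------------
# extended cancer-gene catalog

CATALOG_COLUMNS = ["tissues", "mutation_origin", "hallmark", "repair_pathway"]


def build_ext_catalog(
    core_genes: Iterable[str],
    census_tables: Iterable[pd.DataFrame],
    tissue_map: TissueMap,
    hallmarks: Mapping[str, str] | None = None,
    core_tissues: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Merge the scored core gene list with census-style catalogs.

    Census tables carry columns gene, tissue (';'-separated fine labels) and
    origin ('germline' | 'somatic' | 'both').  Tissue labels pass through the
    tissue map's grouping (e.g. melanoma / skin basal cell / skin squamous
    cell are joined into skin); origins disagreeing between sources become
    'both'.  Returns a DataFrame indexed by gene with columns ``tissues``
    (frozenset), ``mutation_origin``, ``hallmark`` and ``repair_pathway``
    (initially 'none'; filled by the repair-pathway assignment stage).
    Genes with no tissue in any source are retained with empty tissues and
    logged — downstream tissue analyses must exclude them.
    """
    hallmarks = dict(hallmarks or {})
    tissues: dict[str, set[str]] = {}
    origins: dict[str, set[str]] = {}
    for gene in core_genes:
        tissues.setdefault(gene, set())
        origins.setdefault(gene, set())
    if core_tissues:
        for gene, labels in core_tissues.items():
            tissues.setdefault(gene, set()).update(
                tissue_map.group(lab) for lab in labels
            )
            origins.setdefault(gene, set())
    for table in census_tables:
        for _, row in table.iterrows():
            gene = row["gene"]
            tissues.setdefault(gene, set())
            origins.setdefault(gene, set())
            raw = row.get("tissue", "")
            if isinstance(raw, str) and raw:
                for lab in raw.split(";"):
                    lab = lab.strip()
                    if lab:
                        tissues[gene].add(tissue_map.group(lab))
            origin = row.get("origin", "")
            if isinstance(origin, str) and origin:
                if origin not in ORIGINS:
                    raise ValueError(f"unknown mutation origin {origin!r}")
                if origin == "both":
                    origins[gene].update(("germline", "somatic"))
                else:
                    origins[gene].add(origin)

    rows = []
    n_empty = 0
    for gene in sorted(tissues):
        tset = frozenset(tissues[gene])
        if not tset:
            n_empty += 1
        oset = origins[gene]
        if oset == {"germline"}:
            origin = "germline"
        elif oset == {"somatic"}:
            origin = "somatic"
        elif oset:
            origin = "both"
        else:
            origin = "somatic"  # scored-core genes come from somatic calls
        hm = hallmarks.get(gene, "other")
        if hm not in HALLMARKS:
            raise ValueError(f"unknown hallmark class {hm!r} for {gene}")
        rows.append((gene, tset, origin, hm, "none"))
    if n_empty:
        logger.warning(
            "%d catalog genes have no tissue annotation; excluded from "
            "tissue analyses",
            n_empty,
        )
    catalog = pd.DataFrame(
        rows, columns=["gene", *CATALOG_COLUMNS]
    ).set_index("gene")
    return catalog
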