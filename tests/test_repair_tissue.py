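import networkx as nx
import numpy as np
import pandas as pd
import pytest

from canspec.io_formats import OntologyGraph
from canspec.repair_tissue import (
    DEFAULT_REPAIR_TERMS,
    assign_repair_pathways,
    breadth_comparison,
    germline_fold_enrichment,
    hallmark_specificity,
    pathway_tissue_counts,
    pathway_tissue_fisher,
    pca_tissues,
)
from oracles import fisher_pvalue_enumeration


def _repair_graph():
    g = nx.DiGraph()
    g.add_node("R", namespace="bp")
    for term in DEFAULT_REPAIR_TERMS.values():
        g.add_node(term, namespace="bp")
        g.add_edge(term, "R")
    return g


def _catalog(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "tissues", "mutation_origin", "hallmark",
                 "repair_pathway"],
    ).set_index("gene")


class TestAssignment:
    def test_unique_and_multiple_assignment(self):
        g = _repair_graph()
        graph = OntologyGraph(
            graph=g,
            annotations={
                "a": frozenset({DEFAULT_REPAIR_TERMS["NER"]}),
                "b": frozenset(
                    {DEFAULT_REPAIR_TERMS["NER"], DEFAULT_REPAIR_TERMS["DSBR"]}
                ),
                "c": frozenset({"R"}),
            },
        )
        cat = _catalog(
            [
                ("a", frozenset({"skin"}), "germline", "dna_repair", "none"),
                ("b", frozenset({"breast"}), "germline", "dna_repair", "none"),
                ("c", frozenset({"colon"}), "somatic", "other", "none"),
            ]
        )
        out = assign_repair_pathways(cat, graph)
        assert out.loc["a", "repair_pathway"] == "NER"
        assert out.loc["b", "repair_pathway"] == "multiple"
        assert out.loc["c", "repair_pathway"] == "none"

    def test_38_genes_11_multi_gives_27_unique(self):
        g = _repair_graph()
        terms = list(DEFAULT_REPAIR_TERMS.values())
        ann = {}
        rows = []
        for i in range(38):
            gene = f"r{i:02d}"
            if i < 11:
                ann[gene] = frozenset(terms[:2])
            else:
                ann[gene] = frozenset({terms[i % 3]})
            rows.append((gene, frozenset({"skin"}), "germline", "dna_repair",
                         "none"))
        graph = OntologyGraph(graph=g, annotations=ann)
        out = assign_repair_pathways(_catalog(rows), graph)
        unique = out["repair_pathway"].isin(["NER", "MM", "DSBR"]).sum()
        assert unique == 27

    def test_missing_class_term_rejected(self):
        g = nx.DiGraph()
        g.add_node("R", namespace="bp")
        graph = OntologyGraph(graph=g, annotations={})
        with pytest.raises(ValueError, match="missing"):
            assign_repair_pathways(_catalog([]), graph)


class TestCounts:
    def test_gene_counts_once_per_tissue(self):
        cat = _catalog(
            [
                ("a", frozenset({"skin", "breast"}), "germline", "dna_repair",
                 "NER"),
                ("b", frozenset({"skin"}), "germline", "dna_repair", "MM"),
                ("c", frozenset({"colon"}), "somatic", "dna_repair", "multiple"),
            ]
        )
        counts = pathway_tissue_counts(cat)
        assert counts.loc["skin", "NER"] == 1
        assert counts.loc["breast", "NER"] == 1
        assert counts.loc["skin", "MM"] == 1
        assert "colon" not in counts.index  # multiple excluded
        # row sums equal per-tissue unique-gene tallies
        assert counts.loc["skin"].sum() == 2


class TestFisher:
    def test_diagonal_table(self):
        counts = pd.DataFrame(
            {"NER": [2, 0], "MM": [0, 2], "DSBR": [0, 0]},
            index=["skin", "colon"],
        )
        res = pathway_tissue_fisher(counts, "NER", "skin")
        assert res.table == ((2, 0), (0, 2))
        assert res.pvalue == pytest.approx(1 / 3)

    def test_independent_table_p_one(self):
        counts = pd.DataFrame(
            {"NER": [1, 1], "MM": [1, 1], "DSBR": [0, 0]},
            index=["skin", "colon"],
        )
        res = pathway_tissue_fisher(counts, "NER", "skin")
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self, rng):
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            counts = pd.DataFrame(
                {"NER": [a, c], "MM": [b, d], "DSBR": [0, 0]},
                index=["t1", "t2"],
            )
            res = pathway_tissue_fisher(counts, "NER", "t1")
            assert res.pvalue == pytest.approx(
                fisher_pvalue_enumeration(a, b, c, d), abs=1e-9
            )

    def test_empty_margin_p_one(self, caplog):
        counts = pd.DataFrame(
            {"NER": [0, 0], "MM": [1, 1], "DSBR": [1, 0]},
            index=["t1", "t2"],
        )
        with caplog.at_level("INFO"):
            res = pathway_tissue_fisher(counts, "NER", "t1")
        assert res.pvalue == 1.0


class TestGermlineFold:
    def test_reported_worked_example(self):
        assert germline_fold_enrichment(18, 66, 28, 670) == 6.5

    def test_identical_proportions_give_one(self):
        assert germline_fold_enrichment(7, 50, 7, 50) == 1.0

    def test_matches_ratio_of_proportions(self, rng):
        for _ in range(25):
            n_total = int(rng.integers(50, 1000))
            n_path = int(rng.integers(5, n_total // 2))
            n_germ = int(rng.integers(5, n_total // 2))
            n_pg = int(rng.integers(1, min(n_path, n_germ) + 1))
            expected = round((n_pg / n_germ) / (n_path / n_total), 1)
            assert germline_fold_enrichment(n_pg, n_germ, n_path,
                                            n_total) == expected

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            germline_fold_enrichment(0, 66, 28, 670)


class TestBreadthAndHallmark:
    def test_both_origin_excluded_and_exact_p(self):
        rows = [
            ("g1", frozenset({"a"}), "germline", "other", "none"),
            ("g2", frozenset({"b"}), "germline", "other", "none"),
            ("g3", frozenset({"c"}), "germline", "other", "none"),
            ("s1", frozenset({"a", "b", "c", "d", "e"}), "somatic", "other",
             "none"),
            ("s2", frozenset({"a", "b", "c", "d", "e", "f"}), "somatic",
             "other", "none"),
            ("s3", frozenset({"a", "b", "c", "d", "e", "f", "g"}), "somatic",
             "other", "none"),
            ("x1", frozenset({"a"} ), "both", "other", "none"),
        ]
        res = breadth_comparison(_catalog(rows))
        assert res.n_a == 3 and res.n_b == 3  # the 'both' gene never enters
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_breadths_p_one(self):
        rows = [
            (f"g{i}", frozenset({"a"}), origin, "other", "none")
            for i, origin in enumerate(["germline"] * 3 + ["somatic"] * 3)
        ]
        res = breadth_comparison(_catalog(rows))
        assert res.pvalue == 1.0

    def test_hallmark_pairwise_results(self, rng):
        rows = []
        scores = {}
        for i in range(8):
            g = f"rep{i}"
            rows.append((g, frozenset({"a"}), "germline", "dna_repair", "none"))
            scores[g] = float(-5 + rng.normal(0, 0.1))
        for i in range(25):
            g = f"onc{i}"
            rows.append((g, frozenset({"a"}), "somatic", "oncogene", "none"))
            scores[g] = float(5 + rng.normal(0, 0.1))
        for i in range(18):
            g = f"tsg{i}"
            rows.append((g, frozenset({"a"}), "somatic", "tumor_suppressor",
                         "none"))
            scores[g] = float(5 + rng.normal(0, 0.1))
        frame = pd.DataFrame({"score": pd.Series(scores)})
        res = hallmark_specificity(frame, _catalog(rows))
        assert res[("oncogene", "dna_repair")].pvalue < 0.05
        assert res[("tumor_suppressor", "dna_repair")].pvalue < 0.05
        assert res[("oncogene", "tumor_suppressor")].pvalue > 0.05


class TestPCA:
    def test_collinear_points_single_component(self):
        counts = pd.DataFrame(
            {"NER": [1.0, 2.0, 3.0], "MM": [0.0, 0.0, 0.0],
             "DSBR": [0.0, 0.0, 0.0]},
            index=["t1", "t2", "t3"],
        )
        res = pca_tissues(counts)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 10, size=(6, 3)).astype(float),
            index=[f"t{i}" for i in range(6)],
            columns=["NER", "MM", "DSBR"],
        )
        res = pca_tissues(counts)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        counts = pd.DataFrame(
            rng.normal(size=(5, 3)),
            index=[f"t{i}" for i in range(5)],
            columns=["NER", "MM", "DSBR"],
        )
        res = pca_tissues(counts, n_components=3)
        centered = counts.to_numpy() - counts.to_numpy().mean(axis=0)
        reconstructed = res.coordinates.to_numpy() @ res.loadings.to_numpy()
        assert np.allclose(reconstructed, centered, atol=1e-10)

    def test_row_order_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 10, size=(5, 3)).astype(float),
            index=[f"t{i}" for i in range(5)],
            columns=["NER", "MM", "DSBR"],
        )
        res1 = pca_tissues(counts)
        res2 = pca_tissues(counts.iloc[::-1])
        assert np.allclose(
            res1.coordinates.sort_index().to_numpy(),
            res2.coordinates.sort_index().to_numpy(),
            atol=1e-9,
        )

    def test_zero_variance_rejected(self):
        counts = pd.DataFrame(
            {"NER": [1.0, 1.0, 1.0], "MM": [2.0, 2.0, 2.0],
             "DSBR": [0.0, 0.0, 0.0]},
            index=["t1", "t2", "t3"],
        )
        with pytest.raises(ValueError, match="variance"):
            pca_tissues(counts)
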