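import numpy as np
import pandas as pd
import pytest

from canspec.interaction_enrich import (
    chemical_enrichment,
    filter_network,
    pollutant_fraction,
    specific_gene_sets,
    strain_counts,
    virus_strain_specificity,
    virus_tissue_profile,
)
from canspec.io_formats import (
    BipartiteNetwork,
    MutationSignificanceTable,
    TissueMap,
)
from oracles import fisher_pvalue_enumeration


def _network(edge_rows, partner_rows):
    edges = pd.DataFrame(
        edge_rows,
        columns=["gene", "partner", "partner_kind", "evidence_count",
                 "study_size"],
    )
    partners = pd.DataFrame(
        partner_rows,
        columns=["partner", "is_drug", "is_air_pollutant", "virus_species"],
    ).set_index("partner")
    return BipartiteNetwork(edges=edges, partners=partners)


@pytest.fixture
def chem_net():
    return _network(
        [
            ("g1", "c1", "chemical", 1, 600),
            ("g2", "c1", "chemical", 3, 600),
            ("g3", "c2", "chemical", 2, 20),
            ("g4", "drugA", "chemical", 5, 600),
        ],
        [
            ("c1", False, True, ""),
            ("c2", False, False, ""),
            ("drugA", True, False, ""),
        ],
    )


class TestFilters:
    def test_evidence_filter(self, chem_net):
        out = filter_network(chem_net, min_evidence=2)
        assert set(out.edges["gene"]) == {"g2", "g3", "g4"}

    def test_drug_filter(self, chem_net):
        out = filter_network(chem_net, exclude_drugs=True)
        assert "drugA" not in set(out.edges["partner"])

    def test_study_size_filter(self, chem_net):
        out = filter_network(chem_net, min_study_size=30)
        assert "c2" not in set(out.edges["partner"])

    def test_filters_commute(self, chem_net):
        orders = [
            filter_network(
                filter_network(chem_net, min_evidence=2), min_study_size=30
            ),
            filter_network(
                filter_network(chem_net, min_study_size=30), min_evidence=2
            ),
            filter_network(chem_net, min_evidence=2, min_study_size=30),
        ]
        frames = [
            o.edges.sort_values(["gene", "partner"]).reset_index(drop=True)
            for o in orders
        ]
        for f in frames[1:]:
            pd.testing.assert_frame_equal(frames[0], f)

    def test_empty_result_names_filter(self, chem_net):
        with pytest.raises(ValueError, match="min_evidence=99"):
            filter_network(chem_net, min_evidence=99)


class TestSpecificSets:
    def _table(self):
        genes = [f"s{i}" for i in range(8)] + ["multi", "weak"] + [
            f"b{i}" for i in range(8)
        ]
        q = pd.DataFrame(1.0, index=pd.Index(genes, name="gene"),
                         columns=["LUAD", "BRCA", "LAML"])
        for i in range(8):
            q.loc[f"s{i}", "LUAD"] = 1e-9
            q.loc[f"b{i}", "LAML"] = 1e-9
        q.loc["multi", ["LUAD", "BRCA"]] = 1e-9
        q.loc["weak", "BRCA"] = 1e-9
        pan = pd.Series(0.5, index=q.index, name="pan_q")
        return MutationSignificanceTable(q=q, pan_q=pan)

    def test_single_type_grouping_and_filters(self):
        sets = specific_gene_sets(self._table(), TissueMap.default(),
                                  min_genes=8)
        # multi-type gene excluded; BRCA has only 1 specific gene -> dropped;
        # LAML is not solid -> dropped
        assert set(sets) == {"LUAD"}
        assert sets["LUAD"] == frozenset({f"s{i}" for i in range(8)})

    def test_non_solid_kept_when_allowed(self):
        sets = specific_gene_sets(self._table(), TissueMap.default(),
                                  min_genes=8, solid_only=False)
        assert set(sets) == {"LUAD", "LAML"}

    def test_no_survivors_rejected(self):
        with pytest.raises(ValueError, match="specific genes"):
            specific_gene_sets(self._table(), TissueMap.default(),
                               min_genes=50)


class TestChemicalEnrichment:
    def _sets(self):
        return {
            "LUAD": frozenset({f"l{i}" for i in range(20)}),
            "BRCA": frozenset({f"b{i}" for i in range(20)}),
        }

    def _net_from_hits(self, hits):
        edge_rows = [
            (g, chem, "chemical", 2, 600) for chem, genes in hits.items()
            for g in genes
        ]
        partner_rows = [(chem, False, False, "") for chem in hits]
        return _network(edge_rows, partner_rows)

    def test_independent_chemical_not_reportable(self):
        hits = {"c_even": [f"l{i}" for i in range(10)]
                + [f"b{i}" for i in range(10)]}
        out = chemical_enrichment(self._sets(), self._net_from_hits(hits))
        row = out[(out["cancer_type"] == "LUAD") & (out["chemical"] == "c_even")]
        assert row["chi2"].iloc[0] == pytest.approx(0.0)
        assert row["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # [[20, 10], [10, 20]]: chi2 = 60*(400-100)^2/30^4 = 6.667
        hits = {"c_skew": [f"l{i}" for i in range(20)]
                + [f"b{i}" for i in range(10)]}
        sets = {
            "LUAD": frozenset({f"l{i}" for i in range(30)}),
            "BRCA": frozenset({f"b{i}" for i in range(30)}),
        }
        out = chemical_enrichment(sets, self._net_from_hits(hits))
        row = out[(out["cancer_type"] == "LUAD")].iloc[0]
        assert row["chi2"] == pytest.approx(6.6667, abs=1e-3)
        assert row["pvalue"] == pytest.approx(0.0098, abs=2e-4)
        assert not row["fisher_fallback"]

    def test_fisher_fallback_flagged_below_expected_five(self):
        hits = {"c_rare": ["l0", "l1"]}
        out = chemical_enrichment(self._sets(), self._net_from_hits(hits))
        assert out["fisher_fallback"].all()

    def test_bh_invariant_to_input_order(self):
        hits = {
            "c1": [f"l{i}" for i in range(12)],
            "c2": ["l0", "b0", "b1"],
            "c3": [f"b{i}" for i in range(9)],
        }
        out1 = chemical_enrichment(self._sets(), self._net_from_hits(hits))
        out2 = chemical_enrichment(
            dict(reversed(list(self._sets().items()))),
            self._net_from_hits(dict(reversed(list(hits.items())))),
        )
        merged = out1.merge(
            out2, on=["cancer_type", "chemical"], suffixes=("_a", "_b")
        )
        assert np.allclose(merged["qvalue_a"], merged["qvalue_b"])

    def test_coverage_and_reportability(self):
        hits = {"c_good": [f"l{i}" for i in range(10)]}
        out = chemical_enrichment(self._sets(), self._net_from_hits(hits))
        row = out[(out["cancer_type"] == "LUAD")].iloc[0]
        assert row["coverage"] == pytest.approx(0.5)
        assert bool(row["reportable"]) == (
            row["qvalue"] < 0.01 and row["coverage"] >= 0.2
        )


class TestPollutantFraction:
    def test_four_of_five(self):
        flags = {c: c != "resv" for c in
                 ["resv", "asbestos", "cadmium", "ctet", "arsenite"]}
        background = [f"bg{i}" for i in range(874)] + list(flags)
        frac, p = pollutant_fraction(list(flags), flags, background)
        assert frac == pytest.approx(0.8)
        assert p < 0.01

    def test_zero_flagged_empty_background_rate(self):
        frac, p = pollutant_fraction(["a", "b"], {}, ["a", "b", "c", "d"])
        assert frac == 0.0
        assert p == 1.0

    def test_matches_hypergeometric_oracle(self, rng):
        for _ in range(20):
            n_rep = int(rng.integers(2, 8))
            n_bg = int(rng.integers(n_rep + 2, 40))
            chems = [f"c{i}" for i in range(n_bg)]
            flags = {c: bool(rng.random() < 0.3) for c in chems}
            reportable = chems[:n_rep]
            frac, p = pollutant_fraction(reportable, flags, chems)
            a = sum(flags[c] for c in reportable)
            b = n_rep - a
            c_ = sum(flags[c] for c in chems[n_rep:])
            d = (n_bg - n_rep) - c_
            assert p == pytest.approx(
                fisher_pvalue_enumeration(a, b, c_, d), abs=1e-9
            )


class TestVirus:
    def _virus_net(self):
        return _network(
            [
                ("g1", "EBV_s1", "virus_strain", 1, 600),
                ("g1", "EBV_s2", "virus_strain", 1, 600),
                ("g2", "EBV_s1", "virus_strain", 1, 600),
                ("g2", "HPV_s1", "virus_strain", 1, 600),
                ("g3", "HPV_s1", "virus_strain", 1, 600),
            ],
            [
                ("EBV_s1", False, False, "EBV"),
                ("EBV_s2", False, False, "EBV"),
                ("HPV_s1", False, False, "HPV"),
            ],
        )

    def test_strains_counted_not_species(self):
        counts = strain_counts(self._virus_net())
        assert counts["g1"] == 2  # two strains of one species
        assert counts["g2"] == 2
        assert counts["g3"] == 1

    def test_duplicate_edges_do_not_change_counts(self):
        net = self._virus_net()
        doubled = BipartiteNetwork(
            edges=pd.concat([net.edges, net.edges.iloc[[0]]],
                            ignore_index=True),
            partners=net.partners,
        )
        assert strain_counts(doubled)["g1"] == 2

    def test_breadth_comparison_exact_p(self):
        rows = []
        for i, n_t in enumerate([1, 1, 1]):
            rows.append((f"one{i}", frozenset({f"t{j}" for j in range(n_t)}),
                         "somatic", "other", "none"))
        for i, n_t in enumerate([5, 6, 7]):
            rows.append((f"many{i}",
                         frozenset({f"t{j}" for j in range(n_t)}),
                         "somatic", "other", "none"))
        catalog = pd.DataFrame(
            rows, columns=["gene", "tissues", "mutation_origin", "hallmark",
                           "repair_pathway"]
        ).set_index("gene")
        edges = [(f"one{i}", "v_s1", "virus_strain", 1, 600) for i in range(3)]
        for i in range(3):
            edges += [
                (f"many{i}", f"v_s{j}", "virus_strain", 1, 600)
                for j in range(1, 4)
            ]
        net = _network(
            edges,
            [(f"v_s{j}", False, False, "V") for j in range(1, 4)],
        )
        res = virus_strain_specificity(net, catalog)
        assert res["le1_vs_gt1"].pvalue == pytest.approx(0.1)

    def test_profile_fractions(self):
        catalog = pd.DataFrame(
            [
                ("g1", frozenset({"blood"}), "somatic", "other", "none"),
                ("g2", frozenset({"blood", "skin"}), "somatic", "other",
                 "none"),
                ("g3", frozenset({"skin"}), "somatic", "other", "none"),
            ],
            columns=["gene", "tissues", "mutation_origin", "hallmark",
                     "repair_pathway"],
        ).set_index("gene")
        net = self._virus_net()
        groups = TissueMap.default_system_groups()
        prof = virus_tissue_profile(net, catalog, ["EBV", "HPV"], groups)
        # EBV interactors g1, g2: both hematopoietic, one skin
        assert prof.loc["EBV", "hematopoietic"] == pytest.approx(1.0)
        assert prof.loc["EBV", "skin"] == pytest.approx(0.5)
        # HPV interactors g2, g3: one hematopoietic, both skin
        assert prof.loc["HPV", "skin"] == pytest.approx(1.0)

    def test_virus_without_interactors_dropped(self, caplog):
        catalog = pd.DataFrame(
            [("g9", frozenset({"skin"}), "somatic", "other", "none")],
            columns=["gene", "tissues", "mutation_origin", "hallmark",
                     "repair_pathway"],
        ).set_index("gene")
        net = self._virus_net()
        with caplog.at_level("WARNING"):
            with pytest.raises(ValueError, match="no virus"):
                virus_tissue_profile(
                    net, catalog, ["EBV"], TissueMap.default_system_groups()
                )
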