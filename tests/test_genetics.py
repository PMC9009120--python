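"""GWAS filtering, SNP-to-gene windows, GO over-representation, shared pathways."""

import math

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hallmarknet.genetics import (
    EnrichmentResult,
    GeneInterval,
    GeneLinkTable,
    GwasRecord,
    assign_snps_to_genes,
    build_hallmark_gene_sets,
    expected_overlap_count,
    filter_gwas_records,
    go_enrichment,
    match_go_terms,
    pathway_ard_links,
    propagate_annotation,
    read_bed,
    read_obo_dag,
    shared_significant_pathways,
)


def rec(snp="rs1", chrom="1", pos=500, p=1e-10, trait="D1", ancestry="European", study=""):
    return GwasRecord(snp, chrom, pos, p, trait, ancestry, study)


GENE = GeneInterval("G1", "1", 100_000, 120_000, "+")


class TestFilter:
    def test_strict_p_threshold(self):
        kept = filter_gwas_records([rec(p=4e-8), rec(snp="rs2", p=6e-8), rec(snp="rs3", p=5e-8)])
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_ancestry_exclusion(self):
        records = [rec(ancestry="European"), rec(snp="rs2", ancestry="European, Amish")]
        kept = filter_gwas_records(records, ancestry_exclude=["Amish"])
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_ancestry_inclusion_patterns(self):
        records = [rec(ancestry="European"), rec(snp="rs2", ancestry="East Asian")]
        kept = filter_gwas_records(records, ancestry_include=["European"])
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_study_id_de_overlap(self):
        records = [rec(study="111"), rec(snp="rs2", study="222")]
        kept = filter_gwas_records(records, exclude_study_ids=["111"])
        assert [r.snp_id for r in kept] == ["rs2"]

    def test_empty_records(self):
        assert filter_gwas_records([]) == []


class TestAssignment:
    def test_snp_inside_gene_links(self):
        table = assign_snps_to_genes([rec(pos=110_000)], [GENE])
        assert set(table.rows["gene_id"]) == {"G1"}

    def test_window_boundary_strictly_less(self):
        near = rec(snp="near", pos=GENE.start - 49_999)
        at = rec(snp="at", pos=GENE.start - 50_000)
        table = assign_snps_to_genes([near, at], [GENE])
        assert list(table.rows["snp_ids"]) == [("near",)]

    def test_wider_window_for_newly_prioritized_rerun(self):
        far = rec(pos=GENE.start - 60_000)
        assert len(assign_snps_to_genes([far], [GENE]).rows) == 0
        assert len(assign_snps_to_genes([far], [GENE], window_bp=75_000).rows) == 1

    def test_downstream_distance_symmetric(self):
        down = rec(pos=GENE.end + 49_999)
        up = rec(pos=GENE.start - 49_999)
        for r in (down, up):
            assert len(assign_snps_to_genes([r], [GENE]).rows) == 1

    def test_strand_ignored(self):
        minus = GeneInterval("G1", "1", 100_000, 120_000, "-")
        r = rec(pos=GENE.start - 10)
        assert len(assign_snps_to_genes([r], [minus]).rows) == 1

    def test_unknown_chromosome_skipped(self):
        table = assign_snps_to_genes([rec(chrom="X", pos=110_000)], [GENE])
        assert len(table.rows) == 0

    def test_record_order_invariant(self):
        records = [rec(snp=f"rs{i}", pos=100_000 + i) for i in range(5)]
        a = assign_snps_to_genes(records, [GENE]).rows
        b = assign_snps_to_genes(records[::-1], [GENE]).rows
        pd.testing.assert_frame_equal(a, b)

    def test_trait_to_ard_mapping(self):
        table = assign_snps_to_genes(
            [rec(pos=110_000, trait="EFO:1")], [GENE], trait_to_ard={"EFO:1": "ARD7"}
        )
        assert set(table.rows["ard_id"]) == {"ARD7"}

    @given(st.integers(min_value=0, max_value=100_000), st.integers(min_value=0, max_value=100_000))
    def test_window_monotonicity(self, w1, w2):
        w1, w2 = min(w1, w2), max(w1, w2)
        records = [rec(snp=f"rs{i}", pos=p) for i, p in enumerate([60_000, 99_000, 110_000, 130_000, 190_000])]
        small = assign_snps_to_genes(records, [GENE], window_bp=w1)
        big = assign_snps_to_genes(records, [GENE], window_bp=w2)
        small_links = {(r.ard_id, r.gene_id, r.snp_ids) for r in small.rows.itertuples()}
        big_links = {(r.ard_id, r.gene_id, r.snp_ids) for r in big.rows.itertuples()}
        assert len(small.rows) <= len(big.rows)
        assert {(a, g) for a, g, _ in small_links} <= {(a, g) for a, g, _ in big_links}


def test_bed_read_converts_to_one_based(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("1\t100\t1000\tG1\t0\t+\n")
    (iv,) = read_bed(bed)
    assert (iv.start, iv.end) == (101, 1000)
    # the first covered base (101) is containment distance 0; base 100 lies outside
    inside = rec(pos=101)
    assert len(assign_snps_to_genes([inside], [iv], window_bp=1).rows) == 1


class TestGeneSets:
    def _links(self):
        rows = pd.DataFrame(
            [
                {"ard_id": "D1", "gene_id": "a", "snp_ids": ("rs1",)},
                {"ard_id": "D1", "gene_id": "b", "snp_ids": ("rs2",)},
                {"ard_id": "D2", "gene_id": "b", "snp_ids": ("rs3",)},
                {"ard_id": "D2", "gene_id": "c", "snp_ids": ("rs4",)},
            ]
        )
        return GeneLinkTable(rows=rows, id_map={"a": "pa", "b": "pb", "c": "pc"})

    def test_union_over_top_ards(self):
        links = self._links()
        sets = build_hallmark_gene_sets({"H1": ["D1", "D2"]}, links)
        assert sets["H1"] == {"pa", "pb", "pc"}

    def test_unlinked_ard_contributes_nothing(self):
        sets = build_hallmark_gene_sets({"H1": ["D1", "D9"]}, self._links())
        assert sets["H1"] == {"pa", "pb"}

    def test_accepts_ranked_pairs(self):
        sets = build_hallmark_gene_sets({"H1": [("D1", 0.5)]}, self._links())
        assert sets["H1"] == {"pa", "pb"}

    def test_unmapped_genes_dropped(self):
        links = self._links()
        links.id_map.pop("c")
        sets = build_hallmark_gene_sets({"H1": ["D2"]}, links)
        assert sets["H1"] == {"pb"}

    def test_duplicate_ard_gene_rows_rejected(self):
        rows = pd.DataFrame(
            [
                {"ard_id": "D1", "gene_id": "a", "snp_ids": ("rs1",)},
                {"ard_id": "D1", "gene_id": "a", "snp_ids": ("rs2",)},
            ]
        )
        with pytest.raises(ValueError):
            GeneLinkTable(rows=rows)


class TestExpectedCount:
    @pytest.mark.parametrize(
        "list_size, term_size, background, expected",
        [(100, 50, 1000, 5.0), (0, 50, 1000, 0.0), (1000, 1000, 1000, 1000.0)],
    )
    def test_known_values(self, list_size, term_size, background, expected):
        assert expected_overlap_count(list_size, term_size, background) == expected

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            expected_overlap_count(1, 1, 0)

    @given(st.integers(min_value=0, max_value=50), st.integers(min_value=1, max_value=3))
    def test_linear_in_list_size(self, list_size, factor):
        base = expected_overlap_count(list_size, 10, 1000)
        assert expected_overlap_count(list_size * factor, 10, 1000) == pytest.approx(factor * base)


def hypergeom_tail(x, N, K, n):
    """Independent oracle: exact sum of hypergeometric point masses for X >= x."""
    total = 0.0
    for i in range(x, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


class TestGoEnrichment:
    def _flat_setup(self, term_proteins, background_size):
        background = [f"p{i}" for i in range(background_size)]
        annotation = {p: {"T1"} for p in background[:term_proteins]}
        for p in background[term_proteins:]:
            annotation[p] = {"T0"}
        return background, annotation

    def test_small_terms_excluded(self):
        background, annotation = self._flat_setup(4, 50)
        result = go_enrichment(background[:10], annotation, background, min_term_size=5)
        assert "T1" not in set(result.table["term_id"])

    def test_fisher_matches_hypergeometric_oracle(self):
        background, annotation = self._flat_setup(10, 100)
        study = background[:5] + [f"p{i}" for i in range(50, 55)]  # 5 in T1, 5 outside
        result = go_enrichment(study, annotation, background, min_term_size=5)
        p = result.table.set_index("term_id").loc["T1", "p_value"]
        assert p == pytest.approx(hypergeom_tail(5, 100, 10, 10), abs=1e-12)

    def test_zero_overlap_not_significant(self):
        background, annotation = self._flat_setup(10, 100)
        study = [f"p{i}" for i in range(50, 60)]
        result = go_enrichment(study, annotation, background)
        row = result.table.set_index("term_id").loc["T1"]
        assert row["p_value"] > 0.05 and not row["significant"]

    def test_proteins_outside_background_dropped(self):
        background, annotation = self._flat_setup(10, 100)
        result = go_enrichment(background[:5] + ["alien1", "alien2"], annotation, background)
        assert result.n_dropped == 2
        assert result.list_size == 5

    def test_empty_intersection_rejected(self):
        background, annotation = self._flat_setup(10, 100)
        with pytest.raises(ValueError):
            go_enrichment(["alien"], annotation, background)

    def test_annotation_propagates_to_ancestors(self):
        dag = nx.DiGraph()
        dag.add_node("GO:ROOT", name="biological_process")
        dag.add_node("GO:PARENT", name="parent process")
        dag.add_node("GO:CHILD", name="child process")
        dag.add_edge("GO:CHILD", "GO:PARENT")
        dag.add_edge("GO:PARENT", "GO:ROOT")
        background = [f"p{i}" for i in range(20)]
        annotation = {p: ({"GO:CHILD"} if i < 6 else {"GO:ROOT"}) for i, p in enumerate(background)}
        result = go_enrichment(background[:5], annotation, background, dag=dag, min_term_size=5)
        by_term = result.table.set_index("term_id")
        assert by_term.loc["GO:PARENT", "term_size"] == 6
        assert by_term.loc["GO:PARENT", "list_count"] == 5

    def test_expected_count_column(self):
        background, annotation = self._flat_setup(10, 100)
        result = go_enrichment(background[:10], annotation, background)
        row = result.table.set_index("term_id").loc["T1"]
        assert row["expected"] == pytest.approx(10 * 10 / 100)

    def test_elim_removes_child_genes_from_parent(self):
        dag = nx.DiGraph()
        for t in ("GO:ROOT", "GO:PARENT", "GO:CHILD"):
            dag.add_node(t, name=t.lower())
        dag.add_edge("GO:CHILD", "GO:PARENT")
        dag.add_edge("GO:PARENT", "GO:ROOT")
        background = [f"p{i}" for i in range(40)]
        annotation = {p: {"GO:CHILD"} if i < 8 else {"GO:ROOT"} for i, p in enumerate(background)}
        study = background[:8]
        classic = go_enrichment(study, annotation, background, dag=dag, min_term_size=5)
        elim = go_enrichment(study, annotation, background, dag=dag, min_term_size=5, method="elim")
        c = classic.table.set_index("term_id")
        e = elim.table.set_index("term_id")
        assert c.loc["GO:PARENT", "p_value"] < 0.05  # redundant hit under classic
        assert e.loc["GO:PARENT", "p_value"] > c.loc["GO:PARENT", "p_value"]


class TestTermMatchingAndSharing:
    def _result(self, rows):
        table = pd.DataFrame(rows)
        table["expected"] = 1.0
        return EnrichmentResult(table=table, list_size=10, background_size=100, n_dropped=0)

    def test_cascade_keyword_matches_significant_term(self):
        result = self._result(
            [
                {"term_id": "GO:1", "name": "positive regulation of ERK1 and ERK2 cascade",
                 "list_count": 5, "term_size": 10, "p_value": 0.001, "significant": True},
                {"term_id": "GO:2", "name": "some signaling pathway",
                 "list_count": 1, "term_size": 10, "p_value": 0.8, "significant": False},
                {"term_id": "GO:3", "name": "cascaded nonsense",
                 "list_count": 5, "term_size": 10, "p_value": 0.001, "significant": True},
            ]
        )
        matched = match_go_terms(result, {"pathway": ["pathway", "cascade"]})
        assert matched["pathway"] == ["GO:1"]  # GO:2 not significant; "cascaded" no boundary match

    def test_no_significant_terms_empty(self):
        result = self._result(
            [{"term_id": "GO:1", "name": "x pathway", "list_count": 0, "term_size": 10,
              "p_value": 0.9, "significant": False}]
        )
        assert match_go_terms(result, {"pathway": ["pathway"]}) == {"pathway": []}

    def _nine_results(self, drop_in=None):
        results = {}
        for i in range(9):
            sig = not (drop_in == i)
            results[f"H{i}"] = self._result(
                [{"term_id": "GO:SHARED", "name": "shared signaling pathway", "list_count": 5,
                  "term_size": 10, "p_value": 0.001 if sig else 0.9, "significant": sig}]
            )
        return results

    def test_term_significant_in_all_nine_kept(self):
        assert shared_significant_pathways(self._nine_results()) == {"GO:SHARED"}

    def test_term_significant_in_eight_dropped(self):
        assert shared_significant_pathways(self._nine_results(drop_in=3)) == set()

    def test_wrong_result_count_rejected(self):
        results = self._nine_results()
        results.pop("H0")
        with pytest.raises(ValueError):
            shared_significant_pathways(results)
        assert shared_significant_pathways(results, expected_lists=8) == {"GO:SHARED"}


class TestPathwayArdLinks:
    def test_single_pathway_counts(self):
        links = GeneLinkTable(
            rows=pd.DataFrame(
                [
                    {"ard_id": "D1", "gene_id": "g1", "snp_ids": ("rs1",)},
                    {"ard_id": "D2", "gene_id": "g1", "snp_ids": ("rs2",)},
                ]
            ),
            id_map={"g1": "p1"},
        )
        table = pathway_ard_links(
            ["GO:PW"], {"H1": {"p1"}}, links, annotation={"p1": {"GO:PW"}}
        )
        row = table.iloc[0]
        assert row["n_proteins"] == 1 and row["n_ards"] == 2
        assert set(row["ards"]) == {"D1", "D2"}

    def test_disjoint_protein_sets_union_additively(self):
        links = GeneLinkTable(
            rows=pd.DataFrame(
                [
                    {"ard_id": "D1", "gene_id": "g1", "snp_ids": ("rs1",)},
                    {"ard_id": "D2", "gene_id": "g2", "snp_ids": ("rs2",)},
                ]
            ),
            id_map={"g1": "p1", "g2": "p2"},
        )
        table = pathway_ard_links(
            ["GO:PW"],
            {"H1": {"p1"}, "H2": {"p2"}},
            links,
            annotation={"p1": {"GO:PW"}, "p2": {"GO:PW"}},
        )
        assert table.iloc[0]["n_proteins"] == 2


def test_obo_round_trip(tmp_path):
    obo = tmp_path / "mini.obo"
    obo.write_text(
        "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: child pathway\n"
        "namespace: biological_process\nis_a: GO:0000002 ! parent\n\n"
        "[Term]\nid: GO:0000002\nname: parent\nnamespace: biological_process\n"
    )
    dag = read_obo_dag(obo)
    assert dag.has_edge("GO:0000001", "GO:0000002")
    propagated = propagate_annotation({"p1": {"GO:0000001"}}, dag)
    assert propagated["p1"] == {"GO:0000001", "GO:0000002"}
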