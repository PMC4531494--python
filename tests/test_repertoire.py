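from collections import Counter

import pytest

from airrkit import (
    ClonotypeDefinition,
    ClonotypeMode,
    Functionality,
    build_clonotype_table,
    clonotype_key,
    gene_usage,
    summarize_functionality,
    table_from_keys,
)
from .conftest import make_record


class TestFunctionalitySummary:
    def test_counts_partition_the_input(self, small_records):
        s = summarize_functionality(small_records)
        assert s.total == len(small_records) == 5
        assert s.counts[Functionality.PRODUCTIVE] == 2
        assert s.counts[Functionality.UNPRODUCTIVE] == 1
        assert s.counts[Functionality.UNKNOWN] == 1
        assert s.counts[Functionality.NO_RESULT] == 1
        assert sum(s.counts.values()) == s.total
        assert abs(sum(s.frequencies.values()) - 1.0) < 1e-12

    def test_empty_input(self):
        s = summarize_functionality([])
        assert s.total == 0
        assert all(v == 0 for v in s.counts.values())
        assert all(v == 0.0 for v in s.frequencies.values())

    def test_single_class(self):
        records = [make_record(i) for i in range(10)]
        s = summarize_functionality(records)
        assert s.frequencies[Functionality.PRODUCTIVE] == 1.0


class TestGeneUsage:
    def test_counts_match_brute_force_tally(self):
        genes = ["TRBV6-4", "TRBV6-4", "TRBV12-3", "TRBV12-3"]
        records = [make_record(i, v=f"Homsap {g}*01 F")
                   for i, g in enumerate(genes)]
        df = gene_usage(records, "V")
        assert len(df) == 2
        assert set(df["count"]) == {2}
        assert set(df["frequency"]) == {0.5}

    def test_missing_segment_yields_empty_table(self, small_records):
        light_chain_like = [r for r in small_records if r.d_call is None]
        assert gene_usage(light_chain_like, "D").empty

    def test_allele_level_refines_gene_level(self):
        records = [
            make_record(0, v="Homsap TRBV6-4*01 F"),
            make_record(1, v="Homsap TRBV6-4*02 F"),
            make_record(2, v="Homsap TRBV6-4*01 F"),
        ]
        gene_df = gene_usage(records, "V", level="gene")
        allele_df = gene_usage(records, "V", level="allele")
        assert list(gene_df["name"]) == ["TRBV6-4"]
        assert gene_df["count"].iloc[0] == 3
        assert dict(zip(allele_df["name"], allele_df["count"])) == {
            "TRBV6-4*01": 2, "TRBV6-4*02": 1}
        assert len(allele_df) >= len(gene_df)

    def test_rows_sorted_desc_count_then_name(self):
        records = ([make_record(i, v="Homsap TRBV9*01 F") for i in range(2)]
                   + [make_record(9, v="Homsap TRBV2*01 F")]
                   + [make_record(10, v="Homsap TRBV28*01 F")])
        df = gene_usage(records, "V")
        assert list(df["name"]) == ["TRBV9", "TRBV2", "TRBV28"]


class TestClonotypeKey:
    def test_cdr3_aa_key_is_the_sequence(self, small_records):
        key = clonotype_key(small_records[0], ClonotypeDefinition())
        assert key == "ASSMGQNNEQF"

    def test_stop_codon_character_is_legal(self, small_records):
        key = clonotype_key(small_records[2], ClonotypeDefinition())
        assert key == "ASSDD*RGGTDTQY"

    def test_vdj_gene_key_joined_with_pipes(self, small_records):
        d = ClonotypeDefinition(mode=ClonotypeMode.VDJ_GENES)
        assert clonotype_key(small_records[0], d) == "TRBV6-4|TRBD2|TRBJ2-1"

    def test_vdj_key_renders_absent_d_as_dash(self, small_records):
        d = ClonotypeDefinition(mode=ClonotypeMode.VDJ_GENES)
        assert clonotype_key(small_records[3], d) == "TRBV12-3|-|TRBJ2-7"

    def test_vdj_allele_level_distinguishes_alleles(self, small_records):
        d = ClonotypeDefinition(mode=ClonotypeMode.VDJ_GENES, level="allele")
        k0 = clonotype_key(small_records[0], d)
        k1 = clonotype_key(small_records[1], d)
        assert k0 != k1 and k0.startswith("TRBV6-4*01")

    def test_no_result_records_never_yield_a_key(self, small_records):
        for mode in ClonotypeMode:
            d = ClonotypeDefinition(mode=mode)
            assert clonotype_key(small_records[4], d) is None

    def test_excluded_functionality_yields_no_key(self, small_records):
        d = ClonotypeDefinition.productive_only()
        assert clonotype_key(small_records[2], d) is None
        assert clonotype_key(small_records[0], d) == "ASSMGQNNEQF"

    def test_no_result_cannot_be_included(self):
        with pytest.raises(ValueError):
            ClonotypeDefinition(include=frozenset({Functionality.NO_RESULT}))


class TestClonotypeTable:
    def test_counts_and_percentages(self):
        table = table_from_keys(["A", "A", "A", "B"], ClonotypeDefinition())
        assert table.n_records_used == 4
        assert dict(zip(table.df["key"], table.df["count"])) == {"A": 3, "B": 1}
        assert dict(zip(table.df["key"], table.df["frequency"])) == {
            "A": 75.0, "B": 25.0}

    def test_all_records_excluded_gives_empty_table(self, small_records):
        no_result_only = [small_records[4]]
        table = build_clonotype_table(no_result_only)
        assert len(table) == 0 and table.n_records_used == 0

    def test_counts_equal_independent_tally(self, sim_repertoire,
                                            default_definition):
        records, _ = sim_repertoire
        table = build_clonotype_table(records, default_definition)
        oracle = Counter(k for k in (clonotype_key(r, default_definition)
                                     for r in records) if k is not None)
        assert dict(zip(table.df["key"], table.df["count"])) == dict(oracle)
        assert table.n_records_used == sum(oracle.values())

    def test_frequencies_sum_to_100(self, sim_repertoire, default_definition):
        records, _ = sim_repertoire
        table = build_clonotype_table(records, default_definition)
        assert abs(table.df["frequency"].sum() - 100.0) < 1e-6

    def test_rows_sorted_desc_count_then_key(self):
        table = table_from_keys(["B", "A", "B", "A", "C"], ClonotypeDefinition())
        assert list(table.df["key"]) == ["A", "B", "C"]
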