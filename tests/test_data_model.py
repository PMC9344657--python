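import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import richtrend as rt
from richtrend.data_model import (ParseError, RANKS, TaxaCountTable, TaxonomyMap,
                                  aggregate_by_rank, build_design,
                                  parse_qiime_lineage, parse_taxonomy,
                                  read_count_table)


class TestReadCountTable:
    def test_depths_are_column_sums(self, tiny_counts_tsv):
        t = read_count_table(tiny_counts_tsv, format="tsv")
        assert list(t.depths) == [7, 4]
        assert t.taxon_ids == ["t1", "t2", "t3"]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(ParseError):
            read_count_table(p)

    def test_duplicate_taxon_named_in_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("taxon_id\ts1\nt1\t1\nt1\t2\n")
        with pytest.raises(ParseError, match="t1"):
            read_count_table(p)

    @pytest.mark.parametrize("bad,msg", [("-1", "negative"), ("0.5", "non-integer")])
    def test_bad_counts_rejected(self, tmp_path, bad, msg):
        p = tmp_path / "bad.tsv"
        p.write_text(f"taxon_id\ts1\nt1\t{bad}\n")
        with pytest.raises(ParseError, match=msg):
            read_count_table(p)

    def test_tsv_round_trip_bit_exact(self, tmp_path, tiny_counts_tsv):
        t = read_count_table(tiny_counts_tsv)
        out = tmp_path / "rt.tsv"
        t.to_tsv(out)
        t2 = read_count_table(out)
        assert t.counts.equals(t2.counts)

    def test_biom_json_reader(self, tmp_path):
        doc = {"rows": [{"id": "t1"}, {"id": "t2"}],
               "columns": [{"id": "s1"}, {"id": "s2"}],
               "matrix_type": "sparse",
               "data": [[0, 0, 5], [1, 1, 3]]}
        p = tmp_path / "x.biom"
        p.write_text(json.dumps(doc))
        t = read_count_table(p, format="biom-json")
        assert t.counts.loc["t1", "s1"] == 5
        assert t.counts.loc["t2", "s1"] == 0


class TestTaxonomy:
    def test_qiime_string_parsing(self):
        toks = parse_qiime_lineage("k__Bacteria;p__Proteobacteria;c__;o__;f__;g__Pseudomonas")
        # a gap at class makes everything below unassigned, including genus
        assert toks[0] == "Bacteria" and toks[2] == "unassigned"
        toks2 = parse_qiime_lineage("k__Bacteria;p__Firmicutes;c__Bacilli;o__X;f__Y;g__Z")
        assert toks2[-1] == "Z"

    def test_seven_token_lineage_truncated(self):
        toks = parse_qiime_lineage("k__A;p__B;c__C;o__D;f__E;g__F;s__species")
        assert len(toks) == 6 and toks[-1] == "F"

    def test_rank_columns_blank_genus(self):
        df = pd.DataFrame({"taxon_id": ["t1"], "kingdom": ["Bacteria"],
                           "phylum": ["P"], "class": ["C"], "order": ["O"],
                           "family": ["F"], "genus": [""]})
        tm = parse_taxonomy(df, dialect="rank_columns")
        assert tm.rank("genus")["t1"] == "unassigned"

    def test_missing_taxon_strict_vs_lenient(self):
        df = pd.DataFrame({"taxon_id": ["t1"], "lineage": ["k__B;p__;c__;o__;f__;g__"]})
        with pytest.raises(ParseError):
            parse_taxonomy(df, taxon_ids=["t1", "t2"], strict=True)
        tm = parse_taxonomy(df, taxon_ids=["t1", "t2"], strict=False)
        assert tm.rank("kingdom")["t2"] == "unassigned"


def _toy_inputs():
    counts = pd.DataFrame({"s1": [5, 0, 2, 4], "s2": [0, 1, 3, 0]},
                          index=["a1", "a2", "b1", "u1"])
    table = TaxaCountTable(counts)
    lin = pd.DataFrame(
        [["Bacteria", "P", "C", "O", "F1", "GenA"],
         ["Bacteria", "P", "C", "O", "F1", "GenA"],
         ["Bacteria", "P", "C", "O", "F2", "GenB"],
         ["Bacteria", "P", "C", "O", "F2", "unassigned"]],
        index=["a1", "a2", "b1", "u1"], columns=list(RANKS))
    return table, TaxonomyMap(lin)


class TestAggregate:
    def test_richness_and_abundance(self):
        table, tm = _toy_inputs()
        agg = aggregate_by_rank(table, tm)
        assert agg.n.loc["GenA", "s1"] == 1 and agg.y.loc["GenA", "s1"] == 5
        assert agg.n.loc["GenA", "s2"] == 1 and agg.y.loc["GenA", "s2"] == 1
        assert agg.n_plus["s1"] == 3

    def test_unassigned_pooled_per_family_conserves_depth(self):
        table, tm = _toy_inputs()
        agg = aggregate_by_rank(table, tm)
        assert "unassigned@F2" in agg.group_ids
        assert (agg.y.sum(axis=0) == table.depths).all()

    def test_drop_mode_loses_unassigned(self):
        table, tm = _toy_inputs()
        agg = aggregate_by_rank(table, tm, pool_unassigned=False)
        assert all(not g.startswith("unassigned") for g in agg.group_ids)
        assert agg.y["s1"].sum() == table.depths["s1"] - 4

    def test_one_taxon_per_genus_gives_binary_richness(self):
        counts = pd.DataFrame({"s1": [3, 0], "s2": [1, 9]}, index=["x", "y"])
        lin = pd.DataFrame([["B", "P", "C", "O", "F", "G1"],
                            ["B", "P", "C", "O", "F", "G2"]],
                           index=["x", "y"], columns=list(RANKS))
        agg = aggregate_by_rank(TaxaCountTable(counts), TaxonomyMap(lin))
        assert set(np.unique(agg.n.to_numpy())) <= {0, 1}

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_depth_conservation_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 8)
        counts = pd.DataFrame(rng.integers(0, 20, size=(k, 3)),
                              index=[f"t{i}" for i in range(k)],
                              columns=list("abc"))
        if counts.to_numpy().sum() == 0:
            counts.iloc[0, 0] = 1
        genera = [f"G{rng.integers(0, 3)}" for _ in range(k)]
        lin = pd.DataFrame([["B", "P", "C", "O", "F", g] for g in genera],
                           index=counts.index, columns=list(RANKS))
        agg = aggregate_by_rank(TaxaCountTable(counts), TaxonomyMap(lin))
        assert (agg.y.sum(axis=0) == counts.sum(axis=0)).all()
        assert (agg.n.to_numpy() <= agg.y.to_numpy()).all()
        assert ((agg.n.to_numpy() == 0) == (agg.y.to_numpy() == 0)).all()


class TestDesign:
    def test_treatment_coding_lexicographic_reference(self):
        df = pd.DataFrame({"sample_id": ["s1", "s2", "s3"],
                           "group": ["B", "A", "B"], "age": [1.0, 2.0, 3.0]})
        X = build_design(df)
        assert X.columns == ["Intercept", "group[B]", "age"]
        assert list(X.frame["group[B]"]) == [1.0, 0.0, 1.0]

    def test_reference_override(self):
        df = pd.DataFrame({"sample_id": ["s1", "s2"], "group": ["A", "B"]})
        X = build_design(df, reference={"group": "B"})
        assert X.columns == ["Intercept", "group[A]"]

    def test_rank_deficiency_detected(self):
        df = pd.DataFrame({"sample_id": ["s1", "s2"], "c": [1.0, 1.0]})
        X = build_design(df)
        with pytest.raises(ValueError, match="rank"):
            X.check_full_rank()
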