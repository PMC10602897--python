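"""Feature encoding: one-hot, counts, raw, quantum, assembly and pruning."""

import numpy as np
import pandas as pd
import pytest

from guideforest import encode as e
from tests.conftest import random_guides


class TestGuide:
    def test_length_and_alphabet_enforced(self):
        with pytest.raises(e.EncodingError):
            e.Guide(seq="ACGT")
        with pytest.raises(e.EncodingError, match="position 3"):
            e.Guide(seq="ACXTACGTACGTACGTACGT")

    def test_pam_must_be_ngg(self):
        with pytest.raises(e.EncodingError):
            e.Guide(seq="A" * 20, pam="TGA")
        e.Guide(seq="A" * 20, pam="TGG")  # ok


class TestOnehotPositional:
    def test_width_is_384(self):
        out = e.onehot_positional(["ACGT" * 5])
        assert out.shape[1] == 384

    def test_exactly_39_bits_set(self):
        gs = random_guides(10, seed=1)
        sums = e.onehot_positional(gs).sum(axis=1)
        assert (sums == 39).all()

    def test_poly_a_guide(self):
        row = e.onehot_positional(["A" * 20]).iloc[0]
        assert all(row[f"A@{p}"] == 1 for p in range(1, 21))
        assert all(row[f"AA@{p}"] == 1 for p in range(1, 20))
        assert row.sum() == 39

    def test_one_bit_per_group(self):
        row = e.onehot_positional(["ACGTACGTACGTACGTACGT"]).iloc[0]
        for p in range(1, 21):
            assert sum(row[f"{b}@{p}"] for b in "ACGT") == 1
        for p in range(1, 20):
            assert sum(row[f"{x}{y}@{p}"] for x in "ACGT" for y in "ACGT") == 1

    def test_column_sums_match_base_frequencies(self):
        gs = random_guides(50, seed=2)
        block = e.onehot_positional(gs)
        for p in (1, 10, 20):
            for b in "ACGT":
                expected = sum(g.seq[p - 1] == b for g in gs)
                assert block[f"{b}@{p}"].sum() == expected


class TestPositionIndependentCounts:
    def test_poly_g(self):
        row = e.position_independent_counts(["G" * 20]).iloc[0]
        assert row["count_G"] == 20 and row["count_GG"] == 19
        assert row.drop(["count_G", "count_GG"]).sum() == 0

    def test_alternating_ac_hand_count(self):
        row = e.position_independent_counts(["ACACACACACACACACACAC"]).iloc[0]
        assert row["count_A"] == 10 and row["count_C"] == 10
        assert row["count_AC"] == 10 and row["count_CA"] == 9

    def test_sums(self):
        gs = random_guides(20, seed=3)
        block = e.position_independent_counts(gs)
        singles = block[[f"count_{b}" for b in "ACGT"]].sum(axis=1)
        pairs = block[[c for c in block if len(c) == 8 and c.startswith("count_")]].sum(axis=1)
        assert (singles == 20).all() and (pairs == 19).all()

    def test_pam_indicator(self):
        row = e.position_independent_counts([e.Guide(seq="A" * 20, pam="TGG")]).iloc[0]
        assert row["pam_N=T"] == 1
        assert row[["pam_N=A", "pam_N=C", "pam_N=G"]].sum() == 0


class TestTm:
    def test_half_gc_20mer(self):
        # 64.9 + 41 * (10 - 16.4) / 20
        assert e.tm_watson_crick("G" * 10 + "A" * 10) == pytest.approx(51.78)

    def test_all_at_20mer(self):
        assert e.tm_watson_crick("AT" * 10) == pytest.approx(31.28)

    def test_fixed_point_structure(self):
        # when nG+nC equals 16.4 the correction vanishes; verify algebraically
        # via two evaluations bracketing the fixed point of the formula
        lo = e.tm_watson_crick("G" * 16 + "A" * 4)  # nGC=16 < 16.4
        hi = e.tm_watson_crick("G" * 17 + "A" * 3)  # nGC=17 > 16.4
        assert lo < 64.9 < hi
        seq40 = "G" * 16 + "A" * 4
        assert e.tm_watson_crick(seq40) == pytest.approx(64.9 + 41 * (16 - 16.4) / 20)

    def test_empty_sequence_rejected(self):
        with pytest.raises(e.EncodingError):
            e.tm_watson_crick("")


class TestRawFeatures:
    def test_block_width_is_five(self):
        gs = random_guides(5, seed=4, with_context=True)
        block = e.raw_features(gs)
        assert list(block.columns) == list(e.RAW_FEATURE_NAMES)
        assert block.shape[1] == 5

    def test_poly_g_gc_content(self):
        g = e.Guide(seq="G" * 20, distance_to_pam=3, gene_location="TSS")
        assert e.raw_features([g])["gc"].iloc[0] == 1.0

    def test_adjacent_pam_distance_zero(self):
        g = e.Guide(seq="A" * 20, distance_to_pam=0, gene_location="Q2")
        assert e.raw_features([g])["distance_to_pam"].iloc[0] == 0

    def test_missing_context_is_explicit_error(self):
        with pytest.raises(e.EncodingError, match="distance_to_pam"):
            e.raw_features([e.Guide(seq="A" * 20)])

    def test_null_mfe_provider_warns_and_omits(self):
        g = e.Guide(seq="A" * 20, distance_to_pam=1, gene_location="Q1")
        with pytest.warns(UserWarning, match="MFE"):
            block = e.raw_features([g], mfe_provider=e.NullMfe())
        assert "mfe" not in block.columns

    def test_gene_location_expansion(self):
        g = e.Guide(seq="A" * 20, distance_to_pam=1, gene_location="Q3")
        block = e.raw_features(
            [g], features=("gene_location",), expand_gene_location=True
        )
        assert block.shape[1] == 6
        assert block["gene_location=Q3"].iloc[0] == 1


class TestQuantumPositional:
    def test_full_k_set_window_count(self, full_table):
        # 20 + 19 + 18 + 17 windows per property per class
        assert e.quantum_window_count((1, 2, 3, 4)) == 74
        gs = random_guides(3, seed=5)
        block = e.quantum_positional(
            gs, full_table, k_set=(1, 2, 3, 4), classes=("DNA:DNA",),
            properties=("hl_gap",),
        )
        assert block.shape[1] == 74

    def test_constant_table_gives_constant_columns(self, small_table):
        table = small_table
        const = table.df.copy()
        const["hl_gap"] = 0.125
        const["lumo"] = const["homo"] + 0.125
        const_table = type(table)(df=const)
        gs = random_guides(4, seed=6)
        block = e.quantum_positional(
            gs, const_table, k_set=(1, 2), classes=("DNA:DNA",), properties=("hl_gap",)
        )
        assert (block.to_numpy() == 0.125).all()

    def test_window_locality(self, full_table):
        a = e.Guide(seq="ACGT" + "A" * 16)
        b = e.Guide(seq="ACGT" + "C" * 16)
        pa = e.quantum_positional([a], full_table, k_set=(4,), classes=("DNA:RNA",))
        pb = e.quantum_positional([b], full_table, k_set=(4,), classes=("DNA:RNA",))
        shared = [c for c in pa.columns if c.endswith("|p1")]
        assert shared
        assert (pa[shared].iloc[0] == pb[shared].iloc[0]).all()

    def test_missing_record_names_kmer(self, small_table):
        gs = random_guides(2, seed=7)
        with pytest.raises(KeyError, match="DNA:DNA"):
            e.quantum_positional(gs, small_table, k_set=(3,), classes=("DNA:DNA",))


class TestAssembly:
    def test_minmax_normalization(self):
        np.testing.assert_allclose(
            e.minmax_normalize([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0]
        )

    def test_constant_response_rejected(self):
        gs = random_guides(5, seed=8, efficiency=[1.0] * 5)
        with pytest.raises(e.AssemblyError, match="constant"):
            e.assemble_matrix(gs, {"onehot": e.onehot_positional(gs)})

    def test_duplicate_column_pruned_keeps_first(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]})
        assert e.prune_correlated(X) == ["a", "c"]

    def test_pruning_bounds_all_pairs(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(200, 10))
        # 50 columns, many engineered near-duplicates
        cols = {}
        for j in range(50):
            src = base[:, j % 10]
            cols[f"c{j}"] = src + rng.normal(0, 0.05 if j % 2 else 1.0, 200)
        X = pd.DataFrame(cols)
        kept = e.prune_correlated(X, 0.9)
        corr = np.corrcoef(X[kept].to_numpy().T)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.9

    def test_pruning_idempotent(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(50, 20)), columns=[f"c{j}" for j in range(20)])
        kept = e.prune_correlated(X, 0.9)
        assert e.prune_correlated(X[kept], 0.9) == kept

    def test_nan_rejected_with_column_name(self):
        gs = random_guides(4, seed=11, efficiency=[1, 2, 3, 4])
        block = e.onehot_positional(gs).astype(float)
        block.loc[0, "A@1"] = np.nan
        with pytest.raises(e.AssemblyError, match="A@1"):
            e.assemble_matrix(gs, {"onehot": block})

    def test_species_indicator_appended(self):
        base = random_guides(30, seed=12, efficiency=list(range(30)))
        gs = [
            e.Guide(seq=g.seq, efficiency=g.efficiency,
                    species="ecoli" if i % 2 else "hsapiens")
            for i, g in enumerate(base)
        ]
        fm = e.assemble_matrix(gs, {"onehot": e.onehot_positional(gs)})
        species_cols = fm.columns_with_tag("species")
        assert len(species_cols) == 1
        assert set(fm.X[species_cols[0]]) <= {0, 1}

    def test_deterministic_and_stable_column_order(self):
        gs = random_guides(10, seed=13, efficiency=list(range(10)))
        fm1 = e.assemble_matrix(gs, {"onehot": e.onehot_positional(gs)})
        fm2 = e.assemble_matrix(gs, {"onehot": e.onehot_positional(gs)})
        assert fm1.feature_names == fm2.feature_names
        pd.testing.assert_frame_equal(fm1.X, fm2.X)
        pd.testing.assert_series_equal(fm1.y, fm2.y)

    def test_encode_guides_presets(self, small_table):
        gs = random_guides(8, seed=14, with_context=True,
                           efficiency=list(range(8)))
        fm = e.encode_guides(
            gs, feature_sets=("qct",), table=small_table, k_set=(1, 2)
        )
        assert set(fm.provenance) == {"quantum"}

    def test_matrix_round_trip_via_tsv(self, tmp_path):
        gs = random_guides(6, seed=15, efficiency=list(range(6)))
        fm = e.assemble_matrix(gs, {"onehot": e.onehot_positional(gs)})
        path = tmp_path / "X.tsv"
        fm.write(path, header_comment="seed=0")
        df = pd.read_csv(path, sep="\t", comment="#")
        assert df.shape == (6, fm.X.shape[1] + 1)  # + response column
        side = pd.read_csv(
            tmp_path / "X.tsv.provenance.tsv", sep="\t", index_col=0
        )
        assert (side["provenance"] == "onehot").all()


class TestGuideIO:
    def test_tsv_round_trip(self, tmp_path):
        gs = random_guides(5, seed=16, with_context=True, efficiency=list(range(5)))
        path = tmp_path / "guides.tsv"
        e.write_guides_tsv(gs, path)
        back = e.read_guides_tsv(path)
        assert [g.seq for g in back] == [g.seq for g in gs]
        assert [g.distance_to_pam for g in back] == [g.distance_to_pam for g in gs]

    def test_fasta_reader(self, tmp_path):
        path = tmp_path / "guides.fa"
        path.write_text(">g1\nACGTACGTACGTACGTACGT\n>g2\nTTTTACGTACGTACGTACGT\n")
        back = e.read_guides_fasta(path)
        assert len(back) == 2 and back[1].seq.startswith("TTTT")
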