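"""Sequence-context features, Grantham lookups, feature assembly and the
encoding/imputation contract."""

import math

import numpy as np
import pandas as pd
import pytest

from caddforge.features import (
    FeatureError,
    FeatureSpec,
    assemble_features,
    encode_and_impute,
    sequence_context_features,
)
from caddforge.genome import Genome
from caddforge.grantham import GRANTHAM, grantham
from caddforge.tracks import load_track


class TestSequenceContext:
    def test_all_g_window(self):
        g = Genome({"chr1": "G" * 21})
        out = sequence_context_features(g, "chr1", 11, window=10)
        assert out["gc_fraction"] == 1.0
        assert out["cpg_count"] == 0
        assert out["ref_base"] == "G"

    def test_hand_counted_toy(self):
        g = Genome({"chr1": "ACGCGT"})
        # window 2 around position 3 covers ACGCG: 4/5 GC, CpGs at 2 and 4
        out = sequence_context_features(g, "chr1", 3, window=2)
        assert out["gc_fraction"] == pytest.approx(4 / 5)
        assert out["cpg_count"] == 2
        # a window covering the whole sequence: 4/6 GC, still 2 CpGs
        full = sequence_context_features(g, "chr1", 3, window=5)
        assert full["gc_fraction"] == pytest.approx(4 / 6)
        assert full["cpg_count"] == 2

    def test_edge_clipping_uses_actual_window(self):
        g = Genome({"chr1": "GGATATATAT"})
        out = sequence_context_features(g, "chr1", 1, window=3)
        # clipped window is positions 1-4: GGAT -> 2/4 GC
        assert out["gc_fraction"] == pytest.approx(0.5)

    def test_all_n_window_is_missing(self):
        g = Genome({"chr1": "NNNNN"})
        out = sequence_context_features(g, "chr1", 3, window=1)
        assert math.isnan(out["gc_fraction"])

    def test_out_of_range_position(self):
        with pytest.raises(FeatureError):
            sequence_context_features(Genome({"chr1": "ACGT"}), "chr1", 9)


class TestGrantham:
    def test_identity_is_zero(self):
        assert grantham("L", "L") == 0

    @pytest.mark.parametrize(
        "a, b, d",
        [("L", "I", 5), ("C", "W", 215), ("R", "L", 102), ("S", "R", 110),
         ("D", "E", 45), ("F", "Y", 22)],
    )
    def test_published_values(self, a, b, d):
        assert grantham(a, b) == d

    def test_symmetry_and_range(self):
        aas = sorted({a for a, _ in GRANTHAM})
        assert len(aas) == 20
        for a in aas:
            for b in aas:
                assert grantham(a, b) == grantham(b, a)
                assert grantham(a, b) >= 0

    def test_non_standard_residue_is_missing(self):
        assert grantham("L", "X") is None
        assert grantham("*", "L") is None


def _keys(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "from", "to"])


class TestAssemble:
    def test_builtins_only(self):
        g = Genome({"chr1": "ACGTACGTAC"})
        keys = _keys([("chr1", 3, "G", "A"), ("chr1", 5, "A", "T")])
        specs = [
            FeatureSpec("gc", "gc_fraction", "numeric"),
            FeatureSpec("refb", "ref_base", "categorical", levels=tuple("ACGT")),
        ]
        rec = assemble_features(keys, specs, {}, g, context_window=2)
        assert list(rec.columns) == ["gc", "refb"]
        assert rec["refb"].tolist() == ["G", "A"]

    def test_track_joining_and_missing(self, tmp_path):
        g = Genome({"chr1": "ACGTACGTAC"})
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t2\t5\tstate1\n")
        track = load_track(bed, "bed", "state", "categorical", genome=g)
        keys = _keys([("chr1", 3, "G", "A"), ("chr1", 9, "A", "T")])
        specs = [
            FeatureSpec("state", "state", "categorical", levels=("state1", "state2"))
        ]
        rec = assemble_features(keys, specs, {"state": track}, g)
        assert rec["state"].tolist()[0] == "state1"
        assert rec["state"].tolist()[1] is None   # outside every interval

    def test_unknown_source_is_config_error(self):
        g = Genome({"chr1": "ACGT"})
        with pytest.raises(FeatureError, match="nosuch"):
            assemble_features(
                _keys([("chr1", 1, "A", "C")]),
                [FeatureSpec("x", "nosuch", "numeric")],
                {},
                g,
            )


class TestEncodeImpute:
    def test_no_missing_values_matrix_equals_raw(self):
        records = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        specs = [FeatureSpec("a", "a", "numeric", imputation="fixed", fixed_value=0.0)]
        fm = encode_and_impute(records, specs, labels=np.array([0, 1, 1]))
        assert fm.column_names == ["a"]
        assert np.array_equal(fm.X[:, 0], [1.0, 2.0, 3.0])
        assert fm.imputation_stats == {}

    def test_mean_uses_only_simulated_rows(self):
        records = pd.DataFrame(
            {"a": [np.nan, 100.0, 1.0, 2.0, 3.0, np.nan]}
        )
        labels = np.array([0, 0, 1, 1, 1, 1])
        specs = [FeatureSpec("a", "a", "numeric", imputation="mean_from_simulated")]
        fm = encode_and_impute(records, specs, labels)
        # simulated-class values are {1,2,3}; the derived 100.0 must not leak
        assert fm.imputation_stats["a"] == pytest.approx(2.0)
        assert fm.X[0, 0] == pytest.approx(2.0)
        assert fm.X[5, 0] == pytest.approx(2.0)

    def test_mean_with_no_simulated_values_is_an_error(self):
        records = pd.DataFrame({"a": [1.0, np.nan]})
        labels = np.array([0, 1])
        specs = [FeatureSpec("a", "a", "numeric", imputation="mean_from_simulated")]
        with pytest.raises(FeatureError, match="simulated"):
            encode_and_impute(records, specs, labels)

    def test_indicator_imputation(self):
        records = pd.DataFrame({"a": [5.0, np.nan]})
        specs = [FeatureSpec("a", "a", "numeric", imputation="indicator")]
        fm = encode_and_impute(records, specs, labels=np.array([0, 1]))
        assert fm.column_names == ["a", "a__missing"]
        assert fm.X.tolist() == [[5.0, 0.0], [0.0, 1.0]]

    def test_one_hot_groups_sum_to_one_or_flag_missing(self):
        records = pd.DataFrame({"c": ["x", "y", None, "unseen"]})
        specs = [FeatureSpec("c", "c", "categorical", levels=("x", "y", "z"))]
        fm = encode_and_impute(records, specs, labels=np.zeros(4, dtype=int))
        assert fm.column_names == ["c=x", "c=y", "c=z", "c__missing"]
        onehot = fm.X[:, :3].sum(axis=1)
        flag = fm.X[:, 3]
        assert onehot.tolist() == [1, 1, 0, 0]
        assert flag.tolist() == [0, 0, 1, 1]

    def test_column_count_formula(self):
        specs = [
            FeatureSpec("n1", "n1", "numeric", imputation="indicator"),
            FeatureSpec("n2", "n2", "numeric", imputation="fixed", fixed_value=1.0),
            FeatureSpec("c1", "c1", "categorical", levels=("a", "b", "c")),
        ]
        records = pd.DataFrame({"n1": [1.0], "n2": [2.0], "c1": ["a"]})
        fm = encode_and_impute(records, specs, labels=None)
        # numeric(1+1 indicator) + numeric(1) + categorical(3+1 indicator)
        assert fm.X.shape[1] == 2 + 1 + 4

    def test_encoding_is_deterministic(self):
        rng = np.random.default_rng(0)
        records = pd.DataFrame(
            {"a": rng.normal(size=50), "c": rng.choice(["x", "y"], size=50)}
        )
        records.loc[3, "a"] = np.nan
        specs = [
            FeatureSpec("a", "a", "numeric", imputation="mean_from_simulated"),
            FeatureSpec("c", "c", "categorical", levels=("x", "y")),
        ]
        labels = (rng.random(50) < 0.5).astype(int)
        fm1 = encode_and_impute(records, specs, labels)
        fm2 = encode_and_impute(records, specs, labels)
        assert np.array_equal(fm1.X, fm2.X)

    def test_scoring_reuses_training_stats(self):
        train_records = pd.DataFrame({"a": [1.0, 3.0, np.nan]})
        labels = np.array([0, 1, 1])
        specs = [FeatureSpec("a", "a", "numeric", imputation="mean_from_simulated")]
        fm = encode_and_impute(train_records, specs, labels)
        assert fm.imputation_stats["a"] == pytest.approx(3.0)
        score_records = pd.DataFrame({"a": [np.nan, 50.0]})
        scored = encode_and_impute(
            score_records, specs, labels=None, stats=fm.imputation_stats
        )
        # the missing cell takes the TRAINING mean, not anything local
        assert scored.X[0, 0] == pytest.approx(3.0)
        assert scored.X[1, 0] == 50.0

    def test_categorical_rejects_mean_imputation(self):
        with pytest.raises(FeatureError, match="indicator"):
            FeatureSpec("c", "c", "categorical", imputation="mean_from_simulated",
                        levels=("a",))
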