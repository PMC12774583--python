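"""SNV enumeration, raw scoring, PHRED scaling and score-table I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caddforge.genome import Genome
from caddforge.model import TrainedModel
from caddforge.scoring import (
    ScoreTable,
    ScoringError,
    enumerate_snvs,
    phred_scale,
    raw_score,
    read_scores,
    write_scores,
)


def _collect(genome, region=None, **kw):
    frames = list(enumerate_snvs(genome, region, **kw))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


class TestEnumerate:
    def test_single_base_genome(self):
        df = _collect(Genome({"chr1": "A"}))
        assert df[["pos", "from", "to"]].values.tolist() == [
            [1, "A", "C"], [1, "A", "G"], [1, "A", "T"],
        ]

    def test_n_bases_are_skipped(self):
        df = _collect(Genome({"chr1": "ACGTNNACGT"}))
        assert len(df) == 3 * 8

    def test_region_restriction(self):
        df = _collect(Genome({"chr1": "ACGTACGTAC"}), region=("chr1", 5, 7))
        assert len(df) == 9
        assert df["pos"].min() == 5 and df["pos"].max() == 7

    def test_order_is_deterministic_across_chunks(self):
        g = Genome({"chr1": "ACGTACGTACGTACGT"})
        small = _collect(g, chunk_size=3)
        big = _collect(g, chunk_size=1000)
        assert small.equals(big)

    def test_bad_region(self):
        with pytest.raises(ScoringError):
            _collect(Genome({"chr1": "ACGT"}), region=("chr1", 2, 9))


class TestRawScore:
    def _model(self, w, b):
        w = np.asarray(w, dtype=float)
        return TrainedModel(
            column_names=[f"f{j}" for j in range(len(w))],
            weights=w, intercept=b, l2=0.1, max_iter=100, converged=True,
        )

    def test_zero_model_scores_zero(self):
        model = self._model([0.0, 0.0], 0.0)
        assert raw_score(model, np.array([[3.0, -1.0]]))[0] == 0.0

    def test_linear_arithmetic(self):
        model = self._model([2.0], -1.0)
        assert raw_score(model, np.array([[3.0]]))[0] == 5.0

    def test_monotone_in_positive_weight_feature(self):
        model = self._model([1.5, -0.5], 0.2)
        xs = np.linspace(-5, 5, 50)
        scores = raw_score(model, np.column_stack([xs, np.zeros(50)]))
        assert np.all(np.diff(scores) > 0)

    def test_column_mismatch_is_an_error(self):
        model = self._model([1.0], 0.0)
        with pytest.raises(Exception, match="columns"):
            model.decision_values(np.ones((2, 3)))


class TestPhredScale:
    def test_analytic_identities(self):
        scores = np.arange(1000, dtype=float)       # distinct raw scores
        phred = phred_scale(scores)
        # lowest-ranked variant (i = N) scores exactly 0
        assert phred[np.argmin(scores)] == 0.0
        # top rank of N=1000 scores -10*log10(1/1000) = 30
        assert phred[np.argmax(scores)] == pytest.approx(30.0)
        # full identity: sorted descending, phred_i = -10 log10(i/N)
        expected = -10 * np.log10(np.arange(1, 1001) / 1000)
        assert np.allclose(np.sort(phred)[::-1], expected)

    def test_all_ties_share_one_value(self):
        phred = phred_scale(np.full(7, 3.14))
        assert np.all(phred == phred[0])
        # min-rank tie policy: the shared rank is 1
        assert phred[0] == pytest.approx(-10 * np.log10(1 / 7))

    def test_tie_groups_get_min_rank(self):
        phred = phred_scale(np.array([5.0, 5.0, 1.0]))
        assert phred[0] == phred[1] == pytest.approx(-10 * np.log10(1 / 3))
        assert phred[2] == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=500)
        phred = phred_scale(scores)
        assert phred.min() == 0.0
        assert phred.max() == pytest.approx(10 * np.log10(500))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ScoringError):
            phred_scale(np.array([]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=64)
        assert np.allclose(
            phred_scale(scores), phred_scale(np.tanh(scores) * 5 + 2)
        )

    def test_matches_explicit_sort_on_small_input(self):
        """Rank-then-emit equals an explicit in-memory sort."""
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 10, size=40).astype(float)
        phred = phred_scale(scores)
        order = np.argsort(-scores, kind="stable")
        expected = np.empty(40)
        rank_of = {}
        for rank, idx in enumerate(order, start=1):
            key = scores[idx]
            rank_of.setdefault(key, rank)           # min rank per tie group
            expected[idx] = -10 * np.log10(rank_of[key] / 40)
        assert np.allclose(phred, expected)


class TestScoreIO:
    def _table(self):
        rows = pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "pos": [1, 1, 1, 2, 2, 2],
                "ref": ["A"] * 3 + ["C"] * 3,
                "alt": ["C", "G", "T", "A", "G", "T"],
                "raw_score": [0.5, 1.5, -0.25, 2.0, 0.0, 1.0],
            }
        )
        rows["phred"] = phred_scale(rows["raw_score"].to_numpy())
        return ScoreTable(rows=rows, region_label="chr1:1-2")

    def test_round_trip_to_printed_precision(self, tmp_path):
        table = self._table()
        path = tmp_path / "scores.tsv"
        write_scores(table, path)
        again = read_scores(path)
        assert again.region_label == "chr1:1-2"
        assert len(again.rows) == 6
        assert np.allclose(again.rows["phred"], table.rows["phred"], atol=5e-4)
        assert again.rows["alt"].tolist() == table.rows["alt"].tolist()

    def test_line_count_includes_headers(self, tmp_path):
        path = tmp_path / "scores.tsv"
        write_scores(self._table(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 6 + 2          # rank-set line + column header

    def test_empty_table_writes_headers_only(self, tmp_path):
        empty = ScoreTable(
            rows=pd.DataFrame(
                columns=["chrom", "pos", "ref", "alt", "raw_score", "phred"]
            ),
            region_label="genome",
        )
        path = tmp_path / "scores.tsv"
        write_scores(empty, path)
        assert len(path.read_text().splitlines()) == 2

    def test_unsorted_table_is_rejected(self, tmp_path):
        table = self._table()
        table.rows = table.rows.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ScoringError, match="sorted"):
            write_scores(table, tmp_path / "x.tsv")
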