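"""Filtering and descriptive repertoire statistics."""

import math

import numpy as np
import pytest

from tcrtrack import diversity as div
from tcrtrack.errors import EmptyRepertoireError, ParameterError
from tests.conftest import make_table


class TestFilter:
    def test_threshold_is_inclusive_at_min_count(self):
        t = make_table([
            ("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 9),
            ("TRB", "TRBV9", "TRBJ1-1", "CASSCCCCCF", 10),
        ])
        out = div.filter_clonotypes(t, 10)
        assert list(out.df["cdr3_aa"]) == ["CASSCCCCCF"]

    def test_rows_aggregate_before_thresholding(self):
        t = make_table([
            ("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 6),
            ("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 5),
        ])
        out = div.filter_clonotypes(t, 10)
        assert out.n_clonotypes == 1
        assert out.df["count"].iloc[0] == 11

    def test_min_count_one_only_aggregates(self, trb_table):
        out = div.filter_clonotypes(trb_table, 1)
        assert out.n_clonotypes == trb_table.n_clonotypes

    def test_min_count_below_one_rejected(self, trb_table):
        with pytest.raises(ParameterError):
            div.filter_clonotypes(trb_table, 0)

    def test_raising_min_count_never_increases_richness(self, trb_table):
        rich = [
            div.filter_clonotypes(trb_table, mc).n_clonotypes
            for mc in (1, 5, 10, 20)
        ]
        assert rich == sorted(rich, reverse=True)


class TestShannon:
    def test_single_clonotype_has_zero_diversity(self):
        t = make_table([("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 50)])
        assert div.shannon_diversity(t) == 0.0

    @pytest.mark.parametrize("k", [2, 5, 17])
    def test_uniform_distribution_gives_log_k(self, k):
        rows = [("TRB", "TRBV9", "TRBJ1-1", f"CASS{'A' * i}QYF", 7)
                for i in range(1, k + 1)]
        assert div.shannon_diversity(make_table(rows)) == pytest.approx(math.log(k))

    def test_counts_10_5_5(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397
        t = make_table([
            ("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 10),
            ("TRB", "TRBV9", "TRBJ1-1", "CASSCCCCCF", 5),
            ("TRB", "TRBV9", "TRBJ1-1", "CASSDDDDDF", 5),
        ])
        assert div.shannon_diversity(t) == pytest.approx(1.0397, abs=1e-4)

    def test_base_option_rescales(self, trb_table):
        h_nats = div.shannon_diversity(trb_table)
        h_bits = div.shannon_diversity(trb_table, base=2)
        assert h_bits == pytest.approx(h_nats / math.log(2))

    def test_empty_table_is_error(self):
        with pytest.raises(EmptyRepertoireError):
            div.shannon_diversity(make_table([]))


class TestOccupancy:
    def test_saturates_below_n(self):
        t = make_table([("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 50)])
        assert div.top_n_occupancy(t, 10) == 100.0

    def test_uniform_20_top10_is_half(self):
        rows = [("TRB", "TRBV9", "TRBJ1-1", f"CASS{'A' * i}QYF", 3)
                for i in range(1, 21)]
        assert div.top_n_occupancy(make_table(rows), 10) == pytest.approx(50.0)

    def test_counts_50_30_20_top2(self):
        t = make_table([
            ("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 50),
            ("TRB", "TRBV9", "TRBJ1-1", "CASSCCCCCF", 30),
            ("TRB", "TRBV9", "TRBJ1-1", "CASSDDDDDF", 20),
        ])
        assert div.top_n_occupancy(t, 2) == pytest.approx(80.0)

    def test_n_below_one_rejected(self, trb_table):
        with pytest.raises(ParameterError):
            div.top_n_occupancy(trb_table, 0)


class TestVJUsage:
    def test_single_rearrangement(self):
        rows = [("TRB", "TRBV27", "TRBJ2-1", f"CASS{'A' * i}QYF", 5)
                for i in range(1, 4)]
        usage = div.vj_usage(make_table(rows))
        assert usage.n_v == 1 and usage.n_vj == 1
        assert usage.matrix.loc["TRBV27", "TRBJ2-1"] == pytest.approx(1.0)

    def test_two_by_two_uniform(self):
        rows = [
            ("TRB", v, j, f"CASS{v[-1]}{j[-1]}AAQYF", 9)
            for v in ("TRBV9", "TRBV27")
            for j in ("TRBJ1-1", "TRBJ2-1")
        ]
        usage = div.vj_usage(make_table(rows))
        assert np.allclose(usage.matrix.to_numpy(), 0.25)
        assert usage.n_vj == 4

    def test_marginals_are_row_and_column_sums(self, trb_table):
        usage = div.vj_usage(trb_table)
        assert np.allclose(usage.v_marginal, usage.matrix.sum(axis=1))
        assert np.allclose(usage.j_marginal, usage.matrix.sum(axis=0))
        assert usage.matrix.to_numpy().sum() == pytest.approx(1.0)

    def test_count_weighting_differs_when_counts_skewed(self):
        rows = [
            ("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 90),
            ("TRB", "TRBV27", "TRBJ2-1", "CASSCCCCCF", 10),
        ]
        t = make_table(rows)
        by_clone = div.vj_usage(t, weight="clonotype")
        by_count = div.vj_usage(t, weight="count")
        assert by_clone.matrix.loc["TRBV9", "TRBJ1-1"] == pytest.approx(0.5)
        assert by_count.matrix.loc["TRBV9", "TRBJ1-1"] == pytest.approx(0.9)


class TestSharedCdr3:
    def _tables(self):
        a = make_table([("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 9),
                        ("TRB", "TRBV9", "TRBJ1-1", "CASSCCCCCF", 9)],
                       sample_id="a")
        b = make_table([("TRB", "TRBV27", "TRBJ2-1", "CASSCCCCCF", 9),
                        ("TRB", "TRBV9", "TRBJ1-1", "CASSDDDDDF", 9)],
                       sample_id="b")
        c = make_table([("TRB", "TRBV9", "TRBJ1-1", "CASSCCCCCF", 9)],
                       sample_id="c")
        return a, b, c

    def test_three_way_shared_sequence(self):
        mat = div.pairwise_shared_cdr3(self._tables(), "TRB")
        assert mat.loc["a", "a"] == 2
        assert mat.loc["a", "b"] == mat.loc["b", "a"] == 1
        assert mat.loc["a", "c"] == mat.loc["b", "c"] == 1

    def test_disjoint_repertoires_share_nothing(self):
        a = make_table([("TRB", "TRBV9", "TRBJ1-1", "CASSAAAAAF", 9)], sample_id="a")
        b = make_table([("TRB", "TRBV9", "TRBJ1-1", "CASSEEEEEF", 9)], sample_id="b")
        mat = div.pairwise_shared_cdr3([a, b], "TRB")
        assert mat.loc["a", "b"] == 0

    def test_overlap_bounded_by_diagonal(self):
        mat = div.pairwise_shared_cdr3(self._tables(), "TRB")
        for i in mat.index:
            for j in mat.columns:
                if i != j:
                    assert mat.loc[i, j] <= min(mat.loc[i, i], mat.loc[j, j])

    def test_chain_mismatch_rejected(self):
        a = make_table([("TRA", "TRAV1", "TRAJ4", "CAASAAAAF", 9)], sample_id="a")
        b = make_table([("TRB", "TRBV9", "TRBJ1-1", "CASSEEEEEF", 9)], sample_id="b")
        with pytest.raises(ParameterError):
            div.pairwise_shared_cdr3([a, b], "TRB")


def test_statistics_invariant_to_row_order(trb_table):
    shuffled = trb_table.with_df(
        trb_table.df.sample(frac=1, random_state=7).reset_index(drop=True)
    )
    assert div.shannon_diversity(shuffled) == pytest.approx(
        div.shannon_diversity(trb_table)
    )
    assert div.top_n_occupancy(shuffled, 2) == pytest.approx(
        div.top_n_occupancy(trb_table, 2)
    )
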