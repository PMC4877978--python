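import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import finebin as fb
from finebin.grouped import GroupedDataError


class TestGroupedCounts:
    def test_invariants_enforced(self):
        with pytest.raises(GroupedDataError):
            fb.GroupedCounts([0, 5, 5], [1, 2])  # non-increasing edges
        with pytest.raises(GroupedDataError):
            fb.GroupedCounts([0, 5, 10], [1, -2])  # negative count
        with pytest.raises(GroupedDataError):
            fb.GroupedCounts([0, 5], [1, 2])  # length mismatch

    def test_totals_and_widths(self, toy_gc):
        assert toy_gc.total_n == 30
        assert toy_gc.widths.tolist() == [5, 5]


class TestReadGrouped:
    def test_reads_sorted_contiguous_rows(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("age_low,age_high,count\n5,10,20\n0,5,10\n")
        gc = fb.read_grouped(p)
        assert gc.edges.tolist() == [0, 5, 10]
        assert gc.counts.tolist() == [10, 20]

    def test_gap_names_offending_row(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("age_low,age_high,count\n0,5,3\n6,10,4\n")
        with pytest.raises(GroupedDataError, match="row 1"):
            fb.read_grouped(p)

    def test_open_ended_label_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("age_low,age_high,count\n80,85,3\n85,85+,4\n")
        with pytest.raises(GroupedDataError, match="85\\+"):
            fb.read_grouped(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("age_low,age_high,count\n0,5,3\n5,10,-1\n")
        with pytest.raises(GroupedDataError, match="negative"):
            fb.read_grouped(p)

    def test_open_ended_scheme_unequal_widths(self, tmp_path):
        # 17 five-year classes to 85, the closed 85+ group, a zero closing bin
        rows = [f"{5*i},{5*i+5},{i + 1}" for i in range(17)]
        rows += ["85,115,7", "115,130,0"]
        p = tmp_path / "b.csv"
        p.write_text("age_low,age_high,count\n" + "\n".join(rows))
        gc = fb.read_grouped(p)
        assert gc.nbins == 19
        assert gc.widths.tolist() == [5.0] * 17 + [30.0, 15.0]


class TestClosingInterval:
    def test_appends_zero_count_bin(self):
        gc = fb.GroupedCounts([105, 110, 115], [4, 2])
        out = fb.append_closing_interval(gc, 130)
        assert out.edges[-1] == 130 and out.counts[-1] == 0
        assert out.total_n == gc.total_n
        np.testing.assert_array_equal(out.counts[:-1], gc.counts)

    def test_empty_interval_rejected(self):
        gc = fb.GroupedCounts([0, 115], [5])
        with pytest.raises(ValueError):
            fb.append_closing_interval(gc, 115)


class TestGroupSample:
    def test_half_open_convention(self):
        gc = fb.group_sample([1.2, 4.9, 5.0], [0, 5, 10])
        assert gc.counts.tolist() == [2, 1]

    def test_empty_values(self):
        gc = fb.group_sample([], [0, 5, 10])
        assert gc.counts.tolist() == [0, 0]
        assert gc.total_n == 0

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError):
            fb.group_sample([11.0], [0, 5, 10])

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        values = fb.sample_weibull(1000, seed=rng)
        edges = fb.scheme_edges("B")
        gc = fb.group_sample(values, edges)
        # independent per-value linear scan
        oracle = np.zeros(len(edges) - 1)
        for v in values:
            for i in range(len(edges) - 1):
                if edges[i] <= v < edges[i + 1]:
                    oracle[i] += 1
                    break
        np.testing.assert_array_equal(gc.counts, oracle)
        assert gc.total_n == 1000


class TestHistogramDensity:
    def test_hand_values(self, toy_gc):
        np.testing.assert_allclose(fb.histogram_density(toy_gc), [10 / 150, 20 / 150])
        single = fb.GroupedCounts([0, 10], [7])
        np.testing.assert_allclose(fb.histogram_density(single), [0.1])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fb.histogram_density(fb.GroupedCounts([0, 5], [0]))

    def test_integrates_to_one(self, random_grouped):
        rng = np.random.default_rng(3)
        for _ in range(50):
            gc = random_grouped(rng)
            integral = float(fb.histogram_density(gc) @ gc.widths)
            assert abs(integral - 1.0) < 1e-12


class TestCumulativeKnots:
    def test_hand_values(self, toy_gc):
        x, y = fb.cumulative_knots(toy_gc)
        assert x.tolist() == [0, 5, 10]
        assert y.tolist() == [0, 10, 30]

    def test_flat_tail_shares_final_value(self):
        gc = fb.append_closing_interval(fb.GroupedCounts([0, 115], [9]), 130)
        _, y = fb.cumulative_knots(gc)
        assert y[-1] == y[-2] == 9

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=10))
    def test_differencing_round_trip(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        edges = np.arange(len(counts) + 1) * 5.0
        gc = fb.GroupedCounts(edges, counts)
        _, y = fb.cumulative_knots(gc)
        np.testing.assert_array_equal(np.diff(y), gc.counts)


class TestWriteFine:
    def test_round_trip(self, tmp_path, toy_gc):
        est = fb.ungroup_by_interpolation(toy_gc, variant="pchip")
        out = tmp_path / "fine.csv"
        fb.write_fine(est, out)
        text = out.read_text()
        assert text.startswith("# method=pchip")
        import pandas as pd

        df = pd.read_csv(out, comment="#")
        assert len(df) == est.grid.J
        np.testing.assert_allclose(df["count"], est.gamma)
        assert abs(df["density"].sum() - est.gamma.sum() / toy_gc.total_n) < 1e-12
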