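"""Quality filters, normalizations and the log2 transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcna.io_counts import BinGrid, CountMatrix
from cellcna.preprocess import (LRC_FLOOR, filter_bins_by_tracks,
                                filter_cells_by_gini, filter_extreme_bins,
                                gini_coefficient, library_size_normalize,
                                median_normalize, preprocess, to_lrc)
from cellcna.simulate import make_bingrid, simulate_counts, simulate_tree


def _grid(gc, mappability):
    n = len(gc)
    return BinGrid(np.array(["chr1"] * n), np.arange(n) * 200_000,
                   (np.arange(n) + 1) * 200_000, np.asarray(gc, float),
                   np.asarray(mappability, float), 200_000)


class TestTrackFilter:
    def test_all_clean_bins_pass(self):
        bg = _grid([0.5] * 4, [1.0] * 4)
        cm = CountMatrix(np.ones((2, 4), dtype=int), ["a", "b"], bg)
        out, report = filter_bins_by_tracks(cm)
        assert out.n_bins == 4 and not report.removed_bins

    @pytest.mark.parametrize("gc,mp,reason", [
        ([0.05, 0.5, 0.5], [1, 1, 1], "gc_low"),
        ([0.5, 0.95, 0.5], [1, 1, 1], "gc_high"),
        ([0.5, 0.5, 0.5], [1, 0.5, 1], "mappability"),
    ])
    def test_each_threshold_removes_with_its_reason(self, gc, mp, reason):
        cm = CountMatrix(np.ones((1, 3), dtype=int), ["a"], _grid(gc, mp))
        out, report = filter_bins_by_tracks(cm)
        assert out.n_bins == 2
        assert len(report.removed_bins) == 1
        assert report.removed_bins[0][1] == reason

    def test_all_bins_removed_is_an_error(self):
        cm = CountMatrix(np.ones((1, 2), dtype=int),
                         ["a"], _grid([0.01, 0.02], [1, 1]))
        with pytest.raises(ValueError, match="no bins survive"):
            filter_bins_by_tracks(cm)


class TestLibrarySize:
    @pytest.mark.parametrize("row,expected", [
        ([2, 2, 2], [1, 1, 1]),
        ([1, 2, 3], [0.5, 1.0, 1.5]),
    ])
    def test_rows_divide_by_their_mean(self, row, expected):
        out = library_size_normalize(np.array([row], dtype=float), ["c"])
        assert np.allclose(out[0], expected)

    def test_every_row_mean_becomes_one(self, rng):
        counts = rng.integers(1, 50, size=(5, 30)).astype(float)
        out = library_size_normalize(counts, [f"c{i}" for i in range(5)])
        assert np.allclose(out.mean(axis=1), 1.0)

    def test_zero_mean_cell_is_an_error(self):
        with pytest.raises(ValueError, match="dead"):
            library_size_normalize(np.array([[0, 0], [1, 1]], dtype=float),
                                   ["dead", "ok"])


class TestExtremeBinFilter:
    def test_identical_means_remove_nothing(self):
        bg = _grid([0.5] * 100, [1.0] * 100)
        norm = np.ones((3, 100))
        out, bg2, _ = filter_extreme_bins(norm, bg, q=0.01)
        assert out.shape[1] >= 98  # ties at the boundary are kept

    def test_strict_quantile_cut_removes_extremes(self):
        bg = _grid([0.5] * 100, [1.0] * 100)
        norm = np.tile(np.arange(1.0, 101.0), (2, 1))
        out, bg2, report = filter_extreme_bins(norm, bg, q=0.01)
        removed = {idx for idx, _ in report.removed_bins}
        assert removed == {0, 99}  # means 1 and 100

    def test_q_zero_removes_nothing(self):
        bg = _grid([0.5] * 10, [1.0] * 10)
        norm = np.tile(np.arange(10.0), (2, 1))
        out, _, _ = filter_extreme_bins(norm, bg, q=0.0)
        assert out.shape[1] == 10


class TestGini:
    @pytest.mark.parametrize("row,expected", [
        ([1, 1, 1, 1], 0.0),
        ([0, 0, 0, 4], 0.75),
        ([0, 4], 0.5),
    ])
    def test_known_values(self, row, expected):
        assert gini_coefficient(np.array(row, float)) == pytest.approx(expected)

    def test_matches_pairwise_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 10, size=rng.integers(2, 40))
            if x.sum() == 0:
                continue
            n = len(x)
            brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())
            assert gini_coefficient(x) == pytest.approx(brute, abs=1e-12)

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30),
           st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, xs, a):
        x = np.array(xs)
        assert gini_coefficient(a * x) == pytest.approx(gini_coefficient(x),
                                                        rel=1e-9)

    def test_all_zero_row_is_an_error(self):
        with pytest.raises(ValueError):
            gini_coefficient(np.zeros(4))


class TestGiniCellFilter:
    def test_uniform_cells_survive(self):
        norm = np.ones((3, 8))
        out, ids, report = filter_cells_by_gini(norm, list("abc"),
                                                np.ones((3, 8)))
        assert ids == list("abc") and not report.removed_cells

    def test_concentrated_cell_is_removed_with_its_gini(self):
        raw = np.vstack([np.ones(4), np.array([0, 0, 0, 4.0])])
        norm = raw.copy()
        out, ids, report = filter_cells_by_gini(norm, ["ok", "bad"], raw)
        assert ids == ["ok"]
        assert report.removed_cells[0][0] == "bad"
        assert report.removed_cells[0][1] == pytest.approx(0.75)

    def test_vacuous_threshold_removes_nobody(self):
        raw = np.vstack([np.ones(4), np.array([0, 0, 0, 4.0])])
        out, ids, _ = filter_cells_by_gini(raw, ["a", "b"], raw, threshold=1.0)
        assert ids == ["a", "b"]


class TestMedianNormalize:
    def test_single_stratum_is_identity(self):
        bg = _grid([0.5] * 6, [1.0] * 6)
        norm = np.array([[1.0, 2, 3, 4, 5, 6]])
        assert np.allclose(median_normalize(norm, bg), norm)

    def test_two_strata_rescale_by_their_medians(self):
        # stratum A (gc 0.30) has median 0.5, stratum B (gc 0.70) median 2.0
        bg = _grid([0.3, 0.3, 0.3, 0.7, 0.7, 0.7], [1.0] * 6)
        row = np.array([[0.4, 0.5, 0.6, 1.9, 2.0, 2.1]])
        out = median_normalize(row, bg)
        m = np.median(row)
        assert np.allclose(out[0, :3], row[0, :3] * m / 0.5)
        assert np.allclose(out[0, 3:], row[0, 3:] * m / 2.0)

    def test_direct_formula_value(self):
        # r_k = 100 with cell median 50 and stratum median 100 -> 50
        bg = _grid([0.3] * 3 + [0.7] * 2, [1.0] * 5)
        row = np.array([[30.0, 50.0, 40.0, 100.0, 100.0]])
        out = median_normalize(row, bg)
        assert out[0, 3] == pytest.approx(100.0 * 50.0 / 100.0)


class TestLRC:
    @pytest.mark.parametrize("value,expected", [
        (1.0, 0.0), (2.0, 1.0), (0.0, np.log2(LRC_FLOOR)),
    ])
    def test_log2_with_floor(self, value, expected, small_bingrid):
        lrc = to_lrc(np.full((1, 3), value), ["c"], small_bingrid)
        assert lrc.lrc[0, 0] == pytest.approx(expected)


def test_pipeline_lrc_mean_tracks_copy_ratio():
    """Unbiased simulated counts give LRC ~ log2(c/ploidy) per region."""
    bg = make_bingrid({"chr1": 30_000_000, "chr2": 30_000_000}, bin_size=200_000)
    tree = simulate_tree(1, ploidy=2, bingrid=bg, seed=7)
    cm, gt = simulate_counts(tree, 40, depth_mean=200.0, normal_fraction=0.0,
                             seed=8)
    lrc, report = preprocess(cm)
    col_of = {lab: k for k, lab in enumerate(cm.bingrid.labels())}
    keep = np.array([col_of[lab] for lab in lrc.bingrid.labels()])
    row_of = {c: i for i, c in enumerate(cm.cell_ids)}
    rows = np.array([row_of[c] for c in lrc.cell_ids])
    cn = gt.cn[np.ix_(rows, keep)]
    for c in np.unique(cn):
        sel = cn == c
        expected = np.log2(0.5 * c) - np.log2(0.5 * gt.acn()[rows].mean())
        assert np.mean(lrc.lrc[sel]) == pytest.approx(expected, abs=0.05)


def test_preprocess_logs_every_removal(rng):
    bg = make_bingrid({"chr1": 10_000_000}, bin_size=200_000,
                      gc=np.r_[0.05, np.full(49, 0.5)])
    tree = simulate_tree(1, ploidy=2, bingrid=bg, seed=1,
                         events_per_edge=(0, 0))
    cm, _ = simulate_counts(tree, 10, seed=2, normal_fraction=0.0)
    lrc, report = preprocess(cm)
    removed = cm.n_bins - lrc.n_bins
    assert removed == len(report.removed_bins)
    reasons = {r for _, r in report.removed_bins}
    assert "gc_low" in reasons
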