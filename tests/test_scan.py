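"""Kernel-smoothed window scan and PCA outlier test."""

import numpy as np
import pandas as pd
import pytest

from ciscopop import scan as cscan
from ciscopop.genotypes import LocusTable
from ciscopop.sim import make_planted_island_genome
from ciscopop.stats import wc_fst

from conftest import random_biallelic


def simple_map(cms, lg="LG1"):
    return LocusTable.simple(
        [f"l{j}" for j in range(len(cms))],
        linkage_groups=[lg] * len(cms), cm=cms,
    )


class TestSmoothing:
    def test_single_locus_at_center(self):
        loci = simple_map([10.0])
        res = cscan.smooth_windows(np.array([0.42]), loci)
        row = res.windows[res.windows.center_cM == 10.0].iloc[0]
        assert row.smoothed == pytest.approx(0.42)
        assert row.n_loci == 1

    def test_constant_statistic_everywhere(self, rng):
        cms = rng.uniform(0, 50, 80)
        res = cscan.smooth_windows(np.full(80, 0.1), simple_map(cms))
        np.testing.assert_allclose(res.windows.smoothed, 0.1, atol=1e-12)

    def test_two_equidistant_loci_average(self):
        loci = simple_map([9.0, 11.0])
        res = cscan.smooth_windows(np.array([0.2, 0.6]), loci)
        row = res.windows[res.windows.center_cM == 10.0].iloc[0]
        assert row.smoothed == pytest.approx(0.4)

    def test_order_invariance(self, rng):
        cms = rng.uniform(0, 30, 40)
        stat = rng.random(40)
        a = cscan.smooth_windows(stat, simple_map(cms))
        perm = rng.permutation(40)
        b = cscan.smooth_windows(stat[perm], simple_map(cms[perm]))
        pd.testing.assert_frame_equal(
            a.windows.sort_values("center_cM").reset_index(drop=True),
            b.windows.sort_values("center_cM").reset_index(drop=True),
        )

    def test_wider_sigma_flattens_surface(self, rng):
        cms = np.sort(rng.uniform(0, 50, 120))
        stat = rng.random(120)
        narrow = cscan.smooth_windows(stat, simple_map(cms), sigma=0.5)
        wide = cscan.smooth_windows(stat, simple_map(cms), sigma=2.5)
        assert wide.windows.smoothed.var() < narrow.windows.smoothed.var()


class TestWindowSignificance:
    def test_single_locus_window_never_significant(self, rng):
        # one extreme locus alone on its LG cannot satisfy the >= 2 rule
        loci = simple_map([5.0])
        res = cscan.smooth_windows(np.array([5.0]), loci)
        pool = np.r_[rng.random(200), 5.0]
        out = cscan.window_significance(res, pool, seed=0)
        assert not out.windows.significant.any()

    def test_null_calibration_about_one_percent(self, rng):
        # exchangeable statistics: windows beat their own null ~1% of the time
        n_sig = n_win = 0
        for s in range(12):
            r = np.random.default_rng(s)
            cms = r.uniform(0, 60, 150)
            stat = r.random(150)
            res = cscan.smooth_windows(stat, simple_map(cms))
            out = cscan.window_significance(res, stat, seed=s)
            n_sig += out.windows.significant.sum()
            n_win += len(out.windows)
        assert n_sig / n_win < 0.03

    def test_planted_island_detected(self):
        hits = 0
        for s in range(5):
            gm, island = make_planted_island_genome(
                n_loci=1000, n_lg=5, island_lg=1, island_span_cm=10,
                island_fst=0.4, background_fst=0.05, seed=100 + s,
            )
            per_locus = wc_fst(gm).per_locus
            res = cscan.smooth_windows(per_locus, gm.loci)
            out = cscan.window_significance(
                res, per_locus[np.isfinite(per_locus)], seed=s
            )
            seg = out.segments
            if seg is not None and len(seg):
                on_lg2 = seg[seg.linkage_group == "LG2"]
                span = (45.0, 55.0)
                if ((on_lg2.end_cM >= span[0]) & (on_lg2.start_cM <= span[1])).any():
                    hits += 1
        assert hits >= 4

    def test_segments_merge_adjacent_windows(self):
        win = pd.DataFrame({
            "linkage_group": ["L"] * 4,
            "center_cM": [3.0, 4.0, 9.0, 10.0],
            "n_loci": [2, 2, 2, 2],
            "smoothed": [1.0] * 4,
            "significant": [True, True, False, True],
        })
        seg = cscan._merge_segments(win, [np.array([0, 1])] * 4, step=1.0)
        assert len(seg) == 2
        assert seg.iloc[0].n_windows == 2


class TestPcaOutliers:
    def test_zero_k_rejected(self, rng):
        gm = random_biallelic(rng, n_ind=10, n_loci=20)
        with pytest.raises(ValueError):
            cscan.pca_outlier_scan(gm, 0)

    def test_null_false_positive_rate(self, rng):
        gm = random_biallelic(rng, n_ind=80, n_loci=500, n_pops=1, missing=0)
        out = cscan.pca_outlier_scan(gm, K=2, alpha=0.05)
        assert out.table.outlier.mean() <= 0.05

    def test_planted_divergent_loci_flagged(self, rng):
        gm, island = make_planted_island_genome(
            n_loci=500, island_fst=0.6, background_fst=0.02,
            island_span_cm=20, seed=4, n_per_pop=60,
        )
        out = cscan.pca_outlier_scan(gm, K=1, alpha=0.05)
        flagged = out.table.outlier.to_numpy()
        assert flagged[island].mean() > 0.5
        assert flagged[np.setdiff1d(np.arange(500), island)].mean() < 0.1


def test_top_loci_table_ranks_and_reports_frequencies(rng):
    gm, island = make_planted_island_genome(
        n_loci=1000, island_span_cm=20, island_fst=0.5,
        background_fst=0.02, seed=6,
    )
    per_locus = wc_fst(gm).per_locus
    tab = cscan.top_loci_table(gm, per_locus, n=5)
    assert len(tab) == 5
    assert (tab.stat.values == np.sort(tab.stat.values)[::-1]).all()
    assert {"freq_P1", "freq_P2"} <= set(tab.columns)
    # top-differentiation loci should overwhelmingly come from the island
    top_ids = set(tab.locus_id)
    island_ids = {gm.loci.locus_ids[i] for i in island}
    assert len(top_ids & island_ids) >= 4


def test_scan_report_counts():
    win = pd.DataFrame({
        "linkage_group": ["L1", "L1", "L2"],
        "center_cM": [1.0, 2.0, 1.0],
        "n_loci": [2, 2, 2],
        "smoothed": [1.0] * 3,
        "significant": [True, False, True],
    })
    res = cscan.WindowScanResult(windows=win)
    rep = cscan.scan_report({"overall": res})
    assert set(rep.linkage_group) == {"L1", "L2"}
    assert rep.n_significant_windows.sum() == 2
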