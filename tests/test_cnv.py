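"""Cut-site depth, unit merging, depth ratios, segmentation, CNA calls."""

import numpy as np
import pandas as pd
import pytest

from radclone import (
    CnvEventSpec,
    SampleSpec,
    SimConfig,
    call_cna,
    depth_ratio,
    detect_cna,
    merge_similar_segments,
    merge_units,
    segment_ratios,
    simulate,
    site_depths,
    process_reads,
)
from radclone.cnv import CnvSegment, CnvUnit, SegmentationParams
from radclone.locus_assign import AssignedRead


def make_units(depths, chrom="chr1", site_spacing=1000):
    return [
        CnvUnit(
            chrom,
            i,
            tuple(site_spacing * (5 * i + j) for j in range(5)),
            float(d),
        )
        for i, d in enumerate(depths)
    ]


def ratio_frame(values, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "unit_index": range(len(values)),
            "start": np.arange(len(values)) * 1000,
            "end": np.arange(len(values)) * 1000 + 900,
            "log2_ratio": values,
        }
    )


def exhaustive_changepoint(x):
    """Oracle: least-squares single-changepoint scan."""
    best_k, best_rss = None, np.inf
    for k in range(1, len(x)):
        rss = np.sum((x[:k] - x[:k].mean()) ** 2) + np.sum((x[k:] - x[k:].mean()) ** 2)
        if rss < best_rss:
            best_k, best_rss = k, rss
    return best_k


class TestSiteDepths:
    def test_perfect_match_rule(self, clean_sim):
        cat = clean_sim.catalog
        assignments = [
            AssignedRead("r1", "S", "B", cat[0].locus_id, cat[0].direction, 0, ""),
            AssignedRead("r2", "S", "B", cat[1].locus_id, cat[1].direction, 1, ""),
            AssignedRead("r3", "S", "B", "OFF_TARGET", None, 0, ""),
        ]
        table = site_depths(assignments, cat)
        # only the zero-mismatch on-target read counts
        assert table["depth"].sum() == 1

    def test_empty_input_zero_table(self, clean_sim):
        table = site_depths([], clean_sim.catalog)
        assert len(table) == len(clean_sim.catalog) // 2
        assert (table["depth"] == 0).all()

    def test_both_directions_summed_near_poisson_mean(self, clean_sim):
        sim = clean_sim  # error-free at per-locus depth 50
        results, _ = process_reads(
            sim.reads, sim.barcode_map, "SbfI", sim.catalog, sim.genome
        )
        table = site_depths(results["normal"].assignments, sim.catalog)
        mean = table["depth"].mean()
        n = len(table)
        assert abs(mean - 100) <= 3 * np.sqrt(100 / n)


class TestMergeUnits:
    def test_twelve_sites_two_units_remainder_dropped(self):
        table = pd.DataFrame(
            {"chrom": "chr1", "cut_pos": range(0, 12_000, 1000), "depth": 10.0}
        )
        units = merge_units(table, unit_size=5)
        assert len(units) == 2
        assert units[0].site_positions == (0, 1000, 2000, 3000, 4000)
        assert units[1].site_positions == (5000, 6000, 7000, 8000, 9000)
        assert all(u.mean_depth == 10.0 for u in units)

    def test_unit_means_match_brute_force(self):
        rng = np.random.default_rng(8)
        depths = rng.poisson(40, size=37)
        table = pd.DataFrame(
            {"chrom": "chr1", "cut_pos": np.arange(37) * 500, "depth": depths}
        )
        units = merge_units(table, 5)
        assert len(units) == 7
        for i, u in enumerate(units):
            assert u.mean_depth == pytest.approx(depths[5 * i : 5 * i + 5].mean())

    def test_too_few_sites_warns(self):
        table = pd.DataFrame({"chrom": "chr1", "cut_pos": [0, 1000], "depth": 5.0})
        with pytest.warns(UserWarning, match="no units"):
            assert merge_units(table, 5) == []


class TestDepthRatio:
    def test_self_ratio_zero(self):
        units = make_units([40, 42, 38, 41])
        table = depth_ratio(units, units)
        assert np.allclose(table["log2_ratio"], 0.0)

    def test_global_scaling_cancels(self):
        ref = make_units([40, 42, 38, 41])
        test = make_units([80, 84, 76, 82])
        table = depth_ratio(test, ref)
        assert np.allclose(table["log2_ratio"], 0.0)

    def test_planted_amplification_with_inflation_correction(self):
        # 2-fold gain on 2 of 20 units; totals normalization shifts the
        # baseline by log2 of the global inflation (1.1)
        base = np.full(20, 50.0)
        test = base.copy()
        test[5:7] *= 2
        table = depth_ratio(make_units(test), make_units(base))
        inflation = test.sum() / base.sum()
        assert inflation == pytest.approx(1.1)
        expected_gain = 1 - np.log2(inflation)
        assert np.allclose(table["log2_ratio"][5:7], expected_gain)
        assert np.allclose(table["log2_ratio"][:5], -np.log2(inflation))

    def test_zero_reference_units_masked(self):
        ref = make_units([40, 0, 38])
        test = make_units([40, 10, 38])
        table = depth_ratio(test, ref)
        assert np.isnan(table["log2_ratio"][1])

    def test_mismatched_structure_rejected(self):
        with pytest.raises(ValueError):
            depth_ratio(make_units([1, 2]), make_units([1, 2, 3]))

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="no unmasked"):
            depth_ratio(
                make_units([1.0, 1.0]),
                make_units([0.0, 0.0]),
                test_total=2.0,
                reference_total=10.0,
            )


class TestSegmentRatios:
    def test_constant_series_single_segment(self):
        rng = np.random.default_rng(1)
        table = ratio_frame(rng.normal(0, 0.01, 80))
        segs = segment_ratios(table, SegmentationParams(seed=5))
        assert len(segs) == 1
        assert segs[0].n_units == 80

    def test_step_series_two_segments_accurate_breakpoint(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(1.0, 0.1, 100)])
        segs = segment_ratios(ratio_frame(x), SegmentationParams(seed=5))
        assert len(segs) == 2
        assert abs((segs[0].last_unit + 1) - 100) <= 2
        assert abs(exhaustive_changepoint(x) - 100) <= 2  # oracle agrees

    def test_two_amplified_regions_recovered(self):
        # the two-amplification pattern: baseline with two elevated runs
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.1, 120)
        x[30:45] += 1.2
        x[80:95] += 1.2
        segs = segment_ratios(ratio_frame(x), SegmentationParams(seed=5))
        assert len(segs) >= 4
        high = [s for s in segs if s.mean_log2 > 0.6]
        assert len(high) == 2
        assert abs(high[0].first_unit - 30) <= 2 and abs(high[0].last_unit - 44) <= 2
        assert abs(high[1].first_unit - 80) <= 2 and abs(high[1].last_unit - 94) <= 2

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.2, 50), rng.normal(0.8, 0.2, 50)])
        a = segment_ratios(ratio_frame(x), SegmentationParams(seed=9))
        b = segment_ratios(ratio_frame(x), SegmentationParams(seed=9))
        assert a == b

    def test_accepted_splits_match_exhaustive_scan_oracle(self):
        # on short series, whenever exactly one split is accepted its
        # location equals the least-squares optimal changepoint
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = int(rng.integers(6, 31))
            k_true = int(rng.integers(2, n - 1))
            x = rng.normal(0, 0.15, n)
            if rng.random() < 0.7:
                x[k_true:] += rng.choice([-1.0, 1.0]) * 1.5
            segs = segment_ratios(ratio_frame(x), SegmentationParams(seed=7))
            if len(segs) == 2:
                assert segs[0].last_unit + 1 == exhaustive_changepoint(x)


class TestMergeSimilarSegments:
    def seg(self, first, last, mean, n, chrom="chr1"):
        return CnvSegment(chrom, first, last, mean, n)

    def test_similar_neighbors_merged(self):
        segs = [self.seg(0, 9, 0.00, 10), self.seg(10, 19, 0.05, 10)]
        merged = merge_similar_segments(segs, tol=0.3)
        assert len(merged) == 1
        assert merged[0].mean_log2 == pytest.approx(0.025)
        assert merged[0].n_units == 20

    def test_distinct_neighbors_kept(self):
        segs = [self.seg(0, 9, 0.0, 10), self.seg(10, 19, 1.0, 10)]
        assert merge_similar_segments(segs, tol=0.3) == segs

    def test_chain_merges_to_fixpoint(self):
        segs = [
            self.seg(0, 0, 0.0, 1),
            self.seg(1, 1, 0.1, 1),
            self.seg(2, 2, 0.2, 1),
            self.seg(3, 3, 1.0, 1),
        ]
        merged = merge_similar_segments(segs, tol=0.3)
        assert len(merged) == 2
        assert merged[0].mean_log2 == pytest.approx(0.1)
        assert merged[1].mean_log2 == 1.0
        # idempotent and unit-count preserving
        assert merge_similar_segments(merged, tol=0.3) == merged
        assert sum(s.n_units for s in merged) == 4

    def test_different_chromosomes_never_merged(self):
        segs = [self.seg(0, 9, 0.0, 10, "chr1"), self.seg(0, 9, 0.0, 10, "chr2")]
        assert len(merge_similar_segments(segs, tol=0.3)) == 2


class TestCallCna:
    def test_threshold_labels(self):
        segs = [
            CnvSegment("chr1", 0, 9, 1.0, 10),
            CnvSegment("chr1", 10, 19, 0.0, 10),
            CnvSegment("chr1", 20, 29, -0.9, 10),
        ]
        states = [s.state for s in call_cna(segs)]
        assert states == ["gain", "neutral", "loss"]

    def test_short_segments_never_called(self):
        segs = [CnvSegment("chr1", 0, 1, 1.5, 2)]
        assert call_cna(segs, min_units=3)[0].state == "neutral"


def cnv_sim(seed, with_gain):
    # sites are planted one per 16 kb slot; the event covers sites 100..149,
    # i.e. units 20..29 of the 50-unit series
    slot = 4_000_000 // 250
    events = (
        (CnvEventSpec(start=100 * slot, end=150 * slot, copy_ratio=2.0,
                      samples=("tumor",)),)
        if with_gain
        else ()
    )
    cfg = SimConfig(
        seed=seed,
        genome_len=4_000_000,
        n_sites=250,
        mean_depth=20,
        duplicate_fraction=0.0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        tree={"clone": ("root", 0)},
        samples={"normal": SampleSpec("root"), "tumor": SampleSpec("clone", 1.0)},
        cnv_events=events,
    )
    sim = simulate(cfg)
    results, _ = process_reads(
        sim.reads, sim.barcode_map, "SbfI", sim.catalog, sim.genome
    )
    t = site_depths(results["tumor"].assignments, sim.catalog)
    r = site_depths(results["normal"].assignments, sim.catalog)
    return sim, t, r


class TestEndToEndCna:
    def test_planted_gain_recovered_with_unit_accuracy(self):
        # single-copy gain over units 20..29 in a pure tumor (log2 ratio 1
        # before total-count normalization)
        sim, t, r = cnv_sim(seed=71, with_gain=True)
        segs, _ = detect_cna(t, r, seg_params=SegmentationParams(seed=1))
        gains = [s for s in segs if s.state == "gain"]
        assert len(gains) == 1
        g = gains[0]
        assert abs(g.first_unit - 20) <= 1 and abs(g.last_unit - 29) <= 1

    def test_normalization_invariance_of_calls(self):
        sim, t, r = cnv_sim(seed=72, with_gain=True)
        segs, _ = detect_cna(t, r, seg_params=SegmentationParams(seed=1))
        t2 = t.assign(depth=t["depth"] * 7)
        segs2, _ = detect_cna(t2, r, seg_params=SegmentationParams(seed=1))
        assert [(s.first_unit, s.last_unit, s.state) for s in segs] == [
            (s.first_unit, s.last_unit, s.state) for s in segs2
        ]

    def test_normal_vs_normal_no_calls(self):
        _, t, r = cnv_sim(seed=73, with_gain=False)
        segs, _ = detect_cna(t, r, seg_params=SegmentationParams(seed=1))
        assert all(s.state == "neutral" for s in segs)
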