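"""Pileups, tumor/normal exact-test calling, RAD curation, VAF comparisons."""

import math

import numpy as np
import pytest

from radclone import (
    CallParams,
    SampleSpec,
    SimConfig,
    build_locus_index,
    build_pileup,
    call_and_curate,
    call_somatic,
    compare_vaf_paired,
    process_reads,
    simulate,
)
from radclone.locus_assign import assign_reads
from radclone.demux import DemuxedRead
from radclone.somatic import (
    CurationParams,
    F_ASYM,
    F_SINGLE_BC,
    curation_filters,
    fisher_one_sided,
    private_variant_screen,
    write_vcf,
)

from conftest import make_locus, make_pileup


def exact_test_oracle(t_alt, t_ref, n_alt, n_ref) -> float:
    """Full hypergeometric enumeration with exact integer arithmetic."""
    N = t_alt + t_ref + n_alt + n_ref
    K = t_alt + n_alt  # total alt
    n = t_alt + t_ref  # tumor draw
    denom = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k) for k in range(t_alt, min(K, n) + 1)
    ) / denom


class TestBuildPileup:
    def test_identical_error_free_reads_all_reference(self, clean_sim):
        sim = clean_sim
        index = build_locus_index(sim.catalog, sim.genome, "SbfI")
        loc = sim.catalog[0]
        expected = index.expected_read(loc.locus_id)
        reads = [
            DemuxedRead(f"r{i}", "S", "AAAAA", expected, np.full(len(expected), 40))
            for i in range(10)
        ]
        pile = build_pileup(assign_reads(reads, index), index, "S")
        lp = pile[loc.locus_id]
        assert lp.n_reads == 10
        assert np.all(lp.depth == 10)
        offs = np.arange(loc.length)
        assert np.all(lp.counts[offs, lp.ref_codes] == 10)
        lp.validate()

    def test_zero_reads_empty_pileup(self, clean_sim):
        index = build_locus_index(clean_sim.catalog, clean_sim.genome, "SbfI")
        pile = build_pileup([], index, "S")
        assert pile.loci == {}

    def test_planted_variant_vaf_in_binomial_interval(self):
        cfg = SimConfig(
            seed=9,
            genome_len=15_000,
            n_sites=5,
            mean_depth=100,
            duplicate_fraction=0.0,
            pcr_error_rate=0.0,
            seq_error_rate=0.0,
            tree={"clone": ("root", 5)},
            samples={"normal": SampleSpec("root"), "tumor": SampleSpec("clone", 1.0)},
        )
        sim = simulate(cfg)
        results, _ = process_reads(
            sim.reads, sim.barcode_map, "SbfI", sim.catalog, sim.genome
        )
        pile = results["tumor"].pileup
        checked = 0
        for mut in sim.truth.mutations:
            for loc in sim.catalog:
                if loc.start <= mut.pos0 < loc.end and loc.locus_id in pile:
                    lp = pile[loc.locus_id]
                    off = (
                        mut.pos0 - loc.cut_pos
                        if loc.direction == "downstream"
                        else loc.cut_pos - 1 - mut.pos0
                    )
                    alt_read = (
                        mut.alt
                        if loc.direction == "downstream"
                        else {"A": "T", "C": "G", "G": "C", "T": "A"}[mut.alt]
                    )
                    depth = lp.depth[off]
                    alt = lp.counts[off, "ACGT".index(alt_read)]
                    # het in a pure tumor: VAF 0.5; 99% binomial interval
                    assert abs(alt - 0.5 * depth) <= 2.58 * math.sqrt(0.25 * depth)
                    checked += 1
        assert checked == 5


class TestFisherOneSided:
    @pytest.mark.parametrize(
        "table",
        [(30, 70, 0, 100), (5, 15, 1, 19), (0, 10, 0, 10), (4, 46, 2, 48), (10, 0, 0, 10)],
    )
    def test_matches_enumeration_oracle(self, table):
        assert fisher_one_sided(*table) == pytest.approx(
            exact_test_oracle(*table), rel=1e-12
        )


class TestCallSomatic:
    def make_pair(self, t_counts, n_counts, flank=100):
        """Pileups with one variant offset (10) and clean background depth."""
        locus = make_locus(flank=flank)
        ref = "A" * flank
        t_alt, t_ref = t_counts
        n_alt, n_ref = n_counts
        tumor = make_pileup(
            "tumor",
            locus,
            ref,
            {10: {"B1": {"C": t_alt - t_alt // 2, "A": t_ref}, "B2": {"C": t_alt // 2}}},
            base_depth=t_alt + t_ref,
        )
        normal = make_pileup(
            "normal",
            locus,
            ref,
            {10: {"B1": {"C": n_alt, "A": n_ref}}},
            base_depth=n_alt + n_ref,
        )
        return tumor, normal

    def test_clear_somatic_site_called_with_oracle_pvalue(self):
        tumor, normal = self.make_pair((30, 70), (0, 100))
        calls = call_somatic(tumor, normal)
        assert len(calls) == 1
        c = calls[0]
        assert (c.ref, c.alt) == ("A", "C")
        assert c.tumor_alt == 30 and c.normal_alt == 0
        assert c.pos1 == 511  # downstream locus at cut 500, offset 10, 1-based
        assert c.p_value == pytest.approx(exact_test_oracle(30, 70, 0, 100), rel=1e-9)

    def test_identical_counts_not_called(self):
        locus = make_locus()
        ref = "A" * 100
        same = {10: {"B1": {"C": 30, "A": 70}, "B2": {"C": 30}}}
        tumor = make_pileup("t", locus, ref, same, base_depth=100)
        normal = make_pileup("n", locus, ref, same, base_depth=100)
        # the shared variant is germline, never a clean somatic candidate
        assert [c for c in call_somatic(tumor, normal) if not c.flags] == []

    def test_below_min_alt_not_called(self):
        tumor, normal = self.make_pair((1, 99), (0, 100))
        assert call_somatic(tumor, normal) == []

    def test_low_depth_flagged(self):
        tumor, normal = self.make_pair((5, 5), (0, 10))
        calls = call_somatic(tumor, normal, CallParams(min_depth=20))
        assert len(calls) == 1 and "low_depth" in calls[0].flags

    def test_germline_flagged(self):
        tumor, normal = self.make_pair((30, 70), (10, 90))
        calls = call_somatic(tumor, normal)
        assert len(calls) == 1 and "germline" in calls[0].flags


class TestCurationFilters:
    def base_call(self, tumor):
        calls = call_somatic(tumor, make_pileup("n", make_locus(), "A" * 100, {}, 100))
        assert len(calls) == 1
        return calls[0]

    def test_single_barcode_alt_flagged(self):
        locus = make_locus()
        tumor = make_pileup(
            "t", locus, "A" * 100, {10: {"B1": {"C": 30, "A": 70}}}, base_depth=100
        )
        call = self.base_call(tumor)
        curation_filters(call, tumor, {("chr1", 500): {"upstream": 100, "downstream": 100}})
        assert F_SINGLE_BC in call.flags and not call.is_pass

    def test_asymmetric_direction_depth_flagged(self):
        locus = make_locus()
        tumor = make_pileup(
            "t", locus, "A" * 100,
            {10: {"B1": {"C": 15, "A": 70}, "B2": {"C": 15}}}, base_depth=100,
        )
        call = self.base_call(tumor)
        curation_filters(call, tumor, {("chr1", 500): {"upstream": 30, "downstream": 300}})
        assert F_ASYM in call.flags  # ratio 0.1 < 1/3

    def test_multi_barcode_balanced_passes(self):
        locus = make_locus()
        tumor = make_pileup(
            "t", locus, "A" * 100,
            {10: {"B1": {"C": 10, "A": 70}, "B2": {"C": 10}, "B3": {"C": 10}}},
            base_depth=100,
        )
        call = self.base_call(tumor)
        curation_filters(call, tumor, {("chr1", 500): {"upstream": 150, "downstream": 180}})
        assert call.is_pass
        assert call.filter_field == "PASS"

    def test_pass_implies_barcode_and_symmetry_bounds(self):
        params = CurationParams()
        locus = make_locus()
        tumor = make_pileup(
            "t", locus, "A" * 100,
            {10: {"B1": {"C": 20, "A": 70}, "B2": {"C": 10}}}, base_depth=100,
        )
        call = self.base_call(tumor)
        dirs = {("chr1", 500): {"upstream": 120, "downstream": 100}}
        curation_filters(call, tumor, dirs, params)
        if call.is_pass:
            lp = tumor[call.locus_id]
            n_bc = sum(
                1 for c in lp.by_barcode.values() if c[call.offset, 1] > 0
            )
            assert n_bc >= params.min_barcodes
            lo, hi = 100, 120
            assert lo / hi >= params.symmetry_min


@pytest.fixture(scope="module")
def mosaic_sim():
    # one tissue carries private variants at VAF 0.2; a trunk clone is
    # shared by all tissues (so its variants are private to none)
    cfg = SimConfig(
            seed=21,
        genome_len=30_000,
        n_sites=15,
        mean_depth=120,
        duplicate_fraction=0.0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
        tree={"trunk": ("root", 4), "brain_clone": ("trunk", 3)},
        samples={
            "normal": SampleSpec("root"),
            "brain": SampleSpec("brain_clone", 0.4),
            "liver": SampleSpec("trunk", 0.4),
            "skin": SampleSpec("trunk", 0.4),
        },
    )
    sim = simulate(cfg)
    results, _ = process_reads(
        sim.reads, sim.barcode_map, "SbfI", sim.catalog, sim.genome
    )
    tissues = ["brain", "liver", "skin"]
    calls = {
        t: call_and_curate(results[t].pileup, results["normal"].pileup)
        for t in tissues
    }
    pileups = {t: results[t].pileup for t in tissues}
    return sim, calls, pileups


class TestPrivateVariantScreen:
    def test_private_variants_found_in_their_tissue(self, mosaic_sim):
        sim, calls, pileups = mosaic_sim
        screen = private_variant_screen(calls, pileups)
        private_ids = {m.mutation_id for m in sim.truth.node_mutations["brain_clone"]}
        got = set(screen.loc[screen["private_to"] == "brain", "mutation_id"])
        assert got == private_ids

    def test_shared_variants_not_private(self, mosaic_sim):
        sim, calls, pileups = mosaic_sim
        screen = private_variant_screen(calls, pileups)
        trunk_ids = {m.mutation_id for m in sim.truth.node_mutations["trunk"]}
        shared = screen[screen["mutation_id"].isin(trunk_ids)]
        assert len(shared) == len(trunk_ids)
        assert shared["private_to"].isna().all()

    def test_no_calls_empty_screen(self, mosaic_sim):
        _, _, pileups = mosaic_sim
        screen = private_variant_screen({t: [] for t in pileups}, pileups)
        assert screen.empty

    def test_requires_two_tissues(self, mosaic_sim):
        _, calls, pileups = mosaic_sim
        with pytest.raises(ValueError):
            private_variant_screen({"brain": calls["brain"]}, pileups)


class TestComparePairedVaf:
    def test_three_fixed_pairs_hand_oracle(self):
        # diffs 5, 2, 5: mean 4, sd sqrt(3); t = 4 / (sqrt(3)/sqrt(3)) = 4
        res = compare_vaf_paired([(30, 25), (28, 26), (35, 30)])
        assert res.df == 2
        assert res.t_statistic == pytest.approx(4.0)
        assert res.mean_sorted == pytest.approx(31.0)
        assert res.mean_unsorted == pytest.approx(27.0)

    def test_constant_difference_with_jitter(self):
        rng = np.random.default_rng(0)
        pairs = [(30 + 5 + e, 30 + e2) for e, e2 in rng.normal(0, 0.01, (9, 2))]
        res = compare_vaf_paired(pairs)
        assert res.df == 8 and res.t_statistic > 100

    def test_equal_pairs_t_zero(self):
        res = compare_vaf_paired([(30, 30), (25, 25), (40, 40)])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = compare_vaf_paired([(30, 25), (35, 30)])
        assert math.isinf(res.t_statistic) and res.p_value == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            compare_vaf_paired([(30, 25)])

    def test_sorting_enrichment_recovered_from_simulation(self):
        # sorted (high purity) vs unsorted (contaminated) populations of the
        # same clone: sorted VAFs come out higher
        means = []
        for seed in (31, 32, 33):
            vafs = {}
            for label, purity in (("sorted", 0.9), ("unsorted", 0.55)):
                cfg = SimConfig(
                    seed=seed,
                    genome_len=25_000,
                    n_sites=10,
                    mean_depth=200,
                    duplicate_fraction=0.0,
                    pcr_error_rate=0.0,
                    seq_error_rate=0.0,
                    tree={"clone": ("root", 9)},
                    samples={
                        "normal": SampleSpec("root"),
                        "cells": SampleSpec("clone", purity),
                    },
                )
                sim = simulate(cfg)
                results, _ = process_reads(
                    sim.reads, sim.barcode_map, "SbfI", sim.catalog, sim.genome
                )
                calls = call_and_curate(
                    results["cells"].pileup, results["normal"].pileup
                )
                vafs[label] = {
                    c.mutation_id: 100 * c.tumor_vaf for c in calls if c.is_pass
                }
            common = sorted(set(vafs["sorted"]) & set(vafs["unsorted"]))
            assert len(common) >= 5
            res = compare_vaf_paired(
                [(vafs["sorted"][m], vafs["unsorted"][m]) for m in common]
            )
            means.append((res.mean_sorted, res.mean_unsorted))
        assert all(s > u for s, u in means)


def test_vcf_export_format(tmp_path):
    locus = make_locus()
    tumor = make_pileup(
        "t", locus, "A" * 100,
        {10: {"B1": {"C": 15, "A": 70}, "B2": {"C": 15}}}, base_depth=100,
    )
    normal = make_pileup("n", locus, "A" * 100, {}, 100)
    calls = call_and_curate(tumor, normal)
    path = tmp_path / "calls.vcf"
    write_vcf(calls, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    body = [l for l in lines if not l.startswith("#")]
    assert len(body) == 1
    fields = body[0].split("\t")
    assert fields[0] == "chr1" and fields[1] == "511"
    assert fields[3] == "A" and fields[4] == "C"
    assert "DP_T=100" in fields[7]
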