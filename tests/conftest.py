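"""Shared fixtures and synthetic-pileup builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from radclone import ENZYMES, SimConfig, simulate
from radclone._seq import seq_to_codes
from radclone.digest import RadLocus
from radclone.somatic import LocusPileup, SamplePileup


@pytest.fixture(scope="session")
def sbfi():
    return ENZYMES["SbfI"]


@pytest.fixture(scope="session")
def nsii():
    return ENZYMES["NsiI"]


@pytest.fixture(scope="session")
def clean_sim():
    """Small error-free tumor/normal simulation (no dups, no PCR/seq error)."""
    cfg = SimConfig(
        seed=101,
        genome_len=30_000,
        n_sites=20,
        mean_depth=50,
        duplicate_fraction=0.0,
        pcr_error_rate=0.0,
        seq_error_rate=0.0,
    )
    return simulate(cfg)


def make_locus(
    locus_id: str = "chr1:500:dn",
    chrom: str = "chr1",
    cut_pos: int = 500,
    direction: str = "downstream",
    flank: int = 100,
) -> RadLocus:
    if direction == "downstream":
        return RadLocus(locus_id, chrom, cut_pos, direction, cut_pos, cut_pos + flank)
    return RadLocus(locus_id, chrom, cut_pos, direction, cut_pos - flank, cut_pos)


def make_pileup(
    sample_id: str,
    locus: RadLocus,
    ref_seq: str,
    allele_counts: dict[int, dict[str, dict[str, int]]],
    base_depth: int = 0,
    residual_len: int = 6,
) -> SamplePileup:
    """Build a SamplePileup directly from per-offset allele counts.

    ``allele_counts`` maps offset -> barcode -> base -> count.  Offsets not
    listed get ``base_depth`` reference reads on barcode 'BC0'.
    """
    flank = locus.length
    ref_codes = seq_to_codes(ref_seq)
    assert len(ref_codes) == flank
    barcodes = {"BC0"} | {bc for d in allele_counts.values() for bc in d}
    by_barcode = {bc: np.zeros((flank, 4), dtype=np.int64) for bc in sorted(barcodes)}
    for off in range(flank):
        if off in allele_counts:
            for bc, bases in allele_counts[off].items():
                for base, n in bases.items():
                    by_barcode[bc][off, "ACGT".index(base)] += n
        else:
            by_barcode["BC0"][off, ref_codes[off]] += base_depth
    counts = sum(by_barcode.values())
    pile = SamplePileup(sample_id, residual_len)
    lp = LocusPileup(
        locus, ref_codes, counts, by_barcode, n_reads=int(counts.sum(axis=1).max())
    )
    pile.loci[locus.locus_id] = lp
    return pile
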