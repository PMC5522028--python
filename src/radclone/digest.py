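"""Restriction-enzyme modeling, in silico digestion, and RAD experiment design.

A RADseq experiment sequences the flanks of every genomic occurrence of a
restriction enzyme's recognition motif.  Because the motifs of the supported
enzymes are palindromic, each occurrence yields two sequenced loci, one
reading away from the cut in each direction.  This module scans a reference
for cut sites, builds the two-per-site locus catalog that every downstream
stage (read assignment, somatic calling, copy number) is anchored on, and
provides the desk arithmetic used to choose an enzyme and a sequencing
budget before any data exist: expected cut spacing from motif length and GC
content, fraction of the genome captured, and per-locus depth per sample.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from ._seq import revcomp

__all__ = [
    "RestrictionEnzyme",
    "RadLocus",
    "DigestSummary",
    "DesignParams",
    "ENZYMES",
    "get_enzyme",
    "expected_cut_spacing",
    "digest_sequence",
    "build_rad_loci",
    "genome_representation",
    "plan_depth",
    "write_catalog_bed",
    "read_catalog_bed",
]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A palindromic restriction enzyme.

    ``recognition`` is the double-stranded recognition motif written on the
    top strand; ``cut_offset_top`` is the position of the top-strand
    cleavage boundary, in bases from the motif start.  For a palindromic
    motif the bottom strand is cut at ``len - cut_offset_top``, so enzymes
    with ``cut_offset_top > len/2`` leave 3' overhangs.

    ``residual`` is the motif remnant observed at the start of a genomine
    read after ligation: the last ``cut_offset_top`` bases of the motif
    (equivalently, by palindromy, the reverse complement of the motif up to
    the cut).  It doubles as the cut-site integrity check during
    demultiplexing.
    """

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        motif = self.recognition.upper()
        object.__setattr__(self, "recognition", motif)
        if not motif or set(motif) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition motif must be non-empty ACGT, got {motif!r}"
            )
        if revcomp(motif) != motif:
            raise ValueError(
                f"{self.name}: recognition motif {motif} is not palindromic; "
                "the two-direction RAD locus model requires a palindromic site"
            )
        if not 0 < self.cut_offset_top < len(motif):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset_top} outside motif "
                f"of length {len(motif)}"
            )

    @property
    def motif_len(self) -> int:
        return len(self.recognition)

    @property
    def gc_site(self) -> int:
        return sum(b in "GC" for b in self.recognition)

    @property
    def residual(self) -> str:
        """Post-ligation remnant at the start of every genuine RAD read."""
        return self.recognition[self.motif_len - self.cut_offset_top :]

    @property
    def overhang(self) -> str:
        """Single-stranded overhang produced by the staggered cut."""
        lo = min(self.cut_offset_top, self.motif_len - self.cut_offset_top)
        hi = max(self.cut_offset_top, self.motif_len - self.cut_offset_top)
        return self.recognition[lo:hi]


ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in (
        RestrictionEnzyme("SbfI", "CCTGCAGG", 6),
        RestrictionEnzyme("NsiI", "ATGCAT", 5),
    )
}


def get_enzyme(enzyme: str | RestrictionEnzyme) -> RestrictionEnzyme:
    if isinstance(enzyme, RestrictionEnzyme):
        return enzyme
    try:
        return ENZYMES[enzyme]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {enzyme!r}; built-ins: {sorted(ENZYMES)}"
        ) from None


@dataclass(frozen=True)
class RadLocus:
    """One sequencing direction anchored at one cut site.

    ``cut_pos`` is the 0-based top-strand cleavage boundary.  The upstream
    locus spans ``[cut_pos - flank, cut_pos)`` and is read on the bottom
    strand (away from the cut); the downstream locus spans
    ``[cut_pos, cut_pos + flank)`` and is read on the top strand.  Intervals
    are truncated at sequence ends.
    """

    locus_id: str
    chrom: str
    cut_pos: int
    direction: str  # "upstream" | "downstream"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.direction not in ("upstream", "downstream"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not 0 <= self.start <= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DigestSummary:
    n_sites: int
    n_loci: int
    genome_len: int
    flank_len: int
    fraction_genome: float  # percent of genome in the union of locus intervals

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass(frozen=True)
class DesignParams:
    """Desk parameters for planning a RADseq experiment."""

    motif_len: int
    gc_site: int
    gc_genome: float
    flank_len: int = 100
    reads_per_lane: float = 350e6
    n_samples: int = 1


def expected_cut_spacing(motif_len: int, gc_site: int, gc_genome: float) -> float:
    """Expected bp between cut sites in i.i.d. sequence of the given GC.

    Under an i.i.d. base model with GC fraction ``g``, each of the motif's
    G/C bases occurs with probability g/2 and each A/T base with (1-g)/2,
    so the per-position site probability is
    ``(g/2)**gc_site * ((1-g)/2)**(motif_len-gc_site)`` and the expected
    spacing is its reciprocal.  At g = 0.5 this is 4**motif_len regardless
    of the motif's composition: an 8-cutter every 65,536 bp, a 6-cutter
    every 4,096 bp.

    Returns ``math.inf`` when the motif cannot occur (e.g. a GC-containing
    motif in a GC-free genome) — "no sites expected" rather than overflow.
    """
    if not 0 <= gc_site <= motif_len:
        raise ValueError(f"gc_site {gc_site} outside [0, {motif_len}]")
    if not 0 <= gc_genome <= 1:
        raise ValueError(f"gc_genome {gc_genome} outside [0, 1]")
    p_gc = gc_genome / 2.0
    p_at = (1.0 - gc_genome) / 2.0
    if (p_gc == 0 and gc_site > 0) or (p_at == 0 and gc_site < motif_len):
        return math.inf
    return 1.0 / (p_gc**gc_site * p_at ** (motif_len - gc_site))


def digest_sequence(sequence: str, enzyme: str | RestrictionEnzyme) -> list[int]:
    """Scan one sequence and return 0-based top-strand cut boundaries.

    Soft-masked (lowercase) bases match; N never does.  Overlapping motif
    occurrences are each reported.  A palindromic motif is counted once per
    occurrence (both strands cut at the same duplex position).
    """
    enz = get_enzyme(enzyme)
    motif = enz.recognition
    seq = sequence.upper()
    cuts: list[int] = []
    i = seq.find(motif)
    while i != -1:
        cuts.append(i + enz.cut_offset_top)
        i = seq.find(motif, i + 1)
    return cuts


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def build_rad_loci(
    genome: Mapping[str, str],
    enzyme: str | RestrictionEnzyme,
    flank_len: int = 100,
) -> tuple[list[RadLocus], DigestSummary]:
    """Digest a genome and build the two-loci-per-site RAD catalog.

    ``genome`` maps sequence name to sequence.  Locus intervals are clipped
    to sequence bounds, and ``fraction_genome`` is computed on the interval
    union, so sites closer than the flank length do not double-count bases.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    enz = get_enzyme(enzyme)
    loci: list[RadLocus] = []
    n_sites = 0
    genome_len = 0
    union = 0
    for chrom, seq in genome.items():
        genome_len += len(seq)
        cuts = digest_sequence(seq, enz)
        n_sites += len(cuts)
        intervals = []
        for c in cuts:
            up_s, up_e = max(0, c - flank_len), c
            dn_s, dn_e = c, min(len(seq), c + flank_len)
            loci.append(RadLocus(f"{chrom}:{c}:up", chrom, c, "upstream", up_s, up_e))
            loci.append(RadLocus(f"{chrom}:{c}:dn", chrom, c, "downstream", dn_s, dn_e))
            intervals.append((up_s, dn_e))
        union += _union_length(intervals)
    fraction = 100.0 * union / genome_len if genome_len else 0.0
    summary = DigestSummary(n_sites, 2 * n_sites, genome_len, flank_len, fraction)
    return loci, summary


def genome_representation(n_sites: int, flank_len: int, genome_len: float) -> float:
    """Percent of genome captured, by naive count arithmetic (no union).

    The shortcut used when only a site count is known: each site contributes
    two flanks of ``flank_len`` bp.  An upper bound on the union-based
    fraction from :func:`build_rad_loci`.
    """
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    if n_sites < 0 or flank_len <= 0:
        raise ValueError("n_sites must be >= 0 and flank_len positive")
    return 100.0 * n_sites * 2 * flank_len / genome_len


def plan_depth(n_sites: int, reads_per_lane: float, n_samples: int) -> float:
    """Expected per-locus depth per sample for one lane split across samples.

    Assumes on-target reads distribute uniformly over the ``2 * n_sites``
    loci.  Halving the site count (a rarer cutter) doubles the depth — the
    SbfI / NsiI trade-off.
    """
    if n_sites <= 0 or n_samples <= 0 or reads_per_lane <= 0:
        raise ValueError("n_sites, reads_per_lane and n_samples must be positive")
    return reads_per_lane / (n_samples * 2 * n_sites)


_STRAND = {"downstream": "+", "upstream": "-"}
_DIRECTION = {"+": "downstream", "-": "upstream"}


def write_catalog_bed(loci: Iterable[RadLocus], path: str | Path) -> None:
    """Export the catalog as BED6 (0-based half-open; strand encodes direction)."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t0\t"
                f"{_STRAND[loc.direction]}\n"
            )


def read_catalog_bed(path: str | Path) -> list[RadLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            direction = _DIRECTION[strand]
            start_i, end_i = int(start), int(end)
            cut_pos = start_i if direction == "downstream" else end_i
            loci.append(RadLocus(name, chrom, cut_pos, direction, start_i, end_i))
    return loci
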