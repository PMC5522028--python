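"""Tumor–normal somatic SNV calling at RAD loci, with RAD-specific curation.

Calling proceeds per locus offset from allele-count pileups.  A site is a
candidate when the tumor shows enough alternate reads over sufficient depth
in both samples and the matched normal is clean; candidates are tested with
a one-sided exact test of independence on the tumor/normal allele table and
controlled by Benjamini–Hochberg across tested sites.  The caller is a
deliberately simple stand-in for a production somatic caller — the substance
here is the curation that RAD geometry makes possible:

* multi-barcode confirmation — all reads at a locus share a start position,
  so PCR duplicates are invisible to positional dedup; instead an alternate
  allele must be supported by reads carrying at least two distinct sample
  barcodes, or it is flagged as a likely amplification artifact;
* bidirectional symmetry — the two opposing loci of one cut site should
  receive balanced depth; strong imbalance marks mapping or locus artifacts
  and flags any call at that site.

Also here: the screen for variants private to a single tissue (somatic
mosaicism), and the paired t comparison of variant allele frequencies
between sorted and unsorted cell populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import complement, seq_to_codes
from .digest import RadLocus
from .locus_assign import AssignedRead, LocusIndex

__all__ = [
    "LocusPileup",
    "SamplePileup",
    "CallParams",
    "CurationParams",
    "SomaticCall",
    "PairedVafComparison",
    "build_pileup",
    "fisher_one_sided",
    "call_somatic",
    "curation_filters",
    "curate_calls",
    "call_and_curate",
    "private_variant_screen",
    "compare_vaf_paired",
    "write_vcf",
]

_BASES = "ACGT"


@dataclass
class LocusPileup:
    """Per-offset A/C/G/T counts at one locus, stratified by barcode.

    Offsets index the locus flank in read orientation (0 = first base after
    the enzyme residual).  ``counts`` has shape (flank, 4); ``by_barcode``
    holds the same per barcode and sums to ``counts``.
    """

    locus: RadLocus
    ref_codes: np.ndarray  # flank reference, read orientation, codes 0..3
    counts: np.ndarray  # (flank, 4) int
    by_barcode: dict[str, np.ndarray] = field(default_factory=dict)
    n_reads: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def genomic_pos(self, offset: int) -> int:
        """0-based top-strand genomic position of a flank offset."""
        if self.locus.direction == "downstream":
            return self.locus.cut_pos + offset
        return self.locus.cut_pos - 1 - offset

    def top_strand(self, base: str) -> str:
        return base if self.locus.direction == "downstream" else complement(base)

    def validate(self) -> None:
        if self.by_barcode:
            total = sum(self.by_barcode.values())
            if not np.array_equal(total, self.counts):
                raise AssertionError(
                    f"{self.locus.locus_id}: per-barcode counts do not sum to totals"
                )


class SamplePileup:
    """All locus pileups of one sample, plus per-locus read depth."""

    def __init__(self, sample_id: str, residual_len: int):
        self.sample_id = sample_id
        self.residual_len = residual_len
        self.loci: dict[str, LocusPileup] = {}

    def __getitem__(self, locus_id: str) -> LocusPileup:
        return self.loci[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def direction_depths(self) -> dict[tuple[str, int], dict[str, int]]:
        """Read depth of the two loci of each cut site."""
        out: dict[tuple[str, int], dict[str, int]] = {}
        for lp in self.loci.values():
            key = (lp.locus.chrom, lp.locus.cut_pos)
            out.setdefault(key, {"upstream": 0, "downstream": 0})[
                lp.locus.direction
            ] = lp.n_reads
        return out


def build_pileup(
    assignments: Iterable[AssignedRead],
    index: LocusIndex,
    sample_id: str | None = None,
) -> SamplePileup:
    """Accumulate on-target reads into per-locus allele counts.

    Each read contributes one allele per covered flank offset; its barcode
    is recorded so alternate-allele barcode diversity can be checked later.
    Bases beyond the locus interval raise (they would imply a read longer
    than the locus model allows).
    """
    res_len = len(index.enzyme.residual)
    by_locus: dict[str, list[AssignedRead]] = {}
    sid = sample_id
    for a in assignments:
        if not a.on_target:
            continue
        if sid is None:
            sid = a.sample_id
        by_locus.setdefault(a.locus_id, []).append(a)
    pile = SamplePileup(sid or "", res_len)
    for locus_id, reads in by_locus.items():
        locus = index.locus(locus_id)
        flank = locus.length
        expected = index.expected_read(locus_id)
        ref_codes = seq_to_codes(expected[res_len:])
        counts = np.zeros((flank, 4), dtype=np.int64)
        by_barcode: dict[str, np.ndarray] = {}
        groups: dict[str, list[str]] = {}
        for r in reads:
            body = r.bases[res_len:]
            if len(body) > flank:
                raise ValueError(
                    f"{locus_id}: read {r.read_id} covers offsets beyond the locus"
                )
            groups.setdefault(r.barcode, []).append(body)
        for barcode, bodies in groups.items():
            width = max(len(b) for b in bodies)
            mat = np.full((len(bodies), width), 4, dtype=np.uint8)
            for i, b in enumerate(bodies):
                mat[i, : len(b)] = seq_to_codes(b.upper())
            bc_counts = np.zeros((flank, 4), dtype=np.int64)
            for code in range(4):
                bc_counts[:width, code] = (mat == code).sum(axis=0)
            by_barcode[barcode] = bc_counts
            counts += bc_counts
        lp = LocusPileup(locus, ref_codes, counts, by_barcode, n_reads=len(reads))
        lp.validate()
        pile.loci[locus_id] = lp
    return pile


@dataclass(frozen=True)
class CallParams:
    min_alt: int = 4
    min_depth: int = 20
    max_normal_vaf: float = 0.02
    fdr: float = 0.05


@dataclass(frozen=True)
class CurationParams:
    min_barcodes: int = 2  # distinct barcodes among alt-supporting reads
    symmetry_min: float = 1.0 / 3.0  # min/max depth ratio of the two directions


PASS = "PASS"
F_ASYM = "asymmetric_coverage"
F_SINGLE_BC = "single_barcode"
F_LOW_DEPTH = "low_depth"
F_GERMLINE = "germline"


@dataclass
class SomaticCall:
    chrom: str
    pos0: int  # 0-based top-strand position; exports are 1-based
    ref: str
    alt: str
    locus_id: str
    offset: int
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    p_value: float
    q_value: float = float("nan")
    flags: set[str] = field(default_factory=set)

    @property
    def pos1(self) -> int:
        return self.pos0 + 1

    @property
    def mutation_id(self) -> str:
        return f"{self.chrom}:{self.pos1}:{self.ref}>{self.alt}"

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0

    @property
    def is_pass(self) -> bool:
        return not self.flags

    @property
    def filter_field(self) -> str:
        return PASS if self.is_pass else ";".join(sorted(self.flags))


def fisher_one_sided(t_alt, t_ref, n_alt, n_ref):
    """One-sided exact test that the alt allele is enriched in the tumor.

    P(X >= t_alt) for X hypergeometric with population ``t+n`` reads,
    ``t_alt+n_alt`` alt successes, and a tumor draw of ``t_alt+t_ref`` —
    the one-sided Fisher exact test on the 2x2 table.  Vectorized.
    """
    t_alt = np.asarray(t_alt)
    total = t_alt + t_ref + n_alt + n_ref
    return stats.hypergeom.sf(t_alt - 1, total, t_alt + n_alt, t_alt + t_ref)


def _bh(pvals: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg rejection mask and adjusted p-values."""
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, qvals


def call_somatic(
    tumor: SamplePileup,
    normal: SamplePileup,
    params: CallParams = CallParams(),
) -> list[SomaticCall]:
    """Candidate somatic SNVs from a tumor/normal pileup pair.

    Emits every site where the tumor alt count reaches ``min_alt``.  Sites
    failing the depth requirement are flagged ``low_depth``; sites where the
    normal VAF exceeds ``max_normal_vaf`` are flagged ``germline``.  Clean
    candidates are exact-tested and kept only if significant after
    Benjamini–Hochberg at ``params.fdr``; they then go to curation.
    """
    candidates: list[SomaticCall] = []
    for locus_id, tp in tumor.loci.items():
        if locus_id in normal:
            np_counts = normal[locus_id].counts
        else:
            np_counts = np.zeros_like(tp.counts)
        t_depth = tp.counts.sum(axis=1)
        n_depth = np_counts.sum(axis=1)
        offsets = np.arange(len(tp.ref_codes))
        t = tp.counts.copy()
        t[offsets, tp.ref_codes] = 0  # zero out the reference allele
        alt_codes = t.argmax(axis=1)
        alt_counts = t[offsets, alt_codes]
        for off in np.nonzero(alt_counts >= params.min_alt)[0]:
            off = int(off)
            ref_code = int(tp.ref_codes[off])
            alt_code = int(alt_codes[off])
            t_alt = int(alt_counts[off])
            t_ref = int(tp.counts[off, ref_code])
            n_alt = int(np_counts[off, alt_code])
            n_ref = int(np_counts[off, ref_code])
            call = SomaticCall(
                chrom=tp.locus.chrom,
                pos0=tp.genomic_pos(off),
                ref=tp.top_strand(_BASES[ref_code]),
                alt=tp.top_strand(_BASES[alt_code]),
                locus_id=locus_id,
                offset=off,
                tumor_depth=int(t_depth[off]),
                tumor_alt=t_alt,
                normal_depth=int(n_depth[off]),
                normal_alt=n_alt,
                p_value=float("nan"),
            )
            if call.tumor_depth < params.min_depth or call.normal_depth < params.min_depth:
                call.flags.add(F_LOW_DEPTH)
            if call.normal_depth and call.normal_vaf > params.max_normal_vaf:
                call.flags.add(F_GERMLINE)
            if not call.flags:
                call.p_value = float(fisher_one_sided(t_alt, t_ref, n_alt, n_ref))
            candidates.append(call)
    tested = [c for c in candidates if not c.flags]
    if tested:
        pvals = np.array([c.p_value for c in tested])
        reject, qvals = _bh(pvals, params.fdr)
        kept = []
        for c, r, q in zip(tested, reject, qvals):
            c.q_value = float(q)
            if r:
                kept.append(c)
        tested = kept
    flagged = [c for c in candidates if c.flags]
    return sorted(tested + flagged, key=lambda c: (c.chrom, c.pos0, c.alt))


def curation_filters(
    call: SomaticCall,
    tumor_pileup: SamplePileup,
    cut_site_direction_depths: Mapping[tuple[str, int], Mapping[str, int]],
    params: CurationParams = CurationParams(),
) -> SomaticCall:
    """Apply the RAD-specific artifact filters to one call (in place).

    ``single_barcode``: the alternate allele must be seen on reads carrying
    at least ``min_barcodes`` distinct barcodes — a single-barcode alt is
    indistinguishable from a PCR duplication artifact.
    ``asymmetric_coverage``: depth of the two directions of the call's cut
    site must satisfy min/max >= ``symmetry_min``.
    """
    lp = tumor_pileup[call.locus_id]
    alt_read = call.alt if lp.locus.direction == "downstream" else complement(call.alt)
    alt_code = _BASES.index(alt_read)
    n_bc = sum(
        1 for counts in lp.by_barcode.values() if counts[call.offset, alt_code] > 0
    )
    if n_bc < params.min_barcodes:
        call.flags.add(F_SINGLE_BC)
    dirs = cut_site_direction_depths.get((lp.locus.chrom, lp.locus.cut_pos))
    if dirs is not None:
        lo, hi = sorted((dirs.get("upstream", 0), dirs.get("downstream", 0)))
        if hi == 0 or lo / hi < params.symmetry_min:
            call.flags.add(F_ASYM)
    return call


def curate_calls(
    calls: Sequence[SomaticCall],
    tumor_pileup: SamplePileup,
    params: CurationParams = CurationParams(),
) -> list[SomaticCall]:
    dirs = tumor_pileup.direction_depths()
    return [curation_filters(c, tumor_pileup, dirs, params) for c in calls]


def call_and_curate(
    tumor: SamplePileup,
    normal: SamplePileup,
    call_params: CallParams = CallParams(),
    curation_params: CurationParams = CurationParams(),
) -> list[SomaticCall]:
    """Full somatic pipeline for one tumor/normal pair."""
    return curate_calls(call_somatic(tumor, normal, call_params), tumor, curation_params)


def private_variant_screen(
    calls_by_tissue: Mapping[str, Sequence[SomaticCall]],
    pileups_by_tissue: Mapping[str, SamplePileup],
    present_vaf: float = 0.05,
    absent_vaf: float = 0.01,
    min_depth: int = 20,
) -> pd.DataFrame:
    """Find variants present in exactly one tissue (somatic mosaicism).

    Every PASS call from any tissue is re-examined in every tissue's pileup:
    present means VAF >= ``present_vaf``; absent means VAF <= ``absent_vaf``
    at depth >= ``min_depth``; anything else (insufficient depth, or an
    intermediate VAF) is indeterminate.  A variant is private when it is
    present in exactly one tissue and absent in all others; variants with
    indeterminate tissues are reported but not declared private.
    """
    if len(calls_by_tissue) < 2:
        raise ValueError("need at least two tissues to screen for private variants")
    seen: dict[str, SomaticCall] = {}
    for calls in calls_by_tissue.values():
        for c in calls:
            if c.is_pass and c.mutation_id not in seen:
                seen[c.mutation_id] = c
    rows = []
    tissues = sorted(calls_by_tissue)
    for mut_id, c in sorted(seen.items()):
        row: dict[str, object] = {"mutation_id": mut_id}
        status: dict[str, str] = {}
        for tissue in tissues:
            pile = pileups_by_tissue[tissue]
            vaf = np.nan
            if c.locus_id in pile:
                lp = pile[c.locus_id]
                alt_read = (
                    c.alt if lp.locus.direction == "downstream" else complement(c.alt)
                )
                depth = int(lp.depth[c.offset])
                alt_n = int(lp.counts[c.offset, _BASES.index(alt_read)])
                vaf = alt_n / depth if depth else np.nan
            else:
                depth = 0
            if depth >= min_depth and not np.isnan(vaf) and vaf >= present_vaf:
                status[tissue] = "present"
            elif depth >= min_depth and not np.isnan(vaf) and vaf <= absent_vaf:
                status[tissue] = "absent"
            else:
                status[tissue] = "indeterminate"
            row[f"vaf_{tissue}"] = vaf
            row[f"status_{tissue}"] = status[tissue]
        present = [t for t, s in status.items() if s == "present"]
        absent = [t for t, s in status.items() if s == "absent"]
        row["n_indeterminate"] = len(tissues) - len(present) - len(absent)
        row["private_to"] = (
            present[0]
            if len(present) == 1 and len(absent) == len(tissues) - 1
            else None
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedVafComparison:
    vaf_pairs: tuple[tuple[float, float], ...]
    mean_sorted: float
    mean_unsorted: float
    t_statistic: float
    df: int
    p_value: float


def compare_vaf_paired(
    vaf_pairs: Sequence[tuple[float, float]]
) -> PairedVafComparison:
    """Paired t test on (sorted, unsorted) VAF pairs, VAFs in percent.

    Two-sided p on the per-mutation differences; df = n - 1.  Zero variance
    with a nonzero mean difference is reported as the degenerate limit
    (infinite t, p = 0) with a warning.
    """
    if len(vaf_pairs) < 2:
        raise ValueError("need at least two VAF pairs")
    sorted_v = np.array([a for a, _ in vaf_pairs], dtype=float)
    unsorted_v = np.array([b for _, b in vaf_pairs], dtype=float)
    diffs = sorted_v - unsorted_v
    n = len(diffs)
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.isclose(diffs.mean(), 0.0):
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("zero variance in paired differences; t is degenerate")
            t_stat, p = float(np.sign(diffs.mean()) * np.inf), 0.0
    else:
        res = stats.ttest_rel(sorted_v, unsorted_v)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return PairedVafComparison(
        vaf_pairs=tuple((float(a), float(b)) for a, b in vaf_pairs),
        mean_sorted=float(sorted_v.mean()),
        mean_unsorted=float(unsorted_v.mean()),
        t_statistic=t_stat,
        df=n - 1,
        p_value=p,
    )


def write_vcf(calls: Sequence[SomaticCall], path: str | Path) -> None:
    """Minimal VCF v4.2 export (1-based positions; tumor/normal in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP_T,Number=1,Type=Integer,Description="Tumor depth">\n')
        fh.write('##INFO=<ID=AD_T,Number=1,Type=Integer,Description="Tumor alt count">\n')
        fh.write('##INFO=<ID=AF_T,Number=1,Type=Float,Description="Tumor VAF">\n')
        fh.write('##INFO=<ID=DP_N,Number=1,Type=Integer,Description="Normal depth">\n')
        fh.write('##INFO=<ID=AD_N,Number=1,Type=Integer,Description="Normal alt count">\n')
        fh.write('##INFO=<ID=AF_N,Number=1,Type=Float,Description="Normal VAF">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos0)):
            info = (
                f"DP_T={c.tumor_depth};AD_T={c.tumor_alt};AF_T={c.tumor_vaf:.4f};"
                f"DP_N={c.normal_depth};AD_N={c.normal_alt};AF_N={c.normal_vaf:.4f}"
            )
            fh.write(
                f"{c.chrom}\t{c.pos1}\t{c.mutation_id}\t{c.ref}\t{c.alt}\t.\t"
                f"{c.filter_field}\t{info}\n"
            )
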