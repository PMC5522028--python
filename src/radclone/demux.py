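"""Demultiplexing and quality filtering of multiplexed RAD reads.

Every genuine RAD read is structured ``barcode + enzyme residual + genomic
flank``.  Demultiplexing therefore checks two things at once: the leading
barcode identifies the sample, and the residual immediately after it is the
cut-site integrity check — a read whose residual does not match exactly was
not produced from an intact restriction site and is discarded.  Reads then
pass a sliding-window quality filter on the mean per-base probability of
being correct.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .digest import RestrictionEnzyme, get_enzyme

__all__ = [
    "BarcodeMap",
    "RawRead",
    "DemuxedRead",
    "QualityFilterParams",
    "DemuxReport",
    "demultiplex_read",
    "sliding_window_quality_filter",
    "process_fastq",
    "read_fastq",
]

AMBIGUOUS_BARCODE = "ambiguous_barcode"
BAD_CUTSITE = "bad_cutsite"
LOW_QUALITY = "low_quality"
REASONS = (AMBIGUOUS_BARCODE, BAD_CUTSITE, LOW_QUALITY)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class BarcodeMap:
    """sample_id -> set of equal-length barcodes, globally unique.

    A sample may own several barcodes; RADseq reads all start at the cut
    site, so PCR duplicates cannot be recognized by alignment position and
    are instead controlled by requiring variant support from multiple
    barcodes — which the map must make available.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, frozenset[str]] = {
            s: frozenset(b.upper() for b in bcs) for s, bcs in entries.items()
        }
        if not self.entries:
            raise ValueError("empty barcode map")
        lengths = {len(b) for bcs in self.entries.values() for b in bcs}
        if len(lengths) != 1:
            raise ValueError(f"barcodes of mixed lengths {sorted(lengths)}")
        self.barcode_len = lengths.pop()
        self._by_barcode: dict[str, str] = {}
        for sample, bcs in self.entries.items():
            for bc in bcs:
                if bc in self._by_barcode:
                    raise ValueError(
                        f"barcode {bc} assigned to both {self._by_barcode[bc]} "
                        f"and {sample}"
                    )
                self._by_barcode[bc] = sample
        bcs = sorted(self._by_barcode)
        self.min_distance = (
            min(_hamming(a, b) for i, a in enumerate(bcs) for b in bcs[i + 1 :])
            if len(bcs) > 1
            else self.barcode_len
        )

    @property
    def samples(self) -> list[str]:
        return sorted(self.entries)

    def sample_of(self, barcode: str) -> str | None:
        return self._by_barcode.get(barcode)

    def rescue(self, barcode: str) -> tuple[str, str] | None | str:
        """One-mismatch lookup: (sample, barcode), None, or 'ambiguous'."""
        hits = {
            (s, bc)
            for bc, s in self._by_barcode.items()
            if _hamming(barcode, bc) <= 1
        }
        samples = {s for s, _ in hits}
        if not hits:
            return None
        if len(samples) > 1:
            return "ambiguous"
        return sorted(hits)[0]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        entries: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sample, barcode = line.split("\t")[:2]
                entries.setdefault(sample, set()).add(barcode)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sample in self.samples:
                for bc in sorted(self.entries[sample]):
                    fh.write(f"{sample}\t{bc}\n")


@dataclass
class RawRead:
    """A FASTQ record: bases plus phred-scaled qualities."""

    read_id: str
    bases: str
    quals: np.ndarray  # phred integers

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int32)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )


@dataclass
class DemuxedRead:
    """A barcode-trimmed read assigned to a sample; residual retained."""

    read_id: str
    sample_id: str
    barcode: str
    bases: str
    quals: np.ndarray


@dataclass(frozen=True)
class QualityFilterParams:
    window_frac: float = 0.15  # window length as fraction of read length
    min_p_correct: float = 0.90  # mean probability-correct threshold


@dataclass
class DemuxReport:
    retained_by_sample: dict[str, int] = field(default_factory=dict)
    discarded: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )
    total_reads: int = 0

    @property
    def retained(self) -> int:
        return sum(self.retained_by_sample.values())

    @property
    def retained_fraction(self) -> float:
        return self.retained / self.total_reads if self.total_reads else 0.0

    def check_conservation(self) -> None:
        if self.retained + sum(self.discarded.values()) != self.total_reads:
            raise AssertionError("demux report does not conserve reads")


def demultiplex_read(
    read: RawRead,
    barcode_map: BarcodeMap,
    enzyme: str | RestrictionEnzyme,
    allow_one_mismatch_barcode: bool = False,
) -> tuple[DemuxedRead, None] | tuple[None, str]:
    """Assign a read to a sample and verify its cut-site residual.

    Returns ``(demuxed, None)`` on success or ``(None, reason)`` on
    rejection.  The barcode is trimmed; the residual stays on the read (it
    is genomic sequence in the locus model).  The residual must match
    exactly: one mismatch there rejects the read, since it doubles as the
    cut-site integrity check.
    """
    enz = get_enzyme(enzyme)
    blen = barcode_map.barcode_len
    residual = enz.residual
    if len(read.bases) < blen + len(residual):
        return None, BAD_CUTSITE
    barcode = read.bases[:blen].upper()
    sample = barcode_map.sample_of(barcode)
    if sample is None:
        if allow_one_mismatch_barcode:
            hit = barcode_map.rescue(barcode)
            if hit is None or hit == "ambiguous":
                return None, AMBIGUOUS_BARCODE
            sample, barcode = hit
        else:
            return None, AMBIGUOUS_BARCODE
    if read.bases[blen : blen + len(residual)].upper() != residual:
        return None, BAD_CUTSITE
    return (
        DemuxedRead(
            read.read_id, sample, barcode, read.bases[blen:], read.quals[blen:]
        ),
        None,
    )


def phred_to_p_correct(quals: np.ndarray) -> np.ndarray:
    return 1.0 - 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)


def sliding_window_quality_filter(
    read: RawRead | DemuxedRead, params: QualityFilterParams = QualityFilterParams()
) -> bool:
    """True = keep, False = discard.

    The window is ``ceil(window_frac * len)`` bases and advances one base at
    a time; the read is discarded if the mean probability-correct in any
    window drops below ``min_p_correct``.  A read shorter than the window is
    judged on a single whole-read window.
    """
    n = len(read.quals)
    if n == 0:
        raise ValueError("empty read")
    w = min(n, math.ceil(params.window_frac * n))
    p = phred_to_p_correct(read.quals)
    # all windows pass whenever every base passes on its own
    if p.min() >= params.min_p_correct:
        return True
    csum = np.concatenate(([0.0], np.cumsum(p)))
    means = (csum[w:] - csum[:-w]) / w
    return bool(means.min() >= params.min_p_correct)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a (possibly gzipped) FASTQ as RawRead records."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for n, (title, seq, qual) in enumerate(FastqGeneralIterator(fh), 1):
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ record {n} ({title})")
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int32
            ) - 33
            yield RawRead(title.split()[0], seq, quals)


def process_fastq(
    source: str | Path | Iterable[RawRead],
    barcode_map: BarcodeMap,
    enzyme: str | RestrictionEnzyme,
    params: QualityFilterParams = QualityFilterParams(),
    allow_one_mismatch_barcode: bool = False,
) -> tuple[dict[str, list[DemuxedRead]], DemuxReport]:
    """Demultiplex and quality-filter a read stream.

    ``source`` may be a FASTQ path or any iterable of :class:`RawRead`.
    Per-sample outputs preserve input order.  The quality filter runs on the
    barcode-trimmed read, so the decision is independent of which barcode a
    read carried.
    """
    enz = get_enzyme(enzyme)
    reads = read_fastq(source) if isinstance(source, (str, Path)) else source
    by_sample: dict[str, list[DemuxedRead]] = {s: [] for s in barcode_map.samples}
    report = DemuxReport(retained_by_sample={s: 0 for s in barcode_map.samples})
    for read in reads:
        report.total_reads += 1
        demuxed, reason = demultiplex_read(
            read, barcode_map, enz, allow_one_mismatch_barcode
        )
        if demuxed is None:
            report.discarded[reason] += 1
            continue
        if not sliding_window_quality_filter(demuxed, params):
            report.discarded[LOW_QUALITY] += 1
            continue
        by_sample[demuxed.sample_id].append(demuxed)
        report.retained_by_sample[demuxed.sample_id] += 1
    report.check_conservation()
    return by_sample, report
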