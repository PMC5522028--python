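"""Copy-number alteration detection from cut-site read depth.

RAD read depth at a cut site is proportional to the local copy number, so
copy-number alterations can be read off the depth ratio between a test
sample and a matched reference tissue.  The procedure:

1. count, per cut site, the reads that perfectly match the site (zero
   mismatches, start at the cut boundary), both directions summed;
2. merge 5 consecutive sites into a unit and average, to damp per-site
   depth fluctuation;
3. divide test by reference unit means after normalizing each sample by its
   total on-target read count; work in log2;
4. segment the per-unit log2 ratios by recursive binary splitting with a
   permutation test on the mean-shift statistic;
5. merge neighboring segments with similar means (the segmentation tends to
   hyper-segment long noisy stretches), then label segments as gain, loss
   or neutral by a log2 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import RadLocus
from .locus_assign import AssignedRead

__all__ = [
    "SegmentationParams",
    "CnvUnit",
    "CnvSegment",
    "site_depths",
    "merge_units",
    "depth_ratio",
    "segment_ratios",
    "merge_similar_segments",
    "call_cna",
    "detect_cna",
    "write_segments_bed",
]


def site_depths(
    assignments: Iterable[AssignedRead], catalog: Sequence[RadLocus]
) -> pd.DataFrame:
    """Perfect-match read count per cut site (both directions summed).

    Only reads assigned with zero mismatches contribute: a read whose body
    differs from the locus cannot be trusted to measure that site's copy
    number.  Returns a frame with columns chrom, cut_pos, depth, covering
    every site in the catalog (zeros included), in genomic order.
    """
    per_site: dict[tuple[str, int], int] = {}
    for loc in catalog:
        per_site.setdefault((loc.chrom, loc.cut_pos), 0)
    locus_site = {loc.locus_id: (loc.chrom, loc.cut_pos) for loc in catalog}
    for a in assignments:
        if a.on_target and a.mismatches == 0:
            per_site[locus_site[a.locus_id]] += 1
    rows = [(c, p, d) for (c, p), d in per_site.items()]
    return (
        pd.DataFrame(rows, columns=["chrom", "cut_pos", "depth"])
        .sort_values(["chrom", "cut_pos"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class CnvUnit:
    chrom: str
    index: int  # ordinal within the chromosome
    site_positions: tuple[int, ...]
    mean_depth: float


def merge_units(site_depth_table: pd.DataFrame, unit_size: int = 5) -> list[CnvUnit]:
    """Tile each chromosome's sites into consecutive blocks of ``unit_size``.

    Units are non-overlapping; a trailing remainder shorter than
    ``unit_size`` is dropped.  The unit depth is the arithmetic mean of its
    member sites' counts.
    """
    if unit_size < 1:
        raise ValueError("unit_size must be >= 1")
    units: list[CnvUnit] = []
    for chrom, grp in site_depth_table.groupby("chrom", sort=True):
        grp = grp.sort_values("cut_pos", kind="stable")
        pos = grp["cut_pos"].to_numpy()
        dep = grp["depth"].to_numpy(dtype=float)
        n_full = len(pos) // unit_size
        if n_full == 0:
            warnings.warn(
                f"{chrom}: {len(pos)} sites < unit_size {unit_size}; no units"
            )
            continue
        for i in range(n_full):
            sl = slice(i * unit_size, (i + 1) * unit_size)
            units.append(
                CnvUnit(chrom, i, tuple(int(p) for p in pos[sl]), float(dep[sl].mean()))
            )
    return units


def depth_ratio(
    test_units: Sequence[CnvUnit],
    reference_units: Sequence[CnvUnit],
    test_total: float | None = None,
    reference_total: float | None = None,
) -> pd.DataFrame:
    """Per-unit log2 depth ratio of test over reference.

    Each sample is scaled by its total read count (sum over its units by
    default, or the supplied on-target totals), so a global library-size
    difference cancels.  Units with zero reference depth are masked
    (ratio = NaN) and excluded from segmentation.
    """
    if [(u.chrom, u.index) for u in test_units] != [
        (u.chrom, u.index) for u in reference_units
    ]:
        raise ValueError("test and reference unit structures differ")
    t = np.array([u.mean_depth for u in test_units], dtype=float)
    r = np.array([u.mean_depth for u in reference_units], dtype=float)
    t_tot = float(test_total) if test_total is not None else float(t.sum())
    r_tot = float(reference_total) if reference_total is not None else float(r.sum())
    if t_tot <= 0 or r_tot <= 0:
        raise ValueError("non-positive normalization total")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (t / t_tot) / (r / r_tot)
        log2 = np.log2(ratio)
    log2[r == 0] = np.nan
    if np.all(np.isnan(log2)):
        raise ValueError("no unmasked units (all reference depths zero)")
    return pd.DataFrame(
        {
            "chrom": [u.chrom for u in test_units],
            "unit_index": [u.index for u in test_units],
            "start": [u.site_positions[0] for u in test_units],
            "end": [u.site_positions[-1] for u in test_units],
            "log2_ratio": log2,
        }
    )


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    first_unit: int  # inclusive, positions in the chromosome's unmasked unit list
    last_unit: int  # inclusive
    mean_log2: float
    n_units: int
    state: str = "neutral"  # gain | loss | neutral
    start: int = 0  # genomic span of the covered cut sites
    end: int = 0


@dataclass(frozen=True)
class SegmentationParams:
    n_permutations: int = 1000
    alpha: float = 0.01
    seed: int = 0


class _WindowStat:
    """Max mean-shift statistic over all windows [i, j) of a series.

    The statistic for a window against its complement is
    nW * nC / n * (meanW - meanC)^2 — the between-group sum of squares, i.e.
    the reduction in residual sum of squares from cutting the segment at i
    and j.  Scanning windows rather than single split points (the circular
    statistic of classic read-depth segmentation) keeps power when a
    segment contains two separated shifted regions, where no single split
    separates the means.
    """

    def __init__(self, n: int):
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        w = j - i
        self.valid = (w >= 1) & (w <= n - 1)
        self.n = n
        self.w = np.where(self.valid, w, 1)

    def best(self, x: np.ndarray) -> tuple[int, int, float]:
        csum = np.concatenate(([0.0], np.cumsum(x)))
        total = csum[-1]
        sum_w = csum[None, :] - csum[:, None]
        mean_w = sum_w / self.w
        mean_c = (total - sum_w) / (self.n - self.w)
        stat = np.where(
            self.valid, self.w * (self.n - self.w) / self.n * (mean_w - mean_c) ** 2, -1.0
        )
        flat = int(np.argmax(stat))
        i, j = divmod(flat, self.n + 1)
        return i, j, float(stat[i, j])

    def max_stat(self, x: np.ndarray) -> float:
        return self.best(x)[2]


def _segment_recursive(
    x: np.ndarray,
    offset: int,
    params: SegmentationParams,
    rng: np.random.Generator,
    breaks: list[int],
) -> None:
    n = len(x)
    if n < 2:
        return
    stat_calc = _WindowStat(n)
    i, j, stat = stat_calc.best(x)
    if stat <= 0:
        return
    perm_stats = np.empty(params.n_permutations)
    for k in range(params.n_permutations):
        perm_stats[k] = stat_calc.max_stat(rng.permutation(x))
    p = (1 + np.sum(perm_stats >= stat)) / (1 + params.n_permutations)
    if p > params.alpha:
        return
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    for c in cuts:
        breaks.append(offset + c)
    for lo, hi in zip([0] + cuts, cuts + [n]):
        _segment_recursive(x[lo:hi], offset + lo, params, rng, breaks)


def segment_ratios(
    ratio_table: pd.DataFrame, params: SegmentationParams = SegmentationParams()
) -> list[CnvSegment]:
    """Recursive binary segmentation of per-unit log2 ratios.

    Within each chromosome, the series of unmasked units is recursively
    split at the maximal mean-shift statistic; a split is accepted when its
    permutation p-value (unit order shuffled within the segment) is at most
    ``params.alpha``.  Deterministic for a fixed ``params.seed``.
    """
    segments: list[CnvSegment] = []
    rng = np.random.default_rng(params.seed)
    for chrom, grp in ratio_table.groupby("chrom", sort=True):
        grp = grp.dropna(subset=["log2_ratio"]).sort_values("unit_index", kind="stable")
        x = grp["log2_ratio"].to_numpy(dtype=float)
        if len(x) == 0:
            continue
        breaks: list[int] = []
        _segment_recursive(x, 0, params, rng, breaks)
        bounds = [0] + sorted(breaks) + [len(x)]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segments.append(
                CnvSegment(
                    chrom=chrom,
                    first_unit=lo,
                    last_unit=hi - 1,
                    mean_log2=float(x[lo:hi].mean()),
                    n_units=hi - lo,
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                )
            )
    return segments


def merge_similar_segments(
    segments: Sequence[CnvSegment], tol: float = 0.3
) -> list[CnvSegment]:
    """Merge adjacent segments whose means differ by less than ``tol`` log2.

    Repeatedly merges the adjacent same-chromosome pair with the smallest
    absolute mean difference while that difference is below ``tol``; merged
    means are unit-count-weighted.  Idempotent at the fixpoint.
    """
    segs = sorted(segments, key=lambda s: (s.chrom, s.first_unit))
    while True:
        best_i, best_d = None, tol
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a.chrom != b.chrom:
                continue
            d = abs(a.mean_log2 - b.mean_log2)
            if d < best_d:
                best_i, best_d = i, d
        if best_i is None:
            return segs
        a, b = segs[best_i], segs[best_i + 1]
        n = a.n_units + b.n_units
        merged = CnvSegment(
            chrom=a.chrom,
            first_unit=a.first_unit,
            last_unit=b.last_unit,
            mean_log2=(a.mean_log2 * a.n_units + b.mean_log2 * b.n_units) / n,
            n_units=n,
            start=a.start,
            end=b.end,
        )
        segs[best_i : best_i + 2] = [merged]


def call_cna(
    segments: Sequence[CnvSegment],
    gain_log2: float = 0.58,
    loss_log2: float = -0.58,
    min_units: int = 3,
) -> list[CnvSegment]:
    """Label merged segments gain/loss/neutral by log2 thresholds.

    Defaults of ±0.58 correspond to a 1.5-fold change — between diploid and
    a single-copy gain or loss in a pure sample; short segments (fewer than
    ``min_units`` units) are never called.
    """
    out = []
    for s in segments:
        state = "neutral"
        if s.n_units >= min_units:
            if s.mean_log2 >= gain_log2:
                state = "gain"
            elif s.mean_log2 <= loss_log2:
                state = "loss"
        out.append(replace(s, state=state))
    return out


def detect_cna(
    test_sites: pd.DataFrame,
    reference_sites: pd.DataFrame,
    unit_size: int = 5,
    seg_params: SegmentationParams = SegmentationParams(),
    merge_tol: float = 0.3,
    gain_log2: float = 0.58,
    loss_log2: float = -0.58,
    min_units: int = 3,
) -> tuple[list[CnvSegment], pd.DataFrame]:
    """Site depths -> labeled CNV segments (the full module pipeline)."""
    t_units = merge_units(test_sites, unit_size)
    r_units = merge_units(reference_sites, unit_size)
    ratios = depth_ratio(
        t_units,
        r_units,
        test_total=float(test_sites["depth"].sum()),
        reference_total=float(reference_sites["depth"].sum()),
    )
    segs = merge_similar_segments(segment_ratios(ratios, seg_params), merge_tol)
    return call_cna(segs, gain_log2, loss_log2, min_units), ratios


def write_segments_bed(segments: Sequence[CnvSegment], path: str | Path) -> None:
    """BED export: spanned cut-site range, name = state, score = log2 x 100."""
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t"
                f"{int(round(s.mean_log2 * 100))}\t.\n"
            )
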