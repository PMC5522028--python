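"""End-to-end orchestration: reads -> demux -> assignment -> pileups -> calls.

Thin glue over the stage modules, used by the command-line interface and
anywhere a whole tumor/normal workflow is run in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cnv import CnvSegment, SegmentationParams, detect_cna, site_depths
from .demux import (
    BarcodeMap,
    DemuxReport,
    QualityFilterParams,
    RawRead,
    process_fastq,
)
from .digest import RadLocus, RestrictionEnzyme, get_enzyme
from .locus_assign import (
    AssignedRead,
    CoverageReport,
    LocusIndex,
    assign_reads,
    build_locus_index,
    coverage_metrics,
)
from .somatic import (
    CallParams,
    CurationParams,
    SamplePileup,
    SomaticCall,
    build_pileup,
    call_and_curate,
)

__all__ = ["SampleResult", "process_reads", "tumor_normal_calls", "cna_from_results"]


@dataclass
class SampleResult:
    sample_id: str
    assignments: list[AssignedRead]
    pileup: SamplePileup
    coverage: CoverageReport


def process_reads(
    source: str | Path | Iterable[RawRead],
    barcode_map: BarcodeMap,
    enzyme: str | RestrictionEnzyme,
    catalog: Sequence[RadLocus],
    genome: Mapping[str, str],
    quality_params: QualityFilterParams = QualityFilterParams(),
    max_mismatch: int = 2,
    k: int = 20,
    index: LocusIndex | None = None,
) -> tuple[dict[str, SampleResult], DemuxReport]:
    """Demultiplex, assign and pile up every sample in a read stream."""
    enz = get_enzyme(enzyme)
    if index is None:
        index = build_locus_index(catalog, genome, enz, k)
    by_sample, report = process_fastq(source, barcode_map, enz, quality_params)
    results: dict[str, SampleResult] = {}
    for sample, reads in by_sample.items():
        assignments = assign_reads(reads, index, max_mismatch)
        pileup = build_pileup(assignments, index, sample)
        results[sample] = SampleResult(
            sample_id=sample,
            assignments=assignments,
            pileup=pileup,
            coverage=coverage_metrics(assignments, catalog),
        )
    return results, report


def tumor_normal_calls(
    results: Mapping[str, SampleResult],
    tumor: str,
    normal: str,
    call_params: CallParams = CallParams(),
    curation_params: CurationParams = CurationParams(),
) -> list[SomaticCall]:
    return call_and_curate(
        results[tumor].pileup, results[normal].pileup, call_params, curation_params
    )


def cna_from_results(
    results: Mapping[str, SampleResult],
    catalog: Sequence[RadLocus],
    test: str,
    reference: str,
    unit_size: int = 5,
    seg_params: SegmentationParams = SegmentationParams(),
    **kwargs,
) -> tuple[list[CnvSegment], "pd.DataFrame"]:
    t_sites = site_depths(results[test].assignments, catalog)
    r_sites = site_depths(results[reference].assignments, catalog)
    return detect_cna(t_sites, r_sites, unit_size, seg_params, **kwargs)
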