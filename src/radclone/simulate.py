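"""Clonal-tumor RAD read simulator with full ground truth.

Emulates the data-generating process of a RADseq tumor/normal study end to
end, on a single synthetic chromosome:

* an i.i.d. reference sequence at a chosen GC content with a fixed number
  of enzyme recognition sites planted at mutual spacing of at least two
  flank lengths (accidental occurrences are removed by resampling, so the
  in silico digest finds exactly the planted sites);
* a clone tree rooted at the normal genotype, each edge carrying a chosen
  number of heterozygous somatic SNVs placed inside locus flanks (never
  inside the recognition motif, so planted sites stay intact); a sample
  observes the genotype of one tree node diluted by its purity, giving an
  expected VAF of 0.5 x purity;
* copy-number events as genomic spans with a copy ratio, scaling the
  fragment yield of the cut sites they cover in the affected samples;
* barcoded single-end reads: ``barcode + residual + flank``, per-locus
  fragment counts Poisson at the configured mean depth, PCR duplicates
  sharing their fragment's barcode (and any pre-duplication PCR
  substitution), and uniform per-base sequencing error at the configured
  phred quality.

Every stage of the pipeline can be scored against the returned ground
truth without re-simulation.  All randomness flows from the single
mandatory seed; identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seq import BASE_BYTES, codes_to_seq, seq_to_codes
from .demux import BarcodeMap, RawRead
from .digest import RadLocus, RestrictionEnzyme, build_rad_loci, get_enzyme
from .locus_assign import expected_read_sequence
from .phylo import CloneNode, CloneTree, write_newick

__all__ = [
    "SampleSpec",
    "CnvEventSpec",
    "ArtifactSpec",
    "SimConfig",
    "PlantedMutation",
    "GroundTruth",
    "SimOutput",
    "simulate_genome",
    "simulate_clones",
    "simulate_reads",
    "simulate",
    "write_fastq",
    "write_fasta",
]


@dataclass(frozen=True)
class SampleSpec:
    """A sequenced sample: which clone-tree node it observes, at what purity.

    Purity is the fraction of cells carrying the node's genotype; the rest
    are normal.  Heterozygous diploid mutations then have expected VAF
    0.5 x purity.
    """

    node: str
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity {self.purity} outside [0, 1]")


@dataclass(frozen=True)
class CnvEventSpec:
    """A copy-number event: genomic span and copy ratio (1.0 = neutral).

    Applies to the listed samples, or to every non-root sample when
    ``samples`` is None.  The effective depth scaling in a sample is
    diluted by its purity: 1 + purity x (copy_ratio - 1).
    """

    start: int
    end: int
    copy_ratio: float
    samples: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ArtifactSpec:
    """A forced PCR-duplication artifact for stress-testing curation.

    Injects one fragment carrying a substitution at ``offset`` of the
    chosen locus, amplified into ``n_reads`` identical reads that all share
    a single barcode — the signature the multi-barcode filter must reject.
    """

    sample: str
    site_index: int
    direction: str = "downstream"
    offset: int = 10
    n_reads: int = 8


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the melanoma tumor/normal design: SbfI loci with 100 bp
    flanks, four 5 bp barcodes per sample, ~350x per-locus depth, Q30
    sequencing error, tumor purity 0.6, and a single tumor clone carrying
    heterozygous somatic SNVs.
    """

    seed: int  # mandatory; all randomness derives from it
    genome_len: int = 200_000
    gc: float = 0.4
    chrom: str = "chr1"
    enzyme: str = "SbfI"
    flank_len: int = 100
    n_sites: int = 50
    # clone tree: node -> (parent node, mutations on the incoming edge)
    tree: dict[str, tuple[str, int]] = field(
        default_factory=lambda: {"clone": ("root", 20)}
    )
    samples: dict[str, SampleSpec] = field(
        default_factory=lambda: {
            "normal": SampleSpec("root"),
            "tumor": SampleSpec("clone", purity=0.6),
        }
    )
    cnv_events: tuple[CnvEventSpec, ...] = ()
    mean_depth: float = 350.0
    phred: int = 30
    seq_error_rate: float | None = None  # None -> 10**(-phred/10)
    duplicate_fraction: float = 0.15
    pcr_error_rate: float = 0.001  # per base, on the fragment before duplication
    barcodes_per_sample: int = 4
    barcode_len: int = 5
    scramble_barcode_fraction: float = 0.0
    artifacts: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self) -> None:
        for name, rate in (
            ("gc", self.gc),
            ("duplicate_fraction", self.duplicate_fraction),
            ("pcr_error_rate", self.pcr_error_rate),
            ("scramble_barcode_fraction", self.scramble_barcode_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} {rate} outside [0, 1]")
        if self.duplicate_fraction >= 1.0:
            raise ValueError("duplicate_fraction must be < 1")
        if self.genome_len < 10 * self.flank_len:
            raise ValueError("genome_len must be at least 10 flank lengths")
        roots = {p for p, _ in self.tree.values()} - set(self.tree)
        if self.tree and roots != {"root"}:
            raise ValueError(f"tree must hang from the implicit 'root', got {roots}")
        for s, spec in self.samples.items():
            if spec.node != "root" and spec.node not in self.tree:
                raise ValueError(f"sample {s} observes unknown node {spec.node}")


@dataclass(frozen=True)
class PlantedMutation:
    chrom: str
    pos0: int  # 0-based top-strand position
    ref: str
    alt: str
    edge: str  # clone-tree node whose incoming edge carries the mutation

    @property
    def mutation_id(self) -> str:
        return f"{self.chrom}:{self.pos0 + 1}:{self.ref}>{self.alt}"


@dataclass
class GroundTruth:
    sites: list[int]  # planted cut positions
    mutations: list[PlantedMutation]
    node_mutations: dict[str, list[PlantedMutation]]  # per edge
    sample_mutations: dict[str, list[PlantedMutation]]  # per sample (root-path union)
    sample_expected_vaf: dict[str, float]
    cnv_events: list[CnvEventSpec]
    tree_newick: str
    # per-read provenance, parallel lists in read order
    read_ids: list[str] = field(default_factory=list)
    read_sample: list[str] = field(default_factory=list)
    read_locus: list[str] = field(default_factory=list)
    read_fragment: list[int] = field(default_factory=list)
    read_duplicate_of: list[str | None] = field(default_factory=list)
    read_barcode: list[str] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "sites": self.sites,
            "mutations": [asdict(m) for m in self.mutations],
            "sample_mutations": {
                s: [m.mutation_id for m in ms]
                for s, ms in self.sample_mutations.items()
            },
            "sample_expected_vaf": self.sample_expected_vaf,
            "cnv_events": [asdict(e) for e in self.cnv_events],
            "tree_newick": self.tree_newick,
            "reads": [
                {
                    "read_id": rid,
                    "sample": s,
                    "locus_id": loc,
                    "fragment": frag,
                    "duplicate_of": dup,
                    "barcode": bc,
                }
                for rid, s, loc, frag, dup, bc in zip(
                    self.read_ids,
                    self.read_sample,
                    self.read_locus,
                    self.read_fragment,
                    self.read_duplicate_of,
                    self.read_barcode,
                )
            ],
        }


@dataclass
class SimOutput:
    config: SimConfig
    genome: dict[str, str]
    catalog: list[RadLocus]
    barcode_map: BarcodeMap
    reads: list[RawRead]
    truth: GroundTruth


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[int]]:
    """I.i.d. genome with exactly ``n_sites`` planted recognition sites.

    Sites are placed one per equal-width slot with jitter, guaranteeing
    inter-site spacing of at least ``2 * flank_len + motif``; accidental
    motif occurrences created by the background sequence are removed by
    resampling one of their bases, so a digest finds exactly the planted
    sites.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    enz = get_enzyme(config.enzyme)
    L = enz.motif_len
    g = config.gc
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]  # A C G T
    codes = rng.choice(4, size=config.genome_len, p=probs).astype(np.uint8)
    slot = config.genome_len // config.n_sites
    if slot < 2 * config.flank_len + L + 1:
        raise ValueError(
            f"cannot place {config.n_sites} sites at >= 2 x flank spacing in "
            f"{config.genome_len} bp"
        )
    motif_codes = seq_to_codes(enz.recognition)
    starts = []
    for i in range(config.n_sites):
        lo = i * slot + config.flank_len
        hi = (i + 1) * slot - config.flank_len - L
        m = int(rng.integers(lo, hi + 1))
        starts.append(m)
        codes[m : m + L] = motif_codes
    planted = set(starts)
    seq = codes_to_seq(codes)
    for _ in range(100):
        accidental = [
            i
            for i in _find_all(seq, enz.recognition)
            if i not in planted
        ]
        if not accidental:
            break
        for i in accidental:
            old = codes[i + L // 2]
            codes[i + L // 2] = (old + 1 + rng.integers(0, 3)) % 4
        seq = codes_to_seq(codes)
    else:
        raise RuntimeError("could not purge accidental motif occurrences")
    cuts = [m + enz.cut_offset_top for m in starts]
    return {config.chrom: seq}, cuts


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _truth_tree(config: SimConfig, node_mutations: Mapping[str, list]) -> str:
    """Newick of the simulated clone tree with per-edge mutation counts."""
    nodes: dict[str, CloneNode] = {"root": CloneNode(name="Normal")}
    for name in config.tree:
        nodes[name] = CloneNode(name=name)
    for name, (parent, _) in config.tree.items():
        nodes[parent].children.append(nodes[name])
        nodes[name].edge_mutations = [m.mutation_id for m in node_mutations[name]]
    return write_newick(CloneTree(root=nodes["root"]))


def simulate_clones(
    config: SimConfig,
    genome: Mapping[str, str],
    sites: Sequence[int],
    rng: np.random.Generator,
) -> GroundTruth:
    """Plant edge mutations inside locus flanks and derive sample genotypes.

    Positions are drawn without replacement from the union of locus flank
    intervals minus recognition-motif footprints (so every mutation is
    observable and no planted site is destroyed).  Each sample's mutation
    set is the union over its node's root path; expected VAF is
    0.5 x purity.
    """
    enz = get_enzyme(config.enzyme)
    seq = genome[config.chrom]
    L = enz.motif_len
    reserved = set()  # artifact positions are unplanted by definition
    for art in config.artifacts:
        cut = sites[art.site_index]
        reserved.add(
            cut + art.offset if art.direction == "downstream" else cut - 1 - art.offset
        )
    candidates: list[int] = []
    for c in sites:
        m = c - enz.cut_offset_top
        lo = max(0, c - config.flank_len)
        hi = min(len(seq), c + config.flank_len)
        candidates.extend(
            p for p in range(lo, hi) if not m <= p < m + L and p not in reserved
        )
    n_total = sum(n for _, n in config.tree.values())
    if n_total > len(candidates):
        raise ValueError(
            f"{n_total} mutations requested but only {len(candidates)} "
            "flank positions available"
        )
    chosen = rng.choice(len(candidates), size=n_total, replace=False)
    positions = [candidates[i] for i in chosen]
    node_mutations: dict[str, list[PlantedMutation]] = {}
    k = 0
    for node, (_, n) in config.tree.items():
        muts = []
        for pos in positions[k : k + n]:
            ref = seq[pos]
            others = [b for b in "ACGT" if b != ref]
            alt = others[int(rng.integers(0, 3))]
            muts.append(PlantedMutation(config.chrom, pos, ref, alt, node))
        node_mutations[node] = sorted(muts, key=lambda m: m.pos0)
        k += n
    parents = {node: parent for node, (parent, _) in config.tree.items()}
    sample_mutations: dict[str, list[PlantedMutation]] = {}
    for sample, spec in config.samples.items():
        acc: list[PlantedMutation] = []
        node = spec.node
        while node != "root":
            acc.extend(node_mutations[node])
            node = parents[node]
        sample_mutations[sample] = sorted(acc, key=lambda m: m.pos0)
    return GroundTruth(
        sites=list(sites),
        mutations=[m for ms in node_mutations.values() for m in ms],
        node_mutations=node_mutations,
        sample_mutations=sample_mutations,
        sample_expected_vaf={
            s: 0.5 * spec.purity for s, spec in config.samples.items()
        },
        cnv_events=list(config.cnv_events),
        tree_newick=_truth_tree(config, node_mutations),
    )


def _make_barcodes(config: SimConfig, rng: np.random.Generator) -> BarcodeMap:
    """Greedy Hamming-distance-3 barcode code, four barcodes per sample."""
    n_needed = len(config.samples) * config.barcodes_per_sample
    k = config.barcode_len
    pool = rng.permutation(4**k)
    chosen: list[np.ndarray] = []
    for v in pool:
        digits = np.array([(v // 4**i) % 4 for i in range(k)], dtype=np.uint8)
        if all(np.sum(digits != c) >= 3 for c in chosen):
            chosen.append(digits)
            if len(chosen) == n_needed:
                break
    if len(chosen) < n_needed:
        raise ValueError(
            f"cannot build {n_needed} barcodes of length {k} at Hamming distance 3"
        )
    entries = {}
    it = iter(chosen)
    for sample in sorted(config.samples):
        entries[sample] = {
            codes_to_seq(next(it)) for _ in range(config.barcodes_per_sample)
        }
    return BarcodeMap(entries)


def _copy_ratio(config: SimConfig, sample: str, cut_pos: int) -> float:
    spec = config.samples[sample]
    ratio = 1.0
    for ev in config.cnv_events:
        applies = ev.samples is None or sample in ev.samples
        if ev.samples is None and spec.node == "root":
            applies = False
        if applies and ev.start <= cut_pos < ev.end:
            ratio *= 1.0 + spec.purity * (ev.copy_ratio - 1.0)
    return ratio


def simulate_reads(
    config: SimConfig,
    genome: Mapping[str, str],
    catalog: Sequence[RadLocus],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[list[RawRead], BarcodeMap]:
    """Generate multiplexed reads for every sample; provenance goes to truth.

    Per sample and locus the fragment count is Poisson(mean_depth x local
    copy ratio).  A fragment picks one of the sample's barcodes, carries
    each of the sample's mutations with probability purity x 0.5, may gain
    a pre-duplication PCR substitution, and is emitted as 1 + Poisson(d/(1-d))
    reads (so the expected duplicate fraction is ``duplicate_fraction``),
    each with independent per-base sequencing errors at the configured
    phred.
    """
    enz = get_enzyme(config.enzyme)
    res_len = len(enz.residual)
    lam_dup = (
        config.duplicate_fraction / (1.0 - config.duplicate_fraction)
        if config.duplicate_fraction > 0
        else 0.0
    )
    seq_err = (
        config.seq_error_rate
        if config.seq_error_rate is not None
        else 10.0 ** (-config.phred / 10.0)
    )
    qual_char = chr(config.phred + 33)
    barcode_map = _make_barcodes(config, rng)
    # mutations indexed by (locus_id, read offset in flank) with read-oriented alt
    by_locus_offset: dict[str, list[tuple[int, int, PlantedMutation]]] = {}
    locus_templates: dict[str, np.ndarray] = {}
    for loc in catalog:
        expected = expected_read_sequence(loc, genome, enz)
        locus_templates[loc.locus_id] = seq_to_codes(expected)
    for mut in truth.mutations:
        for loc in catalog:
            if loc.start <= mut.pos0 < loc.end:
                if loc.direction == "downstream":
                    off = mut.pos0 - loc.cut_pos
                    alt_code = int(seq_to_codes(mut.alt)[0])
                else:
                    off = loc.cut_pos - 1 - mut.pos0
                    alt_code = 3 - int(seq_to_codes(mut.alt)[0])  # complement
                by_locus_offset.setdefault(loc.locus_id, []).append(
                    (off, alt_code, mut)
                )
    reads: list[RawRead] = []
    read_counter = 0
    frag_counter = 0
    artifact_lookup: dict[tuple[str, str], list[ArtifactSpec]] = {}
    suffix = {"downstream": "dn", "upstream": "up"}
    for art in config.artifacts:
        cut = truth.sites[art.site_index]
        locus_id = f"{config.chrom}:{cut}:{suffix[art.direction]}"
        artifact_lookup.setdefault((art.sample, locus_id), []).append(art)
    scramble = config.scramble_barcode_fraction
    for sample in sorted(config.samples):
        spec = config.samples[sample]
        barcodes = sorted(barcode_map.entries[sample])
        sample_muts = {m.mutation_id for m in truth.sample_mutations[sample]}
        for loc in catalog:
            template = locus_templates[loc.locus_id]
            width = len(template)
            ratio = _copy_ratio(config, sample, loc.cut_pos)
            n_frag = int(rng.poisson(config.mean_depth * ratio))
            muts_here = [
                (off, alt, m)
                for off, alt, m in by_locus_offset.get(loc.locus_id, [])
                if m.mutation_id in sample_muts
            ]
            if n_frag > 0:
                frags = np.tile(template, (n_frag, 1))
                clonal = rng.random(n_frag) < spec.purity
                for off, alt_code, _ in muts_here:
                    carry = clonal & (rng.random(n_frag) < 0.5)
                    frags[carry, res_len + off] = alt_code
                if config.pcr_error_rate > 0:
                    err = rng.random(frags.shape) < config.pcr_error_rate
                    if err.any():
                        shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                        frags[err] = (frags[err] + shift) % 4
                bc_idx = rng.integers(0, len(barcodes), size=n_frag)
                n_dups = (
                    rng.poisson(lam_dup, size=n_frag)
                    if lam_dup > 0
                    else np.zeros(n_frag, dtype=int)
                )
                copies = 1 + n_dups
                total_reads = int(copies.sum())
                mat = np.repeat(frags, copies, axis=0)
                if seq_err > 0:
                    err = rng.random(mat.shape) < seq_err
                    if err.any():
                        shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                        mat[err] = (mat[err] + shift) % 4
                bodies = BASE_BYTES[mat].view(f"S{width}").ravel()
                row = 0
                for f in range(n_frag):
                    frag_id = frag_counter
                    frag_counter += 1
                    first_id = None
                    for _copy in range(int(copies[f])):
                        read_id = f"r{read_counter}"
                        read_counter += 1
                        barcode = barcodes[int(bc_idx[f])]
                        if scramble > 0 and rng.random() < scramble:
                            while True:
                                bc = codes_to_seq(
                                    rng.integers(
                                        0, 4, size=config.barcode_len
                                    ).astype(np.uint8)
                                )
                                if barcode_map.sample_of(bc) is None:
                                    break
                            barcode_out = bc
                        else:
                            barcode_out = barcode
                        body = bodies[row].decode("ascii")
                        row += 1
                        bases = barcode_out + body
                        quals = np.full(len(bases), config.phred, dtype=np.int32)
                        reads.append(RawRead(read_id, bases, quals))
                        truth.read_ids.append(read_id)
                        truth.read_sample.append(sample)
                        truth.read_locus.append(loc.locus_id)
                        truth.read_fragment.append(frag_id)
                        truth.read_duplicate_of.append(first_id)
                        truth.read_barcode.append(barcode)
                        if first_id is None:
                            first_id = read_id
            for art in artifact_lookup.get((sample, loc.locus_id), []):
                frag_id = frag_counter
                frag_counter += 1
                art_codes = template.copy()
                ref_code = art_codes[res_len + art.offset]
                art_codes[res_len + art.offset] = (ref_code + 1) % 4
                body = codes_to_seq(art_codes)
                barcode = barcodes[int(rng.integers(0, len(barcodes)))]
                first_id = None
                for _ in range(art.n_reads):
                    read_id = f"r{read_counter}"
                    read_counter += 1
                    bases = barcode + body
                    quals = np.full(len(bases), config.phred, dtype=np.int32)
                    reads.append(RawRead(read_id, bases, quals))
                    truth.read_ids.append(read_id)
                    truth.read_sample.append(sample)
                    truth.read_locus.append(loc.locus_id)
                    truth.read_fragment.append(frag_id)
                    truth.read_duplicate_of.append(first_id)
                    truth.read_barcode.append(barcode)
                    if first_id is None:
                        first_id = read_id
    return reads, barcode_map


def simulate(config: SimConfig) -> SimOutput:
    """Run the full generator: genome, clones, reads, ground truth."""
    rng = np.random.default_rng(config.seed)
    genome, sites = simulate_genome(config, rng)
    catalog, _ = build_rad_loci(genome, config.enzyme, config.flank_len)
    truth = simulate_clones(config, genome, sites, rng)
    reads, barcode_map = simulate_reads(config, genome, catalog, truth, rng)
    return SimOutput(config, genome, catalog, barcode_map, reads, truth)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Sequence[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def write_outputs(out: SimOutput, outdir: str | Path) -> None:
    """FASTA, FASTQ, barcode TSV, truth manifest JSON, newick and CNV BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(out.genome, outdir / "genome.fa")
    write_fastq(out.reads, outdir / "reads.fq")
    out.barcode_map.to_tsv(outdir / "barcodes.tsv")
    (outdir / "truth_tree.nwk").write_text(out.truth.tree_newick + "\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(out.truth.manifest(), fh, indent=1)
    with open(outdir / "truth_cnv.bed", "w") as fh:
        for ev in out.truth.cnv_events:
            who = ",".join(ev.samples) if ev.samples else "all_tumor"
            fh.write(
                f"{out.config.chrom}\t{ev.start}\t{ev.end}\t"
                f"ratio={ev.copy_ratio};samples={who}\n"
            )
    with open(outdir / "truth_mutations.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tedge\n")
        for m in out.truth.mutations:
            fh.write(f"{m.chrom}\t{m.pos0 + 1}\t{m.ref}\t{m.alt}\t{m.edge}\n")
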