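"""Seeded generators emulating the study inputs of a synthetic-locus assay.

Everything downstream of sequencing — composition tables, coverage
windows, CAGE-derived TSSs, metaplots — can be exercised on data built
here: an i.i.d. host "genome" with annotated genes and excluded regions,
a forward/reversed/CpG-scrubbed locus trio, stranded signal tracks with
peaks planted at chosen TSS positions over Poisson background, CAGE peak
files whose 5' boundaries are the planted TSSs, and read-interval tables
with chosen per-window densities.

Every generator is a pure function of its seed and spec: rerunning with
the same seed produces byte-identical files.  Alongside each generated
dataset a *truth table* records the planted quantities, so tests compare
pipeline output against bookkeeping rather than hard-coded numbers.

The default fixture (:func:`make_default_state_fixture`) contrasts two
host regimes: "host A", where the integrated locus carries a dense set
of planted TSSs (an active, yeast-like default state), and "host B",
where the locus has none and its read count sits below the geneless-
window background (an inactive, mouse-ES-like default state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io_formats import (
    CoverageTrack,
    GenomicInterval,
    PeakSet,
    ReadRecord,
    SequenceRecord,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_read_table,
)
from .locus_design import ScrubResult, reverse_sequence, scrub_cpg

__all__ = [
    "ContigSpec",
    "PlantedTss",
    "PeakShape",
    "SimulationSpec",
    "GenomeBuild",
    "LocusTrio",
    "SignalBundle",
    "random_sequence",
    "make_genome",
    "make_locus_trio",
    "scrub_position_map",
    "simulate_signal",
    "simulate_read_table",
    "make_default_state_fixture",
]


@dataclass(frozen=True)
class ContigSpec:
    name: str
    length: int
    gc: float = 0.40

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ParameterError(f"contig {self.name}: non-positive length")
        if not 0.0 <= self.gc <= 1.0:
            raise ParameterError(f"contig {self.name}: gc outside [0, 1]")


@dataclass(frozen=True)
class PlantedTss:
    contig: str
    position: int
    strand: str
    strength: float = 1.0


@dataclass(frozen=True)
class PeakShape:
    kind: str = "gaussian"  # delta | gaussian | flat-top
    width: float = 150.0
    height: float = 5.0


@dataclass
class SimulationSpec:
    """Study conditions for one simulated dataset.

    Defaults describe a desk-scale yeast-like host: a 2-Mb genome of
    four 500-kb contigs at GC 0.38, one 100-kb locus at GC 0.41 (the GC
    of the natural template locus), Poisson shot-noise background, and
    Gaussian signal bumps of width 150 bp at planted TSSs.
    """

    seed: int = 0
    genome: list[ContigSpec] = field(default_factory=lambda: [
        ContigSpec("chrI", 500_000, 0.38),
        ContigSpec("chrII", 500_000, 0.38),
        ContigSpec("chrIII", 500_000, 0.38),
        ContigSpec("chrIV", 500_000, 0.38),
    ])
    locus_length: int = 100_000
    locus_gc: float = 0.41
    locus_tss: list[PlantedTss] = field(default_factory=list)
    background_rate: float = 0.5  # mean signal per bp
    peak_shape: PeakShape = field(default_factory=PeakShape)
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ParameterError("copy_number must be >= 0")
        for t in self.locus_tss:
            if not 0 <= t.position < self.locus_length:
                raise ParameterError(
                    f"planted TSS at {t.position} outside locus [0, {self.locus_length})"
                )


@dataclass
class GenomeBuild:
    contigs: list[SequenceRecord]
    genes: PeakSet
    exclusions: PeakSet  # genes + blacklist + centromeres + telomeres

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.contigs}


@dataclass
class LocusTrio:
    forward: SequenceRecord
    reversed: SequenceRecord
    scrubbed: SequenceRecord
    scrub_result: ScrubResult
    # planted feature coordinates in each frame: name -> (fwd, rev, scrubbed)
    bookkeeping: dict[str, dict[str, int | None]]


@dataclass
class SignalBundle:
    plus: CoverageTrack
    minus: CoverageTrack
    cage_peaks: PeakSet
    reads: list[ReadRecord]
    truth: dict


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """An i.i.d. base string at the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list("ACGT"))[idx])


def make_genome(spec: SimulationSpec,
                gene_length: int = 2_000,
                gene_spacing: int = 25_000,
                genic_fraction: float = 0.4,
                telomere_length: int = 5_000) -> GenomeBuild:
    """Build an i.i.d. host genome with genes and excluded regions.

    Genes are planted on a jittered grid (one per ``gene_spacing`` bp)
    confined to the first ``genic_fraction`` of each contig, leaving the
    remainder as gene deserts — without them no 100-kb window would
    survive geneless filtering, unlike a real genome.  Each contig also
    gets two telomeres and a central centromere; genes and all excluded
    features are pooled into the exclusion set used by geneless-window
    filtering.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    contigs, genes, exclusions = [], [], []
    for c in spec.genome:
        contigs.append(SequenceRecord(c.name, random_sequence(rng, c.length, c.gc)))
        genic_end = int(c.length * genic_fraction)
        n_genes = max((genic_end - telomere_length) // gene_spacing, 0)
        for g in range(n_genes):
            lo = telomere_length + g * gene_spacing
            hi = min(telomere_length + (g + 1) * gene_spacing, genic_end) - gene_length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.integers(2) == 0 else "-"
            genes.append(GenomicInterval(c.name, start, start + gene_length, strand))
        exclusions.append(GenomicInterval(c.name, 0, telomere_length, "."))
        exclusions.append(
            GenomicInterval(c.name, c.length - telomere_length, c.length, ".")
        )
        mid = c.length // 2
        exclusions.append(GenomicInterval(c.name, mid - 1_000, mid + 1_000, "."))
    exclusions.extend(genes)
    return GenomeBuild(contigs=contigs, genes=PeakSet(genes),
                       exclusions=PeakSet(exclusions))


def make_locus_trio(spec: SimulationSpec, locus_id: str = "synLocus") -> LocusTrio:
    """A forward locus plus its reversed and CpG-scrubbed variants.

    The reversed member is produced by :func:`~locusforge.locus_design.
    reverse_sequence` and the scrubbed member by scrubbing the reversed
    sequence.  Bookkeeping maps each planted TSS through all three
    coordinate frames (``None`` where the base was deleted by
    scrubbing).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    forward = SequenceRecord(locus_id, random_sequence(rng, spec.locus_length, spec.locus_gc))
    rev = reverse_sequence(forward)
    scrub = scrub_cpg(rev, seed=spec.seed + 1)
    rev_to_scrub = scrub_position_map(len(rev), scrub.deletions)
    bookkeeping: dict[str, dict[str, int | None]] = {}
    length = spec.locus_length
    for i, t in enumerate(spec.locus_tss):
        rev_pos = length - 1 - t.position
        mapped = int(rev_to_scrub[rev_pos]) if rev_to_scrub[rev_pos] >= 0 else None
        bookkeeping[f"tss_{i + 1}"] = {
            "forward": t.position, "reversed": rev_pos, "scrubbed": mapped,
        }
    return LocusTrio(forward=forward, reversed=rev, scrubbed=scrub.scrubbed,
                     scrub_result=scrub, bookkeeping=bookkeeping)


def scrub_position_map(length: int, deletions) -> np.ndarray:
    """Map input coordinates through a scrub deletion log.

    Returns an array where entry i is the position of input base i in
    the scrubbed output, or -1 if that base was deleted.
    """
    surviving = list(range(length))
    deleted = []
    for d in deletions:
        deleted.append(surviving[d.position])
        del surviving[d.position]
    out = np.full(length, -1, dtype=np.int64)
    out[np.asarray(surviving, dtype=np.int64)] = np.arange(len(surviving))
    return out


def _bump(shape: PeakShape, offsets: np.ndarray) -> np.ndarray:
    if shape.kind == "delta":
        return np.where(offsets == 0, shape.height, 0.0)
    if shape.kind == "gaussian":
        return shape.height * np.exp(-0.5 * (offsets / shape.width) ** 2)
    if shape.kind == "flat-top":
        return np.where(np.abs(offsets) <= shape.width / 2, shape.height, 0.0)
    raise ParameterError(f"unknown peak shape {shape.kind!r}")


def simulate_signal(spec: SimulationSpec,
                    contig_lengths: dict[str, int],
                    tss_list: list[PlantedTss],
                    resolution: int = 10,
                    cage_peak_width: int = 50,
                    stream: int = 303) -> SignalBundle:
    """Stranded signal tracks, CAGE peaks and reads around planted TSSs.

    Background is per-bin Poisson shot noise at ``background_rate``
    signal per bp; each planted TSS adds a ``peak_shape`` bump on its
    own strand, scaled by the TSS strength and the locus copy number.
    CAGE peaks are written so their 5' boundary is exactly the planted
    TSS.  Reads are Poisson-placed at the background rate (see
    :func:`simulate_read_table` for controlled per-window densities).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))
    plus, minus = {}, {}
    for contig, length in contig_lengths.items():
        n_bins = -(-length // resolution)
        lam = spec.background_rate * resolution
        plus[contig] = rng.poisson(lam, n_bins) / resolution
        minus[contig] = rng.poisson(lam, n_bins) / resolution
    cage, scores = [], []
    for t in tss_list:
        if t.contig not in contig_lengths:
            raise ParameterError(f"TSS on unknown contig {t.contig!r}")
        length = contig_lengths[t.contig]
        n_bins = len(plus[t.contig])
        scale = t.strength * max(spec.copy_number, 1)
        target = plus if t.strand == "+" else minus
        if spec.peak_shape.kind == "delta":
            # all mass in the bin containing the TSS base; the bin holds
            # the per-base mean, so a height-h spike contributes h/res
            target[t.contig] = target[t.contig].copy()
            target[t.contig][t.position // resolution] += \
                spec.peak_shape.height * scale / resolution
        else:
            centers = np.arange(n_bins) * resolution + resolution / 2
            bump = _bump(spec.peak_shape, centers - t.position) * scale
            target[t.contig] = target[t.contig] + bump
        if t.strand == "+":
            peak = GenomicInterval(
                t.contig, t.position,
                min(t.position + cage_peak_width, length), "+")
        else:
            peak = GenomicInterval(
                t.contig, max(t.position - cage_peak_width + 1, 0),
                t.position + 1, "-")
        cage.append(peak)
        scores.append(t.strength)
    reads = simulate_read_table(
        rng, contig_lengths,
        rate_per_bp={c: spec.background_rate / 100 for c in contig_lengths},
    )
    truth = {
        "planted_tss": [asdict(t) for t in tss_list],
        "background_rate": spec.background_rate,
        "copy_number": spec.copy_number,
        "peak_shape": asdict(spec.peak_shape),
    }
    lengths = dict(contig_lengths)
    return SignalBundle(
        plus=CoverageTrack(plus, resolution=resolution, contig_lengths=lengths),
        minus=CoverageTrack(minus, resolution=resolution, contig_lengths=lengths),
        cage_peaks=PeakSet(cage, scores),
        reads=reads,
        truth=truth,
    )


def simulate_read_table(rng: np.random.Generator,
                        contig_lengths: dict[str, int],
                        rate_per_bp: dict[str, float],
                        read_length: int = 100,
                        frac_secondary: float = 0.02,
                        frac_supplementary: float = 0.01,
                        frac_duplicate: float = 0.05) -> list[ReadRecord]:
    """Uniformly placed reads at a per-contig density, with a SAM-flag mix.

    The read count per contig is Poisson(rate * length); start positions
    are uniform, so any window of W bp sees ~Poisson(rate * W) reads.
    A stated fraction of reads carries the secondary (256),
    supplementary (2048) or duplicate (1024) flag.
    """
    reads: list[ReadRecord] = []
    for contig, length in contig_lengths.items():
        rate = rate_per_bp.get(contig, 0.0)
        n = int(rng.poisson(rate * length))
        if n == 0:
            continue
        starts = np.sort(rng.integers(0, max(length - read_length, 1), size=n))
        u = rng.random(n)
        flags = np.zeros(n, dtype=int)
        flags[u < frac_secondary] = 256
        sel = (u >= frac_secondary) & (u < frac_secondary + frac_supplementary)
        flags[sel] = 2048
        sel = (u >= frac_secondary + frac_supplementary) \
            & (u < frac_secondary + frac_supplementary + frac_duplicate)
        flags[sel] = 1024
        for s, f in zip(starts, flags):
            end = min(int(s) + read_length, length)
            reads.append(ReadRecord(GenomicInterval(contig, int(s), end), int(f)))
    return reads


def _jittered_grid(rng: np.random.Generator, length: int, n: int,
                   jitter: int, margin: int) -> np.ndarray:
    """n quasi-uniform positions: an even grid with bounded jitter."""
    grid = margin + (np.arange(n) + 0.5) * (length - 2 * margin) / n
    pos = grid + rng.integers(-jitter, jitter + 1, size=n)
    return np.clip(pos.astype(int), 0, length - 1)


def make_default_state_fixture(seed: int, out_dir: str | Path | None = None,
                               locus_tss_count: int = 12,
                               genome_tss_per_100kb: float = 4.0,
                               geneless_read_lambda: float = 20.0,
                               locus_read_lambda: float = 1.0,
                               wgs_depth: float = 30.0,
                               copy_number: int = 1) -> dict:
    """End-to-end "two default states" dataset.

    Builds one host genome plus a locus trio whose reversed member is
    integrated as its own contig, then two signal regimes over it:

    * **host A** (active): ~12 planted TSSs across the 100-kb locus and
      a genome-wide TSS grid at 4 per 100 kb, so the planted locus/genome
      CAGE density ratio is ~3 — the regime where naive DNA is pervasively
      transcribed.
    * **host B** (inactive): no locus TSSs; reads fall on the genome at
      ~20 per 100-kb window but on the locus at ~1, placing the locus
      below the geneless-window median.

    Returns a dict of in-memory objects plus a ``truth`` table; when
    ``out_dir`` is given, all files (FASTA/BED/bedGraph/TSV/JSON) are
    written there as well.  Byte-identical across reruns with one seed.
    """
    spec = SimulationSpec(seed=seed, copy_number=copy_number)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))

    genome = make_genome(spec)
    trio = make_locus_trio(spec)
    locus_contig = trio.reversed.id  # the integrated, naive variant
    locus_length = len(trio.reversed)
    contig_lengths = genome.contig_lengths | {locus_contig: locus_length}
    locus_region = GenomicInterval(locus_contig, 0, locus_length, ".")

    # --- host A: planted TSSs on locus and genome ---------------------
    locus_positions = _jittered_grid(rng, locus_length, locus_tss_count,
                                     jitter=2_000, margin=3_000)
    tss_a = [
        PlantedTss(locus_contig, int(p), "+" if i % 2 == 0 else "-", 1.0)
        for i, p in enumerate(locus_positions)
    ]
    for c in spec.genome:
        n = int(round(genome_tss_per_100kb * c.length / 100_000))
        for i, p in enumerate(_jittered_grid(rng, c.length, n,
                                             jitter=8_000, margin=2_000)):
            tss_a.append(PlantedTss(c.name, int(p), "+" if i % 2 == 0 else "-", 1.0))
    host_a = simulate_signal(spec, contig_lengths, tss_a, stream=505)

    # --- host B: background-only locus, gene-level genome reads -------
    rng_b = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    rates = {c.name: geneless_read_lambda / 100_000 for c in spec.genome}
    rates[locus_contig] = locus_read_lambda / 100_000
    host_b_reads = simulate_read_table(rng_b, contig_lengths, rates)

    # --- WGS-like depth track for copy-number estimation --------------
    rng_w = np.random.default_rng(np.random.SeedSequence([seed, 707]))
    wgs_data = {}
    for contig, length in contig_lengths.items():
        n_bins = -(-length // 10)
        lam = wgs_depth * (copy_number if contig == locus_contig else 1)
        wgs_data[contig] = rng_w.poisson(lam, n_bins).astype(float)
    wgs = CoverageTrack(wgs_data, resolution=10, contig_lengths=contig_lengths)

    genome_bp = sum(c.length for c in spec.genome)
    n_genome_tss = sum(1 for t in tss_a if t.contig != locus_contig)
    truth = {
        "seed": seed,
        "locus_contig": locus_contig,
        "locus_length": locus_length,
        "copy_number": copy_number,
        "host_a": {
            "locus_tss": [asdict(t) for t in tss_a if t.contig == locus_contig],
            "genome_tss_count": n_genome_tss,
            "planted_locus_density_per_100kb":
                locus_tss_count * 100_000 / locus_length,
            "planted_genome_density_per_100kb":
                n_genome_tss * 100_000 / genome_bp,
        },
        "host_b": {
            "geneless_read_lambda": geneless_read_lambda,
            "locus_read_lambda": locus_read_lambda,
        },
        "wgs_depth": wgs_depth,
    }

    fixture = {
        "spec": spec,
        "genome": genome,
        "trio": trio,
        "contig_lengths": contig_lengths,
        "locus_region": locus_region,
        "host_a": host_a,
        "host_b_reads": host_b_reads,
        "wgs": wgs,
        "truth": truth,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome.contigs + [trio.reversed], out / "genome.fa")
        write_fasta([trio.forward, trio.reversed, trio.scrubbed],
                    out / "locus_trio.fa")
        write_bed(genome.genes, out / "genes.bed")
        write_bed(genome.exclusions, out / "exclusions.bed")
        write_bed(host_a.cage_peaks, out / "hostA_cage_peaks.bed")
        write_bedgraph(host_a.plus, out / "hostA_signal_plus.bedgraph")
        write_bedgraph(host_a.minus, out / "hostA_signal_minus.bedgraph")
        write_read_table(host_b_reads, out / "hostB_reads.tsv")
        write_bedgraph(wgs, out / "wgs.bedgraph")
        with open(out / "contig_lengths.json", "w", encoding="utf-8") as fh:
            json.dump(contig_lengths, fh, indent=1, sort_keys=True)
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)

    return fixture
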