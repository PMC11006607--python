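"""Coverage quantification over sliding genomic windows.

The procedures here quantify how active a synthetic locus is relative to
its host genome from sequencing coverage alone:

* sliding-window construction (default 100-kb windows, 10-kb step),
* mean depth per region (total per-base read count / region size),
* locus copy-number estimation as locus depth over genome-average depth,
* RPGC (1x) normalization to an effective genome size,
* copy-number-corrected relative coverage of a locus versus the
  genome-wide window average,
* peak density per 100 kb,
* "geneless" window filtering (drop windows touching genes, blacklist
  regions, centromeres or telomeres) and flag-filtered read counting in
  those windows, and
* replicate correlation on binned, outlier-trimmed, log1p signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as _scipy_stats

from .errors import InsufficientDataError, ParameterError
from .io_formats import (
    CoverageTrack,
    GenomicInterval,
    PeakSet,
    ReadRecord,
)

# SAM FLAG bits excluded from counting: unmapped, secondary, supplementary.
# Duplicates (1024) are *not* excluded by this mask.
DEFAULT_EXCLUDE_FLAGS = 4 | 256 | 2048  # = 2308

__all__ = [
    "WindowSet",
    "WindowStat",
    "RelativeCoverage",
    "CopyNumberEstimate",
    "DEFAULT_EXCLUDE_FLAGS",
    "make_windows",
    "mean_depth",
    "estimate_copy_number",
    "rpgc_normalize",
    "relative_coverage",
    "peak_density",
    "geneless_windows",
    "count_reads_in_regions",
    "lower_median",
    "binned_correlation",
]


@dataclass(frozen=True)
class WindowSet:
    """Sliding windows of fixed size/step across one or more contigs."""

    windows: tuple[GenomicInterval, ...]
    size: int
    step: int

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


@dataclass(frozen=True)
class WindowStat:
    """One window (or arbitrary region) with a non-negative value."""

    window: GenomicInterval
    value: float


@dataclass(frozen=True)
class RelativeCoverage:
    """Copy-corrected locus coverage relative to the genome-window mean."""

    locus_mean: float
    genome_mean: float
    copy_number: float
    relative: float


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Depth-ratio copy number: real-valued estimate + nearest-integer call."""

    estimate: float
    integer_call: int


def make_windows(contig_lengths: Mapping[str, int], size: int = 100_000,
                 step: int = 10_000, keep_truncated: bool = False) -> WindowSet:
    """Sliding windows ``[k*step, k*step + size)`` per contig.

    Truncated terminal windows (end past the contig) are dropped by
    default so every window shares the same denominator; pass
    ``keep_truncated=True`` to keep them, clipped to the contig end.
    """
    if step < 1 or size < step:
        raise ParameterError("require size >= step > 0")
    windows: list[GenomicInterval] = []
    for contig, length in contig_lengths.items():
        k = 0
        while True:
            start = k * step
            if start >= length:
                break
            end = start + size
            if end <= length:
                windows.append(GenomicInterval(contig, start, end, "."))
            elif keep_truncated:
                windows.append(GenomicInterval(contig, start, length, "."))
            else:
                break
            k += 1
    return WindowSet(tuple(windows), size=size, step=step)


def mean_depth(track: CoverageTrack, region: GenomicInterval) -> float:
    """Total per-base depth over the region divided by the region size."""
    values = track.values(region)
    return float(values.sum() / len(region))


def estimate_copy_number(wgs: CoverageTrack, locus: GenomicInterval,
                         exclude_contigs: Iterable[str] = ("chrM",)
                         ) -> CopyNumberEstimate:
    """Locus depth divided by the genome-average depth.

    The genome average is taken over all contigs except ``exclude_contigs``
    (mitochondrial DNA is excluded by default: its copy number is
    unrelated to the nuclear baseline).  The locus itself is *not*
    removed from the genome average; for a locus that is small relative
    to the genome the bias is negligible.
    """
    excluded = set(exclude_contigs)
    total_signal = 0.0
    total_length = 0
    for contig, arr in wgs.data.items():
        if contig in excluded:
            continue
        total_signal += float(arr.sum()) * wgs.resolution
        total_length += wgs.contig_lengths[contig]
    if total_length == 0 or total_signal <= 0:
        raise ParameterError("genome coverage is zero; copy number undefined")
    genome_mean = total_signal / total_length
    estimate = mean_depth(wgs, locus) / genome_mean
    return CopyNumberEstimate(estimate=estimate, integer_call=int(round(estimate)))


def rpgc_normalize(track: CoverageTrack, effective_genome_size: int) -> CoverageTrack:
    """Scale a track to 1x coverage of an effective genome size (RPGC).

    Every value is multiplied by ``effective_genome_size / total_signal``
    so that the summed per-base depth equals the effective genome size —
    i.e. mean 1x over it.  Scale-invariant: doubling the input depth
    leaves the output unchanged.
    """
    if effective_genome_size <= 0:
        raise ParameterError("effective genome size must be positive")
    total = track.total_signal()
    if total <= 0:
        raise ParameterError("cannot RPGC-normalize a zero track")
    return track.scaled(effective_genome_size / total)


def relative_coverage(track: CoverageTrack, locus: GenomicInterval,
                      windows: WindowSet, copy_number: float) -> RelativeCoverage:
    """Copy-corrected locus coverage over the genome-window average.

    ``relative = (locus_mean / copy_number) / mean_over_windows(mean_depth)``.
    Invariant under global rescaling of the track.
    """
    if len(windows) == 0:
        raise ParameterError("empty window set")
    if copy_number <= 0:
        raise ParameterError("copy number must be positive")
    locus_mean = mean_depth(track, locus)
    genome_mean = float(np.mean([mean_depth(track, w) for w in windows]))
    if genome_mean <= 0:
        raise ParameterError("genome window mean is zero")
    return RelativeCoverage(
        locus_mean=locus_mean,
        genome_mean=genome_mean,
        copy_number=copy_number,
        relative=(locus_mean / copy_number) / genome_mean,
    )


def peak_density(peaks: PeakSet, region: GenomicInterval | None = None,
                 windows: WindowSet | None = None,
                 assignment: str = "midpoint") -> float:
    """Peaks per 100 kb in one region, or averaged over a window set.

    A peak belongs to a region when its midpoint lies inside it
    (default; avoids double counting across overlapping sliding
    windows), or on any >= 1 bp overlap with ``assignment="overlap"``.
    """
    if (region is None) == (windows is None):
        raise ParameterError("provide exactly one of region or windows")
    if assignment not in ("midpoint", "overlap"):
        raise ParameterError(f"unknown assignment mode {assignment!r}")

    def count_in(r: GenomicInterval) -> int:
        n = 0
        for p in peaks:
            if p.contig != r.contig:
                continue
            if assignment == "midpoint":
                if r.start <= p.midpoint < r.end:
                    n += 1
            elif p.overlaps(r):
                n += 1
        return n

    if region is not None:
        return count_in(region) * 100_000 / len(region)
    densities = [count_in(w) * 100_000 / len(w) for w in windows]
    return float(np.mean(densities))


def geneless_windows(windows: WindowSet, exclusions: PeakSet) -> WindowSet:
    """Drop every window overlapping (>= 1 bp) any exclusion feature.

    Exclusions are typically annotated transcripts, blacklist regions,
    centromeres and telomeres; the surviving windows form a background
    set for transcription-level comparisons.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in exclusions:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    kept = tuple(
        w for w in windows
        if w.contig not in trees or not trees[w.contig].overlap(w.start, w.end)
    )
    return WindowSet(kept, size=windows.size, step=windows.step)


def lower_median(values: Sequence[float]) -> float:
    """Median; for an even count, the lower of the two central values."""
    if len(values) == 0:
        raise InsufficientDataError("median of an empty collection")
    ordered = sorted(values)
    return float(ordered[(len(ordered) - 1) // 2])


def count_reads_in_regions(reads: Sequence[ReadRecord],
                           regions: Iterable[GenomicInterval],
                           exclude_flags: int = DEFAULT_EXCLUDE_FLAGS
                           ) -> tuple[list[WindowStat], float]:
    """Flag-filtered read counts per region, plus the cross-region median.

    A read counts toward a region when it overlaps it by >= 1 bp and its
    FLAG has none of the ``exclude_flags`` bits set (default 2308 =
    unmapped | secondary | supplementary; note duplicates, bit 1024,
    are *included* under this mask).  The median over regions uses the
    lower median for even counts.
    """
    trees: dict[str, IntervalTree] = {}
    region_list = list(regions)
    for idx, r in enumerate(region_list):
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, idx)
    counts = np.zeros(len(region_list), dtype=int)
    for read in reads:
        if read.flags & exclude_flags:
            continue
        tree = trees.get(read.interval.contig)
        if tree is None:
            continue
        for hit in tree.overlap(read.interval.start, read.interval.end):
            counts[hit.data] += 1
    stats = [WindowStat(window=r, value=float(c))
             for r, c in zip(region_list, counts)]
    median = lower_median([s.value for s in stats]) if stats else 0.0
    return stats, median


def binned_correlation(a: CoverageTrack, b: CoverageTrack, bin: int = 10_000,
                       skip_zeros: bool = True, remove_outliers: bool = True,
                       log1p: bool = True, mad_threshold: float = 10.0) -> float:
    """Pearson correlation of two tracks over fixed-size bins.

    Pipeline (mirroring common replicate-concordance practice): compute
    per-bin mean signal on the shared contigs; optionally drop bins that
    are zero in *both* tracks; optionally drop bins where either value
    deviates from its track median by more than ``mad_threshold`` MADs;
    optionally apply log(1 + x); then Pearson r.
    """
    if a.resolution != b.resolution:
        raise ParameterError("tracks differ in resolution")
    shared = [c for c in a.contigs if c in b.data]
    if not shared:
        raise ParameterError("tracks share no contigs")
    xs, ys = [], []
    for contig in shared:
        if a.contig_lengths[contig] != b.contig_lengths[contig]:
            raise ParameterError(f"contig {contig} lengths differ")
        xs.append(_bin_means(a, contig, bin))
        ys.append(_bin_means(b, contig, bin))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if skip_zeros:
        keep = ~((x == 0) & (y == 0))
        x, y = x[keep], y[keep]
    if remove_outliers and len(x):
        keep = _mad_inliers(x, mad_threshold) & _mad_inliers(y, mad_threshold)
        x, y = x[keep], y[keep]
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    if len(x) < 3:
        raise InsufficientDataError(
            f"only {len(x)} bins survive filtering; need >= 3"
        )
    r, _ = _scipy_stats.pearsonr(x, y)
    return float(r)


def _bin_means(track: CoverageTrack, contig: str, bin: int) -> np.ndarray:
    if bin % track.resolution != 0:
        raise ParameterError("bin must be a multiple of the track resolution")
    arr = track.data[contig]
    per_bin = bin // track.resolution
    n_full = len(arr) // per_bin
    if n_full == 0:
        return np.empty(0)
    return arr[:n_full * per_bin].reshape(n_full, per_bin).mean(axis=1)


def _mad_inliers(x: np.ndarray, k: float) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        # degenerate spread: fall back to keeping everything equal to the
        # median plus anything within k * stddev-scale of it
        scale = np.std(x)
        if scale == 0:
            return np.ones(len(x), dtype=bool)
        return np.abs(x - med) <= k * scale
    return np.abs(x - med) <= k * mad
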