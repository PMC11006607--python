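"""TSS derivation, promoter intervals, and TSS-anchored metaplots.

Transcription start sites are taken as the 5' boundary of stranded CAGE
peaks (start for ``+`` peaks, end-1 for ``-`` peaks).  Promoters default
to 200 bp upstream / 100 bp downstream of the TSS.  Metaplots aggregate
a coverage signal over TSS-centred windows (default ±0.5 kb),
orientation-flipped on the minus strand, reporting per-bin mean and
standard error across sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .io_formats import CoverageTrack, GenomicInterval, PeakSet, intersect

logger = logging.getLogger(__name__)

__all__ = [
    "Tss",
    "TssSet",
    "MetaplotProfile",
    "tss_from_cage",
    "promoter_interval",
    "promoters_from_tss",
    "metaplot",
    "smooth_track",
    "promoter_peak_overlap",
]


@dataclass(frozen=True)
class Tss:
    """A transcription start site: a stranded 0-based point."""

    contig: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ParameterError(f"negative TSS position {self.position}")
        if self.strand not in ("+", "-"):
            raise ParameterError(
                f"TSS strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class TssSet:
    sites: tuple[Tss, ...]

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


@dataclass(frozen=True)
class MetaplotProfile:
    """Mean ± standard error of a signal across TSS-anchored windows.

    ``offsets`` are bin-start positions in bp relative to the TSS
    (negative = upstream in the TSS's own orientation); ``n`` is the
    number of sites aggregated and ``n_dropped`` the sites discarded
    because their window exceeded the contig.
    """

    offsets: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: int
    n_dropped: int = 0


def tss_from_cage(peaks: PeakSet) -> TssSet:
    """The 5' coordinate of each stranded CAGE peak.

    ``+`` peak [s, e) -> s; ``-`` peak -> e - 1.  Unstranded peaks are
    an error: CAGE is inherently stranded.
    """
    sites = []
    for p in peaks:
        if p.strand == "+":
            sites.append(Tss(p.contig, p.start, "+"))
        elif p.strand == "-":
            sites.append(Tss(p.contig, p.end - 1, "-"))
        else:
            raise ParameterError(
                f"CAGE peak {p.contig}:{p.start}-{p.end} has no strand"
            )
    return TssSet(tuple(sites))


def promoter_interval(tss: Tss, up: int = 200, down: int = 100,
                      contig_length: int | None = None) -> GenomicInterval:
    """Promoter window around a TSS: ``up`` bp upstream, ``down`` downstream.

    The TSS base is the first downstream base, so the unclipped length is
    exactly ``up + down`` on either strand: ``+`` gives
    ``[tss-up, tss+down)``, ``-`` gives ``[tss-down+1, tss+up+1)``.
    Intervals are clipped to contig bounds (logged).
    """
    if up < 0 or down < 1:
        raise ParameterError("require up >= 0 and down >= 1")
    if tss.strand == "+":
        start, end = tss.position - up, tss.position + down
    else:
        start, end = tss.position - down + 1, tss.position + up + 1
    clipped_start = max(start, 0)
    clipped_end = min(end, contig_length) if contig_length is not None else end
    if (clipped_start, clipped_end) != (start, end):
        logger.warning(
            "promoter at %s:%d(%s) clipped to [%d, %d)",
            tss.contig, tss.position, tss.strand, clipped_start, clipped_end,
        )
    return GenomicInterval(tss.contig, clipped_start, clipped_end, tss.strand)


def promoters_from_tss(tss_set: TssSet, up: int = 200, down: int = 100,
                       contig_lengths: Mapping[str, int] | None = None) -> PeakSet:
    """Promoter intervals for every TSS in a set."""
    lengths = contig_lengths or {}
    return PeakSet([
        promoter_interval(t, up, down, lengths.get(t.contig))
        for t in tss_set
    ])


def smooth_track(track: CoverageTrack, smooth_bp: int = 100) -> CoverageTrack:
    """Centred moving average of width ``smooth_bp`` (in bp) per contig."""
    width = max(1, smooth_bp // track.resolution)
    kernel = np.ones(width) / width
    smoothed = {
        c: np.convolve(arr, kernel, mode="same")
        for c, arr in track.data.items()
    }
    return CoverageTrack(smoothed, resolution=track.resolution,
                         contig_lengths=track.contig_lengths)


def metaplot(track: CoverageTrack, tss_set: TssSet | Iterable[Tss],
             flank: int = 500, bin: int = 10) -> MetaplotProfile:
    """Aggregate a signal over TSS-centred, orientation-flipped windows.

    For each usable TSS the per-base signal over
    ``[tss - flank, tss + flank)`` is extracted, reversed for minus-strand
    sites, and averaged within ``bin``-bp bins; the profile is the
    per-bin mean and standard error (sd/sqrt(n)) across sites.  Sites
    whose window leaves the contig are dropped (zero-padding would bias
    the mean toward 0) and reported via ``n_dropped``.
    """
    if flank < 1 or bin < 1 or flank % bin != 0:
        raise ParameterError("flank must be a positive multiple of bin")
    rows = []
    dropped = 0
    for t in tss_set:
        if t.contig not in track.data:
            dropped += 1
            continue
        if t.strand == "+":
            start, end = t.position - flank, t.position + flank
        else:
            # shifted by one so that offset 0 reads the TSS base itself
            # after reversal, mirroring the plus-strand convention
            start, end = t.position - flank + 1, t.position + flank + 1
        if start < 0 or end > track.contig_lengths[t.contig]:
            dropped += 1
            continue
        values = track.values(GenomicInterval(t.contig, start, end, t.strand))
        if t.strand == "-":
            values = values[::-1]
        rows.append(values.reshape(-1, bin).mean(axis=1))
    if not rows:
        raise InsufficientDataError("no TSS window fits inside the track")
    matrix = np.vstack(rows)
    n = matrix.shape[0]
    mean = matrix.mean(axis=0)
    se = (matrix.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros_like(mean)
    offsets = np.arange(-flank, flank, bin)
    return MetaplotProfile(offsets=offsets, mean=mean, se=se, n=n,
                           n_dropped=dropped)


def promoter_peak_overlap(atac_peaks: PeakSet, promoters: PeakSet) -> PeakSet:
    """ATAC (or other) peaks intersecting putative promoters (>= 1 bp)."""
    return intersect(atac_peaks, promoters)
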