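"""Core domain types and text-format I/O.

Every coordinate in this package is 0-based, half-open (`[start, end)`),
the BED convention.  Converters for 1-based inclusive coordinates (the
convention of genome-browser region strings such as
``chrX:134429208-134529874``) exist only at the I/O boundary
(:func:`parse_region_1based`).

Supported formats: multi-record FASTA, BED3/BED6, UCSC bedGraph, a
GFF3-lite subset (seqid/type/start/end/strand), and a tab-delimited
read-interval table with a SAM-style FLAG column.  All files are read as
UTF-8 text; LF and CRLF line endings are both accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

from .errors import BoundsError, FormatError

logger = logging.getLogger(__name__)

SEQUENCE_ALPHABET = frozenset("ACGTN")

__all__ = [
    "SequenceRecord",
    "GenomicInterval",
    "PeakSet",
    "CoverageTrack",
    "ReadRecord",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3_lite",
    "read_read_table",
    "write_read_table",
    "intersect",
    "parse_region_1based",
    "format_region_1based",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}.

    The sequence is stored uppercase; the identifier must be non-empty
    and free of whitespace.  An empty sequence is representable (the CpG
    scrubber can legally delete a degenerate input like ``"CG"`` down to
    nothing) but is rejected at every file-format boundary.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id: {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - SEQUENCE_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains illegal character(s): "
                + ", ".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig span in 0-based half-open coordinates with a strand.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).  Length is
    ``end - start`` and must be positive.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(
                f"negative start coordinate: {self.contig}:{self.start}"
            )
        if self.end <= self.start:
            raise FormatError(
                f"empty or inverted interval: {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def effective_strand(self) -> str:
        """Resolve ``.`` to ``+`` where orientation matters, with a warning."""
        if self.strand == ".":
            logger.warning(
                "unstranded interval %s:%d-%d treated as '+'",
                self.contig, self.start, self.end,
            )
            return "+"
        return self.strand


@dataclass
class PeakSet:
    """An ordered collection of intervals with optional per-peak scores."""

    peaks: list[GenomicInterval] = field(default_factory=list)
    scores: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scores:
            self.scores = [None] * len(self.peaks)
        if len(self.scores) != len(self.peaks):
            raise FormatError("scores and peaks differ in length")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.peaks)

    def sorted(self) -> "PeakSet":
        order = sorted(range(len(self.peaks)),
                       key=lambda i: (self.peaks[i].contig, self.peaks[i].start))
        return PeakSet([self.peaks[i] for i in order],
                       [self.scores[i] for i in order])

    def contigs(self) -> set[str]:
        return {p.contig for p in self.peaks}


class CoverageTrack:
    """Non-negative signal over one or more contigs at a fixed bin size.

    ``resolution`` is the bin width in bp (1 = per-base).  Each contig is
    a float array whose length times the resolution covers the contig;
    the final bin may extend past the contig end when the length is not a
    multiple of the resolution.
    """

    def __init__(self, data: Mapping[str, np.ndarray], resolution: int = 1,
                 contig_lengths: Mapping[str, int] | None = None) -> None:
        if resolution < 1:
            raise FormatError(f"resolution must be >= 1, got {resolution}")
        self.resolution = int(resolution)
        self.data: dict[str, np.ndarray] = {}
        self.contig_lengths: dict[str, int] = {}
        for contig, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise FormatError(f"track for {contig} is not 1-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise FormatError(
                    f"track for {contig} has negative or non-finite values"
                )
            self.data[contig] = arr
            length = (contig_lengths or {}).get(contig, len(arr) * self.resolution)
            if not (len(arr) - 1) * self.resolution < length <= len(arr) * self.resolution:
                raise FormatError(
                    f"array for {contig} does not cover its declared length"
                )
            self.contig_lengths[contig] = int(length)

    @property
    def contigs(self) -> list[str]:
        return list(self.data)

    def total_signal(self) -> float:
        """Sum of per-base depth across the whole track."""
        return float(sum(arr.sum() * self.resolution for arr in self.data.values()))

    def total_length(self) -> int:
        return sum(self.contig_lengths.values())

    def values(self, region: GenomicInterval) -> np.ndarray:
        """Per-base signal over ``region`` (bins expanded to base resolution)."""
        if region.contig not in self.data:
            raise BoundsError(f"unknown contig {region.contig!r}")
        if region.start < 0 or region.end > self.contig_lengths[region.contig]:
            raise BoundsError(
                f"region {region.contig}:{region.start}-{region.end} "
                f"outside contig of length {self.contig_lengths[region.contig]}"
            )
        arr = self.data[region.contig]
        if self.resolution == 1:
            return arr[region.start:region.end]
        per_base = np.repeat(arr, self.resolution)
        return per_base[region.start:region.end]

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: a * factor for c, a in self.data.items()},
            resolution=self.resolution,
            contig_lengths=self.contig_lengths,
        )


@dataclass(frozen=True)
class ReadRecord:
    """An aligned read reduced to its interval plus the SAM FLAG bitfield."""

    interval: GenomicInterval
    flags: int = 0

    def __post_init__(self) -> None:
        if self.flags < 0:
            raise FormatError(f"negative FLAG value: {self.flags}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into validated :class:`SequenceRecord`s.

    Sequences are uppercased; characters outside {A, C, G, T, N} raise a
    :class:`FormatError` naming the offending character.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
        except FormatError as err:
            raise FormatError(f"{path}: {err}") from None
    if not records:
        # distinguish a headerless/garbage file from a legitimately empty list
        text = Path(path).read_text(encoding="utf-8").strip()
        if text and not text.startswith(">"):
            raise FormatError(f"{path}: not a FASTA file (no '>' header)")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3/BED6 into a :class:`PeakSet` (0-based half-open, as BED).

    Column 5, when present and numeric, is kept as the peak score; a
    missing strand column yields strand ``.``.
    """
    peaks: list[GenomicInterval] = []
    scores: list[float | None] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                peaks.append(GenomicInterval(contig, start, end, strand))
            except FormatError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            scores.append(score)
    return PeakSet(peaks, scores)


def write_bed(peaks: PeakSet, path: str | Path, names: Sequence[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, (iv, score) in enumerate(zip(peaks.peaks, peaks.scores)):
            name = names[i] if names is not None else f"peak_{i + 1}"
            score_str = "." if score is None else f"{score:g}"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score_str}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path,
                  contig_lengths: Mapping[str, int],
                  resolution: int = 1) -> CoverageTrack:
    """Materialize a 4-column bedGraph as a :class:`CoverageTrack`.

    Positions not covered by any bedGraph line are zero.  Overlapping
    lines on the same contig are a format error (bedGraph forbids them).
    When ``resolution`` > 1 the per-base signal is averaged within
    fixed-width bins.
    """
    per_base = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: fewer than 4 columns")
            contig = fields[0]
            if contig not in per_base:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed fields") from None
            if start < 0 or end <= start or end > contig_lengths[contig]:
                raise FormatError(
                    f"{path}:{lineno}: bad interval {start}-{end}"
                )
            if covered[contig][start:end].any():
                raise FormatError(
                    f"{path}:{lineno}: overlaps an earlier line on {contig}"
                )
            covered[contig][start:end] = True
            per_base[contig][start:end] = value
    if resolution == 1:
        return CoverageTrack(per_base, resolution=1, contig_lengths=dict(contig_lengths))
    binned = {}
    for contig, arr in per_base.items():
        n_bins = -(-len(arr) // resolution)
        padded = np.zeros(n_bins * resolution)
        padded[:len(arr)] = arr
        # mean over real bases only, so a short terminal bin is not diluted
        widths = np.minimum(resolution, len(arr) - np.arange(n_bins) * resolution)
        binned[contig] = padded.reshape(n_bins, resolution).sum(axis=1) / widths
    return CoverageTrack(binned, resolution=resolution, contig_lengths=dict(contig_lengths))


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging equal-valued adjacent bins."""
    with open(path, "w", encoding="utf-8") as fh:
        for contig, arr in track.data.items():
            length = track.contig_lengths[contig]
            if len(arr) == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                value = arr[s]
                if value == 0:
                    continue
                fh.write(
                    f"{contig}\t{s * track.resolution}"
                    f"\t{min(e * track.resolution, length)}\t{float(value)!r}\n"
                )


# ---------------------------------------------------------------------------
# GFF3-lite


def read_gff3_lite(path: str | Path,
                   feature_types: set[str] | None = None) -> PeakSet:
    """Read a GFF3 file, consuming only seqid/type/start/end/strand.

    GFF3 is 1-based inclusive; intervals are converted to 0-based
    half-open on read.  ``feature_types`` optionally restricts which
    ``type`` values are kept.
    """
    peaks: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: fewer than 8 columns")
            if feature_types is not None and fields[2] not in feature_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = fields[6] if fields[6] in ("+", "-") else "."
            try:
                peaks.append(GenomicInterval(fields[0], start1 - 1, end1, strand))
            except FormatError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
    return PeakSet(peaks)


# ---------------------------------------------------------------------------
# read-interval table


def read_read_table(path: str | Path) -> list[ReadRecord]:
    """Read a tab-delimited table of columns contig, start, end, flags."""
    reads: list[ReadRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: fewer than 4 columns")
            try:
                start, end, flags = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed fields") from None
            try:
                reads.append(ReadRecord(GenomicInterval(fields[0], start, end), flags))
            except FormatError as err:
                raise FormatError(f"{path}:{lineno}: {err}") from None
    return reads


def write_read_table(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#contig\tstart\tend\tflags\n")
        for r in reads:
            fh.write(f"{r.interval.contig}\t{r.interval.start}\t{r.interval.end}\t{r.flags}\n")


# ---------------------------------------------------------------------------
# interval arithmetic


def _trees_by_contig(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    return trees


def intersect(a: PeakSet, b: PeakSet) -> PeakSet:
    """Members of ``a`` overlapping any member of ``b`` by >= 1 bp.

    Strand-blind, `bedtools intersect -u` semantics: each qualifying
    member of ``a`` is reported once, with its score, in input order.
    """
    trees = _trees_by_contig(b)
    kept_peaks, kept_scores = [], []
    for iv, score in zip(a.peaks, a.scores):
        tree = trees.get(iv.contig)
        if tree is not None and tree.overlap(iv.start, iv.end):
            kept_peaks.append(iv)
            kept_scores.append(score)
    return PeakSet(kept_peaks, kept_scores)


# ---------------------------------------------------------------------------
# coordinate-convention converters


def parse_region_1based(text: str, strand: str = ".") -> GenomicInterval:
    """Parse a browser-style region string (1-based, inclusive ends).

    ``"chrX:134429208-134529874"`` becomes the 0-based half-open interval
    ``[134429207, 134529874)`` of length 100,667.
    Commas in coordinates are tolerated.
    """
    try:
        contig, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start1, end1 = int(lo), int(hi)
    except ValueError:
        raise FormatError(f"cannot parse region string {text!r}") from None
    if start1 < 1 or end1 < start1:
        raise FormatError(f"bad 1-based coordinates in {text!r}")
    return GenomicInterval(contig, start1 - 1, end1, strand)


def format_region_1based(iv: GenomicInterval) -> str:
    """Render an interval as a 1-based inclusive browser region string."""
    return f"{iv.contig}:{iv.start + 1}-{iv.end}"
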