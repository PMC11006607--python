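"""Sequence-composition statistics for synthetic-locus characterization.

Covers the composition table of a designed locus (mono- and dinucleotide
counts, GC fraction), CpG observed/expected statistics, windowed GC
tracks, CpG-island detection by windowed thresholding, and IUPAC motif
scanning.

Conventions
-----------
* Dinucleotides are counted with overlap (positions 0..L-2); a pair
  containing N is skipped, and N bases are excluded from the GC
  denominator.
* Expected CpG for a sequence of length L with nC C's and nG G's is
  ``nC * nG / L``; the observed/expected ratio is ~1 for
  composition-random DNA and far below 1 for CpG-depleted mammalian DNA.
* Reversal without complementation leaves mono counts and length
  untouched and maps each dinucleotide count XY to YX — so the CpG count
  of a reversed locus equals the GpC count of the forward locus, while
  the *expected* CpG is invariant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

import numpy as np
from Bio.Seq import Seq

from .errors import ParameterError
from .io_formats import CoverageTrack, GenomicInterval, SequenceRecord

BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a, b in product(BASES, BASES))

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

__all__ = [
    "DinucProfile",
    "CpGStats",
    "CpGIsland",
    "dinuc_profile",
    "predict_reversed_profile",
    "cpg_stats",
    "oe_fold_enrichment",
    "gc_track",
    "find_cpg_islands",
    "iupac_scan",
    "round_half_even",
]


def round_half_even(x: float, digits: int = 2) -> float:
    """Banker's rounding for display values (0.285 -> 0.28, 0.275 -> 0.28)."""
    return float(np.round(x, digits))


@dataclass(frozen=True)
class DinucProfile:
    """Mono- and dinucleotide composition of one sequence.

    ``mono`` holds A/C/G/T counts with N tallied separately under "N";
    ``dinuc`` holds the 16 overlapping dinucleotide counts (N-containing
    pairs skipped).  ``gc_fraction`` uses an N-free denominator.
    """

    length: int
    mono: dict[str, int]
    dinuc: dict[str, int]
    gc_fraction: float

    @property
    def n_count(self) -> int:
        return self.mono.get("N", 0)


@dataclass(frozen=True)
class CpGStats:
    """Observed, expected and observed/expected CpG for one sequence.

    ``expected = nC * nG / L``; ``ratio = observed / expected`` (0 when
    the expectation is 0).  Stored at full precision; round for display
    with :func:`round_half_even`.
    """

    observed: int
    expected: float
    ratio: float

    @classmethod
    def from_counts(cls, observed: int, n_c: int, n_g: int, length: int) -> "CpGStats":
        if length <= 0:
            raise ParameterError("length must be positive")
        expected = n_c * n_g / length
        ratio = observed / expected if expected > 0 else 0.0
        return cls(observed=observed, expected=expected, ratio=ratio)


@dataclass(frozen=True)
class CpGIsland:
    """A maximal run of windows jointly exceeding GC and O/E thresholds."""

    interval: GenomicInterval
    mean_gc: float
    mean_oe: float


def dinuc_profile(rec: SequenceRecord) -> DinucProfile:
    """Count mono- and overlapping dinucleotides of one sequence."""
    seq = rec.seq
    mono = {b: seq.count(b) for b in BASES}
    mono["N"] = seq.count("N")
    dinuc = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        if "N" not in pair:
            dinuc[pair] += 1
    denom = len(seq) - mono["N"]
    gc = (mono["C"] + mono["G"]) / denom if denom else 0.0
    return DinucProfile(length=len(seq), mono=mono, dinuc=dinuc, gc_fraction=gc)


def predict_reversed_profile(p: DinucProfile) -> DinucProfile:
    """Composition of the reversed (not complemented) sequence, predicted
    from the forward profile alone: dinuc'[XY] = dinuc[YX], mono and
    length unchanged."""
    if p.n_count:
        raise ParameterError("reversal prediction requires an N-free profile")
    flipped = {xy: p.dinuc[xy[::-1]] for xy in DINUCLEOTIDES}
    return DinucProfile(length=p.length, mono=dict(p.mono), dinuc=flipped,
                        gc_fraction=p.gc_fraction)


def cpg_stats(p: DinucProfile) -> CpGStats:
    """CpG observed/expected statistics from a composition profile."""
    return CpGStats.from_counts(
        observed=p.dinuc["CG"], n_c=p.mono["C"], n_g=p.mono["G"], length=p.length
    )


def oe_fold_enrichment(a: CpGStats, b: CpGStats) -> float:
    """Ratio of two observed/expected CpG ratios (a relative to b)."""
    if b.ratio == 0:
        raise ParameterError("fold enrichment undefined: reference ratio is 0")
    return a.ratio / b.ratio


def _cumulative_indicator(seq: str, char: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.concatenate(([0], np.cumsum(arr == ord(char))))


def gc_track(rec: SequenceRecord, window: int, step: int) -> CoverageTrack:
    """GC fraction over sliding windows, anchored at each window start.

    Returns a track on contig ``rec.id`` whose bin k holds the GC
    fraction of ``[k*step, k*step + window)``; only full windows are
    emitted.  N bases are excluded from the denominator.
    """
    if window < 1 or step < 1:
        raise ParameterError("window and step must be positive")
    if window > len(rec):
        raise ParameterError(
            f"window ({window}) exceeds sequence length ({len(rec)})"
        )
    cum_c = _cumulative_indicator(rec.seq, "C")
    cum_g = _cumulative_indicator(rec.seq, "G")
    cum_n = _cumulative_indicator(rec.seq, "N")
    starts = np.arange(0, len(rec) - window + 1, step)
    gc = (cum_c[starts + window] - cum_c[starts]) + (cum_g[starts + window] - cum_g[starts])
    denom = window - (cum_n[starts + window] - cum_n[starts])
    values = np.where(denom > 0, gc / np.maximum(denom, 1), 0.0)
    return CoverageTrack({rec.id: values}, resolution=step,
                         contig_lengths={rec.id: len(starts) * step})


def find_cpg_islands(rec: SequenceRecord, window: int = 100, min_len: int = 200,
                     min_gc: float = 0.5, min_oe: float = 0.6) -> list[CpGIsland]:
    """Call CpG islands by windowed GC / observed-expected thresholding.

    Every ``window``-bp window at 1-bp steps is scored for GC fraction
    and CpG O/E (expectation ``nC*nG/window``, as in the global
    statistic).  Maximal runs of windows meeting both thresholds are
    merged into candidate islands spanning from the first qualifying
    window start to the last qualifying window end; candidates shorter
    than ``min_len`` are dropped.  Reported means are averages over the
    qualifying windows of the run.
    """
    if len(rec) < window:
        return []
    seq = rec.seq
    cum_c = _cumulative_indicator(seq, "C")
    cum_g = _cumulative_indicator(seq, "G")
    # CG occurrence starts; a window [i, i+w) sees starts in [i, i+w-1)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum_cg = np.concatenate(([0], np.cumsum(is_cg)))
    starts = np.arange(0, len(seq) - window + 1)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    obs = cum_cg[np.minimum(starts + window - 1, len(cum_cg) - 1)] - cum_cg[starts]
    gc = (n_c + n_g) / window
    expected = n_c * n_g / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, obs / np.maximum(expected, 1e-300), 0.0)
    ok = (gc >= min_gc) & (oe >= min_oe)
    islands: list[CpGIsland] = []
    if not ok.any():
        return islands
    # maximal runs of qualifying window starts
    padded = np.concatenate(([0], ok.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    run_starts, run_ends_excl = edges[0::2], edges[1::2]
    for rs, re_excl in zip(run_starts, run_ends_excl):
        re_ = re_excl - 1
        lo, hi = int(starts[rs]), int(starts[re_]) + window
        if hi - lo < min_len:
            continue
        sel = slice(rs, re_ + 1)
        islands.append(
            CpGIsland(
                interval=GenomicInterval(rec.id, lo, hi, "."),
                mean_gc=float(gc[sel].mean()),
                mean_oe=float(oe[sel].mean()),
            )
        )
    return islands


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for code in pattern.upper():
        if code not in IUPAC_CODES:
            raise ParameterError(f"illegal IUPAC code {code!r} in pattern")
        opts = IUPAC_CODES[code]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def iupac_scan(rec: SequenceRecord, pattern: str,
               both_strands: bool = False) -> list[GenomicInterval]:
    """All (overlapping) matches of an IUPAC-degenerate pattern.

    With ``both_strands``, matches of the pattern's reverse complement
    are also reported, on strand ``-`` (coordinates always on the
    forward sequence).
    """
    if not pattern:
        raise ParameterError("empty pattern")
    width = len(pattern)
    hits = [
        GenomicInterval(rec.id, m.start(), m.start() + width, "+")
        for m in _iupac_regex(pattern).finditer(rec.seq)
    ]
    if both_strands:
        rc = str(Seq(pattern.upper()).reverse_complement())
        hits += [
            GenomicInterval(rec.id, m.start(), m.start() + width, "-")
            for m in _iupac_regex(rc).finditer(rec.seq)
        ]
    return sorted(hits, key=lambda iv: (iv.start, iv.strand))
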