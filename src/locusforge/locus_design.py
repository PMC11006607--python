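"""Design transforms for evolutionarily naive synthetic loci.

Four operations turn a natural locus into synthesizable naive DNA:

* :func:`reverse_sequence` — read the base string right-to-left *without*
  complementing.  This preserves composition-level features (GC content,
  homopolymer runs, repeat density) while ablating evolved coding and
  regulatory information.
* :func:`scrub_cpg` — iteratively remove every CpG dinucleotide by
  deleting, with a fair coin flip, either the C or the G of each
  occurrence, rescanning until none remain (deletions can create new
  CpGs at the junction).
* :func:`minimal_segment_count` / :func:`plan_segments` — split a locus
  into the fewest overlapping segments compatible with a commercial
  synthesis length limit, with a fixed overlap between neighbours for
  homology-based assembly.
* :func:`design_insertion` — build a payload construct flanked by short
  homology arms copied from the target locus, for recombination-mediated
  insertion at a chosen point (e.g. tagging a transcription start site
  with a reporter gene).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import BoundsError, LocusForgeError, ParameterError
from .io_formats import GenomicInterval, SequenceRecord

logger = logging.getLogger(__name__)

_CG = re.compile("CG")

__all__ = [
    "Deletion",
    "ScrubResult",
    "SegmentPlan",
    "InsertionDesign",
    "reverse_sequence",
    "scrub_cpg",
    "replay_deletions",
    "minimal_segment_count",
    "plan_segments",
    "design_insertion",
    "apply_insertion",
]


def _require_acgt(rec: SequenceRecord, op: str) -> None:
    # synthesized DNA cannot contain N, so design transforms refuse it
    if "N" in rec.seq:
        raise ParameterError(f"{op}: sequence {rec.id!r} contains N")


class Deletion(NamedTuple):
    """One base removed during CpG scrubbing.

    ``position`` indexes the *then-current* sequence at the moment of
    deletion, so replaying deletions in order reconstructs the output.
    """

    iteration: int
    position: int
    base: str


@dataclass(frozen=True)
class ScrubResult:
    """Outcome of one seeded CpG-scrubbing run (audit trail included)."""

    scrubbed: SequenceRecord
    deletions: tuple[Deletion, ...]
    n_iterations: int
    seed: int


@dataclass(frozen=True)
class SegmentPlan:
    """A tiling of ``[0, locus_length)`` by overlapping synthesis segments."""

    locus_length: int
    target_len: int
    overlap: int
    segments: tuple[GenomicInterval, ...]

    def segment_sequences(self, rec: SequenceRecord) -> list[SequenceRecord]:
        if len(rec) != self.locus_length:
            raise ParameterError(
                f"sequence length {len(rec)} != plan length {self.locus_length}"
            )
        return [
            SequenceRecord(f"{rec.id}_seg{i + 1:02d}", rec.seq[s.start:s.end])
            for i, s in enumerate(self.segments)
        ]

    def reconstruct(self, segments: list[SequenceRecord]) -> str:
        """Concatenate segment sequences, dropping each leading overlap."""
        if len(segments) != len(self.segments):
            raise ParameterError("segment count mismatch")
        out = [segments[0].seq]
        for prev, cur, seq in zip(self.segments, self.segments[1:], segments[1:]):
            out.append(seq.seq[prev.end - cur.start:])
        return "".join(out)


@dataclass(frozen=True)
class InsertionDesign:
    """A payload plus homology arms copied from the target locus."""

    payload_id: str
    insertion_point: GenomicInterval
    left_arm: str
    right_arm: str
    construct: str


def reverse_sequence(rec: SequenceRecord) -> SequenceRecord:
    """Reverse (do **not** reverse-complement) a sequence.

    ``output[i] = input[L - 1 - i]``; the id gains an ``_R`` suffix.
    Reversal preserves length, every mononucleotide count and GC
    fraction, while mapping each dinucleotide count XY to YX.
    """
    _require_acgt(rec, "reverse_sequence")
    return SequenceRecord(id=rec.id + "_R", seq=rec.seq[::-1])


def scrub_cpg(rec: SequenceRecord, seed: int, max_iterations: int = 100) -> ScrubResult:
    """Eliminate every CpG by randomly deleting the C or the G.

    One iteration locates all ``CG`` start positions in the current
    sequence and processes them right-to-left; each occurrence still
    intact when reached loses either its C or its G, chosen by an
    independent fair coin flip.  Because a deletion can juxtapose a C
    and a G into a fresh CpG, iterations repeat until a scan finds none.
    Deterministic given ``seed``; the deletion log allows exact replay
    (see :func:`replay_deletions`).
    """
    _require_acgt(rec, "scrub_cpg")
    rng = np.random.default_rng(seed)
    current = rec.seq
    deletions: list[Deletion] = []
    iteration = 0
    while True:
        hits = [m.start() for m in _CG.finditer(current)]
        if not hits:
            break
        iteration += 1
        if iteration > max_iterations:  # unreachable: length strictly decreases
            raise LocusForgeError(
                f"scrub_cpg failed to converge in {max_iterations} iterations"
            )
        chars = list(current)
        for pos in reversed(hits):
            # re-check: a righter deletion in this pass may have altered
            # the local context (kept for contract safety; right-to-left
            # processing leaves positions left of a deletion intact)
            if chars[pos] != "C" or chars[pos + 1] != "G":
                continue
            if rng.integers(2) == 0:
                deletions.append(Deletion(iteration, pos, "C"))
                del chars[pos]
            else:
                deletions.append(Deletion(iteration, pos + 1, "G"))
                del chars[pos + 1]
        current = "".join(chars)
    if not current:
        logger.warning("scrub_cpg: sequence %r scrubbed to empty", rec.id)
    return ScrubResult(
        scrubbed=SequenceRecord(id=rec.id + "_noCpG", seq=current),
        deletions=tuple(deletions),
        n_iterations=iteration,
        seed=seed,
    )


def replay_deletions(rec: SequenceRecord, deletions: tuple[Deletion, ...]) -> str:
    """Apply a deletion log to the input sequence; returns the final string.

    Each recorded position indexes the sequence as it stood at deletion
    time, so a simple in-order replay reproduces the scrubbed output.
    """
    chars = list(rec.seq)
    for d in deletions:
        if chars[d.position] != d.base:
            raise LocusForgeError(
                f"audit mismatch at position {d.position}: "
                f"expected {d.base}, found {chars[d.position]}"
            )
        del chars[d.position]
    return "".join(chars)


def minimal_segment_count(length: int, target_len: int, overlap: int) -> int:
    """Fewest segments of length <= ``target_len`` tiling ``length`` bp
    with >= ``overlap`` bp shared between neighbours.

    The smallest n with ``n*target_len - (n-1)*overlap >= length``;
    1 when the locus fits in a single segment.
    """
    if length < 1 or target_len < 1:
        raise ParameterError("length and target_len must be positive")
    if overlap < 0 or overlap >= target_len:
        raise ParameterError(
            f"overlap ({overlap}) must satisfy 0 <= overlap < target_len ({target_len})"
        )
    if length <= target_len:
        return 1
    return math.ceil((length - overlap) / (target_len - overlap))


def plan_segments(rec: SequenceRecord, target_len: int, overlap: int) -> SegmentPlan:
    """Tile a locus with the minimal number of overlapping segments.

    Within the minimal count, segment lengths are balanced (all within
    1 bp of ``(L + (n-1)*overlap) / n``) and consecutive segments share
    exactly ``overlap`` bp — even sizing is synthesis-friendly and makes
    the plan deterministic.
    """
    length = len(rec)
    n = minimal_segment_count(length, target_len, overlap)
    total = length + (n - 1) * overlap
    base, extra = divmod(total, n)
    segments = []
    start = 0
    for i in range(n):
        seg_len = base + (1 if i < extra else 0)
        segments.append(GenomicInterval(rec.id, start, start + seg_len, "+"))
        start += seg_len - overlap
    assert segments[-1].end == length
    return SegmentPlan(length, target_len, overlap, tuple(segments))


def design_insertion(locus: SequenceRecord, point: int, payload: SequenceRecord,
                     arm_len: int = 40) -> InsertionDesign:
    """Flank a payload with homology arms copied from the locus.

    The left arm is ``locus[point - arm_len : point]``, the right arm
    ``locus[point : point + arm_len]``; homologous recombination of the
    construct then inserts the payload exactly at ``point``.
    """
    if arm_len < 1:
        raise ParameterError("arm_len must be positive")
    if point < arm_len or point > len(locus) - arm_len:
        raise BoundsError(
            f"insertion point {point} closer than {arm_len} bp to a locus end"
        )
    left = locus.seq[point - arm_len:point]
    right = locus.seq[point:point + arm_len]
    return InsertionDesign(
        payload_id=payload.id,
        insertion_point=GenomicInterval(locus.id, point, point + 1, "."),
        left_arm=left,
        right_arm=right,
        construct=left + payload.seq + right,
    )


def apply_insertion(locus: SequenceRecord, design: InsertionDesign,
                    payload: SequenceRecord) -> SequenceRecord:
    """In-silico recombination: integrate the construct into the locus."""
    point = design.insertion_point.start
    arm_len = len(design.left_arm)
    if locus.seq[point - arm_len:point] != design.left_arm:
        raise LocusForgeError("left homology arm does not match the locus")
    if locus.seq[point:point + arm_len] != design.right_arm:
        raise LocusForgeError("right homology arm does not match the locus")
    return SequenceRecord(
        id=f"{locus.id}_{payload.id}@{point}",
        seq=locus.seq[:point] + payload.seq + locus.seq[point:],
    )
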