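"""Design a naive locus: reverse it, scrub its CpGs, plan synthesis segments.

Reversing a DNA sequence without complementing it preserves composition
(GC content, homopolymers, repeat density) while destroying evolved
coding and regulatory information; deleting one base of every CpG then
removes the dinucleotide implicated in Polycomb recruitment.
"""

import numpy as np

from locusforge import SequenceRecord, plan_segments, reverse_sequence, scrub_cpg
from locusforge.synthetic_data import random_sequence

rng = np.random.default_rng(42)
locus = SequenceRecord("demo_locus", random_sequence(rng, 20_000, 0.41))

rev = reverse_sequence(locus)
print(f"forward locus: {len(locus):,} bp, reversed -> {rev.id}")

scrub = scrub_cpg(rev, seed=42)
print(f"CpG scrub: {len(scrub.deletions):,} deletions over "
      f"{scrub.n_iterations} iterations, "
      f"{len(rev):,} bp -> {len(scrub.scrubbed):,} bp, "
      f"CG occurrences now {scrub.scrubbed.seq.count('CG')}")

plan = plan_segments(rev, target_len=4_000, overlap=300)
sizes = [len(s) for s in plan.segments]
print(f"synthesis plan: {len(plan.segments)} segments of "
      f"{min(sizes):,}-{max(sizes):,} bp with >= {plan.overlap} bp overlaps")
# The deletion count scales with the CpG content of the reversed locus;
# the segment count is the fewest pieces a 4-kb synthesis limit allows.
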