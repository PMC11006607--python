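"""Composition statistics: dinucleotide profile, CpG O/E, CpG islands.

Reversal maps every dinucleotide count XY to YX, so a GpC-rich natural
locus becomes CpG-rich when reversed — the observed/expected CpG ratio
jumps while the *expected* CpG count is untouched.
"""

import numpy as np

from locusforge import (
    SequenceRecord,
    cpg_stats,
    dinuc_profile,
    find_cpg_islands,
    oe_fold_enrichment,
    predict_reversed_profile,
    reverse_sequence,
)
from locusforge.synthetic_data import random_sequence

rng = np.random.default_rng(7)
# a GpC-skewed sequence, mimicking the CpG depletion of mammalian DNA
parts = []
for _ in range(2_000):
    parts.append("GC" if rng.random() < 0.25 else
                 "".join(rng.choice(list("ACGT"), 5)))
fwd = SequenceRecord("fwd", "".join(parts))
rev = reverse_sequence(fwd)

p_fwd, p_rev = dinuc_profile(fwd), dinuc_profile(rev)
predicted = predict_reversed_profile(p_fwd)
assert predicted.dinuc == p_rev.dinuc  # the reversal identity

s_fwd, s_rev = cpg_stats(p_fwd), cpg_stats(p_rev)
print(f"forward:  CG={s_fwd.observed:,}  GC={p_fwd.dinuc['GC']:,}  "
      f"expected={s_fwd.expected:,.0f}  O/E={s_fwd.ratio:.2f}")
print(f"reversed: CG={s_rev.observed:,}  GC={p_rev.dinuc['GC']:,}  "
      f"expected={s_rev.expected:,.0f}  O/E={s_rev.ratio:.2f}")
print(f"CpG O/E fold enrichment (reversed vs forward): "
      f"{oe_fold_enrichment(s_rev, s_fwd):.2f}")

islands = find_cpg_islands(rev)
print(f"CpG islands in the reversed sequence at default thresholds: "
      f"{len(islands)}")
# Forward CG and reversed GC counts swap exactly; expected CpG is equal
# in both rows because it depends only on base counts and length.
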