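# Methods

This note records the models, conventions and design choices behind
`locusforge`, at the level of detail a user needs to interpret its
output or extend it.

## Coordinates and formats

All internal coordinates are 0-based, half-open (`[start, end)`), with
strand `+`, `-` or `.`.  Browser-style region strings
(`chrX:134429208-134529874`) are treated as 1-based inclusive and
converted at parse time; no other part of the package ever sees 1-based
coordinates.  An unstranded interval is resolved to `+` with a logged
warning wherever orientation matters.  bedGraph is the signal
interchange format; tracks are materialized per base or at a fixed bin
width (the bin holds the per-base mean, and a short terminal bin is
averaged over its real bases only).

## Reversal

`reverse_sequence` returns the base string read right-to-left with no
complementation.  Length, each mononucleotide count and GC fraction are
invariant; every dinucleotide count maps XY → YX.  The practical
consequence for CpG biology: a GpC-rich, CpG-depleted mammalian
sequence becomes CpG-rich when reversed, while the *expected* CpG count
`n_C · n_G / L` is unchanged.  Inputs containing N are rejected —
synthesized DNA cannot contain N, so the design transforms refuse
ambiguity codes rather than guessing.

## CpG scrubbing

One iteration locates every `CG` start in the current sequence and
processes the occurrences right-to-left; each occurrence still intact
when reached loses either its C or its G by an independent fair coin
flip.  Because a deletion can juxtapose a C and a G, iterations repeat
until a scan finds no occurrence.  Right-to-left processing keeps the
indices of unprocessed (lefter) occurrences stable within a pass; the
per-occurrence re-check before deleting is retained as a contract
safety net.  Whether a single pass handles occurrences simultaneously
or sequentially is a genuine degree of freedom in this family of
algorithms — the reachable-output set can differ between choices — so
the convention here is documented rather than claimed universal, and
only two properties are contractual: the output contains no `CG`, and
`len(output) = len(input) − deletions`.

Randomness comes from a named NumPy generator seeded per run; the seed
is recorded in the result.  The deletion log stores, for each deletion,
the iteration number, the position *in the sequence as it stood at that
moment*, and the deleted base, so a simple in-order replay reconstructs
the output exactly (`replay_deletions`).  Termination is guaranteed:
every iteration that finds an occurrence deletes at least one base, so
the iteration count is bounded by the sequence length; the default cap
of 100 iterations is unreachable in practice (random 1-kb sequences
converge in under ten).

A degenerate two-base input `CG` loses exactly one base.  No input can
scrub to an empty string through the `CG` rule alone, but the in-memory
sequence type tolerates emptiness so that the scrubber never has to
fail on pathological inputs; file writers still refuse empty records.

## Synthesis segmentation

The segment count is contractual: the smallest *n* with
`n·target − (n−1)·overlap ≥ L` (1 if the locus fits in one segment).
Within that count, segment lengths are balanced to within 1 bp of
`(L + (n−1)·overlap)/n` and consecutive segments share exactly the
requested overlap.  Balanced sizing is synthesis-friendly and makes the
plan a deterministic function of `(L, target, overlap)`; real projects
sometimes ship one short terminal segment instead (e.g. 27 pieces of
~4 kb plus one of ~2 kb), which satisfies the same count and overlap
contract — the balanced layout is this package's choice, not a claim
about how any particular vendor splits DNA.

## Insertion designs

`design_insertion` copies `arm_len` (default 40) bases on each side of
the insertion point as homology arms and concatenates
`left + payload + right`.  The insertion point is stored as the 1-bp
interval `[p, p+1)` — the base immediately 3′ of the junction — because
the interval type requires non-empty spans.  `apply_insertion` performs
the in-silico recombination and verifies both arms against the locus
before splicing.

## Composition statistics

Dinucleotides are counted with overlap (positions `0..L−2`); pairs
containing N are skipped and N is excluded from the GC denominator, so
for N-free input the dinucleotide counts sum to `L−1`.  CpG statistics
follow the Gardiner-Garden-style expectation `n_C·n_G/L`; the O/E ratio
is stored at full precision and displayed at two decimals with
round-half-even.  Fold enrichment between two sequences divides their
stored ratios; comparing *displayed* (two-decimal) ratios can differ in
the second decimal, which matters when reconciling against rounded
published tables.

CpG islands are called in the windowed-thresholding style of classic
island finders: 100-bp windows at 1-bp shift, each scored for GC
fraction and CpG O/E (using the same `n_C·n_G/window` expectation as
the global statistic, for internal consistency); maximal runs of
windows passing both thresholds (GC ≥ 0.5, O/E ≥ 0.6) are merged into
an island spanning first-window start to last-window end, and islands
shorter than 200 bp are dropped.  All four parameters are configurable.
A CpG-scrubbed sequence has zero observed CpG everywhere, so no island
can pass any positive O/E threshold.

## Coverage quantification

* **Windows** — per contig, `[k·step, k·step+size)` for all `k` with
  the window end inside the contig; truncated tails are dropped by
  default so every window shares one denominator (kept under a flag).
* **Mean depth** — total per-base read count over the region divided by
  the region length; the locus denominator is always the supplied
  interval's length, never a hard-coded constant.
* **Copy number** — locus mean depth over genome mean depth, excluding
  chrM by default (mitochondrial copy number is unrelated to the
  nuclear baseline).  The locus contig is *not* automatically removed
  from the denominator; for a locus that is small relative to the
  genome the bias is negligible, and callers quantifying a locus on its
  own contig can exclude it explicitly.  Both the real-valued estimate
  and a nearest-integer call are reported; clone-acceptance thresholds
  are left to the user.
* **RPGC** — values are scaled by `effective_size / Σ depth` so the
  track integrates to 1× over the effective genome size.
* **Relative coverage** — `(locus_mean / copy_number) / genome_mean`
  where the genome mean averages the per-window means; invariant under
  global rescaling of the track.
* **Peak density** — peaks are assigned to a window when their midpoint
  falls inside it (avoids double counting across overlapping sliding
  windows; "any overlap" is available), scaled to per-100-kb; over a
  window set the per-window densities are averaged.
* **Geneless windows** — windows overlapping any exclusion feature
  (annotated transcripts, blacklist regions, centromeres, telomeres) by
  ≥ 1 bp are removed.
* **Read counting** — a read counts toward a region on ≥ 1 bp overlap
  unless its SAM FLAG intersects the mask 2308
  (unmapped | secondary | supplementary); duplicates (1024) are *kept*,
  matching that mask's semantics.  The cross-region median uses the
  lower median for even counts, keeping it deterministic and integral.
* **Replicate correlation** — per-bin means, then optionally: drop bins
  zero in both tracks; drop bins deviating from their track median by
  more than 10 MADs (the threshold is configurable; when the MAD is
  zero the filter falls back to a standard-deviation scale); log(1+x);
  Pearson r.  Fewer than three surviving bins is an error rather than a
  meaningless coefficient.

## TSSs, promoters, metaplots

A TSS is the 5′ boundary of a stranded CAGE peak: `start` for `+`,
`end − 1` for `-`; unstranded peaks are rejected.  Promoters default to
200 bp upstream and 100 bp downstream with the TSS base as the first
downstream base, so the unclipped length is exactly 300 bp on either
strand (`+`: `[t−200, t+100)`; `-`: `[t−99, t+201)`); the minus-strand
off-by-one convention is symmetric and documented rather than inherited
from any upstream tool.

Metaplots extract per-base signal over `[t − flank, t + flank)`
(minus-strand windows shifted by one so that offset 0 reads the TSS
base after orientation flipping), average within 10-bp bins, and report
the per-bin mean and standard error (sd/√n) across sites.  Sites whose
window exceeds the contig are dropped and counted, not zero-padded —
padding would bias the mean toward zero.  An optional 100-bp centred
moving average (`smooth_track`) reproduces the common
bin-10/smooth-100 track style before extraction; it is off by default.

## Synthetic data

The generators emulate the *statistical* structure of the real inputs,
not their biology: i.i.d. bases at a requested GC (no repeat
structure), Poisson shot noise for depth and read counts, Gaussian
signal bumps (default width 150 bp) at planted TSSs, and uniformly
placed reads with a stated SAM-flag mixture (2% secondary, 1%
supplementary, 5% duplicate).  Genes are planted on a jittered grid
confined to the first 40% of each contig; without such gene deserts no
100-kb window would survive geneless filtering, unlike a real genome.
Every generator is a pure function of `(seed, spec)` — reruns are
byte-identical — and every dataset ships a truth table so downstream
tests compare against bookkeeping, never against copied numbers.

The default end-to-end fixture contrasts two regimes on one 2-Mb,
four-contig host with a 100-kb integrated locus (the reversed member of
a designed trio, carried as its own contig, as custom alignment
references do): **host A** plants 12 TSSs across the locus and a
genome-wide grid at 4 per 100 kb (planted locus/genome density ratio 3,
echoing the ~3× CAGE-peak excess reported for naive loci in a
transcription-permissive host), while **host B** plants none and draws
locus reads at ~1 per 100 kb against a geneless background of ~20 per
100-kb window, so the locus falls below the geneless-window median by
construction.  Genome TSSs sit on a jittered grid rather than a pure
Poisson scatter to keep the realized density close to its target at
desk scale.  Problem sizes (2-Mb genome, 100-kb locus, 10-bp signal
bins) were chosen as the smallest at which 100-kb/10-kb windowing and
per-window Poisson statistics behave as they do at genome scale.

Because the base model is i.i.d. and the noise purely Poisson/Gaussian,
passing tests demonstrate correctness of the *procedures* — not
robustness to repeats, mappability artifacts, GC bias or overdispersed
counts, none of which the generators produce.

## Numerical and degenerate-input conventions

O/E ratio is defined as 0 when the expectation is 0 (all-A input).
`gc_track` emits only full windows, anchored at window starts.  Island
calling on input shorter than one window returns no islands.  Copy
number on a zero-coverage genome, RPGC on a zero track, correlation
with fewer than three surviving bins, and a metaplot with no usable
site all raise typed errors instead of returning NaN.  Exit codes in
the CLI: 0 success, 1 computation error, 2 usage/input error.

## Testing strategy and limitations

The scrubber is checked against an independent recursive oracle that
enumerates every coin-flip path: reachable-output equivalence is
asserted exhaustively for every input up to 4 bp and for a battery of
structured and random inputs up to 12 bp (exhausting all ~22 million
inputs up to 12 bp is not meaningful desk-scale work; the property and
its oracle are length-independent), plus termination on 10,000 random
1-kb sequences.  Quantification procedures are validated against
brute-force loop oracles, seeded Poisson simulations (copy-number
recovery at 1/2/4 copies), and translation/scale-invariance properties.
Known limitations: no BAM/CRAM parsing (text formats and read tables
only), no peak calling, no GC-bias or mappability modelling, and no
codon- or vendor-constraint-aware segmentation.
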