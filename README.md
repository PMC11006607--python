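# locusforge

Tools for designing **evolutionarily naive DNA loci** and quantifying
what a host genome does with them.

A recurring question in regulatory genomics is what the *default
genomic state* of a host cell is: what happens to a large piece of DNA
that carries no evolved promoters, enhancers or genes?  One way to build
such DNA is to take a natural ~100-kb locus and **reverse the base
string without complementing it** — composition-level features (GC
content, homopolymer runs, repeat density) survive, but all evolved
coding and regulatory information is destroyed.  A second derivative
then deletes one base of every CpG dinucleotide, removing the signal
implicated in Polycomb (PRC2) recruitment.  `locusforge` implements the
design transforms, the composition statistics that characterize the
resulting sequences, and the sequencing-coverage pipeline used to ask
whether the naive locus is active in its host.

## What is implemented

**Design** (`locusforge.locus_design`)

- reversal without complementation: `out[i] = in[L-1-i]`
- iterative stochastic CpG scrubbing: scan for `CG`, delete the C or the
  G with a fair coin flip, rescan until none remain (deletions can
  create fresh CpGs at the junction); seeded, with a full deletion audit
- synthesis segmentation: the fewest segments of length ≤ *t* covering
  *L* bp with ≥ *v* bp overlap between neighbours is the smallest *n*
  with *n·t − (n−1)·v ≥ L*
- homology-armed insertion constructs (default 40-bp arms), e.g. for
  tagging a candidate TSS with a reporter gene

**Composition** (`locusforge.seq_features`)

- mono/dinucleotide profiles; the reversal identity
  `dinuc_rev[XY] = dinuc_fwd[YX]`
- CpG statistics: `expected = n_C · n_G / L`,
  `O/E = observed / expected` (≈1 for composition-random DNA, ≪1 for
  CpG-depleted mammalian DNA)
- windowed GC tracks and CpG-island calling (100-bp windows at 1-bp
  shift, min length 200, GC ≥ 0.5, O/E ≥ 0.6 — all configurable)
- IUPAC-degenerate motif scanning on either strand

**Quantification** (`locusforge.coverage_stats`, `locusforge.tss_promoters`)

- 100-kb sliding windows at 10-kb step; mean depth per region
- copy number = locus depth / genome-average depth (chrM excluded)
- RPGC (1×) normalization; copy-corrected relative coverage
- peaks per 100 kb; geneless-window filtering and flag-filtered read
  counting (SAM mask 2308: unmapped/secondary/supplementary excluded,
  duplicates kept); replicate Pearson correlation on binned,
  outlier-trimmed, log1p signal
- TSSs as the 5′ boundary of stranded CAGE peaks; promoters −200/+100;
  TSS-anchored metaplots (±0.5 kb, 10-bp bins, mean ± s.e.)

**Synthetic data** (`locusforge.synthetic_data`) — seeded, byte-stable
generators for a host genome with genes and excluded regions, a
forward/reversed/scrubbed locus trio, stranded signal tracks with bumps
planted at chosen TSSs, CAGE peaks whose 5′ ends are the planted TSSs,
and read tables with chosen per-window Poisson densities, each with a
truth table for testing.

## Worked example

```python
import numpy as np
from locusforge import SequenceRecord, reverse_sequence, scrub_cpg, plan_segments
from locusforge.synthetic_data import random_sequence

locus = SequenceRecord("demo", random_sequence(np.random.default_rng(42), 20_000, 0.41))
rev = reverse_sequence(locus)
scrub = scrub_cpg(rev, seed=42)
plan = plan_segments(rev, target_len=4_000, overlap=300)
```

Running `python examples/01_design_locus.py` (which does exactly this)
prints:

```
forward locus: 20,000 bp, reversed -> demo_locus_R
CpG scrub: 1,097 deletions over 7 iterations, 20,000 bp -> 18,903 bp, CG occurrences now 0
synthesis plan: 6 segments of 3,583-3,584 bp with >= 300 bp overlaps
```

1,097 deletions is one base per CpG eliminated (including CpGs created
by earlier deletions, hence 7 scan iterations); six segments is the
minimum for 20 kb under a 4-kb synthesis limit with 300-bp overlaps.
The other scripts under `examples/` walk through composition statistics,
coverage quantification, TSS/metaplot analysis and the full pipeline;
`locusforge --help` exposes the same capabilities as a CLI.

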