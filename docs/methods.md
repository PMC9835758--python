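# Methods

## The model

`sexscan` classifies assembly material into autosomal, X-linked and
Y-linked compartments from the single assumption of the XX/XY copy-number
model: per-base sequencing depth is proportional to copy number, so the
female/male normalized coverage ratio (the chromosome quotient, CQ) has
expectation 1 on autosomes, 2 on the X and 0 on the Y. Normalization is
RPKM per non-overlapping 10 kb window (reads assigned to the window
containing their start coordinate), with library size defined as the
number of retained (uniquely mapped) reads, which makes RPKM
self-consistent after filtering and makes every CQ invariant under
library rescaling.

The complementary alignment-free signal is the canonical 25-mer content
of the two libraries: sequence present only on the Y is sampled only by
male reads, so k-mers seen in the male library and absent from the female
library, located exactly on the assembly and merged into contiguous
intervals, delineate Y-unique regions at 25 bp resolution — fine enough
to find Y fragments spliced into multi-megabase scaffolds, where windowed
CQ is diluted.

## Thresholds and conventions

| parameter | default | meaning |
|---|---|---|
| window size | 10,000 bp | CQ region size; last window per scaffold may be partial |
| `x_min` | 2 (exclusive) | window/gene tagged X when CQ > 2 (+∞ included) |
| `y_max` | 0.2 (exclusive) | window/gene tagged Y when CQ < 0.2 |
| `scaffold_min_fraction` | 0.40 (inclusive) | X/Y-tagged fraction of scaffold *length* for a candidate call |
| `min_window_fraction` | 0.5 | partial windows shorter than this fraction of the window size stay untagged |
| k | 25 | k-mer length (canonical = lexicographic min of k-mer and reverse complement) |
| `min_male_count` | 2 | male occurrences required for a male-unique k-mer (1 = literal "present in male"; 2 rejects singleton sequencing-error k-mers) |
| `max_female_count` | 0 | female occurrences tolerated (a knob for noisy real libraries) |
| `max_gap` | 0 | merge k-mer spans that overlap or abut; no gap bridging |
| density bin | 1,800,000 bp | Y-unique region density resolution along scaffolds |
| `min_mapq` | 20 | unique-mapping proxy for external BAM input |

Zero-coverage semantics avoid pseudocount bias: CQ = f/m when m > 0, +∞
when m = 0 < f (an X signature at any threshold), undefined when both are
0. Undefined windows are never tagged but still count in the scaffold-call
denominator ("40% of their *length*"). An epsilon-pseudocount mode
(`epsilon`, suggested 0.1 RPKM) is available for noisy real data. The
scaffold-call average CQ excludes infinite/undefined windows and reports
how many were excluded. A gene's context window is the one containing its
midpoint (boundary midpoints belong to the later window, half-open
convention); a length-weighted mean over all spanned windows is reported
alongside. All internal coordinates are 0-based half-open; GFF3 (1-based
closed), BED (0-based half-open) and RepeatMasker `.out` (1-based closed)
are converted at the format boundary.

Read placement on synthetic data uses an exact seed-and-verify matcher
(25 bp seed index, full-length verification on both strands,
case-insensitive). A read is unique when exactly one best full-length
location exists; multi-mapped reads are excluded from coverage by default
— the stand-in for aligning against a repeat-masked genome — with a
seeded `random-best` policy as the alternative. Reads with simulated
errors fall back to the best seed-anchored location when ≥ 95% of bases
match; mapped reads must lie fully within scaffold bounds. External
BAM/SAM alignments bypass the placer: primary records with MAPQ ≥ 20
become unique placements.

## What the synthetic data emulates

`SimConfig` defaults define the standard study: ten 100 kb scaffolds per
compartment, 30% interspersed repeats (diverged 2% per copy from small
per-compartment libraries, soft-masked; an optional fraction drawn from a
library shared across compartments models cross-mapping), five genes per
scaffold (1–3 kb), single-end 100 bp error-free reads at 20× per haploid
copy with Poisson library sizes, GC 0.5. Y-in-autosome misassemblies are
emulated by splicing freshly generated Y-compartment segments into a host
scaffold, with gene/repeat coordinates shifted and the injected interval
recorded in the truth.

Reads are sampled from the simulated *true genome*, not from the assembly
verbatim: a host scaffold carrying an injected segment contributes its
contiguous pre-injection sequence (female reads really do span the
original junction — the insert exists only in the assembly), each
injected segment is a separate male-only source, and every source is
padded with `read_length − 1` bases of deterministic flanking context so
per-base depth is exactly `mean_depth × copy_number` everywhere. Without
the padding, coverage starves at scaffold ends (a k-mer at position 0 is
covered only by reads starting exactly at 0), which fabricates
male-unique k-mers at segment edges — an artifact a real study of
continuous chromosomes cannot show. The consequences: a read's expected
library size is `depth × copy × (L + read_length − 1) / read_length`, and
a ~0.1% minority of reads overhang into context and carry no assembly
origin in their id (origin position −1).

Features of real data deliberately not modeled: paired ends, indels,
quality profiles, GC bias, contamination, heterozygosity and reference
bias, and compartment-specific repeat densities. The last is intentional:
with equal-sized desk-scale compartments, giving the Y a realistically
higher repeat fraction shifts *every* CQ by the ratio of retained library
sizes — an artifact of the scaled-down geometry that an
autosome-dominated real genome does not exhibit — so the generator uses
one repeat fraction for all compartments. Passing tests therefore
demonstrate correctness of the inference given the copy-number model,
not robustness to real-library biases.

## Statistical behavior at the thresholds

The strict `CQ > 2` threshold coincides exactly with the X expectation,
so an X window is tagged with probability ½ regardless of depth (the
noise is symmetric around 2; depth only narrows it). X-scaffold calls
then rest on the margin between the expected 50% tagged length and the
40% rule: with W windows per scaffold the miss probability is
P(Binomial(W, ½) < 0.4·W) — negligible for the multi-hundred-window
scaffolds the method is designed for, but material at ten windows
(≈ 17% per scaffold). Likewise the joint gene + context criterion passes
a true X gene with probability ≈ 0.32 at these depths (both CQs centred
on the threshold, correlation ≈ 0.45). Y calls have no such knife edge
(female coverage is structurally zero) and are essentially
deterministic, as are autosomal non-calls (CQ ≈ 1 is ~18 standard
deviations from either threshold at 20×). The desk-scale evaluation in
`sexscan.evaluate` reports these recovery rates as measured;
`scripts/acceptance.py` reproduces them from scratch.

Male-unique k-mer soundness is measured as the fraction of located hits
whose 25 bp span overlaps truth Y material by ≥ 1 bp (bedtools-style
overlap semantics): a handful of hits per run straddle an injection
boundary by 1–3 bp — they carry 22–24 bases of genuine Y sequence —
and strict containment would count them against the method.

## Problem sizes

The standard evaluation study is 3 Mb of assembly and ~1.6 M reads per
run (~25 s); the misassembly screen is one 3.75 Mb scaffold and ~3 M
reads across both libraries (~1 min), with k-mer counting chunked
in-memory (packed 64-bit canonical codes, k ≤ 31). These sizes put every
compartment mean on ≥ 100 windows and the injected segment across ≥ 2
density bins while keeping a full evaluation under a few minutes on one
CPU; the pipeline itself is linear in reads and genome size.

## Known limitations

- The exact-match placer is a desk-scale stand-in, not a general aligner
  (no gaps, no clipping); real data should come in as BAM.
- In-memory k-mer counting is sized for desk-scale studies, not for
  multi-human-scale libraries.
- CQ confidence intervals and GC-bias correction are out of scope, as are
  repeat annotation itself (only existing masks/tables are summarized)
  and primer design (only candidate amplicon intervals are exported).
- With `min_male_count` at its literal-reading value of 1, sequencing
  errors in the male library flood the male-unique set; the default of 2
  assumes error k-mers are mostly singletons, which holds at ≤ 1%
  substitution error and desk-scale depth.
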