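# Methods

This note documents the models and procedures implemented in `crforest`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Seed-and-extend scanning

Candidates are nucleated on exact seed words of `seed_len = 5` nt.  A short
seed maximizes sensitivity to repeat families that diverge internally: the
seed only needs one conserved 5-mer at a consistent offset across copies.
Seed occurrences are chained when successive gaps fall inside the
admissible array period, `[min_repeat_len + min_spacer_len − seed_len,
max_repeat_len + max_spacer_len]` = [34, 115] nt at the defaults (repeats
20–55 nt, spacers 19–60 nt).  Chains sharing two or more positions are
merged; windows containing `N` never seed, so assembly gaps cannot produce
chimeric seeds.

Extension grows every chain instance in lockstep, one flank column at a
time, while the modal nucleotide across instances reaches the directional
threshold: `ext5_threshold = 0.75`, `ext3_threshold = 0.60`.  Only the next
flanking column is tested — interior mismatches never stop extension,
which is precisely what makes the thresholds meaningful.  Extension also
stops at sequence ends, at instance collisions, and at `max_repeat_len`.

Two consequences of the lenient 3′ threshold are worth stating plainly:

* **Few-copy arrays have soft boundaries.**  With only 3 instances, a
  background flank column passes the 0.60 threshold whenever any two of
  the three flanking characters agree — probability 0.625 for uniform
  background — so 3-copy arrays typically over-extend by one or two
  columns at the 3′ end.  This is inherent to the scanning rule, not a
  defect: the permissive threshold exists to capture degenerate repeat
  ends, and downstream validation operates on the consensus, which
  tolerates a column or two of noise.  Boundary-exact behavior emerges
  at roughly a dozen copies (per-column spurious-extension probability
  ~1 % at 12+ instances), which is why the boundary-recovery benchmark
  plants arrays of 12–18 copies — typical of genuine loci.
* **Chance seed hits near an array can join a chain.**  A 5-mer from the
  repeat recurs in flanking background within chaining distance often
  enough (~5 % per word and side) that a spurious extra "instance" would
  otherwise hijack overlap resolution.  After extension, instances whose
  identity to the candidate consensus falls below
  `min_instance_identity = 0.70` are therefore dropped and spacer bounds
  re-checked.  0.70 sits far below the identity of genuine copies (≥ 0.9
  at realistic intra-array divergence) and far above the ~0.25 identity
  of a random interloper, so the cut is insensitive to its exact value.

Overlapping candidates are resolved by (more repeats, longer span,
leftmost) — an arbitrary but deterministic order.  Consensus is the
per-column mode with ties broken A < C < G < T.  Only the forward strand
is scanned: direct repeats are strand-symmetric, so reverse-strand
scanning would duplicate work.

## Structure features

Repeats are folded as RNA (T read as U) with ViennaRNA's MFE fold when the
bindings are importable; otherwise a bundled Nussinov maximum-pairing
folder (Watson–Crick + GU pairs, minimum loop 3, deterministic traceback)
is used, and the engine is recorded in model provenance so models are
never silently mixed across engines.  `N` is unpairable under both
engines.

The 32 triplet elements collapse `)` to `(` (two structural statuses per
position), slide a 3-window over the structure, and count the pair
(middle nucleotide, window pattern), normalizing by the L−2 windows.
Features are reported on the DNA alphabet (A, C, G, T) even though folding
is RNA.  Windows whose middle nucleotide is `N` stay in the denominator
but increment no cell, keeping vectors comparable across sequences with
gaps.  The canonical feature order (nucleotide-major) is versioned into
model files; loading a model whose order differs is a hard error.

## Classifier

Negatives are drawn from a first-order Markov chain fitted to the positive
repeats (initial distribution from first nucleotides, transitions from
adjacent pairs, add-one smoothing on unobserved rows, lengths resampled
from the training pool), so the two classes share base and dinucleotide
composition and differ mainly in structure — the signal the triplet
elements encode.  The default negative:positive ratio is 1.05.

The forest uses 500 trees, 5 features tried per split, bootstrap
resampling, and a fixed seed; the "repeat" call requires at least 50 % of
trees voting for it (ties go to "repeat").  The 80/20 split is performed
per class with the test partition floored.  Candidates are classified by
their consensus repeat by default; a `majority` mode classifies every
instance and requires more than half labeled "repeat" (useful when the
consensus is blurred by boundary noise).  Evaluation reports confusion
metrics at the vote threshold and a tie-corrected rank-statistic AUC over
vote scores.

Models are serialized with joblib together with format version, feature
order, training configuration and provenance (class sizes, folding
engine).  No pre-trained model ships in the repository — a serialized
forest is a large binary artifact with no provenance a user can audit;
`crf train --synthetic N` rebuilds an equivalent model from the packaged
generator in seconds, and `crf train --positives <fasta>` trains from any
repeat collection.

## Filters

* **k-mer diversity** = distinct k-mers / min(windows, 4^k), k = 3, with
  thresholds 0.2 (consensus repeat), 0.2 (each spacer) and 0.25 (whole
  array span).  The statistic is a reconstruction chosen as the simplest
  one for which "lower = more repetitive" thresholds of this magnitude
  are sensible.  The denominator cap matters: only 4³ = 64 distinct
  3-mers exist, so an uncapped distinct fraction could never reach 0.25
  on spans longer than 258 nt and every genuine multi-repeat array would
  fail.  On repeat- and spacer-length inputs the cap is inactive.
* **Tandem periodicity score**: for each period p ≤ 10, a
  Smith–Waterman-style running score over self-matches at lag p (+1
  match, −5 mismatch, clamped at 0); the best run score is compared to
  the ≥ 10 threshold.  The −5 mismatch penalty mirrors the defaults of
  dedicated tandem-repeat finders; a milder −1 penalty was measured to
  let chance periodicity random-walk past the threshold on 2–5 % of
  genuine array spans, while −5 flags ≤ 0.3 % of them and still catches
  100 % of tandem decoys carrying 5 % point mutations.  True CRISPR
  periodicity (unit ≥ 39 nt) is invisible at periods ≤ 10.
* **Spacer similarity**: positional matches over the shared prefix
  normalized by the longer length (a defensible extension of Hamming
  identity to unequal lengths — length mismatch is penalized); any pair
  above 0.5 rejects the array.

All rules always run (no short-circuit) so every candidate carries a
complete per-rule report.  Classification precedes filtering; both
outcomes are recorded, so the rejecting stage is auditable.

## Synthetic data

The generator emulates (a) stem-loop-bearing repeats: random prefix +
stem arm + 4 nt loop + reverse-complement arm + random suffix, with the
arm defaulting to 40 % of the repeat length (the hairpin spans ~80 % of
the repeat, emulating strongly palindromic repeat families; a fixed short
stem leaves the positives barely more structured than what random
sequence folds into, and the class signal the features are built for
disappears); (b) first-order Markov background negatives; (c) genomes
with planted arrays: i.i.d. uniform background (GC 0.5, adjustable),
arrays placed uniformly with ≥ 100 nt separation, exact truth intervals
returned and asserted against the genome; (d) tandem decoys (a unit
repeated n times).  Training pools cycle repeat lengths over 24–40 nt
with 2 % substitution noise.

What passing tests on this harness show: the scanner recovers planted
periodic structure, the features separate structured from Markov
sequence, and the filters kill the decoy classes they were designed for.
What they do not show: performance on real genomes, where background is
not i.i.d., repeat families are not perfect palindromes, arrays sit next
to cas genes and leaders, and spacers carry phage-derived content.  The
classifier trained on synthetic positives is a demonstration model; for
real use, train on a curated repeat collection.

## Problem sizes and numerical choices

The shipped benchmarks use 1,000 + 1,000 training sequences, 200 scan
replicates on 5 kb genomes, and 50 benchmark genomes of 20 kb with 1–3
arrays each — sizes at which every reported quantity is stable across
seeds (held-out accuracy ~0.98 ± 0.01, boundary recovery ~98–99 %,
benchmark recall/precision ≥ 0.95).  Degenerate inputs are handled
explicitly: poly-nucleotide genomes produce chains whose extensions
violate spacer bounds and are dropped; candidates whose consensus is
shorter than 3 nt are rejected as unfeaturizable; empty Markov rows are
smoothed; the test-partition floor uses an epsilon to avoid float
artifacts (0.2 × 12,000 must be exactly 2,400).

## Known limitations

* Single-strand, exact-seed scanning: repeat families whose copies share
  no exact 5-mer at a consistent offset are missed.
* The tandem score and k-mer statistic are internal reconstructions of
  external-tool behavior, not ports; thresholds are calibrated to the
  generator's conditions and exposed for adjustment.
* Arrays with fewer than ~5 copies have fuzzy 3′ boundaries by design of
  the 0.60 extension threshold.
* The folding engine's temperature/parameter set is whatever ViennaRNA
  defaults to; models record the engine, not the parameter set.
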