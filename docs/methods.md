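# Methods

## The estimator

`kivcn` estimates the total diploid copy number *N* of a tandemly repeated
unit (the motivating case is the ~5.5 kb kringle-IV-type-2 repeat of *LPA*,
whose copy number spans roughly 12–60 across the two haplotypes and is
inversely related to Lp(a) concentration) directly from sequencing reads,
without alignment.  Two canonical k-mer sets are prepared from a reference:

* **repeat k-mers** — present exactly once per repeat unit (multiplicity 6 in
  a reference carrying six units) and nowhere else in the reference;
* **normalization k-mers** — present exactly once, in a nearby single-copy
  region (for *LPA*: the gene minus the repeat array), and nowhere else.

For a sample sequenced at per-haplotype depth *c*, a repeat k-mer is covered
by reads in proportion to *N·c* while a normalization k-mer sees *2c* (one
copy per haplotype).  The estimate is therefore

    N̂ = diploid_factor · mean_repeat / mean_norm,   diploid_factor = 2,

where each mean is the arithmetic mean of occurrence counts over k-mers
**with at least one observation** — a k-mer with count exactly 0 signals
divergence from the reference, a null allele, or a coverage hole, and is
excluded rather than averaged in as a fractional copy (the per-sample report
exposes the missing-k-mer tallies so such samples are visible).  Depth,
read-edge effects (a window is only counted when it lies fully inside a
read) and, to first order, base-calling errors — both means attenuate by
≈(1−e)^k — cancel in the ratio.  The ×2 factor converts the per-haplotype
ratio to the diploid total; it is exposed as `diploid_factor` and was
confirmed by the simulator (regression of estimate on truth has slope ≈ 1;
with factor 1 the slope would be 0.5).

No per-k-mer multiplicity reweighting is applied: database construction
already guarantees one occurrence per repeat unit, so nothing divides by 6.
The mean is the plain arithmetic mean; no robust alternative is enabled by
default.

## Database construction

Five stages, all on canonical k-mers (the lexicographic minimum of a k-mer
and its reverse complement — reads come from both strands, so both the
database and the counter canonicalize; without this, half of all read
k-mers would never match):

1. enumerate k-mers whose windows lie entirely inside the repeat regions,
   and separately inside the normalization regions (BED, 0-based half-open;
   windows straddling a region boundary are excluded; windows containing
   non-ACGT bases are skipped);
2. keep k-mers whose in-region count **equals** the expected multiplicity
   (strict equality; defaults 6 and 1, both configurable so the tool
   generalizes to other VNTRs);
3. discard k-mers occurring anywhere else in the supplied reference
   (any window not fully inside a declared region);
4. discard k-mers shared between the two sets;
5. write both sets as FASTA and TSV in lexicographic order, making rebuilds
   byte-identical.

"Anywhere else" is interpreted relative to whatever reference the user
supplies: a whole genome for production use, a locus-scale sequence for
small studies and tests.  An empty set after filtering is a hard error that
reports the per-stage retention counts.

Default k = 31.  The counting engine packs k-mers into 2-bit 64-bit codes,
which caps k at 31; raising k further mainly trades error robustness for
specificity and is not needed at locus scale.

## Counting

Every length-k window of every read is canonicalized and, if present in the
database (optionally extended by SNP-panel k-mers), counted.  Base
qualities are ignored: an erroneous base simply yields a k-mer that fails
to match, which is precisely the attenuation that cancels in the ratio.
Memory stays O(|database|); only tracked k-mers are stored, and k-mers
never observed keep an explicit count of 0.  Paired files are counted as a
flat read stream (pairing is irrelevant to occurrence counting); gzip is
detected from content, not file name.

The hot path is a numba-jitted rolling-hash kernel (forward and
reverse-complement codes maintained per window, membership via an
open-addressing hash table); a vectorized numpy implementation of the same
contract serves as fallback and is cross-checked against it, and against a
naive per-window tally, in the tests.

## SNP carrier calls

A panel TSV (columns `rsid`, `allele` ∈ {ref, alt}, `kmer`) lists
reference- and alternative-allele k-mers per variant.  Panel k-mers are
counted in the same pass as the database; a sample is a **carrier** when at
least `min_alt_count` (default 1) reads support at least one alternative
k-mer.  The default follows the presence/absence rule appropriate inside a
multi-copy repeat, where zygosity is not identifiable from occurrence
counts alone; note that with threshold 1 a single erroneous k-mer can
create a false carrier — raise `min_alt_count` for noisy libraries.  A
panel k-mer that is also a database k-mer is rejected at load time (its
count would be ambiguous between copy-number and allele signal).

## The simulator

The simulator reproduces the validation protocol at locus scale.  A locus
template is

    5' flank | repeat array (6 diverged units) | normalization region | 3' flank

with defaults matching the real architecture: units of 5,500 bp at 0.5%
expected pairwise divergence (six variants mutated independently from a
common ancestor at rate 0.25%), a 100 kb single-copy normalization region,
5 kb flanks.  Region lengths matter: they set how many reads inform each
occurrence mean and hence the estimation noise floor.  Shrunken loci (used
in the unit tests) behave identically in expectation but are noisier.

Each simulated individual draws per-haplotype copy numbers n1, n2 uniformly
from 6–30 (diploid truth 12–60), fills its array with units drawn uniformly
with replacement from the six variants (replacing the reference array, so
the truth label is exact and fixed before any read exists), and receives
substitutions on haplotype 2 outside the array at 1/1000 bp, a common-SNP
density proxy for the divergence between two real haplotypes.  These
heterozygous substitutions knock out ~3% of normalization k-mers on one
haplotype, deflating `mean_norm` by ~1.5% and hence inflating the estimate
by the same factor — visible as a regression slope of ~1.02 rather than
1.00, and a realistic feature of reference-based k-mer sets.

Reads are 150 bp paired-end: fragments are placed uniformly per haplotype
with insert ~ Normal(400 bp, 60 bp) clipped below at the read length;
"coverage c" means expected depth per haplotype, so each haplotype of
length L receives round(c·L/300) pairs.  Per-base Phred qualities are drawn
from Normal(mean_quality, 3) truncated to [2, 41]; substitution errors are
applied independently at rate 10^(−Q/10) (no indels — the substitution-only
model matches the error process the ratio is robust to; indel errors would
likewise just fail to match).  Everything is deterministic given a seed;
per-sample generators are spawned from a root `SeedSequence`.

What the simulator does **not** emulate: GC-dependent coverage bias,
quality decay along the read and bbmap/Illumina-specific quality profiles,
indels and structural errors, contamination, and the other 99.9% of the
genome (reads never come from elsewhere, so off-target k-mer collisions
with real genomic sequence are not exercised at locus scale — the
background-exclusion filter is instead tested directly with decoy contigs).
Passing validation therefore demonstrates the statistical behaviour of the
estimator under its own model, not performance on any particular real
cohort.

## Validation protocol and expected numbers

`scripts/acceptance.py --seed <int> --out <path>` regenerates the full
grid: 40 samples per condition, coverages 5/10/20/30× at mean quality 28,
and mean qualities 18/20/28 at 10×, reporting the minimum R² between
estimate and truth across each axis.  Typical results (full-scale locus):
R² ≈ 0.991–0.997 per coverage condition (minimum across the axis ≈ 0.992),
≈ 0.993–0.995 across the quality axis, slope ≈ 1.01–1.02, intercept ≈ 0.
At 2× coverage R² drops to ≈ 0.97–0.99; below Q14 accuracy degrades as
k-mer survival (1−e)^31 collapses.  One caveat stated plainly: with 40
samples and truths uniform on 12–60, the sampling SD of R² near 0.99 is
~0.004, so individual conditions at 5× can land on either side of 0.99 —
the acceptance tests compare at a 0.05 slack for this bounded statistic,
with a tighter frozen-seed regression guard.

The whole grid runs in ~1–2 minutes on one CPU; the test suite in ~2
minutes.  Problem sizes (40 samples, full-scale locus) are the protocol's
own; the unit-test fixtures use a ~550 bp/3 kb locus purely for speed.

## Numerical and design notes

* k ≤ 31 (2 bits/base in uint64).  Canonical comparison is on the packed
  integer codes; code order equals lexicographic order on ACGT strings.
* Multiplicity filtering is strict equality, not ≥: a k-mer occurring 5 or
  7 times in the reference array is not a clean per-unit marker.
* Repeat-unit boundary k-mers: the repeat region is one contiguous BED
  interval, so windows spanning unit–unit junctions are counted; with
  diverged units junction k-mers fail the multiplicity-6 filter naturally,
  leaving unit-internal conserved k-mers.
* Estimation requires at least one observed normalization k-mer (otherwise
  a hard "no normalization signal" error); an all-absent repeat set yields
  estimate 0 with a warning rather than an error (a legitimate null-allele
  readout).
* `run_condition` records failed samples as missing and excludes them from
  metrics with a warning; metrics need ≥ 3 successful samples.
* The CLI is a thin layer: `build-db`, `count`, `estimate`, `simulate`,
  `run-experiment`; exit code 0 = success, 1 = usage, 2 = data error.  All
  run parameters live in a flat YAML config (unknown keys rejected) that is
  serialized into every output directory.
* Open choice, resolved: whether the 40 individuals are shared across
  conditions is not fixed by the protocol; both modes exist
  (`shared_truths`), the default draws independent cohorts per condition.
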