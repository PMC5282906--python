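# Methods

## Problem setting

`isocall` detects somatic mutations that are *unique to one sample* in a
cohort of N isogenic samples — single-cell clones derived from a common
ancestor, as produced by mutagenesis experiments in cell culture (e.g.
differently treated DT40 chicken lymphoblast clones sequenced at ~20×).
Because the samples share all germline variation and most alignment
artefacts recur at the same genomic positions across samples, cross-sample
filtering can separate true clone-private mutations from both without any
reference SNP database. Conversely, the method deliberately does not call
shared (germline) variants, does not genotype, and reports at most one
mutated sample per position.

## The decision procedure

At every position of a joint, quality-filtered pileup (mpileup with BAQ
disabled and a base-quality floor of 30 applied upstream):

1. For each sample, the strongest non-reference event is found among
   mismatching bases, insertion sequences and deletion sequences. The
   sample with the highest mutant-allele fraction is the **candidate**;
   ties break by lowest sample index, then SNV > INS > DEL, then
   lexicographic allele, so output is deterministic.
2. The candidate must satisfy `sample_mut_freq >= sample_mut_freq_min`
   and `coverage >= sample_cov_min`.
3. Every other sample must be clean: with `rnf` the reference-read
   fraction, the *noisiest* other sample (minimum rnf) must satisfy
   `rnf >= other_rnf_min`. A heterozygous germline SNP (rnf ≈ 0.5 in all
   samples) or a shared alignment artefact fails this immediately.
4. The **S score** is computed as −log₁₀ p of a Fisher's exact test on the
   2×2 table of (reference-supporting, candidate-allele-supporting) read
   counts in the candidate and in the noisiest other sample. Optional
   per-type thresholds `s_min_snv/ins/del` give a second filtering stage
   that can be tuned on negative controls.

All threshold comparisons are inclusive (≥), so the published defaults
(`sample_mut_freq_min = 0.21`, `other_rnf_min = 0.93`,
`sample_cov_min = 5`) reproduce boundary behaviour exactly. A stricter
fixed operating point for low-FPR use without S tuning is
(0.31, 0.93, 7).

### rnf and indel anchors

In pileup text an indel annotation (`+n<seq>` / `-n<seq>`) rides on an
anchor read whose base matches the reference, so a naive
`ref_count/coverage` would score a sample full of indel-supporting reads
as perfectly clean and the cross-sample veto would never exclude shared
indels. `rnf` therefore subtracts indel-supporting reads from the
reference count: `rnf = (ref_count − indel_support) / coverage`. Samples
with zero coverage return rnf = 1.0 — an uncovered sample carries no
counter-evidence, and letting it veto would suppress every position not
covered in all N samples.

### The Fisher test convention

The test is one-sided toward the candidate being *enriched* for
mutation-supporting reads, computed as the exact hypergeometric tail
P(X ≥ mut_candidate) under fixed margins. When the candidate's mutant
fraction does not strictly exceed the other sample's — including
identical rows and zero margins — the data carry no evidence of a unique
mutation and p is defined as 1 (S = 0). p is computed with
`scipy.stats.hypergeom.sf`; tests verify it against both an independent
integer-arithmetic enumeration of all same-margin tables (agreement
within 1e−10 for all tables with row sums ≤ 25) and
`scipy.stats.fisher_exact(alternative="greater")`.

The "mutation-supporting" column of the other sample counts reads
supporting the *candidate's* allele specifically; a different
non-reference allele in the other sample is not evidence for the
candidate's mutation.

### Post-processing

The raw call list is cleaned per sample and chromosome: SNV calls within
`proximity_bp` (default 10) of an indel call are removed
(indel-adjacent alignment slippage), and of two indel calls within the
window only the higher-S one is kept (ties keep the earlier position).
These rules and the 10 bp window are this package's reconstruction of a
post-processing stage whose published description is not fully specified;
the stage is isolated, configurable, and disabled entirely by
`proximity_bp = 0` or `--no-postprocess`. Note that because removing one
call can rescue a nearby one, call counts are guaranteed monotone in the
thresholds only *before* this stage; the monotonicity tests therefore run
with post-processing off.

## Test-set construction

Given two related genotype groups A and B, per-position mean rnf over the
covered samples of each group places group-specific heterozygous variants
in tight clusters: B-specific het SNPs at (mean_A, mean_B) ≈ (1.0, 0.5),
A-specific at (0.5, 1.0), germline SNPs at (0.5, 0.5) and clean reference
at (1.0, 1.0). Positions inside a square of half-width
`rect_half_width` (default 0.1, a package choice recorded in the
test-set provenance; any value in (0, 0.25) is accepted) around the two
group-specific centres, restricted to user-declared disomic chromosomes,
form the test set. Regions of ploidy > 2 cluster near (1.0, ~0.67) and
fall outside the rectangle by construction. Positions uncovered in any
sample of either group are dropped (configurable minimum covered count);
loss-of-heterozygosity regions are deliberately not distinguished from
germline differences. The indel test set uses the same clustering with
the per-sample fraction of reads *not* supporting an indel in place of
rnf.

## Evaluation protocols

- **TPR**: the caller runs on the starting clone of one genotype together
  with all clones of the other genotype; the first genotype's
  group-specific variants are then unique to that single sample, and TPR
  is the fraction of its group's test set recovered in it.
- **FPR**: unique calls in negative controls — pre-treatment starting
  clones and identical sample pairs (the same DNA preparation sequenced
  twice), in which no true unique mutation can exist. Each member's calls
  count separately. FPR is reported both per control genome and per base
  pair, since at human/chicken genome scale (~1 Gbp) the two published
  normalisations coincide numerically.
- **Sample-number experiment**: random subsets of size n (controls and
  the TPR target always retained), re-called and re-evaluated; mean ± sd
  over seeded replicates. Shrinking n weakens the cross-sample veto —
  hotspots and group-specific variants lose their witnesses — so FPR
  rises as n falls.
- **Down-sampling experiment**: the target sample's reads are thinned by
  binomial sampling with retention ds_factor; alt counts become
  Binomial(count, ds) and coverage shrinks consistently, the count-level
  equivalent of read-level down-sampling. TPR falls as ds drops because
  het variants increasingly miss the mutant-fraction and coverage floors.

## S-score tuning

With negative controls available, per-type S thresholds are set to the
smallest value leaving at most `tolerated_fp` control calls (the next
floating-point number above the (tolerated_fp+1)-th largest control
score). Being an order statistic of the control scores, tuning can never
remove a non-control call whose S exceeds every control score of its
type.

## The synthetic cohort generator

The generator emulates the clone-sequencing design at the pileup-count
level: per sample-position coverage is Poisson(coverage_mean, default
20 — matching starting-clone coverages of ~21× in the motivating data and
the recommended ≥15× floor), and read-class counts are binomial.

Planted structure, all at distinct loci:

- **shared SNPs** — heterozygous in every sample (germline);
- **group-specific SNPs/indels** — heterozygous in every member of one
  group, split evenly between the two groups; these are the test-set
  targets;
- **unique SNVs/indels** — heterozygous in exactly one sample (the
  somatic events the caller must find); starting clones receive none;
- **noise hotspots** — one artefact base planted in k ~ U{2..N} samples
  at per-sample fraction f ~ U(0.2, 0.5), with at least two artefact
  reads per affected sample when depth allows (systematic misalignment
  affects every read of the mismapped locus class, so near-zero support
  in an affected sample is unrealistic);
- **sequencing errors** — Binomial(coverage, error_rate, default 10⁻³)
  reads per cell, spread uniformly over the three non-reference bases.
  Error draws at cells that already own a planted event are subsumed into
  the planted draw (bias O(error_rate)).

Heterozygous allele fraction is 0.5 on disomic chromosomes and 1/3 on
chromosomes flagged non-disomic, reproducing the higher-ploidy clusters
the test-set rectangles must exclude. `plant_identical_pair` re-draws one
sample's planted events into a second sample id with independent
binomial/coverage noise and flags both as negative controls.

The generator works on counts, not reads: it models no read-level error
profiles, mapping quality, strand information, GC bias, or the coverage
dip downstream of a deletion. Passing tests therefore demonstrate the
decision procedure's behaviour under the stated count model, not
robustness to alignment pathologies real pileups can contain beyond the
hotspot model. Reference bases are a deterministic hash of position;
allele identity never influences filtering, only output columns.

## Execution model and problem sizes

The exact per-position decision procedure is Python-level; screening
multi-megabase cohorts position-by-position would dominate runtime, so a
vectorized prescreen selects positions where some sample has
max-allele-count ≥ `sample_mut_freq_min` × coverage and coverage ≥
`sample_cov_min`, and the exact procedure runs on the survivors. The
prescreen provably cannot discard a callable position (a call requires
the argmax-frequency sample to pass both inclusive thresholds), and
equality with the streaming path is tested. Chunked execution partitions
the genome into contiguous ranges, calls each independently and merges by
a global sort before post-processing, so output is byte-identical for any
chunk count.

Validation cohorts are desk-scale by choice: the reference cohort is
1 Mbp × 30 samples at 20× (simulates and calls in well under a minute
each), and the trend experiments use a 200 kbp genome with a denser
hotspot load (150) and more group SNPs (200) so that the
sample-number/coverage trends are sharply resolved with 3 replicates.
All randomness flows through seeded numpy generators; every reported
number is bit-reproducible given (inputs, parameters, seed).

## Known limitations

- One call per position: multi-allelic somatic hits and mutations shared
  by ≥ 2 samples are out of scope by design.
- The deletion coverage dip and `*` placeholders downstream of the anchor
  are not modelled by the simulator (the caller parses them correctly).
- The post-processing stage is a reconstruction (see above).
- Whether upstream pileup generation applied a minimum mapping quality is
  the user's responsibility; the reader does not re-filter.
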