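# isocall

Unique somatic SNV and short-indel calling in cohorts of isogenic
samples, by joint multi-sample pileup filtering.

## The problem

Mutagenesis experiments in cell culture sequence many single-cell clones
derived from one ancestral cell — differently treated, but genetically
identical at the start. The question is which mutations each clone
acquired *on its own*. Conventional tumour/normal callers fit this design
poorly: there is no matched normal, and cell lines like DT40 differ from
their reference genome by millions of SNPs, overwhelming database-driven
germline filtering.

`isocall` exploits the design instead: germline variants and alignment
artefacts recur at the same genomic position in *multiple* samples, while
true clone-private mutations appear in exactly one. At each position of a
joint pileup of all N samples it:

1. nominates the sample with the highest mutant-allele fraction
   (`sample_mut_freq`) as the candidate;
2. requires `sample_mut_freq >= sample_mut_freq_min` (default 0.21) and
   candidate coverage `>= sample_cov_min` (default 5);
3. requires the *noisiest other* sample — minimum reference-read fraction
   rnf among the non-candidates — to satisfy `rnf >= other_rnf_min`
   (default 0.93), which removes shared SNPs and artefacts without any
   variant database;
4. scores confidence as `S = -log10 p`, with p a one-sided Fisher's exact
   test that the two noisiest samples share one base distribution;
   optional per-type S thresholds can be tuned on negative controls
   (starting clones, or the same DNA preparation sequenced twice).

The package also includes the surrounding machinery: construction of
genotype-specific heterozygous test sets by mean-rnf clustering on
disomic chromosomes, TPR/FPR evaluation protocols, sample-number and
coverage-down-sampling experiments, and a synthetic cohort generator
with planted truth that makes the whole pipeline testable end to end
without any external data.

## A worked example

```bash
python examples/01_simulate_and_call.py
```

simulates a 50 kbp, 12-sample cohort at 20× (germline SNPs, noise
hotspots, an identical sample pair, and per-sample unique heterozygous
events), calls it at the default thresholds and prints:

```
samples: 12, genome: 50000 bp
planted unique events: 88
calls emitted:         86
true positives:        86
false positives:       0
TPR: 0.977

first three calls (sample, locus, type, ref>alt, freq, S):
  S03  chr1:263  SNV  A>T  freq=0.52  S=5.2
  S06  chr1:380  SNV  C>A  freq=0.55  S=4.1
  S10  chr1:589  INS  A>AGG  freq=0.44  S=2.9
```

86 of 88 planted unique events are recovered (the two misses fell below
the mutant-fraction or coverage floors by binomial chance) and no shared
SNP, hotspot, or control sample produces a call. The other example
scripts cover test-set clustering (`02`), the cohort-size and
sequencing-depth trends (`03`), and S-score tuning (`04`).

The same workflow is available from the shell:

```bash
isocall simulate --genome-length 50000 --n-samples 12 --out-prefix sim
isocall call --pileup sim.pileup --sample-sheet sim.samples.tsv --out calls.tsv
isocall make-testset --pileup sim.pileup --sample-sheet sim.samples.tsv \
    --group-a WT --group-b MUT --disomic-chroms chr1 --out testset.bed
isocall tune-s --calls calls.tsv --sample-sheet sim.samples.tsv --out tuned.tsv
```

`isocall call` reads any samtools-style multi-sample pileup (generate
with `samtools mpileup -B -Q 30 *.bam`), so real cohorts plug in at the
pileup level.

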