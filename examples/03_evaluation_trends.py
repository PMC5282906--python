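"""How cohort size and sequencing depth shape TPR and FPR.

Re-runs calling on random sample subsets (fewer witnesses for the
cross-sample veto -> more false positives in negative controls) and with
the target sample's coverage binomially thinned (weaker mutant-read
evidence -> lower TPR).  Results are means over seeded replicates.
"""

import dataclasses

from isocall import (
    EvaluationConfig,
    FilterParams,
    SimConfig,
    cohort_rnf_points,
    downsample_experiment,
    plant_identical_pair,
    select_clusters,
    simulate_cohort,
    subset_experiment,
    summarize,
)

cfg = SimConfig(
    chrom_names=("chr1",),
    chrom_lengths=(80_000,),
    disomic=(True,),
    n_samples=20,
    n_shared_snps=40,
    n_group_snps=80,
    n_unique_per_sample=10,
    n_unique_indels_per_sample=2,
    n_noise_hotspots=60,
    seed=13,
)
cohort = simulate_cohort(plant_identical_pair(cfg))

testset = select_clusters(
    cohort_rnf_points(cohort, "WT", "MUT"), ["chr1"], group_a="WT", group_b="MUT"
)
config = EvaluationConfig(
    testset=testset,
    negative_control_ids=cohort.sheet.controls(),
    tpr_target_sample=cohort.config.starting_clones[1],
    genome_size_bp=cohort.genome_size,
    replicates=3,
    seed=5,
)
params = FilterParams()

print(f"test set: {len(testset)} positions; controls: {config.negative_control_ids}")
print("\ncohort size vs control FPR (mean of 3 subsets):")
for n in (6, 10, 20):
    s = summarize(subset_experiment(cohort, params, dataclasses.replace(config, n_subset=n)))
    print(f"  n={n:2d}: FPR {s['fpr_per_genome_mean']:6.2f} calls/control"
          f"  (sd {s['fpr_per_genome_sd']:.2f}),  TPR {s['tpr_mean']:.3f}")

print("\ntarget coverage vs TPR (mean of 3 thinnings):")
for ds in (1.0, 0.7, 0.5):
    s = summarize(downsample_experiment(cohort, params, dataclasses.replace(config, ds_factor=ds)))
    print(f"  ds={ds:.1f}: TPR {s['tpr_mean']:.3f} (sd {s['tpr_sd']:.3f}),"
          f"  FPR {s['fpr_per_genome_mean']:.2f}")
# FPR falls as samples are added; TPR falls as the target is thinned —
# hence the practical advice of >= ~14 samples and >= ~15x coverage.
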