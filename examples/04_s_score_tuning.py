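"""Tune per-type S-score thresholds on negative controls.

With lenient basic thresholds the caller admits some false positives;
every call carries an S score (-log10 of the Fisher's-exact-test p-value
comparing the candidate with the noisiest other sample).  Setting the
threshold just above the strongest control-sample score removes all
control calls while keeping every stronger true call.
"""

from isocall import (
    FilterParams,
    SimConfig,
    call_cohort,
    plant_identical_pair,
    simulate_cohort,
    tune_s,
)

cfg = SimConfig(
    chrom_names=("chr1",),
    chrom_lengths=(60_000,),
    disomic=(True,),
    n_samples=12,
    sequencing_error_rate=2e-3,
    n_shared_snps=30,
    n_group_snps=20,
    n_unique_per_sample=10,
    n_unique_indels_per_sample=3,
    n_noise_hotspots=40,
    seed=19,
)
cohort = simulate_cohort(plant_identical_pair(cfg))

# lenient operating point, as recommended when S tuning will follow
lenient = FilterParams(sample_mut_freq_min=0.15, other_rnf_min=0.9, sample_cov_min=4)
calls = call_cohort(cohort, lenient)

controls = cohort.sheet.controls()
n_control_before = sum(c.sample_id in set(controls) for c in calls)
thresholds, filtered = tune_s(calls, controls, tolerated_fp=0)
n_control_after = sum(c.sample_id in set(controls) for c in filtered)

print(f"negative controls: {controls}")
print(f"calls at lenient thresholds: {len(calls)} ({n_control_before} in controls)")
print("tuned S thresholds:")
for t, v in thresholds.items():
    print(f"  {t}: {v:.3f}")
print(f"calls after tuning: {len(filtered)} ({n_control_after} in controls)")
# Control calls drop to zero; true unique mutations with S above the
# strongest control score are untouched by construction.
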