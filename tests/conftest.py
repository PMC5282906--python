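import pytest

from isocall import FilterParams, SimConfig, plant_identical_pair, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 20 kb, 10-sample cohort with every event class planted."""
    cfg = SimConfig(
        chrom_names=("chr1", "chr2"),
        chrom_lengths=(18_000, 2_000),
        disomic=(True, False),
        n_samples=10,
        coverage_mean=20.0,
        sequencing_error_rate=1e-3,
        n_shared_snps=20,
        n_group_snps=20,
        n_group_indels=6,
        n_unique_per_sample=5,
        n_unique_indels_per_sample=2,
        n_noise_hotspots=5,
        seed=42,
    )
    cfg = plant_identical_pair(cfg)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_params():
    return FilterParams()
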