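import io

import numpy as np
import pytest
from scipy import stats

from isocall import (
    SimConfig,
    plant_identical_pair,
    simulate_cohort,
    write_joint_pileup,
)


def tiny_config(**kw):
    defaults = dict(
        chrom_names=("chr1",),
        chrom_lengths=(5_000,),
        disomic=(True,),
        n_samples=6,
        coverage_mean=20.0,
        sequencing_error_rate=0.0,
        n_shared_snps=5,
        n_group_snps=6,
        n_unique_per_sample=3,
        n_unique_indels_per_sample=1,
        n_noise_hotspots=2,
        seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_no_events_and_no_errors_gives_pure_reference():
    cfg = tiny_config(
        n_shared_snps=0,
        n_group_snps=0,
        n_unique_per_sample=0,
        n_unique_indels_per_sample=0,
        n_noise_hotspots=0,
    )
    cohort = simulate_cohort(cfg)
    assert len(cohort.events) == 0
    p = cohort.position_pileup(123)
    assert all(o.ref_count == o.coverage for o in p.observations)


def test_fixed_seed_is_byte_identical():
    buf1, buf2 = io.StringIO(), io.StringIO()
    for buf in (buf1, buf2):
        cohort = simulate_cohort(tiny_config(sequencing_error_rate=1e-3))
        write_joint_pileup(
            (cohort.position_pileup(i) for i in range(500)), buf
        )
    assert buf1.getvalue() == buf2.getvalue()


def test_different_seeds_differ():
    c1 = simulate_cohort(tiny_config(seed=1))
    c2 = simulate_cohort(tiny_config(seed=2))
    assert not np.array_equal(c1.cov, c2.cov)


def test_truth_completeness_error_free():
    """Every non-reference read in an error-free cohort traces to a truth event."""
    cohort = simulate_cohort(tiny_config())
    truth_keys = {
        cohort.global_index(r.chrom, r.pos) for r in cohort.truth.itertuples()
    }
    event_keys = set(cohort.events["pos"].tolist())
    assert event_keys <= truth_keys


def test_planted_loci_are_mutually_exclusive():
    cohort = simulate_cohort(tiny_config())
    t = cohort.truth
    # one class per locus
    per_pos = t.groupby(["chrom", "pos"])["class"].nunique()
    assert (per_pos == 1).all()


def test_het_alt_fraction_is_binomial():
    """Across many planted het loci, alt counts match Binomial(cov, 0.5)."""
    cfg = tiny_config(
        chrom_lengths=(50_000,),
        n_shared_snps=0,
        n_group_snps=0,
        n_unique_per_sample=120,
        n_unique_indels_per_sample=0,
        n_noise_hotspots=0,
        n_samples=4,
        seed=9,
    )
    cohort = simulate_cohort(cfg)
    ev = cohort.events
    alts = ev["count"].to_numpy()
    covs = cohort.cov[ev["pos"].to_numpy(), ev["sample"].to_numpy()]
    # pooled two-sided binomial check on the total
    n_tot = int(covs.sum())
    p = stats.binomtest(int(alts.sum()), n_tot, 0.5).pvalue
    assert p > 0.01
    # and per-locus variance should not collapse (fractions do vary)
    assert np.std(alts / covs) > 0.02


def test_nondisomic_het_fraction_is_one_third():
    cfg = tiny_config(
        chrom_names=("chr1",),
        chrom_lengths=(50_000,),
        disomic=(False,),
        n_shared_snps=0,
        n_group_snps=0,
        n_unique_per_sample=150,
        n_unique_indels_per_sample=0,
        n_noise_hotspots=0,
        n_samples=4,
        seed=3,
    )
    cohort = simulate_cohort(cfg)
    ev = cohort.events
    covs = cohort.cov[ev["pos"].to_numpy(), ev["sample"].to_numpy()]
    frac = ev["count"].sum() / covs.sum()
    assert frac == pytest.approx(1 / 3, abs=0.03)


def test_hotspots_hit_at_least_two_samples():
    cfg = tiny_config(n_noise_hotspots=10, seed=5)
    cohort = simulate_cohort(cfg)
    noise = cohort.truth[cohort.truth["class"] == "noise"]
    ev = cohort.events
    for r in noise.itertuples():
        g = cohort.global_index(r.chrom, r.pos)
        affected = ev[ev["pos"] == g]["sample"].nunique()
        assert affected >= 2


def test_identical_pair_shares_every_event():
    cfg = plant_identical_pair(tiny_config(), "S05", "S06")
    cohort = simulate_cohort(cfg)
    t = cohort.truth
    pos_src = set(map(tuple, t[t["owner"] == "S05"][["chrom", "pos"]].values))
    pos_dup = set(map(tuple, t[t["owner"] == "S06"][["chrom", "pos"]].values))
    assert pos_src == pos_dup and len(pos_src) > 0
    assert cohort.sheet.control_flags["S05"] and cohort.sheet.control_flags["S06"]
    # unpaired treated samples keep their own unique events
    assert (t["owner"] == "S02").sum() == cfg.n_unique_per_sample + cfg.n_unique_indels_per_sample


def test_pair_members_must_share_group():
    with pytest.raises(ValueError):
        plant_identical_pair(tiny_config(), "S01", "S06").make_sheet()


def test_starting_clones_have_no_unique_events():
    cohort = simulate_cohort(tiny_config())
    owners = set(cohort.truth["owner"])
    for clone in cohort.config.starting_clones:
        assert clone not in owners


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        simulate_cohort(tiny_config(chrom_lengths=(10,), n_shared_snps=100))


def test_thin_sample_preserves_proportions_in_expectation():
    cfg = tiny_config(chrom_lengths=(30_000,), n_unique_per_sample=100, n_samples=4, seed=7)
    cohort = simulate_cohort(cfg)
    rng = np.random.default_rng(0)
    thinned = cohort.thin_sample("S02", 0.5, rng)
    s = cohort.sheet.index("S02")
    ratio = thinned.cov[:, s].sum() / cohort.cov[:, s].sum()
    assert ratio == pytest.approx(0.5, abs=0.01)
    # untouched samples identical
    other = cohort.sheet.index("S03")
    assert np.array_equal(thinned.cov[:, other], cohort.cov[:, other])
    # alt counts never exceed coverage
    ev = thinned.events
    tot = ev.groupby(["pos", "sample"])["count"].sum()
    for (p, smp), c in tot.items():
        assert c <= thinned.cov[p, smp]


def test_subset_remaps_samples():
    cohort = simulate_cohort(tiny_config())
    sub = cohort.subset(["S02", "S04"])
    assert sub.sheet.sample_ids == ["S02", "S04"]
    assert sub.cov.shape[1] == 2
    i_old = cohort.sheet.index("S04")
    assert np.array_equal(sub.cov[:, 1], cohort.cov[:, i_old])
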