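import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from isocall import (
    DEL,
    INS,
    SNV,
    FilterParams,
    PositionPileup,
    SampleObservation,
    call_position,
    call_stream,
    candidate_allele,
    fisher_p,
    noisiest_others,
    post_process,
    rnf,
    s_score,
)
from isocall.model import MutationCall


def obs(cov=0, ref=0, bases=None, ins=None, dels=None):
    return SampleObservation(
        coverage=cov,
        ref_count=ref,
        base_counts=bases or {},
        insertion_counts=ins or {},
        deletion_counts=dels or {},
    )


def fisher_oracle(table):
    """Exact one-sided p by integer enumeration of same-margin tables."""
    (ref_c, mut_c), (ref_o, mut_o) = table
    n1, n2 = ref_c + mut_c, ref_o + mut_o
    total, k_mut = n1 + n2, mut_c + mut_o
    if n1 == 0 or k_mut == 0 or k_mut == total:
        return 1.0
    if mut_c * n2 <= mut_o * n1:  # no candidate enrichment -> no evidence
        return 1.0
    num = sum(
        math.comb(n1, k) * math.comb(n2, k_mut - k)
        for k in range(mut_c, min(n1, k_mut) + 1)
        if k_mut - k <= n2
    )
    return num / math.comb(total, k_mut)


class TestRnf:
    def test_basic_fraction(self):
        assert rnf(obs(cov=100, ref=93, bases={"T": 7})) == pytest.approx(0.93)

    def test_zero_coverage_is_neutral(self):
        # an uncovered sample must not veto calls elsewhere
        assert rnf(obs()) == 1.0

    def test_heterozygous_expectation(self):
        assert rnf(obs(cov=20, ref=10, bases={"A": 10})) == pytest.approx(0.5)

    def test_indel_anchors_are_not_reference_evidence(self):
        # 10 of 20 reads carry a deletion: the sample is half mutant
        assert rnf(obs(cov=20, ref=20, dels={"AC": 10})) == pytest.approx(0.5)


class TestCandidateAllele:
    def test_snv(self):
        assert candidate_allele(obs(cov=10, ref=5, bases={"T": 5}), "G") == (
            SNV,
            "T",
            5,
            0.5,
        )

    def test_insertion(self):
        assert candidate_allele(obs(cov=10, ref=7, ins={"AG": 3}), "G") == (
            INS,
            "AG",
            3,
            0.3,
        )

    def test_tie_breaks_lexicographic_then_type(self):
        o = obs(cov=10, ref=6, bases={"A": 2, "C": 2})
        assert candidate_allele(o, "G")[:2] == (SNV, "A")
        o2 = obs(cov=10, ref=8, bases={"T": 2}, dels={"T": 2})
        assert candidate_allele(o2, "G")[0] == SNV  # SNV beats DEL on ties

    def test_ref_base_excluded(self):
        assert candidate_allele(obs(cov=10, ref=0, bases={"G": 10}), "G") is None

    def test_zero_coverage(self):
        assert candidate_allele(obs(), "G") is None


class TestNoisiestOthers:
    def _position(self, rnfs, candidate=0):
        observations = [obs(cov=100, ref=int(round(100 * r)), bases={"T": 100 - int(round(100 * r))}) for r in rnfs]
        return PositionPileup("chr1", 1, "G", observations)

    def test_minimum_rnf_wins(self):
        p = self._position([0.5, 1.0, 0.95, 0.90])
        assert noisiest_others(p, 0) == (pytest.approx(0.90), 3)

    def test_all_clean_ties_to_lowest_index(self):
        p = self._position([0.5, 1.0, 1.0, 1.0])
        assert noisiest_others(p, 0) == (1.0, 1)

    def test_tie_breaks_lowest_index(self):
        p = self._position([0.5, 0.93, 0.93])
        val, idx = noisiest_others(p, 0)
        assert val == pytest.approx(0.93) and idx == 1

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            noisiest_others(PositionPileup("chr1", 1, "G", [obs(cov=5, ref=5)]), 0)


class TestFisher:
    def test_null_table(self):
        assert fisher_p(((5, 5), (5, 5))) == 1.0

    def test_zero_margin(self):
        assert fisher_p(((10, 0), (10, 0))) == 1.0

    def test_derived_value(self):
        # single extreme table: C(10,5)C(10,0)/C(20,5)
        assert fisher_p(((5, 5), (10, 0))) == pytest.approx(252 / 15504, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            t = tuple(tuple(int(x) for x in row) for row in rng.integers(0, 15, (2, 2)))
            assert fisher_p(t) == pytest.approx(fisher_oracle(t), abs=1e-10)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(100):
            (a, b), (c, d) = rng.integers(0, 20, (2, 2))
            if b * (c + d) <= d * (a + b):
                continue  # enrichment gate returns 1.0 by definition
            p = fisher_p(((int(a), int(b)), (int(c), int(d))))
            p_ref = fisher_exact([[b, a], [d, c]], alternative="greater")[1]
            assert p == pytest.approx(p_ref, abs=1e-10)
            checked += 1
        assert checked > 30

    def test_s_monotone_in_mutant_reads(self):
        # more mutant reads at fixed coverage never lowers confidence
        cov = 30
        scores = [
            s_score(fisher_p(((cov - m, m), (28, 2)))) for m in range(cov + 1)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))


class TestSScore:
    def test_values(self):
        assert s_score(1.0) == 0.0
        assert s_score(0.01) == pytest.approx(2.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            s_score(0.0)
        with pytest.raises(ValueError):
            s_score(1.5)


def four_sample_position(candidate_bases=10, candidate_cov=20, other_mut=(0, 0, 0)):
    observations = [
        obs(cov=candidate_cov, ref=candidate_cov - candidate_bases, bases={"T": candidate_bases})
    ]
    for m in other_mut:
        observations.append(obs(cov=20, ref=20 - m, bases={"T": m} if m else {}))
    return PositionPileup("chr1", 500, "G", observations)


class TestCallPosition:
    def test_clean_unique_het_is_called(self, default_params):
        call = call_position(four_sample_position(), default_params)
        assert call is not None
        assert (call.mut_type, call.alt_allele, call.sample_mut_freq) == (SNV, "T", 0.5)
        assert call.cleanest_other_rnf == 1.0
        assert call.s_score > 2.0

    def test_noisy_other_sample_vetoes(self, default_params):
        # a second sample at rnf 0.90 < 0.93 marks the site as shared noise
        call = call_position(four_sample_position(other_mut=(2, 0, 0)), default_params)
        assert call is None

    def test_coverage_floor(self):
        params = FilterParams(sample_cov_min=7)
        p = four_sample_position(candidate_bases=3, candidate_cov=6)
        assert call_position(p, params) is None

    def test_mut_freq_floor_inclusive(self):
        params = FilterParams(sample_mut_freq_min=0.5)
        assert call_position(four_sample_position(candidate_bases=10), params) is not None
        assert call_position(four_sample_position(candidate_bases=9), params) is None

    def test_s_threshold_filters_by_type(self):
        p = four_sample_position()
        loose = FilterParams(s_min_snv=1.0)
        strict = FilterParams(s_min_snv=100.0)
        assert call_position(p, loose) is not None
        assert call_position(p, strict) is None
        # a DEL threshold must not affect an SNV call
        assert call_position(p, FilterParams(s_min_del=100.0)) is not None

    def test_ref_n_skipped(self, default_params):
        p = four_sample_position()
        p.ref_base = "N"
        assert call_position(p, default_params) is None

    def test_indel_call_alleles(self, default_params):
        observations = [obs(cov=20, ref=20, dels={"AC": 9})] + [
            obs(cov=20, ref=20) for _ in range(3)
        ]
        call = call_position(PositionPileup("chr1", 7, "G", observations), default_params)
        assert call is not None
        assert (call.mut_type, call.ref_allele, call.alt_allele) == (DEL, "GAC", "G")


def mk_call(sample, pos, mut_type=SNV, s=2.0):
    return MutationCall(sample, "chr1", pos, mut_type, "G", "T", 20, 0.5, 1.0, s)


class TestPostProcess:
    def test_snv_near_indel_removed(self):
        calls = [mk_call("S1", 100, SNV), mk_call("S1", 105, DEL)]
        out = post_process(calls, proximity_bp=10)
        assert [c.pos for c in out] == [105]

    def test_different_samples_unaffected(self):
        calls = [mk_call("S1", 100, SNV), mk_call("S2", 105, DEL)]
        assert post_process(calls, proximity_bp=10) == calls

    def test_proximity_zero_is_identity(self):
        calls = [mk_call("S1", 100, SNV), mk_call("S1", 105, DEL)]
        assert post_process(calls, proximity_bp=0) == calls

    def test_lower_s_indel_of_close_pair_removed(self):
        calls = [mk_call("S1", 100, INS, s=1.0), mk_call("S1", 104, DEL, s=3.0)]
        out = post_process(calls, proximity_bp=10)
        assert [c.pos for c in out] == [104]

    def test_distant_indels_kept(self):
        calls = [mk_call("S1", 100, INS, s=1.0), mk_call("S1", 200, DEL, s=3.0)]
        assert post_process(calls, proximity_bp=10) == calls


def test_call_stream_empty_and_sorted(default_params):
    assert call_stream(iter([]), default_params) == []
    positions = [four_sample_position(), four_sample_position()]
    positions[1].pos = 100
    out = call_stream(positions, default_params, sample_ids=["a", "b", "c", "d"])
    assert [c.pos for c in out] == [100, 500]
    assert all(c.sample_id == "a" for c in out)
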