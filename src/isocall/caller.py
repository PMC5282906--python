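"""The core decision procedure for sample-unique mutation calling.

At every genomic position, across N isogenic samples:

1. each sample's strongest non-reference event (base mismatch, insertion
   or deletion) is identified; the sample with the highest mutant-allele
   fraction becomes the *candidate*;
2. the candidate must clear a mutant-fraction floor (``sample_mut_freq_min``)
   and a coverage floor (``sample_cov_min``);
3. every *other* sample must look clean: the noisiest of them (lowest
   reference-read fraction, rnf) must have rnf >= ``other_rnf_min``.  This
   single cross-sample test removes germline SNPs and alignment artefacts,
   which recur at the same position in multiple samples, without any
   variant database;
4. an S score quantifies confidence: S = -log10(p) of a one-sided Fisher's
   exact test that the candidate and the noisiest other sample share one
   base distribution.  Optional per-type S thresholds give a second,
   tunable filtering stage.

A position yields at most one call, for exactly one sample — by design the
method only reports mutations unique to a single sample.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Tuple

from scipy.stats import hypergeom
import numpy as np

from .model import (
    DEL,
    INS,
    SNV,
    FilterParams,
    MutationCall,
    PositionPileup,
    SampleObservation,
)

logger = logging.getLogger(__name__)

_TYPE_PRECEDENCE = {SNV: 0, INS: 1, DEL: 2}


def rnf(obs: SampleObservation) -> float:
    """Reference nucleotide frequency of one sample at one position.

    Reads carrying an indel annotation are not counted as reference
    evidence even though their anchor base matches the reference.  A
    zero-coverage sample returns 1.0: an uncovered sample provides no
    counter-evidence and must not veto calls in the covered samples.
    """
    if obs.coverage == 0:
        return 1.0
    return obs.effective_ref_count() / obs.coverage


def candidate_allele(
    obs: SampleObservation, ref_base: str
) -> Optional[Tuple[str, str, int, float]]:
    """Strongest non-reference event: (mut_type, allele, support, freq).

    Ties are broken by type precedence SNV > INS > DEL, then lexicographic
    allele order, so the choice is deterministic.  Returns None for a
    zero-coverage sample or one with no non-reference evidence.
    """
    if obs.coverage == 0:
        return None
    best: Optional[Tuple[int, int, str, str]] = None  # (-count, prec, allele, type)
    for b, c in obs.base_counts.items():
        if b == ref_base or c <= 0:
            continue
        key = (-c, _TYPE_PRECEDENCE[SNV], b, SNV)
        if best is None or key < best:
            best = key
    for seq, c in obs.insertion_counts.items():
        if c <= 0:
            continue
        key = (-c, _TYPE_PRECEDENCE[INS], seq, INS)
        if best is None or key < best:
            best = key
    for seq, c in obs.deletion_counts.items():
        if c <= 0:
            continue
        key = (-c, _TYPE_PRECEDENCE[DEL], seq, DEL)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    count = -best[0]
    return best[3], best[2], count, count / obs.coverage


def noisiest_others(
    position: PositionPileup, candidate_idx: int
) -> Tuple[float, int]:
    """rnf of the noisiest non-candidate sample and its index.

    The cross-sample threshold applies to the minimum rnf among the other
    samples; ties go to the lowest sample index.
    """
    if len(position.observations) < 2:
        raise ValueError("method requires at least 2 samples")
    best_rnf = None
    best_idx = -1
    for k, obs in enumerate(position.observations):
        if k == candidate_idx:
            continue
        r = rnf(obs)
        if best_rnf is None or r < best_rnf:
            best_rnf = r
            best_idx = k
    return best_rnf, best_idx


def fisher_p(table: Tuple[Tuple[int, int], Tuple[int, int]]) -> float:
    """One-sided Fisher's exact test on a 2x2 table of read counts.

    Rows are (reference-supporting, mutation-supporting) counts of the
    candidate sample and of the noisiest other sample.  The test is
    one-sided toward a sample-unique mutation: when the candidate's
    mutant-read fraction strictly exceeds the other sample's, the p-value
    is the fixed-margin probability of the candidate having at least its
    observed number of mutation-supporting reads (exact hypergeometric
    tail); otherwise the data carry no evidence of candidate enrichment
    and p is 1.  A zero margin likewise returns 1.
    """
    (ref_c, mut_c), (ref_o, mut_o) = table
    for v in (ref_c, mut_c, ref_o, mut_o):
        if v < 0:
            raise ValueError("table cells must be non-negative")
    n1 = ref_c + mut_c
    n2 = ref_o + mut_o
    total = n1 + n2
    k_mut = mut_c + mut_o
    if n1 == 0 or k_mut == 0 or total == k_mut:
        return 1.0  # a zero margin admits only one table
    if mut_c * n2 <= mut_o * n1:
        return 1.0  # candidate not enriched for mutant reads
    p = float(hypergeom.sf(mut_c - 1, total, k_mut, n1))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def s_score(p: float) -> float:
    """S = -log10(p): orders of magnitude of Fisher-test improbability."""
    if p <= 0 or p > 1:
        raise ValueError("p must be in (0, 1]")
    return max(-float(np.log10(p)), 0.0)


def _other_allele_support(obs: SampleObservation, mut_type: str, allele: str) -> int:
    if mut_type == SNV:
        return obs.base_counts.get(allele, 0)
    if mut_type == INS:
        return obs.insertion_counts.get(allele, 0)
    return obs.deletion_counts.get(allele, 0)


def call_position(
    position: PositionPileup, params: FilterParams
) -> Optional[MutationCall]:
    """Apply the full decision procedure at one position.

    Returns the single accepted call, or None.  Positions with reference
    base N are skipped.
    """
    if position.ref_base == "N":
        return None
    if len(position.observations) < 2:
        raise ValueError("method requires at least 2 samples")

    best = None  # (-freq, idx, candidate)
    for idx, obs in enumerate(position.observations):
        cand = candidate_allele(obs, position.ref_base)
        if cand is None:
            continue
        key = (-cand[3], idx)
        if best is None or key < best[:2]:
            best = (key[0], idx, cand)
    if best is None:
        return None
    idx = best[1]
    mut_type, allele, support, freq = best[2]
    obs = position.observations[idx]

    if freq < params.sample_mut_freq_min:
        return None
    if obs.coverage < params.sample_cov_min:
        return None
    cleanest_other_rnf, noisy_idx = noisiest_others(position, idx)
    if cleanest_other_rnf < params.other_rnf_min:
        return None

    noisy = position.observations[noisy_idx]
    table = (
        (obs.effective_ref_count(), support),
        (noisy.effective_ref_count(), _other_allele_support(noisy, mut_type, allele)),
    )
    s = s_score(fisher_p(table))
    s_threshold = params.s_min(mut_type)
    if s_threshold is not None and s < s_threshold:
        return None

    if mut_type == SNV:
        ref_allele, alt_allele = position.ref_base, allele
    elif mut_type == INS:
        ref_allele, alt_allele = position.ref_base, position.ref_base + allele
    else:
        ref_allele, alt_allele = position.ref_base + allele, position.ref_base
    return MutationCall(
        sample_id=str(idx),  # caller of call_position fills real IDs; see call_stream
        chrom=position.chrom,
        pos=position.pos,
        mut_type=mut_type,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        coverage=obs.coverage,
        sample_mut_freq=freq,
        cleanest_other_rnf=cleanest_other_rnf,
        s_score=s,
    )


def call_stream(
    positions: Iterable[PositionPileup],
    params: FilterParams,
    sample_ids: Optional[List[str]] = None,
) -> List[MutationCall]:
    """Run :func:`call_position` over a position stream; sorted output.

    ``sample_ids`` maps observation indices to sample identifiers; when
    omitted the string index is used.
    """
    calls: List[MutationCall] = []
    for position in positions:
        try:
            call = call_position(position, params)
        except ValueError:
            logger.warning(
                "skipping ill-formed position %s:%d", position.chrom, position.pos
            )
            continue
        if call is not None:
            if sample_ids is not None:
                call.sample_id = sample_ids[int(call.sample_id)]
            calls.append(call)
    calls.sort(key=lambda c: c.sort_key())
    return calls


def post_process(calls: List[MutationCall], proximity_bp: int = 10) -> List[MutationCall]:
    """Proximity clean-up of the raw call list.

    Within one sample and chromosome: (a) SNV calls within ``proximity_bp``
    of any indel call are removed (indel-adjacent alignment slippage);
    (b) of any two indel calls within ``proximity_bp``, the lower-S one is
    removed.  ``proximity_bp = 0`` disables the stage.
    """
    if proximity_bp <= 0:
        return list(calls)
    drop = set()
    by_sample_chrom = {}
    for k, c in enumerate(calls):
        by_sample_chrom.setdefault((c.sample_id, c.chrom), []).append((k, c))

    for group in by_sample_chrom.values():
        indels = [(k, c) for k, c in group if c.mut_type in (INS, DEL)]
        # (a) SNVs near any indel call (judged on the raw list)
        for k, c in group:
            if c.mut_type != SNV:
                continue
            if any(abs(c.pos - ic.pos) <= proximity_bp for _, ic in indels):
                drop.add(k)
        # (b) lower-S member of close indel pairs
        indels.sort(key=lambda kc: kc[1].pos)
        for a in range(len(indels)):
            ka, ca = indels[a]
            for b in range(a + 1, len(indels)):
                kb, cb = indels[b]
                if cb.pos - ca.pos > proximity_bp:
                    break
                # drop the lower-scoring one; ties keep the earlier position
                if ca.s_score < cb.s_score:
                    drop.add(ka)
                else:
                    drop.add(kb)
    return [c for k, c in enumerate(calls) if k not in drop]
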