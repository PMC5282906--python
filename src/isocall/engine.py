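"""Fast cohort-level execution of the caller.

The per-position decision procedure (:func:`isocall.caller.call_position`)
is exact but Python-speed; screening a multi-megabase cohort position by
position would dominate runtime even though almost every position is
plain reference.  This module prescreens a :class:`~isocall.simulate.Cohort`
with vectorized numpy/pandas operations and then runs the exact decision
procedure only on surviving candidate positions.

The prescreen keeps a position iff some sample has
``max-single-allele-count / coverage >= sample_mut_freq_min`` and
``coverage >= sample_cov_min``.  This is consistent with the exact caller:
a call requires the argmax-frequency sample to pass both (inclusive)
thresholds, which implies at least one sample passes both — so no position
the exact caller would accept is ever screened out.  Equality of the two
paths is enforced by tests on small cohorts.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .caller import call_position, post_process
from .model import FilterParams, MutationCall
from .simulate import Cohort


def _candidate_positions(
    cohort: Cohort,
    params: FilterParams,
    pos_range: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    ev = cohort.events
    if pos_range is not None:
        lo, hi = pos_range
        ev = ev[(ev["pos"] >= lo) & (ev["pos"] < hi)]
    if not len(ev):
        return np.array([], dtype=np.int64)
    per_allele = ev.groupby(["pos", "sample", "kind", "allele"], as_index=False)[
        "count"
    ].sum()
    per_cell = per_allele.groupby(["pos", "sample"], as_index=False)["count"].max()
    pos = per_cell["pos"].to_numpy()
    smp = per_cell["sample"].to_numpy()
    best = per_cell["count"].to_numpy()
    cov = cohort.cov[pos, smp].astype(np.int64)
    ok = (
        (cov >= params.sample_cov_min)
        & (cov > 0)
        & (best >= params.sample_mut_freq_min * cov)
    )
    return np.unique(pos[ok])


def call_cohort(
    cohort: Cohort,
    params: FilterParams,
    postprocess: bool = True,
    proximity_bp: int = 10,
    pos_range: Optional[Tuple[int, int]] = None,
) -> List[MutationCall]:
    """Run the caller over a whole cohort; deterministic sorted output."""
    survivors = _candidate_positions(cohort, params, pos_range)
    calls: List[MutationCall] = []
    ids = cohort.sheet.sample_ids
    for pos_idx in survivors:
        position = cohort.position_pileup(int(pos_idx))
        call = call_position(position, params)
        if call is not None:
            call.sample_id = ids[int(call.sample_id)]
            calls.append(call)
    calls.sort(key=lambda c: c.sort_key())
    if postprocess:
        calls = post_process(calls, proximity_bp)
    return calls


def run_chunked(
    cohort: Cohort,
    params: FilterParams,
    n_chunks: int = 1,
    postprocess: bool = True,
    proximity_bp: int = 10,
) -> List[MutationCall]:
    """Chunked execution with a deterministic merge.

    The genome is partitioned into ``n_chunks`` contiguous position ranges;
    each chunk is called independently and the results are concatenated,
    sorted and post-processed globally, so output is byte-identical to an
    unchunked run regardless of the chunk count.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    edges = np.linspace(0, cohort.n_positions, n_chunks + 1).astype(int)
    calls: List[MutationCall] = []
    for k in range(n_chunks):
        calls.extend(
            call_cohort(
                cohort,
                params,
                postprocess=False,
                pos_range=(int(edges[k]), int(edges[k + 1])),
            )
        )
    calls.sort(key=lambda c: c.sort_key())
    if postprocess:
        calls = post_process(calls, proximity_bp)
    return calls
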