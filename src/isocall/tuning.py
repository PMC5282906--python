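"""S-score threshold tuning against negative controls.

When negative controls (starting clones, identical sample pairs) are
available, per-type S thresholds can be set directly from the data: for
each mutation type, the smallest threshold that leaves at most
``tolerated_fp`` control calls.  Because thresholding is an order
statistic on the control scores, tuning can never remove a true call
whose S exceeds every control score.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model import DEL, INS, MUT_TYPES, SNV, MutationCall


def tune_s(
    calls: List[MutationCall],
    controls: Sequence[str],
    tolerated_fp: int = 0,
) -> Tuple[Dict[str, float], List[MutationCall]]:
    """Per-type S thresholds leaving <= tolerated_fp control calls.

    Returns ``(thresholds, filtered_calls)`` where ``filtered_calls`` keeps
    calls with ``s_score >= threshold`` of their type.  A type with no
    control calls (or few enough) gets threshold 0.0.
    """
    if not controls:
        raise ValueError("at least one negative control required")
    if tolerated_fp < 0:
        raise ValueError("tolerated_fp must be >= 0")
    control_set = set(controls)
    thresholds: Dict[str, float] = {}
    for mut_type in MUT_TYPES:
        scores = sorted(
            (c.s_score for c in calls if c.sample_id in control_set and c.mut_type == mut_type),
            reverse=True,
        )
        if len(scores) <= tolerated_fp:
            thresholds[mut_type] = 0.0
        else:
            # smallest float strictly above the (tolerated_fp+1)-th largest score
            thresholds[mut_type] = float(np.nextafter(scores[tolerated_fp], np.inf))
    filtered = [c for c in calls if c.s_score >= thresholds[c.mut_type]]
    return thresholds, filtered
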