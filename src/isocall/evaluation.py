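"""TPR/FPR evaluation and sample-number / coverage sensitivity experiments.

True positive rate follows the genotype-specific protocol: the caller is
run on the starting clone of one genotype together with all clones of the
other genotype, so the first genotype's group-specific variants are unique
to that single sample; TPR is the fraction of the group-specific test set
recovered in it.  False positive rate counts unique calls in negative
controls (starting clones and identical sample pairs), where no true
unique mutation can exist; it is reported both per control genome and per
base pair.

Two drivers probe robustness: ``subset_experiment`` re-runs calling on
random sample subsets of size n (controls and the TPR target always
retained), and ``downsample_experiment`` binomially thins the target
sample's reads by a factor ds and re-evaluates.  Both are seeded and
replicate-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import call_cohort
from .model import FilterParams, MutationCall
from .simulate import Cohort
from .testset import TestSet


@dataclass
class EvaluationConfig:
    testset: TestSet
    negative_control_ids: List[str]
    tpr_target_sample: str
    genome_size_bp: int
    n_subset: Optional[int] = None
    ds_factor: Optional[float] = None
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size_bp < 1:
            raise ValueError("genome_size_bp must be positive")
        if self.ds_factor is not None and not 0 < self.ds_factor <= 1:
            raise ValueError("ds_factor must be in (0, 1]")
        if self.n_subset is not None and self.n_subset < 2:
            raise ValueError("n_subset must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class EvaluationResult:
    tpr: float
    fpr_per_genome: float
    fpr_per_bp: float
    calls_in_controls: int
    calls_in_target: int
    testset_size: int
    label: str = ""


def compute_tpr(calls: List[MutationCall], config: EvaluationConfig) -> float:
    """Fraction of the target group's test set called in the target sample."""
    if len(config.testset) == 0:
        raise ValueError("test set is empty")
    target = config.tpr_target_sample
    called = {(c.chrom, c.pos) for c in calls if c.sample_id == target}
    # the test set passed in is expected to be restricted to the target's
    # genotype (evaluate_cohort does this); every position counts
    pts = {(c, p) for c, p, _ in config.testset.positions}
    return len(pts & called) / len(pts)


def compute_fpr(
    calls: List[MutationCall], config: EvaluationConfig
) -> Tuple[float, float]:
    """(mean unique calls per control genome, same normalised per bp)."""
    controls = config.negative_control_ids
    if not controls:
        raise ValueError("at least one negative control required")
    counts = {s: 0 for s in controls}
    for c in calls:
        if c.sample_id in counts:
            counts[c.sample_id] += 1
    per_genome = sum(counts.values()) / len(controls)
    return per_genome, per_genome / config.genome_size_bp


def _tpr_protocol_samples(cohort: Cohort, target: str) -> List[str]:
    """Target starting clone + every clone of the other genotype(s)."""
    sheet = cohort.sheet
    tgt_group = sheet.group_labels[target]
    others = [s for s in sheet.sample_ids if sheet.group_labels[s] != tgt_group]
    if not others:
        raise ValueError("TPR protocol needs samples of another genotype")
    return [target] + others


def _target_testset(config: EvaluationConfig, cohort: Cohort) -> TestSet:
    group = cohort.sheet.group_labels[config.tpr_target_sample]
    ts = TestSet(
        positions={e for e in config.testset.positions if e[2] == group},
        provenance=dict(config.testset.provenance),
    )
    return ts


def evaluate_cohort(
    cohort: Cohort,
    params: FilterParams,
    config: EvaluationConfig,
    label: str = "",
) -> EvaluationResult:
    """One full evaluation: FPR on all samples, TPR via the genotype protocol."""
    # FPR: run on the complete sample set, count control calls
    all_calls = call_cohort(cohort, params)
    fpr_g, fpr_bp = compute_fpr(all_calls, config)
    n_controls_calls = int(round(fpr_g * len(config.negative_control_ids)))

    # TPR: target + other-genotype clones only
    proto_ids = _tpr_protocol_samples(cohort, config.tpr_target_sample)
    sub = cohort.subset(proto_ids)
    tpr_calls = call_cohort(sub, params)
    ts = _target_testset(config, cohort)
    if len(ts) == 0:
        raise ValueError("test set has no positions for the target's group")
    tpr_cfg = EvaluationConfig(
        testset=ts,
        negative_control_ids=config.negative_control_ids,
        tpr_target_sample=config.tpr_target_sample,
        genome_size_bp=config.genome_size_bp,
    )
    tpr = compute_tpr(tpr_calls, tpr_cfg)
    n_target = sum(
        1 for c in tpr_calls if c.sample_id == config.tpr_target_sample
    )
    return EvaluationResult(
        tpr=tpr,
        fpr_per_genome=fpr_g,
        fpr_per_bp=fpr_bp,
        calls_in_controls=n_controls_calls,
        calls_in_target=n_target,
        testset_size=len(ts),
        label=label,
    )


def subset_experiment(
    cohort: Cohort,
    params: FilterParams,
    config: EvaluationConfig,
) -> List[EvaluationResult]:
    """Evaluate on ``replicates`` random sample subsets of size n_subset.

    Controls and the TPR target are always retained; remaining slots are
    drawn without replacement, seeded.
    """
    if config.n_subset is None:
        raise ValueError("n_subset must be set")
    sheet = cohort.sheet
    keep_always = list(
        dict.fromkeys(config.negative_control_ids + [config.tpr_target_sample])
    )
    pool = [s for s in sheet.sample_ids if s not in keep_always]
    n_extra = config.n_subset - len(keep_always)
    if n_extra < 0:
        raise ValueError("n_subset smaller than the retained control/target set")
    if n_extra > len(pool):
        raise ValueError("n_subset exceeds available samples")
    results = []
    for rep in range(config.replicates):
        rng = np.random.default_rng(config.seed + rep)
        extra = list(rng.choice(pool, size=n_extra, replace=False))
        chosen = [s for s in sheet.sample_ids if s in set(keep_always) | set(extra)]
        sub = cohort.subset(chosen)
        results.append(
            evaluate_cohort(sub, params, config, label=f"n={config.n_subset} rep={rep}")
        )
    return results


def downsample_experiment(
    cohort: Cohort,
    params: FilterParams,
    config: EvaluationConfig,
) -> List[EvaluationResult]:
    """Evaluate with the target sample's coverage thinned by ds_factor."""
    if config.ds_factor is None:
        raise ValueError("ds_factor must be set")
    results = []
    for rep in range(config.replicates):
        rng = np.random.default_rng(config.seed + rep)
        thinned = (
            cohort
            if config.ds_factor == 1.0
            else cohort.thin_sample(config.tpr_target_sample, config.ds_factor, rng)
        )
        results.append(
            evaluate_cohort(
                thinned, params, config, label=f"ds={config.ds_factor} rep={rep}"
            )
        )
    return results


def summarize(results: Sequence[EvaluationResult]) -> Dict[str, float]:
    """Mean and standard deviation of TPR and FPR across replicates."""
    tprs = np.array([r.tpr for r in results], dtype=float)
    fprs = np.array([r.fpr_per_genome for r in results], dtype=float)
    return {
        "tpr_mean": float(tprs.mean()),
        "tpr_sd": float(tprs.std(ddof=1)) if len(tprs) > 1 else 0.0,
        "fpr_per_genome_mean": float(fprs.mean()),
        "fpr_per_genome_sd": float(fprs.std(ddof=1)) if len(fprs) > 1 else 0.0,
        "n": len(results),
    }


def write_results(results: Sequence[EvaluationResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "label\ttpr\tfpr_per_genome\tfpr_per_bp\tcalls_in_controls\t"
            "calls_in_target\ttestset_size\n"
        )
        for r in results:
            fh.write(
                f"{r.label}\t{r.tpr:.6g}\t{r.fpr_per_genome:.6g}\t"
                f"{r.fpr_per_bp:.6g}\t{r.calls_in_controls}\t"
                f"{r.calls_in_target}\t{r.testset_size}\n"
            )
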