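"""Shared domain types.

The whole package works at the level of per-position, per-sample allele
counts extracted from a joint (multi-sample) pileup.  A
:class:`SampleObservation` holds the quality-filtered read evidence of one
sample at one position; a :class:`PositionPileup` lines up one observation
per sample, in sample-sheet order; a :class:`MutationCall` is one accepted
sample-unique mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

BASES = ("A", "C", "G", "T")

SNV = "SNV"
INS = "INS"
DEL = "DEL"
MUT_TYPES = (SNV, INS, DEL)


@dataclass
class SampleObservation:
    """Read evidence of a single sample at a single genomic position.

    ``coverage`` is the quality-filtered read depth (the pileup depth
    column); gap placeholders (``*``) and reference skips contribute to
    coverage but to no allele count.  Indel annotations ride on anchor
    reads, so a read supporting an insertion or deletion is also counted
    in ``ref_count`` when its anchor base matches the reference.
    """

    coverage: int = 0
    ref_count: int = 0
    base_counts: Dict[str, int] = field(default_factory=dict)
    insertion_counts: Dict[str, int] = field(default_factory=dict)
    deletion_counts: Dict[str, int] = field(default_factory=dict)

    def indel_support(self) -> int:
        """Total number of reads carrying an insertion or deletion."""
        return sum(self.insertion_counts.values()) + sum(self.deletion_counts.values())

    def effective_ref_count(self) -> int:
        """Reference-supporting reads, excluding indel anchors.

        A read annotated with ``+n<seq>``/``-n<seq>`` matches the reference
        at the anchor base but is evidence for the indel, not for the
        reference haplotype.
        """
        return max(self.ref_count - self.indel_support(), 0)

    def is_empty(self) -> bool:
        return self.coverage == 0


@dataclass
class PositionPileup:
    """One genomic position across all samples (sample-sheet order)."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    observations: List[SampleObservation]


@dataclass
class SampleSheet:
    """Sample identities, group (genotype) labels and negative-control flags."""

    sample_ids: List[str]
    group_labels: Dict[str, str]
    control_flags: Dict[str, bool]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        missing = [s for s in self.sample_ids if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        for s in self.sample_ids:
            self.control_flags.setdefault(s, False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def controls(self) -> List[str]:
        return [s for s in self.sample_ids if self.control_flags[s]]

    def group_members(self, group: str) -> List[str]:
        members = [s for s in self.sample_ids if self.group_labels[s] == group]
        if not members:
            raise ValueError(f"unknown group: {group!r}")
        return members

    def groups(self) -> List[str]:
        seen: List[str] = []
        for s in self.sample_ids:
            g = self.group_labels[s]
            if g not in seen:
                seen.append(g)
        return seen

    def subset(self, sample_ids: List[str]) -> "SampleSheet":
        return SampleSheet(
            sample_ids=list(sample_ids),
            group_labels={s: self.group_labels[s] for s in sample_ids},
            control_flags={s: self.control_flags[s] for s in sample_ids},
        )


@dataclass
class FilterParams:
    """The three core thresholds plus optional per-type S-score cut-offs.

    Defaults are the published operating point for low-FPR calling without
    S tuning: minimum mutant-allele fraction 0.21 in the candidate sample,
    minimum reference fraction 0.93 in the noisiest other sample, and a
    candidate coverage floor of 5 reads.  All comparisons are inclusive.
    """

    sample_mut_freq_min: float = 0.21
    other_rnf_min: float = 0.93
    sample_cov_min: int = 5
    s_min_snv: Optional[float] = None
    s_min_ins: Optional[float] = None
    s_min_del: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sample_mut_freq_min <= 1.0:
            raise ValueError("sample_mut_freq_min must be in [0, 1]")
        if not 0.0 <= self.other_rnf_min <= 1.0:
            raise ValueError("other_rnf_min must be in [0, 1]")
        if self.sample_cov_min < 1:
            raise ValueError("sample_cov_min must be >= 1")
        for v in (self.s_min_snv, self.s_min_ins, self.s_min_del):
            if v is not None and v < 0:
                raise ValueError("S thresholds must be >= 0")

    def s_min(self, mut_type: str) -> Optional[float]:
        return {SNV: self.s_min_snv, INS: self.s_min_ins, DEL: self.s_min_del}[mut_type]

    def replace(self, **kwargs) -> "FilterParams":
        d = dict(
            sample_mut_freq_min=self.sample_mut_freq_min,
            other_rnf_min=self.other_rnf_min,
            sample_cov_min=self.sample_cov_min,
            s_min_snv=self.s_min_snv,
            s_min_ins=self.s_min_ins,
            s_min_del=self.s_min_del,
        )
        d.update(kwargs)
        return FilterParams(**d)


@dataclass
class MutationCall:
    """A sample-unique mutation accepted by all filters."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    mut_type: str  # SNV | INS | DEL
    ref_allele: str
    alt_allele: str
    coverage: int
    sample_mut_freq: float
    cleanest_other_rnf: float
    s_score: float

    def sort_key(self):
        return (self.chrom, self.pos, self.sample_id)
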