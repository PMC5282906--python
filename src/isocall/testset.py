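"""High-confidence test sets from mean reference-fraction clustering.

When two related sample groups (genotypes) are available, positions
carrying a heterozygous variant specific to one group separate cleanly in
the plane of per-group mean reference nucleotide frequency (rnf): a
group-B-specific het SNP sits near (mean_A, mean_B) = (1.0, 0.5), a
group-A-specific one near (0.5, 1.0), germline SNPs near (0.5, 0.5), and
clean reference positions at (1.0, 1.0).  Restricting to disomic
chromosomes keeps het variants at ~50% allele fraction; regions of higher
ploidy produce clusters near (1.0, ~0.7) that a rectangle of half-width
< 0.2 around (1.0, 0.5) excludes by construction.  Positions selected this
way serve as validated genotype-specific heterozygous reference sets for
measuring a caller's true positive rate.

The same machinery builds indel test sets, with the fraction of reads not
supporting an indel taking the place of rnf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .caller import rnf
from .model import PositionPileup, SampleSheet
from .simulate import Cohort


@dataclass
class RnfPoint:
    chrom: str
    pos: int
    mean_rnf_group_a: float
    mean_rnf_group_b: float


@dataclass
class TestSet:
    """Validated group-specific heterozygous positions.

    ``positions`` holds (chrom, pos, expected_group) triples; every entry
    is heterozygous by construction.  ``provenance`` records the rectangle
    bounds and groups used.
    """

    __test__ = False  # not a pytest class despite the name

    positions: Set[Tuple[str, int, str]] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)

    def for_group(self, group: str) -> Set[Tuple[str, int]]:
        return {(c, p) for c, p, g in self.positions if g == group}

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, pos, group in sorted(self.positions):
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{group}\theterozygous\n")

    @classmethod
    def read_bed(cls, path: str) -> "TestSet":
        ts = cls()
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) >= 4:
                    ts.positions.add((f[0], int(f[2]), f[3]))
        return ts


def _group_mean(values: List[float]) -> Optional[float]:
    return sum(values) / len(values) if values else None


def mean_rnf(
    positions: Iterable[PositionPileup],
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    min_covered: Optional[int] = None,
    indel_mode: bool = False,
) -> Iterator[RnfPoint]:
    """Per-position mean rnf of each group, over covered samples only.

    Positions where either group has fewer than ``min_covered`` covered
    samples (default: every member covered) are dropped — a mean over very
    few samples is unstable.  In ``indel_mode`` the per-sample fraction of
    reads not supporting an indel replaces rnf.
    """
    idx_a = [sheet.index(s) for s in sheet.group_members(group_a)]
    idx_b = [sheet.index(s) for s in sheet.group_members(group_b)]
    need_a = len(idx_a) if min_covered is None else min(min_covered, len(idx_a))
    need_b = len(idx_b) if min_covered is None else min(min_covered, len(idx_b))

    def frac(obs) -> float:
        if indel_mode:
            return 1.0 - obs.indel_support() / obs.coverage
        return rnf(obs)

    for p in positions:
        vals_a = [frac(p.observations[i]) for i in idx_a if p.observations[i].coverage > 0]
        vals_b = [frac(p.observations[i]) for i in idx_b if p.observations[i].coverage > 0]
        if len(vals_a) < need_a or len(vals_b) < need_b:
            continue
        yield RnfPoint(p.chrom, p.pos, _group_mean(vals_a), _group_mean(vals_b))


def select_clusters(
    points: Iterable[RnfPoint],
    disomic: Sequence[str],
    rect_half_width: float = 0.1,
    group_a: str = "A",
    group_b: str = "B",
) -> TestSet:
    """Select the two genotype-specific heterozygous clusters.

    A point inside the square of half-width ``rect_half_width`` centred at
    (1.0, 0.5) is a group-B-specific het position (group A reads all
    reference, group B at ~50%); the square at (0.5, 1.0) selects group-A-
    specific positions.  Only positions on ``disomic`` chromosomes are
    eligible.  Half-widths >= 0.25 would let the squares touch germline
    (0.5, 0.5) or higher-ploidy (~0.7) clusters, so they are rejected.
    """
    if not 0 < rect_half_width < 0.25:
        raise ValueError("rect_half_width must be in (0, 0.25)")
    if not disomic:
        raise ValueError("disomic chromosome list must be non-empty")
    dis = set(disomic)
    ts = TestSet(
        provenance={
            "rect_half_width": rect_half_width,
            "centres": {group_b: (1.0, 0.5), group_a: (0.5, 1.0)},
            "groups": (group_a, group_b),
        }
    )
    w = rect_half_width
    for pt in points:
        if pt.chrom not in dis:
            continue
        a, b = pt.mean_rnf_group_a, pt.mean_rnf_group_b
        if abs(a - 1.0) <= w and abs(b - 0.5) <= w:
            ts.positions.add((pt.chrom, pt.pos, group_b))
        elif abs(a - 0.5) <= w and abs(b - 1.0) <= w:
            ts.positions.add((pt.chrom, pt.pos, group_a))
    return ts


def build_snv_testset(
    positions: Iterable[PositionPileup],
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    disomic: Sequence[str],
    rect_half_width: float = 0.1,
    min_covered: Optional[int] = None,
) -> TestSet:
    pts = mean_rnf(positions, sheet, group_a, group_b, min_covered=min_covered)
    return select_clusters(pts, disomic, rect_half_width, group_a, group_b)


def build_indel_testset(
    positions: Iterable[PositionPileup],
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    disomic: Sequence[str],
    rect_half_width: float = 0.1,
    min_covered: Optional[int] = None,
) -> TestSet:
    """Indel analogue: cluster on the fraction of reads without the indel."""
    pts = mean_rnf(
        positions, sheet, group_a, group_b, min_covered=min_covered, indel_mode=True
    )
    return select_clusters(pts, disomic, rect_half_width, group_a, group_b)


def cohort_rnf_points(
    cohort: Cohort,
    group_a: str,
    group_b: str,
    indel_mode: bool = False,
) -> List[RnfPoint]:
    """Vectorized mean-rnf computation for a simulated cohort.

    Only positions carrying at least one non-reference read anywhere can
    leave (1.0, 1.0), so the dense per-position pass is restricted to the
    cohort's event positions; agreement with the streaming
    :func:`mean_rnf` is covered by tests.  Positions with an uncovered
    sample in either group are dropped (the default streaming policy).
    """
    sheet = cohort.sheet
    idx_a = np.array([sheet.index(s) for s in sheet.group_members(group_a)])
    idx_b = np.array([sheet.index(s) for s in sheet.group_members(group_b)])
    ev = cohort.events
    if indel_mode:
        ev = ev[ev["kind"].isin(["INS", "DEL"])]
    if not len(ev):
        return []
    cand = np.unique(ev["pos"].to_numpy())
    # per (pos, sample) total non-reference (or indel-supporting) read count
    nonref = ev.groupby(["pos", "sample"], as_index=False)["count"].sum()
    lookup = np.zeros((len(cand), cohort.n_samples), dtype=np.int64)
    rows = np.searchsorted(cand, nonref["pos"].to_numpy())
    np.add.at(lookup, (rows, nonref["sample"].to_numpy()), nonref["count"].to_numpy())

    cov = cohort.cov[cand].astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - np.where(cov > 0, lookup / cov, 0.0)
    keep = (cov[:, idx_a] > 0).all(axis=1) & (cov[:, idx_b] > 0).all(axis=1)
    mean_a = frac[:, idx_a].mean(axis=1)
    mean_b = frac[:, idx_b].mean(axis=1)

    bounds = np.cumsum(cohort.config.chrom_lengths)
    chrom_idx = np.searchsorted(bounds, cand, side="right")
    starts = np.concatenate(([0], bounds[:-1]))
    local_pos = cand - starts[chrom_idx] + 1
    names = cohort.config.chrom_names
    return [
        RnfPoint(names[c], int(p), float(a), float(b))
        for c, p, a, b, k in zip(chrom_idx, local_pos, mean_a, mean_b, keep)
        if k
    ]


def plot_rnf_scatter(points: Iterable[RnfPoint], path: str, rect_half_width: float = 0.1) -> None:
    """Scatter of group means with the two selection rectangles, for visual QC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    pts = list(points)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        [p.mean_rnf_group_a for p in pts],
        [p.mean_rnf_group_b for p in pts],
        s=6,
        alpha=0.5,
    )
    w = rect_half_width
    for cx, cy in ((1.0, 0.5), (0.5, 1.0)):
        ax.add_patch(
            Rectangle(
                (cx - w, cy - w), 2 * w, 2 * w, fill=False, ls="--", ec="red"
            )
        )
    ax.set_xlabel("mean rnf, group A")
    ax.set_ylabel("mean rnf, group B")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
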