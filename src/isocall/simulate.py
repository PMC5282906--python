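"""Synthetic isogenic sequencing cohorts with known truth.

The generator emulates the structure of a clone-sequencing mutagenesis
experiment: a set of essentially identical starting cells gives rise to N
single-cell clones, which share all germline variation (shared SNPs),
split into genotype groups that differ by group-specific heterozygous
SNPs/indels, and each independently accumulate sample-unique heterozygous
somatic mutations.  Alignment noise is modelled as hotspots: positions
where a correlated fraction of reads is non-reference in several samples
at once — exactly the artefact class the cross-sample filter exists to
remove.

Simulation happens at the pileup-count level: per sample and position,
coverage is Poisson, mutant-read counts are Binomial(coverage, allele
fraction), and sequencing errors are Binomial(coverage, error rate) spread
uniformly over the three non-reference bases.  Heterozygous allele
fraction is 0.5 on disomic chromosomes and 1/3 on chromosomes flagged
non-disomic (one mutated copy of three).

The result is an in-memory :class:`Cohort` (coverage matrix + sparse event
table + sample sheet + truth table) that can stream
:class:`~isocall.model.PositionPileup` objects or be written out as joint
pileup text for small genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DEL, INS, SNV, PositionPileup, SampleObservation, SampleSheet
from .pileup import write_joint_pileup

_BASES = np.array(["A", "C", "G", "T"])

TRUTH_COLUMNS = ["chrom", "pos", "class", "owner", "mut_type", "ref", "alt", "allele"]


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic cohort.

    Defaults mirror a 30-clone, ~20x whole-genome design: two genotype
    groups of equal size, one untreated starting clone per group (negative
    control, no unique mutations), shared germline het SNPs, group-specific
    het SNPs, per-sample unique het SNVs and indels at allele fraction 0.5,
    and cross-sample noise hotspots.
    """

    chrom_names: Tuple[str, ...] = ("chr1", "chr2")
    chrom_lengths: Tuple[int, ...] = (90_000, 10_000)
    disomic: Tuple[bool, ...] = (True, False)
    n_samples: int = 30
    sample_ids: Optional[Tuple[str, ...]] = None
    group_names: Tuple[str, ...] = ("WT", "MUT")
    group_assignment: Optional[Dict[str, str]] = None
    coverage_mean: float = 20.0
    sequencing_error_rate: float = 1e-3
    n_shared_snps: int = 200
    n_group_snps: int = 100
    n_group_indels: int = 0
    n_unique_per_sample: int = 50
    n_unique_indels_per_sample: int = 10
    indel_length_range: Tuple[int, int] = (1, 3)
    n_noise_hotspots: int = 50
    hotspot_fraction_range: Tuple[float, float] = (0.2, 0.5)
    het_allele_fraction: float = 0.5
    starting_clones: Optional[Tuple[str, ...]] = None
    identical_pairs: Tuple[Tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.chrom_names) == len(self.chrom_lengths) == len(self.disomic)):
            raise ValueError("chrom_names, chrom_lengths and disomic must align")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.sample_ids is None:
            width = max(2, len(str(self.n_samples)))
            self.sample_ids = tuple(
                f"S{k + 1:0{width}d}" for k in range(self.n_samples)
            )
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length must equal n_samples")
        if self.group_assignment is None:
            half = (self.n_samples + 1) // 2
            self.group_assignment = {
                s: (self.group_names[0] if k < half else self.group_names[-1])
                for k, s in enumerate(self.sample_ids)
            }
        if self.starting_clones is None:
            firsts = {}
            for s in self.sample_ids:
                firsts.setdefault(self.group_assignment[s], s)
            self.starting_clones = tuple(firsts.values())
        lo, hi = self.indel_length_range
        if not (1 <= lo <= hi):
            raise ValueError("indel_length_range must satisfy 1 <= lo <= hi")
        for src, dup in self.identical_pairs:
            if self.group_assignment[src] != self.group_assignment[dup]:
                raise ValueError("identical-pair members must share a group")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def make_sheet(self) -> SampleSheet:
        controls = set(self.starting_clones)
        for src, dup in self.identical_pairs:
            controls.update((src, dup))
        return SampleSheet(
            sample_ids=list(self.sample_ids),
            group_labels=dict(self.group_assignment),
            control_flags={s: s in controls for s in self.sample_ids},
        )


def plant_identical_pair(
    config: SimConfig,
    source_id: Optional[str] = None,
    duplicate_id: Optional[str] = None,
) -> SimConfig:
    """Turn two samples into an identical pair (same DNA prep sequenced twice).

    The duplicate loses any unique mutations of its own and instead carries
    independent read-level re-draws of every event planted in the source.
    Both members are flagged as negative controls: a mutation present in
    the shared preparation can never be unique to one member, so any
    sample-unique call in either is a false positive.
    """
    ids = list(config.sample_ids)
    if source_id is None or duplicate_id is None:
        group = config.group_assignment[ids[-1]]
        members = [s for s in ids if config.group_assignment[s] == group]
        source_id, duplicate_id = members[-2], members[-1]
    if source_id == duplicate_id:
        raise ValueError("pair members must differ")
    return replace(
        config,
        identical_pairs=config.identical_pairs + ((source_id, duplicate_id),),
    )


def _ref_base_idx(pos_idx: np.ndarray) -> np.ndarray:
    """Deterministic pseudo-random reference base per global position."""
    h = (np.asarray(pos_idx, dtype=np.uint64) * np.uint64(2654435761)) & np.uint64(
        0xFFFFFFFF
    )
    return ((h >> np.uint64(13)) & np.uint64(3)).astype(np.int64)


class Cohort:
    """A simulated cohort: coverage matrix, sparse events, sheet, truth.

    ``cov`` is an (n_positions, n_samples) int array; ``events`` is a
    DataFrame with columns pos (global 0-based index), sample (column
    index), kind (SNV/INS/DEL), allele, count — every non-reference read
    in the cohort appears here.
    """

    def __init__(
        self,
        config: SimConfig,
        sheet: SampleSheet,
        cov: np.ndarray,
        events: pd.DataFrame,
        truth: pd.DataFrame,
    ) -> None:
        self.config = config
        self.sheet = sheet
        self.cov = cov
        self.events = events.reset_index(drop=True)
        self.truth = truth.reset_index(drop=True)
        self._bounds = np.cumsum(config.chrom_lengths)
        self._events_by_pos: Optional[Dict[int, pd.DataFrame]] = None

    # -- coordinates -------------------------------------------------------
    @property
    def n_positions(self) -> int:
        return int(self.cov.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.cov.shape[1])

    @property
    def genome_size(self) -> int:
        return self.n_positions

    def locate(self, pos_idx: int) -> Tuple[str, int]:
        """Global 0-based index -> (chrom, 1-based position)."""
        c = int(np.searchsorted(self._bounds, pos_idx, side="right"))
        start = 0 if c == 0 else int(self._bounds[c - 1])
        return self.config.chrom_names[c], pos_idx - start + 1

    def global_index(self, chrom: str, pos: int) -> int:
        c = self.config.chrom_names.index(chrom)
        start = 0 if c == 0 else int(self._bounds[c - 1])
        return start + pos - 1

    def ref_base(self, pos_idx: int) -> str:
        return str(_BASES[int(_ref_base_idx(np.array([pos_idx]))[0])])

    def is_disomic(self, chrom: str) -> bool:
        return self.config.disomic[self.config.chrom_names.index(chrom)]

    # -- pileup views ------------------------------------------------------
    def _grouped_events(self) -> Dict[int, pd.DataFrame]:
        if self._events_by_pos is None:
            self._events_by_pos = {
                int(p): g for p, g in self.events.groupby("pos", sort=True)
            }
        return self._events_by_pos

    def position_pileup(
        self, pos_idx: int, sample_indices: Optional[Sequence[int]] = None
    ) -> PositionPileup:
        chrom, pos = self.locate(pos_idx)
        ref = self.ref_base(pos_idx)
        if sample_indices is None:
            sample_indices = range(self.n_samples)
        rows = self._grouped_events().get(pos_idx)
        per_sample: Dict[int, List[Tuple[str, str, int]]] = {}
        if rows is not None:
            for s, kind, allele, count in zip(
                rows["sample"], rows["kind"], rows["allele"], rows["count"]
            ):
                per_sample.setdefault(int(s), []).append((kind, allele, int(count)))
        observations = []
        for s in sample_indices:
            c = int(self.cov[pos_idx, s])
            obs = SampleObservation(coverage=c, ref_count=c)
            for kind, allele, count in per_sample.get(int(s), ()):
                if kind == SNV:
                    obs.base_counts[allele] = obs.base_counts.get(allele, 0) + count
                    obs.ref_count -= count
                elif kind == INS:
                    obs.insertion_counts[allele] = (
                        obs.insertion_counts.get(allele, 0) + count
                    )
                else:
                    obs.deletion_counts[allele] = (
                        obs.deletion_counts.get(allele, 0) + count
                    )
            observations.append(obs)
        return PositionPileup(chrom=chrom, pos=pos, ref_base=ref, observations=observations)

    def iter_positions(
        self, sample_indices: Optional[Sequence[int]] = None
    ) -> Iterator[PositionPileup]:
        """Stream every genomic position (intended for small genomes)."""
        for pos_idx in range(self.n_positions):
            yield self.position_pileup(pos_idx, sample_indices)

    def write_pileup(self, path: str) -> None:
        write_joint_pileup(self.iter_positions(), path)

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    # -- truth helpers -----------------------------------------------------
    def unique_truth(self) -> pd.DataFrame:
        """Planted events that are genuinely unique to one sample.

        Events duplicated into an identical-pair member are excluded: they
        exist in two samples and the caller must not report them.
        """
        paired = {s for pair in self.config.identical_pairs for s in pair}
        t = self.truth
        mask = t["class"].str.startswith("unique_") & ~t["owner"].isin(paired)
        return t[mask]

    # -- derived cohorts ---------------------------------------------------
    def subset(self, sample_ids: Sequence[str]) -> "Cohort":
        idx = [self.sheet.index(s) for s in sample_ids]
        remap = {old: new for new, old in enumerate(idx)}
        ev = self.events[self.events["sample"].isin(idx)].copy()
        ev["sample"] = ev["sample"].map(remap)
        cfg = replace(
            self.config,
            n_samples=len(idx),
            sample_ids=tuple(sample_ids),
            group_assignment={s: self.sheet.group_labels[s] for s in sample_ids},
            starting_clones=tuple(
                s for s in self.config.starting_clones if s in sample_ids
            ),
            identical_pairs=tuple(
                p
                for p in self.config.identical_pairs
                if p[0] in sample_ids and p[1] in sample_ids
            ),
        )
        return Cohort(cfg, self.sheet.subset(list(sample_ids)), self.cov[:, idx], ev, self.truth)

    def thin_sample(self, sample_id: str, ds_factor: float, rng: np.random.Generator) -> "Cohort":
        """Binomially down-sample one sample's reads by ``ds_factor``.

        Each read is kept independently with probability ``ds_factor``, so
        mutant counts become Binomial(count, ds) and coverage shrinks
        consistently — the count-level equivalent of read down-sampling.
        """
        if not 0 < ds_factor <= 1:
            raise ValueError("ds_factor must be in (0, 1]")
        s = self.sheet.index(sample_id)
        ev = self.events.copy()
        mask = ev["sample"].to_numpy() == s
        old_alt = ev.loc[mask, "count"].to_numpy()
        new_alt = rng.binomial(old_alt, ds_factor)
        ev.loc[mask, "count"] = new_alt
        # per-position totals before/after thinning
        pos_of = ev.loc[mask, "pos"].to_numpy()
        tot_old = np.zeros(self.n_positions, dtype=np.int64)
        np.add.at(tot_old, pos_of, old_alt)
        tot_new = np.zeros(self.n_positions, dtype=np.int64)
        np.add.at(tot_new, pos_of, new_alt)
        cov = self.cov.copy()
        ref_reads = cov[:, s].astype(np.int64) - tot_old
        cov[:, s] = (rng.binomial(ref_reads, ds_factor) + tot_new).astype(cov.dtype)
        ev = ev[ev["count"] > 0]
        return Cohort(self.config, self.sheet, cov, ev, self.truth)


def _split_evenly(total: int, n: int) -> List[int]:
    base, rem = divmod(total, n)
    return [base + (1 if k < rem else 0) for k in range(n)]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate one cohort; fully deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sheet = config.make_sheet()
    n = config.n_samples
    L = config.genome_length

    # ploidy-dependent het fraction per chromosome
    bounds = np.cumsum(config.chrom_lengths)

    def het_fraction(pos_idx: np.ndarray) -> np.ndarray:
        c = np.searchsorted(bounds, pos_idx, side="right")
        dis = np.asarray(config.disomic)[c]
        return np.where(dis, config.het_allele_fraction, 1.0 / 3.0)

    # ---- planted locus layout -------------------------------------------
    groups = sheet.groups()
    pair_dups = {dup for _, dup in config.identical_pairs}
    unique_owners = [
        s
        for s in config.sample_ids
        if s not in config.starting_clones and s not in pair_dups
    ]
    group_snp_counts = _split_evenly(config.n_group_snps, len(groups))
    group_indel_counts = _split_evenly(config.n_group_indels, len(groups))
    n_unique = len(unique_owners) * (
        config.n_unique_per_sample + config.n_unique_indels_per_sample
    )
    total = (
        config.n_shared_snps
        + sum(group_snp_counts)
        + sum(group_indel_counts)
        + n_unique
        + config.n_noise_hotspots
    )
    if total > L:
        raise ValueError(
            f"cannot place {total} planted loci on a {L} bp genome without collision"
        )
    loci = rng.choice(L, size=total, replace=False)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = loci[cursor : cursor + k]
        cursor += k
        return out

    cov = rng.poisson(config.coverage_mean, size=(L, n)).astype(np.int32)

    ev_pos: List[np.ndarray] = []
    ev_sample: List[np.ndarray] = []
    ev_kind: List[np.ndarray] = []
    ev_allele: List[np.ndarray] = []
    ev_count: List[np.ndarray] = []
    truth_rows: List[tuple] = []

    def chrom_pos(p: int) -> Tuple[str, int]:
        c = int(np.searchsorted(bounds, p, side="right"))
        start = 0 if c == 0 else int(bounds[c - 1])
        return config.chrom_names[c], p - start + 1

    def alt_base_for(pos: np.ndarray) -> np.ndarray:
        ref = _ref_base_idx(pos)
        off = rng.integers(1, 4, size=len(pos))
        return (ref + off) % 4

    def random_seq(length: int) -> str:
        return "".join(_BASES[rng.integers(0, 4, size=length)])

    def add_snv_block(
        pos: np.ndarray, sample_idx: Sequence[int], klass: str, owner_of
    ) -> None:
        """Plant het SNVs at ``pos`` in every sample of ``sample_idx``."""
        alt_idx = alt_base_for(pos)
        f = het_fraction(pos)
        counts = rng.binomial(
            cov[np.ix_(pos, list(sample_idx))], f[:, None]
        )  # (n_loci, n_members)
        for j, p in enumerate(pos):
            chrom, cpos = chrom_pos(int(p))
            ref_b = str(_BASES[_ref_base_idx(np.array([p]))[0]])
            alt_b = str(_BASES[alt_idx[j]])
            for m, s in enumerate(sample_idx):
                c = int(counts[j, m])
                if c > 0:
                    ev_pos.append(np.array([p]))
                    ev_sample.append(np.array([s]))
                    ev_kind.append(np.array([SNV]))
                    ev_allele.append(np.array([alt_b]))
                    ev_count.append(np.array([c]))
            truth_rows.append(
                (chrom, cpos, klass, owner_of, SNV, ref_b, alt_b, alt_b)
            )

    # shared germline SNPs: heterozygous in every sample
    shared_pos = take(config.n_shared_snps)
    if len(shared_pos):
        add_snv_block(shared_pos, list(range(n)), "shared_snp", "all")

    # group-specific het SNPs / indels
    group_snp_pos: Dict[str, np.ndarray] = {}
    for g, k_snp, k_indel in zip(groups, group_snp_counts, group_indel_counts):
        members = [sheet.index(s) for s in sheet.group_members(g)]
        pos_g = take(k_snp)
        group_snp_pos[g] = pos_g
        if len(pos_g):
            add_snv_block(pos_g, members, "group_snp", g)
        for p in take(k_indel):
            chrom, cpos = chrom_pos(int(p))
            ref_b = str(_BASES[_ref_base_idx(np.array([p]))[0]])
            kind = INS if rng.random() < 0.5 else DEL
            seq = random_seq(int(rng.integers(*config.indel_length_range, endpoint=True)))
            f = float(het_fraction(np.array([p]))[0])
            counts = rng.binomial(cov[p, members], f)
            for m, s in enumerate(members):
                c = int(counts[m])
                if c > 0:
                    ev_pos.append(np.array([int(p)]))
                    ev_sample.append(np.array([s]))
                    ev_kind.append(np.array([kind]))
                    ev_allele.append(np.array([seq]))
                    ev_count.append(np.array([c]))
            klass = "group_ins" if kind == INS else "group_del"
            ref_a = ref_b if kind == INS else ref_b + seq
            alt_a = ref_b + seq if kind == INS else ref_b
            truth_rows.append((chrom, cpos, klass, g, kind, ref_a, alt_a, seq))

    # per-sample unique het SNVs and indels
    unique_events_of: Dict[str, List[tuple]] = {s: [] for s in unique_owners}
    for sid in unique_owners:
        s = sheet.index(sid)
        pos_u = take(config.n_unique_per_sample)
        if len(pos_u):
            alt_idx = alt_base_for(pos_u)
            f = het_fraction(pos_u)
            counts = rng.binomial(cov[pos_u, s], f)
            for j, p in enumerate(pos_u):
                chrom, cpos = chrom_pos(int(p))
                ref_b = str(_BASES[_ref_base_idx(np.array([p]))[0]])
                alt_b = str(_BASES[alt_idx[j]])
                c = int(counts[j])
                if c > 0:
                    ev_pos.append(np.array([int(p)]))
                    ev_sample.append(np.array([s]))
                    ev_kind.append(np.array([SNV]))
                    ev_allele.append(np.array([alt_b]))
                    ev_count.append(np.array([c]))
                truth_rows.append(
                    (chrom, cpos, "unique_snv", sid, SNV, ref_b, alt_b, alt_b)
                )
                unique_events_of[sid].append((int(p), SNV, alt_b, ref_b))
        for p in take(config.n_unique_indels_per_sample):
            chrom, cpos = chrom_pos(int(p))
            ref_b = str(_BASES[_ref_base_idx(np.array([p]))[0]])
            kind = INS if rng.random() < 0.5 else DEL
            seq = random_seq(int(rng.integers(*config.indel_length_range, endpoint=True)))
            f = float(het_fraction(np.array([p]))[0])
            c = int(rng.binomial(cov[int(p), s], f))
            if c > 0:
                ev_pos.append(np.array([int(p)]))
                ev_sample.append(np.array([s]))
                ev_kind.append(np.array([kind]))
                ev_allele.append(np.array([seq]))
                ev_count.append(np.array([c]))
            klass = "unique_ins" if kind == INS else "unique_del"
            ref_a = ref_b if kind == INS else ref_b + seq
            alt_a = ref_b + seq if kind == INS else ref_b
            truth_rows.append((chrom, cpos, klass, sid, kind, ref_a, alt_a, seq))
            unique_events_of[sid].append((int(p), kind, seq, ref_b))

    # identical pairs: duplicate the source's unique events into the dup
    for src, dup in config.identical_pairs:
        d = sheet.index(dup)
        for p, kind, allele, ref_b in unique_events_of.get(src, []):
            f = float(het_fraction(np.array([p]))[0])
            c = int(rng.binomial(cov[p, d], f))
            if c > 0:
                ev_pos.append(np.array([p]))
                ev_sample.append(np.array([d]))
                ev_kind.append(np.array([kind]))
                ev_allele.append(np.array([allele]))
                ev_count.append(np.array([c]))
            chrom, cpos = chrom_pos(p)
            klass = {SNV: "unique_snv", INS: "unique_ins", DEL: "unique_del"}[kind]
            ref_a = ref_b if kind in (SNV, INS) else ref_b + allele
            alt_a = {SNV: allele, INS: ref_b + allele, DEL: ref_b}[kind]
            truth_rows.append((chrom, cpos, klass, dup, kind, ref_a, alt_a, allele))

    # noise hotspots: correlated artefact reads in >= 2 samples
    lo_f, hi_f = config.hotspot_fraction_range
    for p in take(config.n_noise_hotspots):
        k = int(rng.integers(2, n + 1))
        samples = rng.choice(n, size=k, replace=False)
        fs = rng.uniform(lo_f, hi_f, size=k)
        alt_idx = int(alt_base_for(np.array([int(p)]))[0])
        alt_b = str(_BASES[alt_idx])
        chrom, cpos = chrom_pos(int(p))
        ref_b = str(_BASES[_ref_base_idx(np.array([int(p)]))[0]])
        for s, f in zip(samples, fs):
            c_cov = int(cov[int(p), s])
            # systematic misalignment: at least 2 artefact reads when depth allows
            c = int(np.clip(rng.binomial(c_cov, f), min(2, c_cov), c_cov))
            if c > 0:
                ev_pos.append(np.array([int(p)]))
                ev_sample.append(np.array([s]))
                ev_kind.append(np.array([SNV]))
                ev_allele.append(np.array([alt_b]))
                ev_count.append(np.array([c]))
        truth_rows.append((chrom, cpos, "noise", "multi", SNV, ref_b, alt_b, alt_b))

    planted = pd.DataFrame(
        {
            "pos": np.concatenate(ev_pos) if ev_pos else np.array([], dtype=np.int64),
            "sample": np.concatenate(ev_sample) if ev_sample else np.array([], dtype=np.int64),
            "kind": np.concatenate(ev_kind) if ev_kind else np.array([], dtype=object),
            "allele": np.concatenate(ev_allele) if ev_allele else np.array([], dtype=object),
            "count": np.concatenate(ev_count) if ev_count else np.array([], dtype=np.int64),
        }
    )

    # ---- sequencing errors ----------------------------------------------
    frames = [planted]
    if config.sequencing_error_rate > 0:
        err = rng.binomial(cov, config.sequencing_error_rate)
        pos_nz, sample_nz = np.nonzero(err)
        counts_nz = err[pos_nz, sample_nz]
        # one row per error read, each with an independent non-reference base
        read_pos = np.repeat(pos_nz, counts_nz)
        read_sample = np.repeat(sample_nz, counts_nz)
        ref_idx = _ref_base_idx(read_pos)
        base_idx = (ref_idx + rng.integers(1, 4, size=len(read_pos))) % 4
        err_df = (
            pd.DataFrame(
                {
                    "pos": read_pos,
                    "sample": read_sample,
                    "allele": _BASES[base_idx],
                }
            )
            .groupby(["pos", "sample", "allele"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
        )
        err_df["kind"] = SNV
        # planted cells already consumed their read budget; errors there are
        # subsumed into the planted draw (bias O(error_rate), documented)
        if len(planted):
            key_planted = set(
                zip(planted["pos"].tolist(), planted["sample"].tolist())
            )
            keep = [
                (p, s) not in key_planted
                for p, s in zip(err_df["pos"].tolist(), err_df["sample"].tolist())
            ]
            err_df = err_df[keep]
        frames.append(err_df[["pos", "sample", "kind", "allele", "count"]])

    events = pd.concat(frames, ignore_index=True)
    if len(events):
        events = (
            events.groupby(["pos", "sample", "kind", "allele"], as_index=False)["count"]
            .sum()
            .sort_values(["pos", "sample"], kind="mergesort")
        )
    events = events.astype({"pos": np.int64, "sample": np.int64, "count": np.int64})

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chrom", "pos", "owner"], kind="mergesort")
    return Cohort(config, sheet, cov, events, truth)
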