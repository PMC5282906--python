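"""Reading and writing the samtools multi-sample pileup text dialect.

A joint pileup line is ``chrom  pos  ref`` followed by one
``depth  bases  quals`` triplet per sample, in sample-sheet order.  Base
columns use the usual mpileup encoding: ``.``/``,`` for reference matches,
base letters for mismatches, ``+n<seq>``/``-n<seq>`` for indels anchored on
the preceding read, ``^X``/``$`` for read starts/ends, ``*`` for deleted-base
placeholders and ``>``/``<`` for reference skips.  Base-quality filtering
(e.g. mpileup ``-B -Q 30``) is an upstream responsibility; the reader does
not re-filter.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import io
from typing import IO, Iterable, Iterator, List, Union

import yaml

from .model import BASES, MutationCall, PositionPileup, SampleObservation, SampleSheet

_READ_BASES = set("ACGTNacgtn")
_INDEL_CHARS = set("ACGTNacgtn")


class PileupFormatError(ValueError):
    pass


def parse_base_string(base_field: str, ref_base: str, line: int = 0) -> SampleObservation:
    """Convert one pileup base column into allele counts.

    ``coverage`` here is the number of read symbols consumed; callers that
    have the depth column available should prefer it (see
    :func:`read_joint_pileup`).
    """
    obs = SampleObservation()
    if base_field == "*":  # samtools placeholder for a zero-depth sample
        return obs
    i = 0
    n = len(base_field)
    while i < n:
        c = base_field[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupFormatError(
                    f"truncated '^' escape at line {line}, column {i + 1}"
                )
            i += 2  # '^' + mapping quality char
        elif c == "$":
            i += 1
        elif c in ".,":
            obs.ref_count += 1
            obs.coverage += 1
            i += 1
        elif c in _READ_BASES:
            b = c.upper()
            if b != "N":
                obs.base_counts[b] = obs.base_counts.get(b, 0) + 1
            obs.coverage += 1
            i += 1
        elif c in "*><":
            # gap placeholder / reference skip: depth but no allele
            obs.coverage += 1
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and base_field[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupFormatError(
                    f"indel without length at line {line}, column {i + 1}"
                )
            length = int(base_field[i + 1 : j])
            seq = base_field[j : j + length]
            if len(seq) < length or any(ch not in _INDEL_CHARS for ch in seq):
                raise PileupFormatError(
                    f"malformed indel sequence at line {line}, column {i + 1}"
                )
            seq = seq.upper()  # pool forward/reverse-strand evidence
            target = obs.insertion_counts if c == "+" else obs.deletion_counts
            target[seq] = target.get(seq, 0) + 1
            i = j + length
        else:
            raise PileupFormatError(
                f"unexpected character {c!r} at line {line}, column {i + 1}"
            )
    return obs


def render_base_string(obs: SampleObservation) -> str:
    """Render counts back into a pileup base column (inverse of parsing).

    Indel annotations are attached to the leading reference-match symbols;
    the observation must carry at least as many read symbols as indel
    events.  Used by the simulator and for round-trip testing.
    """
    symbols: List[str] = ["."] * obs.ref_count
    for b in sorted(obs.base_counts):
        symbols.extend(b * obs.base_counts[b])
    n_star = obs.coverage - len(symbols)
    if n_star < 0:
        raise ValueError("counts exceed coverage; cannot render")
    symbols.extend("*" * n_star)
    annotations: List[str] = []
    for seq in sorted(obs.insertion_counts):
        annotations.extend([f"+{len(seq)}{seq}"] * obs.insertion_counts[seq])
    for seq in sorted(obs.deletion_counts):
        annotations.extend([f"-{len(seq)}{seq}"] * obs.deletion_counts[seq])
    if len(annotations) > len(symbols):
        raise ValueError("more indel events than read symbols; cannot anchor")
    out = []
    for k, sym in enumerate(symbols):
        out.append(sym)
        if k < len(annotations):
            out.append(annotations[k])
    return "".join(out) if out else "*"


def read_joint_pileup(
    source: Union[str, IO[str], Iterable[str]], sheet: SampleSheet
) -> Iterator[PositionPileup]:
    """Stream :class:`PositionPileup` objects from a joint pileup.

    ``source`` may be a path, an open text handle or any iterable of lines.
    The depth column is authoritative for per-sample coverage; a sample
    with depth 0 yields an empty observation.
    """
    if isinstance(source, str):
        with open(source) as fh:
            yield from read_joint_pileup(fh, sheet)
        return
    n = sheet.n_samples
    for lineno, raw in enumerate(source, start=1):
        raw = raw.rstrip("\n")
        if not raw:
            continue
        fields = raw.split("\t")
        if len(fields) != 3 + 3 * n:
            raise PileupFormatError(
                f"line {lineno}: expected {3 + 3 * n} columns for "
                f"{n} samples, got {len(fields)}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        pos = int(pos_s)
        if pos < 1:
            raise PileupFormatError(f"line {lineno}: position must be >= 1")
        observations = []
        for k in range(n):
            depth = int(fields[3 + 3 * k])
            if depth == 0:
                observations.append(SampleObservation())
                continue
            obs = parse_base_string(fields[4 + 3 * k], ref.upper(), line=lineno)
            obs.coverage = depth  # depth column is authoritative
            observations.append(obs)
        yield PositionPileup(chrom=chrom, pos=pos, ref_base=ref.upper(), observations=observations)


def write_joint_pileup(
    positions: Iterable[PositionPileup], destination: Union[str, IO[str]]
) -> None:
    """Write positions as joint pileup text (qualities rendered as 'I')."""
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            write_joint_pileup(positions, fh)
        return
    for p in positions:
        fields = [p.chrom, str(p.pos), p.ref_base]
        for obs in p.observations:
            if obs.coverage == 0:
                fields.extend(["0", "*", "*"])
            else:
                fields.extend(
                    [str(obs.coverage), render_base_string(obs), "I" * obs.coverage]
                )
        destination.write("\t".join(fields) + "\n")


CALL_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "type",
    "ref",
    "alt",
    "coverage",
    "sample_mut_freq",
    "cleanest_other_rnf",
    "s_score",
]


def write_calls(calls: List[MutationCall], destination: Union[str, IO[str]]) -> None:
    """Write a tab-separated mutation table, sorted by (chrom, pos, sample)."""
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            write_calls(calls, fh)
        return
    destination.write("\t".join(CALL_COLUMNS) + "\n")
    for c in sorted(calls, key=lambda c: c.sort_key()):
        destination.write(
            "\t".join(
                [
                    c.sample_id,
                    c.chrom,
                    str(c.pos),
                    c.mut_type,
                    c.ref_allele,
                    c.alt_allele,
                    str(c.coverage),
                    f"{c.sample_mut_freq:.6g}",
                    f"{c.cleanest_other_rnf:.6g}",
                    f"{c.s_score:.6g}",
                ]
            )
            + "\n"
        )


def read_calls(source: Union[str, IO[str]]) -> List[MutationCall]:
    if isinstance(source, str):
        with open(source) as fh:
            return read_calls(fh)
    header = source.readline().rstrip("\n").split("\t")
    if header != CALL_COLUMNS:
        raise PileupFormatError(f"unexpected call-table header: {header}")
    calls = []
    for raw in source:
        raw = raw.rstrip("\n")
        if not raw:
            continue
        f = raw.split("\t")
        calls.append(
            MutationCall(
                sample_id=f[0],
                chrom=f[1],
                pos=int(f[2]),
                mut_type=f[3],
                ref_allele=f[4],
                alt_allele=f[5],
                coverage=int(f[6]),
                sample_mut_freq=float(f[7]),
                cleanest_other_rnf=float(f[8]),
                s_score=float(f[9]),
            )
        )
    return calls


def read_sample_sheet(path: str) -> SampleSheet:
    """Read a sample sheet from TSV (sample_id, group, is_control) or YAML."""
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        ids = [str(e["sample_id"]) for e in data["samples"]]
        return SampleSheet(
            sample_ids=ids,
            group_labels={str(e["sample_id"]): str(e["group"]) for e in data["samples"]},
            control_flags={
                str(e["sample_id"]): bool(e.get("is_control", False))
                for e in data["samples"]
            },
        )
    ids: List[str] = []
    groups = {}
    controls = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for req in ("sample_id", "group", "is_control"):
            if req not in idx:
                raise ValueError(f"sample sheet missing column {req!r}")
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            f = raw.split("\t")
            sid = f[idx["sample_id"]]
            ids.append(sid)
            groups[sid] = f[idx["group"]]
            controls[sid] = f[idx["is_control"]].strip().lower() in ("1", "true", "yes")
    return SampleSheet(sample_ids=ids, group_labels=groups, control_flags=controls)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\tis_control\n")
        for s in sheet.sample_ids:
            fh.write(
                f"{s}\t{sheet.group_labels[s]}\t{int(sheet.control_flags[s])}\n"
            )
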