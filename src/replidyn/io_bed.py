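"""Fork-call BED dialects and annotation-track I/O.

Every coordinate inside the package is 0-based, half-open; files follow the
BED convention (tab-separated, same coordinate system).

Two fork dialects are supported:

``normalized``
    The canonical 13-column interchange written by this package::

        chrom  fork_start  fork_end  read_id  read_start  read_end
        direction(L|R)  strand(+|-)  edu_start  edu_end  brdu_start
        brdu_end  stall_score

``forksense_raw``
    An adapter for the per-direction fork-call files emitted by nanopore
    analog-detection pipelines (separate leftForks/rightForks BEDs).  The
    exact column layout of those files is not standardized; the adapter
    assumes 9 columns::

        chrom  fork_start  fork_end  read_id  read_start  read_end
        strand  analog_boundary  stall_score

    where ``analog_boundary`` splits the first analog (EdU) segment from the
    second (BrdU) segment, EdU lying on the origin-proximal side: for a
    rightward fork EdU occupies [fork_start, boundary) and BrdU
    [boundary, fork_end); for a leftward fork the mirror image.  Fork
    direction is taken from the file name (``left``/``right``) or passed
    explicitly.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "ForkRecord",
    "GenomicInterval",
    "AnnotationTrack",
    "BedParseError",
    "ParseIssue",
    "NORMALIZED_COLUMNS",
    "read_fork_bed",
    "merge_fork_beds",
    "write_fork_bed",
    "fork_frame",
    "records_from_frame",
    "read_track",
    "write_track",
    "write_bed",
    "read_genome",
    "write_genome",
]

NORMALIZED_COLUMNS = [
    "chrom", "fork_start", "fork_end", "read_id", "read_start", "read_end",
    "direction", "strand", "edu_start", "edu_end", "brdu_start", "brdu_end",
    "stall_score",
]

STALL_CODES = (-1, -2, -3, -4)

TRACK_KINDS = ("chromatin_state", "timing", "genes", "peaks", "blacklist")


class BedParseError(ValueError):
    """Raised for malformed BED lines; the message names the file and line."""


@dataclass
class ParseIssue:
    line_no: int
    message: str


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self):
        return self.end - self.start


@dataclass
class ForkRecord:
    """One per-read replication-fork call with its two analog segments."""

    chrom: str
    fork_start: int
    fork_end: int
    read_id: str
    read_start: int
    read_end: int
    direction: str  # L or R (direction of fork movement)
    strand: str  # + or - (read mapping strand)
    edu_start: int
    edu_end: int
    brdu_start: int
    brdu_end: int
    stall_score: float

    @property
    def edu_length(self) -> int:
        return self.edu_end - self.edu_start

    @property
    def brdu_length(self) -> int:
        return self.brdu_end - self.brdu_start

    @property
    def read_length(self) -> int:
        return self.read_end - self.read_start

    def validate(self) -> None:
        r = self
        if not r.fork_start < r.fork_end:
            raise ValueError(f"{r.read_id}: fork_end <= fork_start")
        if r.direction not in ("L", "R"):
            raise ValueError(f"{r.read_id}: direction {r.direction!r} not in L/R")
        if r.strand not in ("+", "-"):
            raise ValueError(f"{r.read_id}: strand {r.strand!r} not in +/-")
        for name, s, e in (("edu", r.edu_start, r.edu_end), ("brdu", r.brdu_start, r.brdu_end)):
            if s > e:
                raise ValueError(f"{r.read_id}: {name} segment inverted")
            if s < r.read_start or e > r.read_end:
                raise ValueError(f"{r.read_id}: {name} segment outside read")
        # segments must not overlap
        if min(r.edu_end, r.brdu_end) > max(r.edu_start, r.brdu_start):
            raise ValueError(f"{r.read_id}: EdU and BrdU segments overlap")
        # direction fixes the genomic order of the analog segments
        if r.edu_length and r.brdu_length:
            if r.direction == "R" and r.brdu_start < r.edu_end:
                raise ValueError(f"{r.read_id}: R fork but BrdU not 3' of EdU")
            if r.direction == "L" and r.brdu_end > r.edu_start:
                raise ValueError(f"{r.read_id}: L fork but BrdU not 5' of EdU")


def _parse_normalized(parts, line_no):
    if len(parts) != 13:
        raise BedParseError(f"line {line_no}: expected 13 columns, got {len(parts)}")
    return ForkRecord(
        chrom=parts[0], fork_start=int(parts[1]), fork_end=int(parts[2]),
        read_id=parts[3], read_start=int(parts[4]), read_end=int(parts[5]),
        direction=parts[6], strand=parts[7],
        edu_start=int(parts[8]), edu_end=int(parts[9]),
        brdu_start=int(parts[10]), brdu_end=int(parts[11]),
        stall_score=float(parts[12]),
    )


def _parse_forksense_raw(parts, line_no, direction):
    if len(parts) != 9:
        raise BedParseError(f"line {line_no}: expected 9 columns, got {len(parts)}")
    fork_start, fork_end = int(parts[1]), int(parts[2])
    boundary = int(parts[7])
    if direction == "R":
        edu = (fork_start, boundary)
        brdu = (boundary, fork_end)
    else:
        brdu = (fork_start, boundary)
        edu = (boundary, fork_end)
    return ForkRecord(
        chrom=parts[0], fork_start=fork_start, fork_end=fork_end,
        read_id=parts[3], read_start=int(parts[4]), read_end=int(parts[5]),
        direction=direction, strand=parts[6],
        edu_start=edu[0], edu_end=edu[1], brdu_start=brdu[0], brdu_end=brdu[1],
        stall_score=float(parts[8]),
    )


def _infer_direction(path: str) -> str:
    base = os.path.basename(path).lower()
    if "left" in base:
        return "L"
    if "right" in base:
        return "R"
    raise BedParseError(
        f"{path}: cannot infer fork direction from file name; pass direction='L'/'R'"
    )


def read_fork_bed(path, dialect: str = "normalized", direction: str | None = None,
                  on_error: str = "raise"):
    """Read fork calls from one BED file.

    ``on_error='raise'`` raises :class:`BedParseError` at the first bad line;
    ``'collect'`` returns ``(records, issues)`` so that no input line is
    silently dropped (line count == parsed + reported issues).
    """
    if dialect not in ("normalized", "forksense_raw"):
        raise BedParseError(f"unknown dialect {dialect!r}")
    if dialect == "forksense_raw" and direction is None:
        direction = _infer_direction(str(path))
    records, issues = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if dialect == "normalized":
                    rec = _parse_normalized(parts, line_no)
                else:
                    rec = _parse_forksense_raw(parts, line_no, direction)
                rec.validate()
            except (ValueError, BedParseError) as exc:
                if on_error == "raise":
                    raise BedParseError(f"{path}: line {line_no}: {exc}") from None
                issues.append(ParseIssue(line_no, str(exc)))
                continue
            records.append(rec)
    if on_error == "collect":
        return records, issues
    return records


def merge_fork_beds(left_path, right_path, dialect: str = "forksense_raw"):
    """Merge per-direction fork files into one record list (L then R)."""
    left = read_fork_bed(left_path, dialect=dialect, direction="L")
    right = read_fork_bed(right_path, dialect=dialect, direction="R")
    return left + right


def write_fork_bed(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            vals = [getattr(r, f.name) for f in fields(ForkRecord)]
            fh.write("\t".join(str(v) for v in vals) + "\n")


def fork_frame(records) -> pd.DataFrame:
    """Tabular view of fork records with derived length columns."""
    df = pd.DataFrame([{f.name: getattr(r, f.name) for f in fields(ForkRecord)} for r in records],
                      columns=NORMALIZED_COLUMNS)
    df["edu_length"] = df["edu_end"] - df["edu_start"]
    df["brdu_length"] = df["brdu_end"] - df["brdu_start"]
    df["read_length"] = df["read_end"] - df["read_start"]
    return df


def records_from_frame(df: pd.DataFrame):
    return [ForkRecord(**{c: row[c] for c in NORMALIZED_COLUMNS}) for _, row in df.iterrows()]


@dataclass
class AnnotationTrack:
    """A typed, sorted genomic-interval annotation set.

    Payload columns by kind: chromatin_state -> ``state`` (0-9);
    timing -> ``score`` (float), ``group`` (0-3); genes -> ``name``,
    ``strand``, ``rpkm``; peaks/blacklist -> none.
    """

    kind: str
    records: pd.DataFrame

    def __post_init__(self):
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        df = self.records.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValueError(f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        if self.kind == "chromatin_state":
            if not df["state"].isin(range(10)).all():
                raise ValueError("chromatin state outside 0..9")
            df["state"] = df["state"].astype(int)
        elif self.kind == "timing":
            if not df["group"].isin(range(4)).all():
                raise ValueError("timing group outside 0..3")
            df["group"] = df["group"].astype(int)
            df["score"] = df["score"].astype(float)
        elif self.kind == "genes":
            if not df["strand"].isin(["+", "-"]).all():
                raise ValueError("gene strand not in +/-")
            if (df["rpkm"] < 0).any():
                raise ValueError("negative RPKM")
        self.records = df

    def __len__(self):
        return len(self.records)


_TRACK_COLUMNS = {
    "chromatin_state": ["chrom", "start", "end", "state"],
    "timing": ["chrom", "start", "end", "score", "group"],
    "genes": ["chrom", "start", "end", "name", "score", "strand", "rpkm"],
    "peaks": ["chrom", "start", "end"],
    "blacklist": ["chrom", "start", "end"],
}


def read_track(path, kind: str) -> AnnotationTrack:
    """Read an annotation BED of the given kind (see :class:`AnnotationTrack`)."""
    if kind not in TRACK_KINDS:
        raise ValueError(f"unknown track kind {kind!r}")
    cols = _TRACK_COLUMNS[kind]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=cols, usecols=range(len(cols)))
    if kind == "genes":
        df = df.drop(columns=["score"])
    return AnnotationTrack(kind, df)


def write_track(track: AnnotationTrack, path) -> None:
    df = track.records.copy()
    if track.kind == "genes":
        df = df[["chrom", "start", "end", "name"]].assign(
            score=0, strand=track.records["strand"], rpkm=track.records["rpkm"])
    else:
        df = df[_TRACK_COLUMNS[track.kind]]
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or list(df.columns)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_genome(path) -> dict[str, int]:
    """Read a two-column chrom-sizes file."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split()[:2]
                out[name] = int(length)
    return out


def write_genome(genome: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")
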