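"""Reference and region handling: named intervals, breakpoint clustering,
and coverage-track summarisation.

All coordinates are 0-based half-open internally; BED output is native,
and 1-based positions appear only in human-readable reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Region",
    "RegionSpec",
    "BreakpointSet",
    "SignalTrack",
    "read_fasta",
    "write_fasta",
    "make_regions",
    "cluster_breakpoints",
    "summarize_track",
    "read_breakpoints_tsv",
    "read_signal_track",
    "write_bed",
]

_VALID_STRANDS = ("plus", "minus", "both")


@dataclass(frozen=True)
class Region:
    """A named genomic interval, the unit all analyses are reported on."""

    name: str
    ref_id: str
    start: int
    end: int
    strand: str = "both"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.name!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Region") -> "Region | None":
        """Intersection with another region on the same reference, or None."""
        if self.ref_id != other.ref_id:
            raise ValueError("overlap requires regions on the same ref_id")
        start = max(self.start, other.start)
        end = min(self.end, other.end)
        if start >= end:
            return None
        return Region(f"{self.name}&{other.name}", self.ref_id, start, end)

    def union_span(self, other: "Region") -> "Region":
        """Smallest interval covering both regions (same ref_id)."""
        if self.ref_id != other.ref_id:
            raise ValueError("union requires regions on the same ref_id")
        return Region(
            f"{self.name}|{other.name}",
            self.ref_id,
            min(self.start, other.start),
            max(self.end, other.end),
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class RegionSpec:
    """Regions given as offsets from a shared anchor (e.g. a promoter TSS).

    entries: (name, offset_from_anchor, length) triples, offsets and lengths
    in nucleotides, both non-negative.
    """

    anchor_position: int
    entries: tuple[tuple[str, int, int], ...]
    ref_id: str = "ref"

    def __post_init__(self) -> None:
        for name, offset, length in self.entries:
            if offset < 0 or length <= 0:
                raise ValueError(
                    f"entry {name!r}: offset must be >= 0 and length > 0, "
                    f"got offset={offset}, length={length}"
                )


@dataclass
class BreakpointSet:
    """Observed breakpoint coordinates; duplicates allowed (several patients
    can share a site). Positions are kept sorted."""

    positions: list[int]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.positions = sorted(int(p) for p in self.positions)


@dataclass
class SignalTrack:
    """Piecewise-constant coverage signal (bedGraph / wiggle semantics)."""

    ref_id: str
    intervals: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        prev_end = None
        for start, end, value in self.intervals:
            if end <= start:
                raise ValueError(f"empty/negative interval [{start}, {end})")
            if not math.isfinite(value):
                raise ValueError(f"non-finite value {value} at [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"overlapping intervals in track {self.ref_id!r} at position {start}"
                )
            prev_end = end


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercase sequence}.

    Sequences are case-folded to upper; only A/C/G/T/N are accepted.
    Raises ValueError on an empty file, duplicate ids, or other characters.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains illegal characters {sorted(bad)} "
                "(alphabet is ACGTN)"
            )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write sequences as FASTA with fixed line width."""
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_regions(spec: RegionSpec) -> tuple[list[Region], Region]:
    """Instantiate Regions from anchored offsets.

    Each entry (name, offset, length) becomes
    [anchor + offset, anchor + offset + length). Also returns the union
    span covering all entries.
    """
    if not spec.entries:
        raise ValueError("RegionSpec has no entries")
    regions = []
    for name, offset, length in spec.entries:
        start = spec.anchor_position + offset
        if start < 0:
            raise ValueError(f"entry {name!r} yields negative start {start}")
        regions.append(Region(name, spec.ref_id, start, start + length))
    span = Region(
        "union",
        spec.ref_id,
        min(r.start for r in regions),
        max(r.end for r in regions),
    )
    return regions, span


def cluster_breakpoints(
    bps: BreakpointSet, gap_threshold: int
) -> list[tuple[int, int, int, int]]:
    """Single-linkage 1-D clustering of breakpoint positions.

    Consecutive sorted positions join one cluster iff their gap is
    <= gap_threshold. Returns (cluster_id, start, end, count) tuples
    left to right; start/end are the min/max member positions (inclusive).
    """
    if gap_threshold <= 0:
        raise ValueError("gap_threshold must be positive")
    pos = bps.positions
    if not pos:
        return []
    clusters: list[tuple[int, int, int, int]] = []
    cstart = pos[0]
    cprev = pos[0]
    count = 1
    for p in pos[1:]:
        if p - cprev <= gap_threshold:
            count += 1
        else:
            clusters.append((len(clusters), cstart, cprev, count))
            cstart = p
            count = 1
        cprev = p
    clusters.append((len(clusters), cstart, cprev, count))
    return clusters


_UNDEFINED = float("nan")


def summarize_track(track: SignalTrack, region: Region) -> tuple[float, float, float]:
    """Base-weighted (mean, max, covered_fraction) of a track over a region.

    Uncovered bases contribute nothing to the mean; a fully uncovered
    region returns (nan, nan, 0.0).
    """
    if track.ref_id != region.ref_id:
        raise ValueError(
            f"track ref {track.ref_id!r} does not match region ref {region.ref_id!r}"
        )
    covered = 0
    weighted = 0.0
    vmax = None
    for start, end, value in track.intervals:
        lo = max(start, region.start)
        hi = min(end, region.end)
        if lo >= hi:
            continue
        covered += hi - lo
        weighted += value * (hi - lo)
        vmax = value if vmax is None else max(vmax, value)
    if covered == 0:
        return (_UNDEFINED, _UNDEFINED, 0.0)
    return (weighted / covered, vmax, covered / region.length)


def read_breakpoints_tsv(path: str | Path, position_column: str = "position",
                         source_label: str | None = None) -> BreakpointSet:
    """Load breakpoints from a TSV with a header row."""
    import csv

    positions: list[int] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or position_column not in reader.fieldnames:
            raise ValueError(f"TSV {path} lacks a {position_column!r} column")
        for row in reader:
            positions.append(int(row[position_column]))
    return BreakpointSet(positions, source_label or str(path))


def read_signal_track(path: str | Path, ref_id: str | None = None) -> SignalTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) file.

    Only one reference sequence per file is supported; if ref_id is given,
    lines on other references are skipped. Intervals touching the same base
    twice are an error (silent overwrite would hide malformed input).
    """
    intervals: list[tuple[int, int, float]] = []
    track_ref: str | None = ref_id
    mode = "bedgraph"
    chrom = None
    pos = 0
    step = 1
    span = 1

    def _want(c: str) -> bool:
        return track_ref is None or c == track_ref

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
                continue
            fields = line.split()
            if mode == "fixed":
                if _want(chrom):
                    track_ref = track_ref or chrom
                    intervals.append((pos, pos + span, float(fields[0])))
                pos += step
            elif mode == "variable":
                if _want(chrom):
                    track_ref = track_ref or chrom
                    p = int(fields[0]) - 1
                    intervals.append((p, p + span, float(fields[1])))
            else:  # bedGraph: chrom start end value, 0-based half-open
                if len(fields) != 4:
                    raise ValueError(f"malformed bedGraph line: {line!r}")
                c, s, e, v = fields
                if _want(c):
                    track_ref = track_ref or c
                    intervals.append((int(s), int(e), float(v)))
    if track_ref is None:
        raise ValueError(f"no usable intervals in {path}")
    return SignalTrack(track_ref, intervals)  # overlap check in __post_init__


def write_bed(rows: Sequence[tuple], path: str | Path) -> None:
    """Write BED rows (4 or 6 columns) as tab-separated text."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
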