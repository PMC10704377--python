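"""Synthetic clone simulation with full ground truth.

Generates reference loci, bisulfite clone sets with planted single-
stranded footprints, and AID-mutagenized clone sets, so that every
pipeline stage can be tested against known truth. The generator encodes
the study design it emulates: clones derive from the top or bottom
strand; cytosines inside a planted footprint convert nearly completely
(p_ss, default 0.95) while background conversion elsewhere is sparse
(p_bg, default 0.02); sequencing error substitutes bases uniformly at a
low rate; and AID deamination is confined to single-stranded intervals.
Footprints are strand-specific: a bottom-strand footprint produces no
excess conversion on top-strand clones.

All randomness flows from a single integer seed through one
numpy Generator, so a given parameter set is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .regions import write_fasta

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_reference",
    "simulate_bisulfite_clones",
    "simulate_aid_clones",
    "evaluate_recovery",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Parameters of a simulated bisulfite experiment.

    footprints are (strand, start, end) with end exclusive; strand_mix is
    the fraction of clones drawn from the bottom strand.
    """

    ref_length: int = 600
    gc_fraction: float = 0.57
    planted_g4: list[tuple[int, str]] = field(default_factory=list)
    footprints: list[tuple[str, int, int]] = field(default_factory=list)
    footprint_informative_density: float = 0.4
    p_ss: float = 0.95
    p_bg: float = 0.02
    p_seq_err: float = 0.001
    n_clones: int = 50
    strand_mix: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_ss, self.p_bg, self.p_seq_err, self.strand_mix,
                  self.gc_fraction, self.footprint_informative_density):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for strand, start, end in self.footprints:
            if strand not in ("top", "bottom"):
                raise ValueError(f"footprint strand must be top/bottom, got {strand!r}")
            if not (0 <= start < end <= self.ref_length):
                raise ValueError(
                    f"footprint [{start}, {end}) outside [0, {self.ref_length})"
                )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_g4"] = [list(x) for x in d["planted_g4"]]
        d["footprints"] = [list(x) for x in d["footprints"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["planted_g4"] = [(int(p), str(m)) for p, m in d.get("planted_g4", [])]
        d["footprints"] = [(s, int(a), int(b)) for s, a, b in d.get("footprints", [])]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated clone set."""

    strands: dict[str, str] = field(default_factory=dict)
    converted_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    footprints: list[tuple[str, int, int]] = field(default_factory=list)
    mutations: dict[str, tuple[tuple[int, str, str], ...]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("clone_id\tstrand\tconverted_positions\tmutations\n")
            for cid in self.strands:
                conv = ",".join(map(str, self.converted_positions.get(cid, ())))
                muts = ",".join(
                    f"{p}:{r}>{a}" for p, r, a in self.mutations.get(cid, ())
                )
                fh.write(f"{cid}\t{self.strands[cid]}\t{conv}\t{muts}\n")
            for strand, start, end in self.footprints:
                fh.write(f"#footprint\t{strand}\t{start}\t{end}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        truth = cls()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("clone_id")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if fields[0] == "#footprint":
                    truth.footprints.append((fields[1], int(fields[2]), int(fields[3])))
                    continue
                cid, strand, conv, muts = fields
                truth.strands[cid] = strand
                truth.converted_positions[cid] = tuple(
                    int(x) for x in conv.split(",") if x
                )
                parsed = []
                for m in muts.split(","):
                    if not m:
                        continue
                    pos, change = m.split(":")
                    r, a = change.split(">")
                    parsed.append((int(pos), r, a))
                truth.mutations[cid] = tuple(parsed)
        return truth


def simulate_reference(params: SimParams) -> tuple[str, list[tuple[int, str]]]:
    """I.i.d. background sequence at the requested GC fraction with the
    planted motifs overwritten at their positions. Returns the sequence
    and the planted-motif coordinates.

    Inside footprint intervals the composition is skewed so that the
    informative cytosines of the footprint's strand (reference G's for a
    bottom-strand footprint, C's for a top-strand one) occur at
    ``footprint_informative_density``: R-loop-forming regions are
    G-skewed on the displaced strand, and planting a footprint over
    unskewed sequence would not resemble one.
    """
    rng = np.random.default_rng(params.seed)
    gc = params.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=params.ref_length, p=probs)
    dens = params.footprint_informative_density
    for strand, start, end in params.footprints:
        info_base = "G" if strand == "bottom" else "C"
        info_idx = "ACGT".index(info_base)
        rest = [p for i, p in enumerate(probs) if i != info_idx]
        rest_total = sum(rest)
        fp_probs = [0.0] * 4
        fp_probs[info_idx] = dens
        k = 0
        for i in range(4):
            if i != info_idx:
                fp_probs[i] = (1 - dens) * rest[k] / rest_total
                k += 1
        seq[start:end] = rng.choice(_BASES, size=end - start, p=fp_probs)
    placed: list[tuple[int, int]] = []
    for pos, motif in params.planted_g4:
        if pos < 0 or pos + len(motif) > params.ref_length:
            raise ValueError(f"planted motif at {pos} exceeds reference bounds")
        for s, e in placed:
            if pos < e and pos + len(motif) > s:
                raise ValueError(f"planted motifs overlap at {pos}")
        placed.append((pos, pos + len(motif)))
        seq[pos : pos + len(motif)] = list(motif)
    return "".join(seq), list(params.planted_g4)


def _apply_seq_errors(
    seq: np.ndarray, p_err: float, rng: np.random.Generator
) -> np.ndarray:
    if p_err <= 0:
        return seq
    hit = rng.random(seq.size) < p_err
    idx = np.flatnonzero(hit)
    for i in idx:
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(3)]
    return seq


def simulate_bisulfite_clones(
    ref: str, params: SimParams
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate bisulfite-treated clones in top-strand coordinates.

    Per clone: draw the strand of origin (bottom with probability
    strand_mix); each informative cytosine — reference C for top-strand
    clones, reference G for bottom-strand clones — converts with p_ss
    when inside a same-strand footprint, else with p_bg; sequencing error
    then substitutes uniformly. Conversions read as C->T (top) or G->A
    (bottom). Truth records every decision.
    """
    rng = np.random.default_rng(params.seed)
    ref_arr = np.array(list(ref))
    c_pos = np.flatnonzero(ref_arr == "C")
    g_pos = np.flatnonzero(ref_arr == "G")
    clones: list[tuple[str, str]] = []
    truth = SimTruth(footprints=list(params.footprints))
    for k in range(params.n_clones):
        cid = f"clone_{k:04d}"
        strand = "bottom" if rng.random() < params.strand_mix else "top"
        info = g_pos if strand == "bottom" else c_pos
        expected = "A" if strand == "bottom" else "T"
        in_fp = np.zeros(info.size, dtype=bool)
        for fp_strand, start, end in params.footprints:
            if fp_strand == strand:
                in_fp |= (info >= start) & (info < end)
        p = np.where(in_fp, params.p_ss, params.p_bg)
        converted = rng.random(info.size) < p
        seq = ref_arr.copy()
        conv_positions = info[converted]
        seq[conv_positions] = expected
        seq = _apply_seq_errors(seq, params.p_seq_err, rng)
        clones.append((cid, "".join(seq)))
        truth.strands[cid] = strand
        truth.converted_positions[cid] = tuple(int(p) for p in conv_positions)
    return clones, truth


def simulate_aid_clones(
    ref: str,
    ss_intervals: Sequence[tuple[int, int]],
    deamination_rate: float,
    n_clones: int,
    seed: int,
    misrepair_fraction: float = 0.0,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate AID deamination confined to single-stranded intervals.

    Each C (top strand) and G (a bottom-strand C in top coordinates)
    inside ss_intervals deaminates with deamination_rate per clone,
    reading as C->T (resp. G->A). A misrepair_fraction of deamination
    events instead becomes a random other substitution, emulating
    aberrant base-excision repair of the uracil.
    """
    if not (0.0 <= deamination_rate <= 1.0):
        raise ValueError("deamination_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ref_arr = np.array(list(ref))
    exposed = [
        i
        for i in range(len(ref))
        if ref_arr[i] in ("C", "G")
        and any(lo <= i < hi for lo, hi in ss_intervals)
    ]
    truth = SimTruth(footprints=[("both", lo, hi) for lo, hi in ss_intervals])
    clones: list[tuple[str, str]] = []
    for k in range(n_clones):
        cid = f"aid_{k:04d}"
        seq = ref_arr.copy()
        muts: list[tuple[int, str, str]] = []
        for i in exposed:
            if rng.random() >= deamination_rate:
                continue
            ref_base = str(ref_arr[i])
            if misrepair_fraction > 0 and rng.random() < misrepair_fraction:
                alt = [b for b in "ACGT" if b != ref_base][rng.integers(3)]
            else:
                alt = "T" if ref_base == "C" else "A"
            seq[i] = alt
            muts.append((i, ref_base, alt))
        clones.append((cid, "".join(seq)))
        truth.strands[cid] = "both"
        truth.mutations[cid] = tuple(muts)
        truth.converted_positions[cid] = tuple(
            p for p, r, a in muts if (r, a) in (("C", "T"), ("G", "A"))
        )
    return clones, truth


def evaluate_recovery(
    called: Sequence[tuple[int, int]],
    truth_intervals: Sequence[tuple[int, int]],
) -> tuple[float, float, float]:
    """Compare called footprint intervals with planted truth.

    A call matches a truth interval when their reciprocal overlap is at
    least 0.5 (overlap >= half of each interval's length). Returns
    (precision, recall, mean absolute boundary error in nt over
    matches); precision/recall are NaN when their denominator is zero,
    boundary error is NaN with no matches.
    """
    matched_calls: set[int] = set()
    matched_truth: set[int] = set()
    boundary_errors: list[float] = []
    for ci, (cs, ce) in enumerate(called):
        for ti, (ts, te) in enumerate(truth_intervals):
            ov = min(ce, te) - max(cs, ts)
            if ov <= 0:
                continue
            if ov >= 0.5 * (ce - cs) and ov >= 0.5 * (te - ts):
                matched_calls.add(ci)
                if ti not in matched_truth:
                    matched_truth.add(ti)
                boundary_errors.append((abs(cs - ts) + abs(ce - te)) / 2)
    precision = len(matched_calls) / len(called) if called else float("nan")
    recall = (
        len(matched_truth) / len(truth_intervals) if truth_intervals else float("nan")
    )
    boundary = float(np.mean(boundary_errors)) if boundary_errors else float("nan")
    return precision, recall, boundary


def write_fixture(
    out_dir: str | Path, params: SimParams, mode: str = "bisulfite"
) -> Path:
    """Generate and write a complete fixture (reference FASTA, clone
    FASTA, truth TSV, parameter YAML) into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref, _ = simulate_reference(params)
    write_fasta({"ref": ref}, out / "reference.fasta")
    if mode == "bisulfite":
        clones, truth = simulate_bisulfite_clones(ref, params)
    elif mode == "aid":
        intervals = [(s, e) for _, s, e in params.footprints]
        clones, truth = simulate_aid_clones(
            ref, intervals, params.p_ss, params.n_clones, params.seed
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    write_fasta(clones, out / "clones.fasta")
    truth.to_tsv(out / "truth.tsv")
    params.to_yaml(out / "params.yaml")
    return out
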