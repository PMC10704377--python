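"""Single-molecule bisulfite footprinting.

Sodium bisulfite deaminates cytosine to uracil only where the DNA is
single-stranded; after PCR and cloning, a converted cytosine reads as T
(top strand) or, for molecules derived from the bottom strand, as G->A in
top-strand coordinates. Dense runs of converted cytosines in one clone
("stretches") therefore map single-strandedness — R-loops or a
G-quadruplex-displaced strand — at single-molecule resolution.

This module takes clones aligned to a reference amplicon through:
strand-of-origin assignment, per-cytosine conversion calling with CpG
handling (CpG methylation blocks conversion and would otherwise be read
as double-strandedness), stretch detection (continuous runs and dense
windows), per-position conversion frequency, and footprint-interval
calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "ConversionCall",
    "ConversionProfile",
    "StretchConfig",
    "Stretch",
    "FootprintCall",
    "CloneAlignment",
    "AlignmentRejected",
    "bisulfite_reference",
    "align_clone",
    "assign_strand",
    "call_conversions",
    "apply_cpg_rule",
    "find_stretches",
    "classify_clone",
    "positionwise_frequency",
    "call_footprints",
    "compare_conditions",
    "profiles_to_matrix",
]

CONVERTED = "converted"
UNCONVERTED = "unconverted"
EXCLUDED = "excluded"
MISMATCH_OTHER = "mismatch_other"

_STATUS_CODE = {CONVERTED: "1", UNCONVERTED: "0", EXCLUDED: "E", MISMATCH_OTHER: "M"}


@dataclass(frozen=True)
class ConversionCall:
    """Call at one informative reference position of one clone."""

    ref_pos: int
    context: str  # "CpG" | "non-CpG"
    status: str  # converted | unconverted | excluded | mismatch_other


@dataclass
class ConversionProfile:
    """Per-reference-cytosine conversion calls for a single clone.

    For top-strand clones the informative positions are reference C's;
    for bottom-strand clones they are reference G's (the bottom-strand
    cytosines read in top coordinates). Calls are sorted by ref_pos.
    """

    clone_id: str
    strand_of_origin: str  # top | bottom | undetermined
    calls: list[ConversionCall] = field(default_factory=list)
    n_mismatch_other: int = 0

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=lambda c: c.ref_pos)

    @property
    def n_informative(self) -> int:
        return len(self.calls)

    @property
    def mismatch_fraction(self) -> float:
        return self.n_mismatch_other / len(self.calls) if self.calls else 0.0

    @property
    def qc_flagged(self) -> bool:
        """True when >5% of informative positions carry non-bisulfite substitutions."""
        return self.mismatch_fraction > 0.05


@dataclass(frozen=True)
class StretchConfig:
    """Thresholds defining a conversion stretch.

    min_run: continuous-conversion threshold (count of consecutive
        converted cytosines).
    window / min_in_window: dense-window criterion, e.g. 12 converted of
        15 consecutive informative cytosines.
    cpg_run_k: number of continuous conversions required immediately
        before a CpG for its conversion to be trusted (methylated CpGs
        resist bisulfite whether single-stranded or not).
    """

    min_run: int = 10
    window: int = 15
    min_in_window: int = 12
    cpg_run_k: int = 4

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not (0 < self.min_in_window <= self.window):
            raise ValueError("require 0 < min_in_window <= window")
        if self.cpg_run_k < 0:
            raise ValueError("cpg_run_k must be >= 0")


@dataclass(frozen=True)
class Stretch:
    """A maximal run or dense window of converted cytosines in one clone."""

    start_pos: int  # ref coordinate of the first converted C (inclusive)
    end_pos: int  # ref coordinate of the last converted C (inclusive)
    n_converted: int
    n_informative: int
    kind: str  # continuous | windowed

    @property
    def span_nt(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class FootprintCall:
    """A single-stranded interval supported by many clones."""

    start: int
    end: int  # half-open
    strand: str
    mean_conversion_fraction: float
    n_supporting_clones: int

    @property
    def span_nt(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class AlignmentRejected(ValueError):
    """Clone failed the alignment identity floor."""


@dataclass
class CloneAlignment:
    """Column mapping of a clone onto the reference.

    columns: (ref_pos | None, clone_pos | None) per alignment column;
    None marks a gap on that side. identity is computed over aligned
    substitution columns that are not bisulfite-ambiguous (ref C / clone
    T and ref G / clone A pairs carry no identity information).
    """

    columns: list[tuple[int | None, int | None]]
    identity: float
    score: float

    def clone_base_at(self) -> dict[int, str | None]:  # pragma: no cover - helper
        raise NotImplementedError


def bisulfite_reference(ref: str, strand: str) -> str:
    """Fully converted reference in top coordinates.

    strand='top': every C -> T (direct deamination read-out).
    strand='bottom': every G -> A; a bottom-strand cytosine sits opposite
    a top-strand guanine, so its conversion reads as G->A in top
    coordinates.
    """
    _check_acgt(ref)
    if strand == "top":
        return ref.replace("C", "T")
    if strand == "bottom":
        return ref.replace("G", "A")
    raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")


def _check_acgt(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")


def _make_aligner() -> Align.PairwiseAligner:
    # Bisulfite-aware asymmetric scoring: ref C vs clone T and ref G vs
    # clone A score as matches so conversions cannot distort the alignment.
    alphabet = "ACGT"
    matrix = np.full((4, 4), -1.0)
    np.fill_diagonal(matrix, 1.0)
    matrix[alphabet.index("C"), alphabet.index("T")] = 1.0
    matrix[alphabet.index("G"), alphabet.index("A")] = 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.Array(
        alphabet=alphabet, dims=2, data=matrix
    )
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


_BISULFITE_PAIRS = {("C", "T"), ("G", "A")}


def align_clone(
    clone: str, ref: str, min_identity: float = 0.9
) -> CloneAlignment:
    """Global, affine-gap, bisulfite-aware alignment of a clone to the
    reference (target = reference, query = clone).

    C/T and G/A columns are substitution-neutral so that conversion does
    not penalise the alignment. Identity is measured over the remaining
    ("fully informative") substitution columns; clones below
    ``min_identity`` are rejected.
    """
    if not clone or not ref:
        raise ValueError("clone and reference must be nonempty")
    _check_acgt(clone)
    _check_acgt(ref)
    aligner = _make_aligner()
    aln = aligner.align(ref, clone)[0]
    indices = aln.indices  # 2 x n_columns, -1 at gaps
    columns: list[tuple[int | None, int | None]] = []
    n_info = 0
    n_match = 0
    for r, q in zip(indices[0], indices[1]):
        rp = int(r) if r >= 0 else None
        qp = int(q) if q >= 0 else None
        columns.append((rp, qp))
        if rp is None or qp is None:
            continue
        rb, qb = ref[rp], clone[qp]
        if (rb, qb) in _BISULFITE_PAIRS:
            continue
        n_info += 1
        if rb == qb:
            n_match += 1
    identity = n_match / n_info if n_info else 1.0
    if identity < min_identity:
        raise AlignmentRejected(
            f"alignment identity {identity:.3f} below floor {min_identity:.3f}"
        )
    return CloneAlignment(columns=columns, identity=identity, score=float(aln.score))


def assign_strand(
    clone: str,
    ref: str,
    alignment: CloneAlignment | None = None,
    min_informative: int = 3,
    min_score: float = 0.8,
) -> tuple[str, float]:
    """Infer which strand a bisulfite clone derives from.

    Counts C->T columns (top-strand conversion signature) against G->A
    columns (bottom-strand signature in top coordinates). The strand with
    the majority wins; score = majority count / total. Returns
    ('undetermined', score) when fewer than ``min_informative``
    conversion-like mismatches exist or the majority is weaker than
    ``min_score``.
    """
    if alignment is None:
        alignment = align_clone(clone, ref)
    n_ct = 0
    n_ga = 0
    for rp, qp in alignment.columns:
        if rp is None or qp is None:
            continue
        rb, qb = ref[rp], clone[qp]
        if rb == "C" and qb == "T":
            n_ct += 1
        elif rb == "G" and qb == "A":
            n_ga += 1
    total = n_ct + n_ga
    if total == 0:
        return ("undetermined", 0.0)
    score = max(n_ct, n_ga) / total
    if total < min_informative or score < min_score:
        return ("undetermined", score)
    return ("top" if n_ct > n_ga else "bottom", score)


def _cpg_context(ref: str, pos: int, strand: str) -> str:
    # CpG is palindromic: a bottom-strand C (top-coordinate G at pos) is in
    # CpG context iff the top strand reads C,G at pos-1,pos.
    if strand == "top":
        return "CpG" if pos + 1 < len(ref) and ref[pos + 1] == "G" else "non-CpG"
    return "CpG" if pos > 0 and ref[pos - 1] == "C" else "non-CpG"


def call_conversions(
    clone: str,
    ref: str,
    strand: str,
    clone_id: str = "clone",
    alignment: CloneAlignment | None = None,
) -> ConversionProfile:
    """Call conversion status at every informative reference position.

    Informative positions are reference C's (top-strand clones) or G's
    (bottom-strand clones). A position is 'converted' when the clone
    shows the bisulfite-expected base (T, resp. A), 'unconverted' when it
    matches the reference, 'mismatch_other' for any other base, and
    'excluded' at alignment gaps.
    """
    if strand not in ("top", "bottom"):
        raise ValueError(
            "strand must be 'top' or 'bottom'; run assign_strand first "
            f"(got {strand!r})"
        )
    if alignment is None:
        alignment = align_clone(clone, ref)
    info_base = "C" if strand == "top" else "G"
    expected = "T" if strand == "top" else "A"
    clone_at: dict[int, str | None] = {}
    covered_ref: set[int] = set()
    for rp, qp in alignment.columns:
        if rp is None:
            continue
        covered_ref.add(rp)
        clone_at[rp] = clone[qp] if qp is not None else None
    calls: list[ConversionCall] = []
    n_other = 0
    for pos, base in enumerate(ref):
        if base != info_base:
            continue
        context = _cpg_context(ref, pos, strand)
        if pos not in covered_ref or clone_at.get(pos) is None:
            status = EXCLUDED
        else:
            qb = clone_at[pos]
            if qb == expected:
                status = CONVERTED
            elif qb == base:
                status = UNCONVERTED
            else:
                status = MISMATCH_OTHER
                n_other += 1
        calls.append(ConversionCall(pos, context, status))
    return ConversionProfile(
        clone_id=clone_id,
        strand_of_origin=strand,
        calls=calls,
        n_mismatch_other=n_other,
    )


def apply_cpg_rule(profile: ConversionProfile, cpg_run_k: int = 4) -> ConversionProfile:
    """Resolve the CpG-methylation ambiguity.

    A converted call at a CpG is trusted only when the ``cpg_run_k``
    informative non-CpG calls immediately preceding it — along the
    molecule's own 5'->3' direction (ascending coordinates for top-strand
    clones, descending for bottom-strand) — are all converted; otherwise
    it is reclassified 'excluded' (a methylated CpG resists bisulfite
    regardless of strandedness). Non-CpG calls are never touched and the
    operation is idempotent.
    """
    if cpg_run_k == 0:
        return profile
    calls = profile.calls
    order = range(len(calls)) if profile.strand_of_origin != "bottom" else range(
        len(calls) - 1, -1, -1
    )
    ordered = list(order)
    index_in_order = {idx: k for k, idx in enumerate(ordered)}
    new_calls = list(calls)
    for idx in ordered:
        call = calls[idx]
        if call.context != "CpG" or call.status != CONVERTED:
            continue
        # walk backwards along the molecule collecting non-CpG calls
        seen = 0
        ok = True
        k = index_in_order[idx] - 1
        while k >= 0 and seen < cpg_run_k:
            prev = calls[ordered[k]]
            if prev.context != "CpG":
                seen += 1
                if prev.status != CONVERTED:
                    ok = False
                    break
            k -= 1
        if seen < cpg_run_k:
            ok = False
        if not ok:
            new_calls[idx] = replace(call, status=EXCLUDED)
    return ConversionProfile(
        clone_id=profile.clone_id,
        strand_of_origin=profile.strand_of_origin,
        calls=new_calls,
        n_mismatch_other=profile.n_mismatch_other,
    )


def find_stretches(profile: ConversionProfile, cfg: StretchConfig) -> list[Stretch]:
    """Detect conversion stretches in one clone.

    Continuous mode: maximal runs of >= cfg.min_run consecutive
    informative calls with status 'converted'; any non-converted call
    (including 'excluded') breaks a run.

    Windowed mode: over the informative calls with 'excluded' ones
    skipped, every window of cfg.window consecutive calls containing
    >= cfg.min_in_window conversions qualifies; overlapping qualifying
    windows merge into one stretch.
    """
    calls = profile.calls
    stretches: list[Stretch] = []

    # continuous runs
    run: list[ConversionCall] = []
    for call in calls + [None]:  # sentinel flush
        if call is not None and call.status == CONVERTED:
            run.append(call)
            continue
        if len(run) >= cfg.min_run:
            stretches.append(
                Stretch(
                    start_pos=run[0].ref_pos,
                    end_pos=run[-1].ref_pos,
                    n_converted=len(run),
                    n_informative=len(run),
                    kind="continuous",
                )
            )
        run = []

    # dense windows (excluded calls skipped, not counted as failures)
    usable = [c for c in calls if c.status != EXCLUDED]
    w, m = cfg.window, cfg.min_in_window
    if len(usable) >= w:
        conv = np.array([c.status == CONVERTED for c in usable], dtype=int)
        sums = np.convolve(conv, np.ones(w, dtype=int), mode="valid")
        qualifying = np.flatnonzero(sums >= m)
        if qualifying.size:
            # merge overlapping qualifying windows over call indices
            spans: list[list[int]] = []
            for q in qualifying:
                if spans and q <= spans[-1][1]:  # windows [q, q+w) overlap
                    spans[-1][1] = q + w - 1
                else:
                    spans.append([q, q + w - 1])
            for lo, hi in spans:
                seg = usable[lo : hi + 1]
                n_conv = sum(c.status == CONVERTED for c in seg)
                stretches.append(
                    Stretch(
                        start_pos=seg[0].ref_pos,
                        end_pos=seg[-1].ref_pos,
                        n_converted=n_conv,
                        n_informative=len(seg),
                        kind="windowed",
                    )
                )
    return stretches


def _max_continuous_run(profile: ConversionProfile) -> int:
    best = cur = 0
    for call in profile.calls:
        if call.status == CONVERTED:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def classify_clone(profile: ConversionProfile, cfg: StretchConfig) -> str:
    """Highest stretch category a clone attains.

    'run_gt15' for a continuous run of more than 15 conversions,
    'run_gt10' for more than 10, 'windowed_only' when only the dense-
    window criterion is met, 'none' otherwise.
    """
    longest = _max_continuous_run(profile)
    if longest > 15:
        return "run_gt15"
    if longest > 10:
        return "run_gt10"
    windowed = [s for s in find_stretches(profile, cfg) if s.kind == "windowed"]
    if windowed:
        return "windowed_only"
    return "none"


def positionwise_frequency(
    profiles: Sequence[ConversionProfile],
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Cumulative per-position conversion frequency across clones.

    All profiles must share a strand (top- and bottom-strand clones read
    different cytosines and are summarised separately). Excluded calls
    reduce the coverage denominator. Returns a DataFrame with columns
    ref_pos, n_converted, n_covered, fraction (NaN where uncovered).
    """
    if not profiles:
        return pd.DataFrame(columns=["ref_pos", "n_converted", "n_covered", "fraction"])
    strands = {p.strand_of_origin for p in profiles}
    if len(strands) > 1:
        raise ValueError(
            f"mixed-strand input {sorted(strands)}: summarize each strand separately"
        )
    conv: dict[int, int] = {}
    cov: dict[int, int] = {}
    for p in profiles:
        for call in p.calls:
            if region is not None and not (region[0] <= call.ref_pos < region[1]):
                continue
            cov.setdefault(call.ref_pos, 0)
            conv.setdefault(call.ref_pos, 0)
            if call.status == EXCLUDED:
                continue
            cov[call.ref_pos] += 1
            if call.status == CONVERTED:
                conv[call.ref_pos] += 1
    positions = sorted(cov)
    n_conv = [conv[p] for p in positions]
    n_cov = [cov[p] for p in positions]
    frac = [c / n if n else math.nan for c, n in zip(n_conv, n_cov)]
    return pd.DataFrame(
        {
            "ref_pos": positions,
            "n_converted": n_conv,
            "n_covered": n_cov,
            "fraction": frac,
        }
    )


def call_footprints(
    freq_table: pd.DataFrame,
    min_fraction: float = 0.5,
    min_span_nt: int = 30,
    max_gap_nt: int = 20,
    profiles: Sequence[ConversionProfile] = (),
    strand: str = "both",
) -> list[FootprintCall]:
    """Call single-stranded footprint intervals from a frequency table.

    Informative positions with conversion fraction >= min_fraction are
    merged into intervals, bridging gaps of at most max_gap_nt between
    consecutive qualifying positions; intervals spanning < min_span_nt
    are dropped. A clone supports a footprint when at least half of its
    covered informative calls inside the interval are converted.
    """
    if min_fraction <= 0 or min_span_nt <= 0 or max_gap_nt < 0:
        raise ValueError("thresholds must be positive (max_gap_nt >= 0)")
    if freq_table.empty:
        return []
    qual = freq_table[
        (freq_table["n_covered"] > 0) & (freq_table["fraction"] >= min_fraction)
    ]["ref_pos"].to_numpy()
    if qual.size == 0:
        return []
    groups: list[list[int]] = [[int(qual[0]), int(qual[0])]]
    for p in qual[1:]:
        if p - groups[-1][1] - 1 <= max_gap_nt:
            groups[-1][1] = int(p)
        else:
            groups.append([int(p), int(p)])
    calls: list[FootprintCall] = []
    for lo, hi in groups:
        if hi - lo + 1 < min_span_nt:
            continue
        inside = freq_table[
            (freq_table["ref_pos"] >= lo)
            & (freq_table["ref_pos"] <= hi)
            & (freq_table["n_covered"] > 0)
        ]
        mean_frac = float(inside["fraction"].mean())
        n_support = 0
        for prof in profiles:
            seg = [
                c
                for c in prof.calls
                if lo <= c.ref_pos <= hi and c.status != EXCLUDED
            ]
            if not seg:
                continue
            n_conv = sum(c.status == CONVERTED for c in seg)
            if n_conv / len(seg) >= 0.5:
                n_support += 1
        calls.append(
            FootprintCall(
                start=lo,
                end=hi + 1,
                strand=strand,
                mean_conversion_fraction=mean_frac,
                n_supporting_clones=n_support,
            )
        )
    return calls


def compare_conditions(
    profiles_a: Sequence[ConversionProfile],
    profiles_b: Sequence[ConversionProfile],
    cfg: StretchConfig,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Clone-classification counts for two conditions (e.g. with and
    without RNase H). Counts are cumulative: a clone with a run of 17
    counts in both n_run_gt10 and n_run_gt15. Zero counts are reported
    as 0."""
    if not profiles_a or not profiles_b:
        raise ValueError("both condition sets must be nonempty")
    rows = []
    for label, profiles in zip(labels, (profiles_a, profiles_b)):
        runs = [_max_continuous_run(p) for p in profiles]
        n_windowed = sum(
            1
            for p in profiles
            if any(s.kind == "windowed" for s in find_stretches(p, cfg))
        )
        rows.append(
            {
                "condition": label,
                "n_run_gt10": sum(r > 10 for r in runs),
                "n_run_gt15": sum(r > 15 for r in runs),
                "n_windowed": n_windowed,
                "n_total": len(profiles),
            }
        )
    return pd.DataFrame(rows)


def profiles_to_matrix(profiles: Iterable[ConversionProfile]) -> pd.DataFrame:
    """Clone x position matrix with cells in {1,0,E,M} for export."""
    data = {
        p.clone_id: {c.ref_pos: _STATUS_CODE[c.status] for c in p.calls}
        for p in profiles
    }
    df = pd.DataFrame.from_dict(data, orient="index")
    return df.reindex(sorted(df.columns), axis=1)
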