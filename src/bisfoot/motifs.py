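"""Sequence-motif scanners: AID WRC hotspots, G-quadruplex motifs
(conventional and extended), GC content and GC skew.

The conventional G-quadruplex motif is four guanine tracts of at least
three G's separated by loops of 1-7 nt. The extended definition admits
two deviations seen in experimentally supported quadruplexes that
pattern-matching tools score as negative: a single long loop (foldable
as a duplex hairpin) and a single bulged tract of the form G+NG+ (one
non-G interruption, total G count still meeting the tract minimum).

Greedy non-overlapping reporting: the scan takes the leftmost start at
which any valid tract/loop decomposition begins, reports the maximal hit
there (largest end; ties broken toward larger tract ends, pure tracts
preferred over bulged), and resumes after the hit's end. A brute-force
enumerator over all decompositions exists for cross-checking
(`g4_brute_force`).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "MotifHit",
    "G4Config",
    "find_wrc",
    "find_g4_conventional",
    "find_g4_extended",
    "g4_brute_force",
    "gc_content",
    "gc_skew",
]

_WRC_RE = re.compile(r"(?=([AT][AG]C))")
_GYW_RE = re.compile(r"(?=(G[CT][AT]))")


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; coordinates are 0-based half-open on the
    plus strand."""

    motif_class: str  # WRC | G4_conventional | G4_extended
    strand: str  # plus | minus
    start: int
    end: int
    matched_sequence: str
    tracts: tuple[tuple[int, int], ...] = ()  # 4 G-tract spans for G4 hits
    loops: tuple[int, ...] = ()  # 3 loop lengths for G4 hits
    bulged: tuple[bool, ...] = ()  # per-tract bulge flags
    long_loop: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class G4Config:
    """G-quadruplex motif definition.

    min_tract: minimum G count per tract.
    min_loop / max_loop_std: standard loop-length bounds (nt).
    max_long_loop: upper bound for the single permitted long loop
        (hairpin-forming); at most one loop may exceed max_loop_std.
    allow_bulge: permit one tract of form G+NG+ (single non-G
        interruption) with total G count >= min_tract.
    """

    min_tract: int = 3
    min_loop: int = 1
    max_loop_std: int = 7
    max_long_loop: int = 21
    allow_bulge: bool = True

    def __post_init__(self) -> None:
        if self.min_tract < 2:
            raise ValueError("min_tract must be >= 2")
        if self.max_long_loop < self.max_loop_std:
            raise ValueError("max_long_loop must be >= max_loop_std")
        if not (1 <= self.min_loop <= self.max_loop_std):
            raise ValueError("require 1 <= min_loop <= max_loop_std")


def find_wrc(seq: str, both_strands: bool = True) -> list[MotifHit]:
    """All WRC occurrences (W=A/T, R=A/G, C), overlapping hits included.

    Minus-strand occurrences are reported as GYW matches on the plus
    strand (G, Y=C/T, W=A/T) with strand='minus' and plus coordinates.
    """
    hits = [
        MotifHit("WRC", "plus", m.start(), m.start() + 3, m.group(1))
        for m in _WRC_RE.finditer(seq)
    ]
    if both_strands:
        hits += [
            MotifHit("WRC", "minus", m.start(), m.start() + 3, m.group(1))
            for m in _GYW_RE.finditer(seq)
        ]
    return sorted(hits, key=lambda h: (h.start, h.strand))


# ---------------------------------------------------------------------------
# G-quadruplex scanning


def _tract_candidates(
    seq: str, p: int, cfg: G4Config, allow_bulge: bool
) -> list[tuple[int, bool]]:
    """Tract spans starting exactly at p: (end, bulged) pairs."""
    n = len(seq)
    if p >= n or seq[p] != "G":
        return []
    i = p
    while i < n and seq[i] == "G":
        i += 1
    run = i - p
    out = [(p + k, False) for k in range(cfg.min_tract, run + 1)]
    if allow_bulge:
        # the single interruption necessarily follows the maximal leading G run
        j = p + run
        if j < n - 1 and seq[j] != "G" and seq[j + 1] == "G":
            jj = j + 1
            while jj < n and seq[jj] == "G":
                jj += 1
            for b in range(1, jj - j):
                if run + b >= cfg.min_tract:
                    out.append((j + 1 + b, True))
    return out


def _loop_bounds(cfg: G4Config, long_used: bool) -> tuple[int, int]:
    return (cfg.min_loop, cfg.max_loop_std if long_used else cfg.max_long_loop)


def _best_end(
    seq: str,
    pos: int,
    tracts_left: int,
    long_used: bool,
    bulge_used: bool,
    cfg: G4Config,
    memo: dict,
) -> int | None:
    """Maximum final end of a valid partial motif whose next tract starts
    exactly at pos, or None if impossible. Memoized."""
    key = (pos, tracts_left, long_used, bulge_used)
    if key in memo:
        return memo[key]
    best: int | None = None
    for tend, bulged in _tract_candidates(
        seq, pos, cfg, cfg.allow_bulge and not bulge_used
    ):
        if tracts_left == 1:
            cand: int | None = tend
        else:
            cand = None
            lo, hi = _loop_bounds(cfg, long_used)
            for loop in range(lo, hi + 1):
                sub = _best_end(
                    seq,
                    tend + loop,
                    tracts_left - 1,
                    long_used or loop > cfg.max_loop_std,
                    bulge_used or bulged,
                    cfg,
                    memo,
                )
                if sub is not None and (cand is None or sub > cand):
                    cand = sub
        if cand is not None and (best is None or cand > best):
            best = cand
    memo[key] = best
    return best


def _decomp_key(tracts: Sequence[tuple[int, int, bool]]) -> tuple:
    """Canonical tie-break among equal-start decompositions: final end
    first, then per tract in order (end, pure-before-bulged, start),
    all maximized lexicographically."""
    key: list = [tracts[-1][1]]
    for start, end, bulged in tracts:
        key.extend((end, not bulged, start))
    return tuple(key)


def _reconstruct(
    seq: str,
    pos: int,
    tracts_left: int,
    long_used: bool,
    bulge_used: bool,
    target: int,
    cfg: G4Config,
    memo: dict,
) -> tuple[list[tuple[int, int, bool]], list[int]] | None:
    """Canonical decomposition reaching final end == target, chosen
    stage by stage with the _decomp_key ordering: per tract, maximal
    end, then pure preferred over bulged, then maximal start (i.e. the
    longest permissible preceding loop)."""

    rec_memo: dict = {}

    def stage(
        p: int, left: int, lng: bool, blg: bool
    ) -> list[tuple[int, int, bool]] | None:
        state = (p, left, lng, blg)
        if state in rec_memo:
            return rec_memo[state]
        best: tuple | None = None
        best_tr: list[tuple[int, int, bool]] | None = None
        for tend, bulged in _tract_candidates(
            seq, p, cfg, cfg.allow_bulge and not blg
        ):
            if left == 1:
                if tend != target:
                    continue
                cand = [(p, tend, bulged)]
                key = _decomp_key(cand)
                if best is None or key > best:
                    best, best_tr = key, cand
                continue
            lo, hi = _loop_bounds(cfg, lng)
            for loop in range(lo, hi + 1):
                nxt_long = lng or loop > cfg.max_loop_std
                nxt_blg = blg or bulged
                if (
                    _best_end(seq, tend + loop, left - 1, nxt_long, nxt_blg, cfg, memo)
                    != target
                ):
                    continue
                sub = stage(tend + loop, left - 1, nxt_long, nxt_blg)
                if sub is None:
                    continue
                cand = [(p, tend, bulged)] + sub
                key = _decomp_key(cand)
                if best is None or key > best:
                    best, best_tr = key, cand
        rec_memo[state] = best_tr
        return best_tr

    tracts = stage(pos, tracts_left, long_used, bulge_used)
    if tracts is None:
        return None
    loops = [tracts[k + 1][0] - tracts[k][1] for k in range(len(tracts) - 1)]
    return tracts, loops


def _make_g4_hit(
    seq: str,
    tracts: list[tuple[int, int, bool]],
    loops: list[int],
    cfg: G4Config,
    motif_class: str,
) -> MotifHit:
    start, end = tracts[0][0], tracts[-1][1]
    return MotifHit(
        motif_class=motif_class,
        strand="plus",
        start=start,
        end=end,
        matched_sequence=seq[start:end],
        tracts=tuple((t[0], t[1]) for t in tracts),
        loops=tuple(loops),
        bulged=tuple(t[2] for t in tracts),
        long_loop=any(l > cfg.max_loop_std for l in loops),
    )


def _scan_g4(seq: str, cfg: G4Config, motif_class: str) -> list[MotifHit]:
    hits: list[MotifHit] = []
    memo: dict = {}
    i = 0
    n = len(seq)
    while i < n:
        target = _best_end(seq, i, 4, False, False, cfg, memo)
        if target is None:
            i += 1
            continue
        rec = _reconstruct(seq, i, 4, False, False, target, cfg, memo)
        assert rec is not None
        hits.append(_make_g4_hit(seq, rec[0], rec[1], cfg, motif_class))
        i = target  # non-overlapping: resume after the hit
    return hits


def find_g4_conventional(seq: str, min_tract: int = 3) -> list[MotifHit]:
    """Conventional G-quadruplex motifs: four G-tracts (>= min_tract G's)
    with loops of 1-7 nt; greedy leftmost-maximal non-overlapping hits."""
    cfg = G4Config(
        min_tract=min_tract, max_loop_std=7, max_long_loop=7, allow_bulge=False
    )
    return _scan_g4(seq, cfg, "G4_conventional")


def find_g4_extended(seq: str, cfg: G4Config | None = None) -> list[MotifHit]:
    """Extended G-quadruplex motifs: as conventional, plus at most one
    long (hairpin-forming) loop and, if cfg.allow_bulge, at most one
    bulged G+NG+ tract. Every conventional hit is also an extended hit
    under the same min_tract."""
    if cfg is None:
        cfg = G4Config()
    return _scan_g4(seq, cfg, "G4_extended")


def g4_match_spans(seq: str, cfg: G4Config) -> set[tuple[int, int]]:
    """Every (start, end) span admitting at least one valid tract/loop
    decomposition, ignoring the greedy non-overlapping report. Under a
    permissive config this is a superset of any stricter config's spans
    (a conventional match is always a valid extended match)."""
    memo: dict = {}

    def end_set(pos: int, tracts_left: int, long_used: bool, bulge_used: bool) -> frozenset[int]:
        key = (pos, tracts_left, long_used, bulge_used)
        if key in memo:
            return memo[key]
        ends: set[int] = set()
        for tend, bulged in _tract_candidates(
            seq, pos, cfg, cfg.allow_bulge and not bulge_used
        ):
            if tracts_left == 1:
                ends.add(tend)
                continue
            lo, hi = _loop_bounds(cfg, long_used)
            for loop in range(lo, hi + 1):
                ends |= end_set(
                    tend + loop,
                    tracts_left - 1,
                    long_used or loop > cfg.max_loop_std,
                    bulge_used or bulged,
                )
        result = frozenset(ends)
        memo[key] = result
        return result

    spans: set[tuple[int, int]] = set()
    for s in range(len(seq)):
        for e in end_set(s, 4, False, False):
            spans.add((s, e))
    return spans


def g4_brute_force(
    seq: str, cfg: G4Config, overlapping: bool = False
) -> list[MotifHit]:
    """Exhaustive G4 search: try all 4-tract decompositions.

    With overlapping=True every distinct decomposition is returned;
    otherwise greedy non-overlapping reporting with the same canonical
    tie-break as the scanner. Exponential — use on short strings only.
    """
    n = len(seq)
    decomps: list[tuple[list[tuple[int, int, bool]], list[int]]] = []

    def extend(tracts: list[tuple[int, int, bool]]) -> None:
        if len(tracts) == 4:
            loops = [
                tracts[k + 1][0] - tracts[k][1] for k in range(3)
            ]
            n_long = sum(l > cfg.max_loop_std for l in loops)
            if n_long > 1 or any(
                l < cfg.min_loop or l > cfg.max_long_loop for l in loops
            ):
                return
            if sum(t[2] for t in tracts) > 1:
                return
            decomps.append((list(tracts), loops))
            return
        lo = tracts[-1][1] + cfg.min_loop
        hi = tracts[-1][1] + cfg.max_long_loop
        for p in range(lo, min(hi, n - 1) + 1):
            for tend, bulged in _all_tracts_at(seq, p, cfg):
                tracts.append((p, tend, bulged))
                extend(tracts)
                tracts.pop()

    for p in range(n):
        for tend, bulged in _all_tracts_at(seq, p, cfg):
            extend([(p, tend, bulged)])

    hits = [
        _make_g4_hit(seq, tr, lp, cfg, "G4")
        for tr, lp in decomps
    ]
    if overlapping:
        return sorted(hits, key=lambda h: (h.start, h.end))
    # greedy non-overlapping with the scanner's canonical tie-break
    chosen: list[MotifHit] = []
    pool = decomps
    cursor = 0
    while True:
        avail = [(tr, lp) for tr, lp in pool if tr[0][0] >= cursor]
        if not avail:
            break
        s = min(tr[0][0] for tr, lp in avail)
        at_s = [(tr, lp) for tr, lp in avail if tr[0][0] == s]
        best = max(at_s, key=lambda d: _decomp_key(d[0]))
        chosen.append(_make_g4_hit(seq, best[0], best[1], cfg, "G4"))
        cursor = best[0][-1][1]
    return chosen


def _all_tracts_at(seq: str, p: int, cfg: G4Config) -> list[tuple[int, int, bool]]:
    """All tract spans starting at p, enumerated directly from the
    definition (pure G run or single-interruption G+NG+)."""
    out: list[tuple[int, int, bool]] = []
    n = len(seq)
    max_len = min(n - p, 2 * cfg.min_tract + cfg.max_long_loop)  # generous cap
    for end in range(p + cfg.min_tract, p + max_len + 1):
        sub = seq[p:end]
        if not sub or sub[0] != "G" or sub[-1] != "G":
            continue
        non_g = [k for k, b in enumerate(sub) if b != "G"]
        if not non_g:
            out.append((p, end, False))
        elif cfg.allow_bulge and len(non_g) == 1 and len(sub) - 1 >= cfg.min_tract:
            out.append((p, end, True))
    return [(t[1], t[2]) for t in out]


# ---------------------------------------------------------------------------
# Base composition


def gc_content(seq: str) -> float:
    """Percent G+C of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def gc_skew(seq: str, window: int, step: int = 1) -> pd.DataFrame:
    """Sliding-window GC skew, (G - C) / (G + C) per window.

    Windows with no G or C report NaN. Returns a DataFrame with columns
    window_start, skew.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    starts = list(range(0, len(seq) - window + 1, step))
    skews = []
    for s in starts:
        sub = seq[s : s + window]
        g, c = sub.count("G"), sub.count("C")
        skews.append((g - c) / (g + c) if g + c else math.nan)
    return pd.DataFrame({"window_start": starts, "skew": skews})
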