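"""AID-induced mutation analysis.

Activation-induced cytidine deaminase (AID) converts cytosine to uracil
on single-stranded DNA; after replication this reads as C->T (or G->A
for events on the bottom strand), while aberrant base-excision repair of
the uracil can produce any other substitution. Mutation frequency is the
number of point mutations per total nucleotide sequenced across clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .bisulfite import CloneAlignment, align_clone
from .motifs import MotifHit

__all__ = [
    "MutationRecord",
    "MutationSummary",
    "call_mutations",
    "sequenced_nt",
    "mutation_frequency",
    "condition_reduction",
    "annotate_mutations",
]

_BISULFITE_LIKE = {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class MutationRecord:
    """One substitution in one clone relative to the reference."""

    clone_id: str
    ref_pos: int
    ref_base: str
    alt_base: str
    in_motif: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT":
                raise ValueError(f"illegal base {b!r}")

    @property
    def substitution_class(self) -> str:
        return f"{self.ref_base}->{self.alt_base}"


@dataclass
class MutationSummary:
    """Mutation counts and per-nucleotide frequency."""

    n_mutations: int
    total_nt_sequenced: int
    per_class: dict[str, int] = field(default_factory=dict)

    @property
    def frequency(self) -> float:
        return self.n_mutations / self.total_nt_sequenced

    @property
    def frequency_percent(self) -> float:
        return 100.0 * self.frequency


def call_mutations(
    clone: str,
    ref: str,
    clone_id: str = "clone",
    exclude_bisulfite_like: bool = False,
    alignment: CloneAlignment | None = None,
    gap_flank: int = 2,
) -> tuple[list[MutationRecord], int]:
    """Call substitutions of a clone against the reference.

    Returns (records, n_indel_columns). With exclude_bisulfite_like,
    C->T and G->A records are suppressed (in bisulfite-treated material
    these are conversions, not mutations). Substitutions within
    ``gap_flank`` nt of an alignment gap are excluded as indel-induced
    artifacts (they count toward n_indel_columns).
    """
    if alignment is None:
        alignment = align_clone(clone, ref)
    cols = alignment.columns
    gap_cols = [k for k, (rp, qp) in enumerate(cols) if rp is None or qp is None]
    near_gap = set()
    for g in gap_cols:
        near_gap.update(range(g - gap_flank, g + gap_flank + 1))
    records: list[MutationRecord] = []
    n_excluded = len(gap_cols)
    for k, (rp, qp) in enumerate(cols):
        if rp is None or qp is None:
            continue
        rb, qb = ref[rp], clone[qp]
        if rb == qb:
            continue
        if k in near_gap:
            n_excluded += 1
            continue
        if exclude_bisulfite_like and (rb, qb) in _BISULFITE_LIKE:
            continue
        records.append(MutationRecord(clone_id, rp, rb, qb))
    return records, n_excluded


def sequenced_nt(clones: Sequence[str], ref: str) -> int:
    """Total aligned, non-gap clone nucleotides across a clone set."""
    total = 0
    for clone in clones:
        aln = align_clone(clone, ref)
        total += sum(1 for rp, qp in aln.columns if rp is not None and qp is not None)
    return total


def mutation_frequency(
    records: Sequence[MutationRecord], total_nt: int
) -> MutationSummary:
    """Mutations per total nucleotide sequenced, with per-class counts."""
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    per_class: dict[str, int] = {}
    for rec in records:
        per_class[rec.substitution_class] = per_class.get(rec.substitution_class, 0) + 1
    return MutationSummary(
        n_mutations=len(records), total_nt_sequenced=total_nt, per_class=per_class
    )


def condition_reduction(freq_a: float, freq_b: float) -> float:
    """Percent reduction of condition B relative to condition A,
    100 * (a - b) / a. Used e.g. for the with/without-RNase H
    comparison."""
    if freq_a <= 0:
        raise ValueError("freq_a must be positive")
    return 100.0 * (freq_a - freq_b) / freq_a


def annotate_mutations(
    records: Sequence[MutationRecord],
    motif_hits: Sequence[MotifHit],
    flank: int = 5,
) -> list[MutationRecord]:
    """Flag mutations falling inside a motif hit or within ``flank`` nt
    of one (half-open spans; a hit [s,e) with flank f covers
    [s-f, e+f))."""
    spans = [(h.start - flank, h.end + flank) for h in motif_hits]
    out = []
    for rec in records:
        flagged = any(lo <= rec.ref_pos < hi for lo, hi in spans)
        out.append(replace(rec, in_motif=flagged))
    return out


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Tabular view of mutation records (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "clone_id": r.clone_id,
                "ref_pos": r.ref_pos,
                "ref_base": r.ref_base,
                "alt_base": r.alt_base,
                "substitution_class": r.substitution_class,
                "in_motif": r.in_motif,
            }
            for r in records
        ],
        columns=[
            "clone_id",
            "ref_pos",
            "ref_base",
            "alt_base",
            "substitution_class",
            "in_motif",
        ],
    )


def write_vcf_like(
    records: Sequence[MutationRecord], ref_id: str, path: str
) -> None:
    """Minimal VCF-style output: CHROM, 1-based POS, REF, ALT, INFO with
    clone id and motif flag."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2-minimal\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda x: (x.ref_pos, x.clone_id)):
            info = f"CLONE={r.clone_id};IN_MOTIF={1 if r.in_motif else 0}"
            fh.write(
                f"{ref_id}\t{r.ref_pos + 1}\t.\t{r.ref_base}\t{r.alt_base}\t.\t.\t{info}\n"
            )
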