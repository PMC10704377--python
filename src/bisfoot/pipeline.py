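"""End-to-end orchestration of the footprinting, motif-scan and
mutation analyses, shared by the CLI and by library callers."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import bisulfite as bf
from . import motifs as mt
from . import mutations as mu
from .regions import Region, write_bed

logger = logging.getLogger("bisfoot")

__all__ = ["FootprintResult", "run_footprint", "run_scan", "run_mutations"]


@dataclass
class FootprintResult:
    """Per-strand outputs of the footprint pipeline."""

    profiles: dict[str, list[bf.ConversionProfile]]
    frequency: dict[str, pd.DataFrame]
    footprints: dict[str, list[bf.FootprintCall]]
    stretches: dict[str, list[tuple[str, bf.Stretch]]]
    n_rejected: int = 0
    n_undetermined: int = 0

    @property
    def n_clones(self) -> int:
        return sum(len(v) for v in self.profiles.values())


def run_footprint(
    ref: str,
    clones: Sequence[tuple[str, str]],
    cfg: bf.StretchConfig | None = None,
    min_fraction: float = 0.5,
    min_span_nt: int = 30,
    max_gap_nt: int = 20,
    min_identity: float = 0.9,
    strands: tuple[str, ...] = ("top", "bottom"),
) -> FootprintResult:
    """align -> assign_strand -> call_conversions -> apply_cpg_rule ->
    find_stretches -> positionwise_frequency -> call_footprints,
    separately per strand of origin."""
    cfg = cfg or bf.StretchConfig()
    profiles: dict[str, list[bf.ConversionProfile]] = {s: [] for s in strands}
    stretches: dict[str, list[tuple[str, bf.Stretch]]] = {s: [] for s in strands}
    n_rejected = 0
    n_undetermined = 0
    for clone_id, seq in clones:
        try:
            aln = bf.align_clone(seq, ref, min_identity=min_identity)
        except bf.AlignmentRejected as exc:
            logger.warning("clone %s rejected: %s", clone_id, exc)
            n_rejected += 1
            continue
        strand, score = bf.assign_strand(seq, ref, alignment=aln)
        if strand == "undetermined":
            logger.info("clone %s strand undetermined (score %.2f)", clone_id, score)
            n_undetermined += 1
            continue
        if strand not in profiles:
            continue
        profile = bf.call_conversions(seq, ref, strand, clone_id=clone_id, alignment=aln)
        profile = bf.apply_cpg_rule(profile, cfg.cpg_run_k)
        profiles[strand].append(profile)
        for s in bf.find_stretches(profile, cfg):
            stretches[strand].append((clone_id, s))
    if clones and n_rejected > len(clones) / 2:
        raise bf.AlignmentRejected(
            f"{n_rejected} of {len(clones)} clones rejected at alignment; "
            "check that clones match the reference amplicon"
        )
    frequency = {}
    footprints = {}
    for strand in strands:
        freq = bf.positionwise_frequency(profiles[strand])
        frequency[strand] = freq
        if profiles[strand]:
            footprints[strand] = bf.call_footprints(
                freq,
                min_fraction=min_fraction,
                min_span_nt=min_span_nt,
                max_gap_nt=max_gap_nt,
                profiles=profiles[strand],
                strand=strand,
            )
        else:
            logger.warning("no %s-strand clones: empty summary", strand)
            footprints[strand] = []
    return FootprintResult(
        profiles=profiles,
        frequency=frequency,
        footprints=footprints,
        stretches=stretches,
        n_rejected=n_rejected,
        n_undetermined=n_undetermined,
    )


def write_footprint_outputs(result: FootprintResult, ref_id: str, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bed_rows = []
    for strand, calls in result.footprints.items():
        strand_sym = "+" if strand == "top" else "-"
        for k, fp in enumerate(calls):
            bed_rows.append(
                (
                    ref_id,
                    fp.start,
                    fp.end,
                    f"footprint_{strand}_{k}",
                    int(round(fp.mean_conversion_fraction * 1000)),
                    strand_sym,
                )
            )
    write_bed(bed_rows, out / "footprints.bed")
    stretch_rows = []
    for strand, pairs in result.stretches.items():
        strand_sym = "+" if strand == "top" else "-"
        for clone_id, s in pairs:
            stretch_rows.append(
                (
                    ref_id,
                    s.start_pos,
                    s.end_pos + 1,
                    f"{clone_id}_{s.kind}",
                    s.n_converted,
                    strand_sym,
                )
            )
    write_bed(stretch_rows, out / "stretches.bed")
    for strand, profs in result.profiles.items():
        if profs:
            bf.profiles_to_matrix(profs).to_csv(
                out / f"profiles_{strand}.tsv", sep="\t", index_label="clone_id"
            )
        result.frequency[strand].to_csv(
            out / f"frequency_{strand}.tsv", sep="\t", index=False
        )
    summary = pd.DataFrame(
        [
            {
                "strand": strand,
                "n_clones": len(result.profiles[strand]),
                "n_footprints": len(result.footprints[strand]),
                "n_stretches": len(result.stretches[strand]),
            }
            for strand in result.profiles
        ]
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)


def run_scan(
    ref: str,
    regions: Sequence[Region],
    g4_cfg: mt.G4Config | None = None,
    skew_window: int = 100,
    skew_step: int = 10,
    wrc_both_strands: bool = True,
) -> tuple[pd.DataFrame, list[tuple[Region, mt.MotifHit]], pd.DataFrame]:
    """Motif scan per region: WRC, conventional and extended G4 counts,
    GC content; plus a whole-reference GC-skew profile.

    Returns (per-region summary table, per-region hits, skew profile).
    Hit coordinates are absolute (reference) coordinates.
    """
    g4_cfg = g4_cfg or mt.G4Config()
    rows = []
    all_hits: list[tuple[Region, mt.MotifHit]] = []
    for region in regions:
        if region.end > len(ref):
            raise ValueError(
                f"region {region.name!r} [{region.start},{region.end}) outside "
                f"reference of length {len(ref)}"
            )
        sub = ref[region.start : region.end]
        wrc = mt.find_wrc(sub, both_strands=wrc_both_strands)
        wrc_plus = [h for h in wrc if h.strand == "plus"]
        g4c = mt.find_g4_conventional(sub, min_tract=g4_cfg.min_tract)
        g4e = mt.find_g4_extended(sub, g4_cfg)
        for h in wrc + g4c + g4e:
            shifted = mt.MotifHit(
                motif_class=h.motif_class,
                strand=h.strand,
                start=h.start + region.start,
                end=h.end + region.start,
                matched_sequence=h.matched_sequence,
                tracts=tuple((a + region.start, b + region.start) for a, b in h.tracts),
                loops=h.loops,
                bulged=h.bulged,
                long_loop=h.long_loop,
            )
            all_hits.append((region, shifted))
        rows.append(
            {
                "region": region.name,
                "start": region.start,
                "end": region.end,
                "n_wrc_both": len(wrc),
                "n_wrc_plus": len(wrc_plus),
                "n_g4_conventional": len(g4c),
                "n_g4_extended": len(g4e),
                "gc_content": mt.gc_content(sub),
            }
        )
    skew = (
        mt.gc_skew(ref, skew_window, skew_step)
        if skew_window <= len(ref)
        else pd.DataFrame(columns=["window_start", "skew"])
    )
    return pd.DataFrame(rows), all_hits, skew


def anchored_region_scan(
    ref: str,
    anchor: int,
    entries: Sequence[tuple[str, int, int]],
    shifts: Sequence[int] = tuple(range(-20, 21)),
    g4_cfg: mt.G4Config | None = None,
    ref_id: str = "ref",
) -> pd.DataFrame:
    """Motif summary for anchor-offset regions under anchor shifts.

    When regions are defined as offsets from an anchor (e.g. a promoter
    TSS) whose exact coordinate is uncertain, motif counts should be
    reported together with their sensitivity to the anchor choice. The
    scan is repeated with the anchor displaced by each value in
    ``shifts``; rows carry anchor_shift, region and the per-region
    counts, so count stability across shifts can be read directly.
    """
    from .regions import RegionSpec, make_regions

    frames = []
    for shift in shifts:
        spec = RegionSpec(anchor + shift, tuple(entries), ref_id=ref_id)
        regions, _ = make_regions(spec)
        if any(r.end > len(ref) for r in regions):
            raise ValueError(f"anchor shift {shift} pushes a region past the reference")
        summary, _, _ = run_scan(ref, regions, g4_cfg, skew_window=len(ref))
        summary.insert(0, "anchor_shift", shift)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def run_mutations(
    ref: str,
    clones: Sequence[tuple[str, str]],
    exclude_bisulfite_like: bool = False,
    motif_hits: Sequence[mt.MotifHit] = (),
    motif_flank: int = 5,
) -> tuple[list[mu.MutationRecord], mu.MutationSummary]:
    """call_mutations over a clone set, optional motif annotation, then
    mutation_frequency over total aligned nucleotides."""
    records: list[mu.MutationRecord] = []
    total_nt = 0
    for clone_id, seq in clones:
        aln = bf.align_clone(seq, ref)
        recs, _ = mu.call_mutations(
            seq,
            ref,
            clone_id=clone_id,
            exclude_bisulfite_like=exclude_bisulfite_like,
            alignment=aln,
        )
        records.extend(recs)
        total_nt += sum(
            1 for rp, qp in aln.columns if rp is not None and qp is not None
        )
    if motif_hits:
        records = mu.annotate_mutations(records, motif_hits, flank=motif_flank)
    summary = mu.mutation_frequency(records, total_nt)
    return records, summary
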