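import math
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bisfoot.bisulfite import (
    AlignmentRejected,
    ConversionCall,
    ConversionProfile,
    StretchConfig,
    align_clone,
    apply_cpg_rule,
    assign_strand,
    bisulfite_reference,
    call_conversions,
    call_footprints,
    classify_clone,
    compare_conditions,
    find_stretches,
    positionwise_frequency,
)
from bisfoot.simulate import SimParams, simulate_bisulfite_clones, simulate_reference

from conftest import make_profile

REF = "ACGTCCGGTACGTCAGTTGACGCATCGGAT"


class TestBisulfiteReference:
    @pytest.mark.parametrize(
        "seq,strand,expected",
        [
            ("ACGT", "top", "ATGT"),
            ("AACG", "bottom", "AACA"),
            ("TTTT", "top", "TTTT"),
            ("GGGG", "bottom", "AAAA"),
        ],
    )
    def test_full_conversion(self, seq, strand, expected):
        assert bisulfite_reference(seq, strand) == expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            bisulfite_reference("ACGN", "top")


class TestAlignClone:
    def test_identity(self):
        aln = align_clone(REF, REF)
        assert aln.identity == 1.0
        assert all(rp is not None and qp is not None for rp, qp in aln.columns)

    def test_fully_converted_clone_aligns_without_gaps(self):
        for strand in ("top", "bottom"):
            clone = bisulfite_reference(REF, strand)
            aln = align_clone(clone, REF)
            assert len(aln.columns) == len(REF)
            assert all(rp is not None and qp is not None for rp, qp in aln.columns)

    def test_internal_deletion_gives_gap_columns(self):
        clone = REF[:10] + REF[12:]
        aln = align_clone(clone, REF)
        gaps = [(rp, qp) for rp, qp in aln.columns if qp is None]
        assert len(gaps) == 2
        covered = [rp for rp, qp in aln.columns if rp is not None and qp is not None]
        assert len(covered) == len(REF) - 2

    def test_low_identity_rejected(self):
        clone = "T" * len(REF)
        with pytest.raises(AlignmentRejected):
            align_clone(clone, REF)


class TestAssignStrand:
    def test_majority_ct_is_top(self):
        # ref has Cs at 8 chosen positions converted and one G->A error
        ref = "ACAC" * 6  # 12 C's
        clone = list(ref)
        c_idx = [i for i, b in enumerate(ref) if b == "C"]
        for i in c_idx[:8]:
            clone[i] = "T"
        strand, score = assign_strand("".join(clone), ref)
        assert strand == "top"
        assert score == 1.0

    def test_mixed_counts_score(self):
        # 8 C->T against 1 G->A: top with score 8/9
        ref = "CA" * 8 + "GA"
        clone = "TA" * 8 + "AA"
        strand, score = assign_strand(clone, ref)
        assert strand == "top"
        assert score == pytest.approx(8 / 9)

    def test_identical_clone_undetermined(self):
        strand, score = assign_strand(REF, REF)
        assert strand == "undetermined"
        assert score == 0.0

    def test_one_sided_bottom(self):
        ref = "GT" * 12
        clone = "AT" * 12
        strand, score = assign_strand(clone, ref)
        assert (strand, score) == ("bottom", 1.0)

    def test_below_minimum_informative(self):
        ref = "ACTTTTTTTTTA"
        clone = "ATTTTTTTTTTA"  # a single C->T
        strand, _ = assign_strand(clone, ref)
        assert strand == "undetermined"


class TestCallConversions:
    def test_manual_enumeration(self):
        profile = call_conversions("ATCGTT", "ACCGTC", "top")
        by_pos = {c.ref_pos: c for c in profile.calls}
        assert set(by_pos) == {1, 2, 5}
        assert (by_pos[1].status, by_pos[1].context) == ("converted", "non-CpG")
        assert (by_pos[2].status, by_pos[2].context) == ("unconverted", "CpG")
        assert (by_pos[5].status, by_pos[5].context) == ("converted", "non-CpG")

    @pytest.mark.parametrize("strand", ["top", "bottom"])
    def test_fully_converted_round_trip(self, strand):
        clone = bisulfite_reference(REF, strand)
        profile = call_conversions(clone, REF, strand)
        assert profile.calls  # informative positions exist
        assert all(c.status == "converted" for c in profile.calls)
        assert profile.n_mismatch_other == 0

    @pytest.mark.parametrize("strand", ["top", "bottom"])
    def test_unconverted_clone(self, strand):
        profile = call_conversions(REF, REF, strand)
        assert all(c.status == "unconverted" for c in profile.calls)

    def test_bottom_strand_cpg_context(self):
        # top CG at 2-3: the bottom-strand C sits at top G (pos 3)
        profile = call_conversions("AACGAA", "AACGAA", "bottom")
        (call,) = profile.calls
        assert (call.ref_pos, call.context) == (3, "CpG")

    def test_undetermined_strand_rejected(self):
        with pytest.raises(ValueError, match="assign_strand"):
            call_conversions(REF, REF, "undetermined")

    def test_gap_columns_excluded(self):
        # deletes "CA" at 13-14, a context where the gap placement is
        # unambiguous even under C/T-neutral scoring
        clone = REF[:13] + REF[15:]
        profile = call_conversions(clone, REF, "top")
        by_pos = {c.ref_pos: c for c in profile.calls}
        assert by_pos[13].status == "excluded"


class TestCpGRule:
    def test_preceded_by_run_kept(self):
        prof = make_profile("11111", contexts=["non-CpG"] * 4 + ["CpG"])
        out = apply_cpg_rule(prof, 4)
        assert out.calls[4].status == "converted"

    def test_broken_run_excluded(self):
        prof = make_profile("10111", contexts=["non-CpG"] * 4 + ["CpG"])
        out = apply_cpg_rule(prof, 4)
        assert out.calls[4].status == "excluded"

    def test_k_zero_is_identity(self):
        prof = make_profile("10101", contexts=["non-CpG", "CpG"] * 2 + ["CpG"])
        out = apply_cpg_rule(prof, 0)
        assert [c.status for c in out.calls] == [c.status for c in prof.calls]

    def test_too_few_preceding_calls_excluded(self):
        prof = make_profile("111", contexts=["non-CpG"] * 2 + ["CpG"])
        assert apply_cpg_rule(prof, 4).calls[2].status == "excluded"

    def test_bottom_strand_reads_descending(self):
        # for bottom-strand molecules 5'->3' runs toward lower top
        # coordinates, so the certifying run sits at higher positions
        prof = make_profile(
            "11111", contexts=["CpG"] + ["non-CpG"] * 4, strand="bottom"
        )
        assert apply_cpg_rule(prof, 4).calls[0].status == "converted"

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from("10EM"), st.booleans()),
            min_size=1,
            max_size=40,
        ),
        st.integers(0, 6),
        st.sampled_from(["top", "bottom"]),
    )
    def test_idempotent_and_noncpg_untouched(self, spec, k, strand):
        statuses = "".join(s for s, _ in spec)
        contexts = ["CpG" if c else "non-CpG" for _, c in spec]
        prof = make_profile(statuses, contexts=contexts, strand=strand)
        once = apply_cpg_rule(prof, k)
        twice = apply_cpg_rule(once, k)
        assert [c.status for c in once.calls] == [c.status for c in twice.calls]
        for before, after in zip(prof.calls, once.calls):
            if before.context != "CpG":
                assert before.status == after.status


def brute_force_continuous(calls, min_run):
    """Independent oracle: regex run scan over the status string."""
    s = "".join("1" if c.status == "converted" else "." for c in calls)
    out = []
    for m in re.finditer(r"1+", s):
        if m.end() - m.start() >= min_run:
            seg = calls[m.start() : m.end()]
            out.append((seg[0].ref_pos, seg[-1].ref_pos, len(seg)))
    return out


def brute_force_windowed(calls, window, min_in):
    """Independent oracle: evaluate every window slice, merge by index."""
    usable = [c for c in calls if c.status != "excluded"]
    flags = [c.status == "converted" for c in usable]
    qualifying = [
        i
        for i in range(0, len(usable) - window + 1)
        if sum(flags[i : i + window]) >= min_in
    ]
    merged = []
    for q in qualifying:
        if merged and q <= merged[-1][1]:
            merged[-1][1] = q + window - 1
        else:
            merged.append([q, q + window - 1])
    return [
        (usable[lo].ref_pos, usable[hi].ref_pos, sum(flags[lo : hi + 1]))
        for lo, hi in merged
    ]


class TestFindStretches:
    def test_simple_run(self):
        prof = make_profile("1" * 12)
        out = find_stretches(prof, StretchConfig(min_run=10))
        cont = [s for s in out if s.kind == "continuous"]
        assert len(cont) == 1
        assert cont[0].n_converted == 12

    def test_windowed_dense_conversion(self):
        statuses = "111011101111111"  # 13 of 15 converted
        prof = make_profile(statuses)
        out = find_stretches(prof, StretchConfig(min_run=14, window=15, min_in_window=12))
        windowed = [s for s in out if s.kind == "windowed"]
        assert len(windowed) == 1
        assert windowed[0].n_converted == 13

    def test_all_unconverted(self):
        prof = make_profile("0" * 20)
        assert find_stretches(prof, StretchConfig()) == []

    def test_excluded_breaks_continuous_run(self):
        prof = make_profile("11111E11111")
        out = find_stretches(prof, StretchConfig(min_run=5))
        cont = [s for s in out if s.kind == "continuous"]
        assert [s.n_converted for s in cont] == [5, 5]

    def test_excluded_skipped_in_windowed_mode(self):
        statuses = "1111E1111E1111"  # 12 converted in 12 usable calls
        prof = make_profile(statuses)
        out = find_stretches(prof, StretchConfig(min_run=99, window=12, min_in_window=12))
        assert [s.kind for s in out] == ["windowed"]

    def test_oracle_equivalence_on_random_call_strings(self):
        """Continuous and windowed detection match exhaustive brute
        force on 1,000 random call strings."""
        rng = np.random.default_rng(2024)
        cfg = StretchConfig(min_run=4, window=8, min_in_window=6)
        for _ in range(1000):
            n = int(rng.integers(1, 61))
            statuses = "".join(rng.choice(list("10EM"), p=[0.5, 0.3, 0.1, 0.1], size=n))
            positions = np.cumsum(rng.integers(1, 6, size=n)).tolist()
            prof = make_profile(statuses, positions=positions)
            got = find_stretches(prof, cfg)
            got_cont = [
                (s.start_pos, s.end_pos, s.n_converted)
                for s in got
                if s.kind == "continuous"
            ]
            got_win = [
                (s.start_pos, s.end_pos, s.n_converted)
                for s in got
                if s.kind == "windowed"
            ]
            assert got_cont == brute_force_continuous(prof.calls, cfg.min_run)
            assert got_win == brute_force_windowed(
                prof.calls, cfg.window, cfg.min_in_window
            )


class TestClassifyClone:
    @pytest.mark.parametrize(
        "statuses,expected",
        [
            ("1" * 16, "run_gt15"),
            ("1" * 11, "run_gt10"),
            ("1" * 10, "none"),
            ("0" * 30, "none"),
        ],
    )
    def test_run_thresholds(self, statuses, expected):
        prof = make_profile(statuses)
        assert classify_clone(prof, StretchConfig()) == expected

    def test_windowed_only(self):
        statuses = "111111110111011"  # longest run 8, but 13 of 15 in window
        prof = make_profile(statuses)
        assert classify_clone(prof, StretchConfig(window=15, min_in_window=12)) == "windowed_only"


class TestPositionwiseFrequency:
    def test_half_converted(self):
        profs = [
            make_profile("1", clone_id="a"),
            make_profile("0", clone_id="b"),
        ]
        out = positionwise_frequency(profs)
        assert out["fraction"].tolist() == [0.5]

    def test_all_excluded_position(self):
        profs = [make_profile("E", clone_id=c) for c in "ab"]
        out = positionwise_frequency(profs)
        assert out["n_covered"].tolist() == [0]
        assert math.isnan(out["fraction"].iloc[0])

    def test_excluded_reduces_denominator(self):
        profs = [make_profile("1", clone_id=f"c{i}") for i in range(7)]
        profs += [make_profile("0", clone_id="u0"), make_profile("0", clone_id="u1")]
        profs += [make_profile("E", clone_id="e0")]
        out = positionwise_frequency(profs)
        assert out["n_covered"].tolist() == [9]
        assert out["fraction"].iloc[0] == pytest.approx(7 / 9)

    def test_mixed_strand_rejected(self):
        profs = [
            make_profile("1", strand="top", clone_id="a"),
            make_profile("1", strand="bottom", clone_id="b"),
        ]
        with pytest.raises(ValueError, match="strand"):
            positionwise_frequency(profs)

    def test_conversion_mass_conserved(self):
        rng = np.random.default_rng(5)
        profs = [
            make_profile(
                "".join(rng.choice(list("10E"), size=20)), clone_id=f"c{i}"
            )
            for i in range(10)
        ]
        out = positionwise_frequency(profs)
        total_calls = sum(
            sum(c.status == "converted" for c in p.calls) for p in profs
        )
        assert out["n_converted"].sum() == total_calls
        frac = out["fraction"].dropna()
        assert ((frac >= 0) & (frac <= 1)).all()


def freq_frame(rows):
    return pd.DataFrame(rows, columns=["ref_pos", "n_converted", "n_covered", "fraction"])


class TestCallFootprints:
    def test_plateau_recovered(self):
        rows = [(p, 8, 10, 0.8) for p in range(100, 160)]
        rows += [(p, 0, 10, 0.0) for p in range(160, 300)]
        out = call_footprints(freq_frame(rows), 0.5, 30, 10)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 160)
        assert out[0].mean_conversion_fraction == pytest.approx(0.8, abs=0.1)

    def test_background_yields_nothing(self):
        rows = [(p, 0, 50, 0.02) for p in range(300)]
        assert call_footprints(freq_frame(rows), 0.5, 30, 10) == []

    def test_distant_plateaus_stay_separate(self):
        rows = [(p, 8, 10, 0.8) for p in range(0, 60)]
        rows += [(p, 0, 10, 0.0) for p in range(60, 260)]
        rows += [(p, 8, 10, 0.8) for p in range(260, 320)]
        out = call_footprints(freq_frame(rows), 0.5, 30, 20)
        assert [(f.start, f.end) for f in out] == [(0, 60), (260, 320)]

    def test_short_plateau_dropped(self):
        rows = [(p, 8, 10, 0.8) for p in range(100, 120)]
        assert call_footprints(freq_frame(rows), 0.5, 30, 10) == []

    def test_empty_table(self):
        assert call_footprints(freq_frame([]), 0.5, 30, 10) == []

    def test_supporting_clones_counted(self):
        rows = [(p, 9, 10, 0.9) for p in range(0, 40)]
        supporters = [
            make_profile("1" * 40, positions=list(range(40)), clone_id=f"s{i}")
            for i in range(3)
        ]
        nonsupporter = make_profile("0" * 40, positions=list(range(40)), clone_id="n")
        out = call_footprints(
            freq_frame(rows), 0.5, 30, 10, profiles=supporters + [nonsupporter]
        )
        assert out[0].n_supporting_clones == 3


class TestCompareConditions:
    def _simulate(self, footprints, seed, p_ss=0.95):
        params = SimParams(
            ref_length=400,
            footprints=footprints,
            p_ss=p_ss,
            p_bg=0.02,
            n_clones=50,
            strand_mix=1.0,
            seed=seed,
        )
        ref, _ = simulate_reference(params)
        clones, _ = simulate_bisulfite_clones(ref, params)
        return [
            call_conversions(seq, ref, "bottom", clone_id=cid) for cid, seq in clones
        ]

    def test_rnaseh_like_condition_has_no_long_runs(self):
        """Without footprints, background conversion at 2% cannot
        produce a run of more than ten conversions in 50 clones."""
        with_fp = self._simulate([("bottom", 150, 210)], seed=8)
        without_fp = self._simulate([], seed=9)
        table = compare_conditions(with_fp, without_fp, StretchConfig(), ("plus", "minus"))
        minus_row = table[table["condition"] == "minus"].iloc[0]
        assert minus_row["n_run_gt10"] == 0
        plus_row = table[table["condition"] == "plus"].iloc[0]
        assert plus_row["n_run_gt10"] >= 1
        assert plus_row["n_total"] == minus_row["n_total"] == 50

    def test_identical_sets_identical_rows(self):
        profs = self._simulate([("bottom", 150, 210)], seed=8)
        table = compare_conditions(profs, profs, StretchConfig())
        a, b = table.iloc[0], table.iloc[1]
        assert (a.drop("condition") == b.drop("condition")).all()
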