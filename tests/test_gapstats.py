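"""BTOP decoding, alignment summaries, best-hit filtering, pair statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from orthocanon.gapstats import (
    AlignmentSummary,
    BtopError,
    GAP_QUERY,
    GAP_SUBJECT,
    Gap,
    Identity,
    Mismatch,
    best_hit_filter,
    decode_btop,
    encode_btop,
    expanded_length,
    proteome_pair_stats,
    summarize_alignment,
)
from orthocanon.io import SearchHit


def hit(btop, align_len=0, pid=0.0, qlen=500, evalue=1e-30, **kw):
    return SearchHit(
        query_acc=kw.get("query_acc", "Q1"),
        subject_acc=kw.get("subject_acc", "S1"),
        percent_identity=pid,
        align_len=align_len or expanded_length(decode_btop(btop)),
        e_value=evalue,
        bit_score=kw.get("bit_score", 100.0),
        query_len=qlen,
        subject_len=kw.get("subject_len", 500),
        btop=btop,
    )


class TestDecodeBtop:
    def test_pure_identity_run(self):
        assert decode_btop("259") == [Identity(259)]

    def test_mismatch_splits_runs(self):
        events = decode_btop("10AG5")
        assert events == [Identity(10), Mismatch("A", "G"), Identity(5)]
        assert expanded_length(events) == 16

    def test_adjacent_query_gaps_merge(self):
        events = decode_btop("4-A-A2")
        assert events == [Identity(4), Gap(GAP_QUERY, "AA"), Identity(2)]
        assert events[1].length == 2

    def test_subject_gap_side(self):
        events = decode_btop("3K-2")
        assert events[1] == Gap(GAP_SUBJECT, "K")

    def test_opposite_side_gaps_do_not_merge(self):
        events = decode_btop("1-AK-1")
        assert events[1:3] == [Gap(GAP_QUERY, "A"), Gap(GAP_SUBJECT, "K")]

    def test_illegal_pair_reports_offset(self):
        with pytest.raises(BtopError, match="offset 2"):
            decode_btop("12*-")

    def test_dangling_character(self):
        with pytest.raises(BtopError, match="dangling"):
            decode_btop("12A")

    def test_encode_inverts_decode(self):
        for s in ["259", "10AG5", "4-A-A2", "3K-2", "1-AK-1", "KR5-G-G10W-"]:
            assert encode_btop(decode_btop(s)) == s

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.one_of(
                st.integers(1, 300).map(Identity),
                st.tuples(
                    st.sampled_from("ACDKR"), st.sampled_from("GHWYE")
                ).map(lambda t: Mismatch(*t)),
                st.tuples(
                    st.sampled_from([GAP_QUERY, GAP_SUBJECT]),
                    st.text(alphabet="ACDKR", min_size=1, max_size=8),
                ).map(lambda t: Gap(*t)),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_round_trip_preserves_events(self, events):
        # canonicalize first: adjacent identity runs / same-side gaps are
        # not representable as distinct BTOP tokens
        merged = []
        for ev in events:
            if merged and isinstance(ev, Identity) and isinstance(merged[-1], Identity):
                merged[-1] = Identity(merged[-1].length + ev.length)
            elif (
                merged
                and isinstance(ev, Gap)
                and isinstance(merged[-1], Gap)
                and merged[-1].side == ev.side
            ):
                merged[-1] = Gap(ev.side, merged[-1].residues + ev.residues)
            else:
                merged.append(ev)
        events = merged
        decoded = decode_btop(encode_btop(events))
        assert expanded_length(decoded) == expanded_length(events)
        assert sum(e.length for e in decoded if isinstance(e, Gap)) == sum(
            e.length for e in events if isinstance(e, Gap)
        )
        assert encode_btop(decode_btop(encode_btop(decoded))) == encode_btop(decoded)


class TestSummarize:
    def test_gapless_alignment(self):
        s = summarize_alignment(hit("100"))
        assert s.max_gap == 0 and s.percent_identity == 100.0

    def test_long_insertion_like_intro_example(self):
        # ~96%-identical alignment with a single 104-residue subject-side
        # insertion (gap in the query row)
        btop = "150" + "-A" * 104 + "KR" * 10 + "131"
        s = summarize_alignment(hit(btop))
        assert s.max_gap == 104
        assert s.align_len == 150 + 104 + 10 + 131
        assert s.percent_identity == pytest.approx(
            100 * (150 + 131) / s.align_len
        )

    def test_gap_threshold_counts(self):
        btop = "10" + "A-" * 3 + "20" + "-K" * 7 + "5"
        s = summarize_alignment(hit(btop))
        assert s.max_gap == 7
        assert s.n_gaps_ge(5) == 1
        assert s.n_gaps_ge(3) == 2

    def test_align_len_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align_len"):
            summarize_alignment(hit("100", align_len=99))

    def test_printed_identity_cross_checked(self):
        with pytest.raises(ValueError, match="identity"):
            summarize_alignment(hit("50AG49", pid=50.0))

    def test_conservation_invariant(self):
        for btop in ["259", "10AG5", "4-A-A2", "150-K-K10WY30"]:
            events = decode_btop(btop)
            s = summarize_alignment(hit(btop))
            runs = sum(e.length for e in events if isinstance(e, Identity))
            mms = sum(1 for e in events if isinstance(e, Mismatch))
            gaps = sum(e.length for e in events if isinstance(e, Gap))
            assert runs + mms + gaps == s.align_len


class TestBestHitFilter:
    def test_short_query_dropped(self):
        assert best_hit_filter([hit("200", qlen=80)]) == []

    def test_boundary_query_length_dropped(self):
        assert best_hit_filter([hit("200", qlen=100)]) == []

    def test_lowest_evalue_wins(self):
        h1 = hit("200", evalue=1e-8, subject_acc="S1")
        h2 = hit("300", evalue=1e-12, subject_acc="S2")
        (kept,) = best_hit_filter([h1, h2])
        assert kept.subject_acc == "S2"

    def test_evalue_boundary_strict(self):
        assert best_hit_filter([hit("200", evalue=1e-6)]) == []
        assert best_hit_filter([hit("200", evalue=9.9e-7)]) != []

    def test_bit_score_breaks_evalue_ties(self):
        h1 = hit("200", evalue=1e-8, bit_score=100.0, subject_acc="S1")
        h2 = hit("300", evalue=1e-8, bit_score=200.0, subject_acc="S2")
        (kept,) = best_hit_filter([h1, h2])
        assert kept.subject_acc == "S2"


def summary(pid_percent, max_gap, i=0):
    n_cols = 1000
    nid = round(pid_percent / 100 * n_cols)
    gaps = [(GAP_SUBJECT, max_gap)] if max_gap else []
    return AlignmentSummary(
        query_acc=f"Q{i}", subject_acc=f"S{i}", align_len=n_cols,
        n_identical=nid, gap_events=gaps,
    )


class TestPairStats:
    def test_all_gapless_fractions_zero(self):
        stats = proteome_pair_stats([summary(95, 0, i) for i in range(10)])
        assert stats.gap_ge_frac_gt90[5] == 0.0
        assert (stats.table["frac_gap_ge_5"] == 0).all()

    def test_planted_twenty_percent(self):
        summaries = [summary(95, 8 if i < 2 else 0, i) for i in range(10)]
        stats = proteome_pair_stats(summaries)
        assert stats.n_gt90 == 10
        assert stats.gap_ge_frac_gt90[5] == pytest.approx(0.2)

    def test_bins_are_half_open(self):
        summaries = [summary(90.0, 0, 0), summary(91.0, 0, 1)]
        stats = proteome_pair_stats(summaries, id_bins=[90.0, 91.0, 92.0])
        assert stats.table.loc[0, "n"] == 1  # [90, 91) holds exactly 90.0
        assert stats.table.loc[1, "n"] == 1
        # the >90% subset is strict: 90.0 excluded
        assert stats.n_gt90 == 1

    def test_identity_100_lands_in_default_bins(self):
        stats = proteome_pair_stats([summary(100, 0)])
        assert stats.table["n"].sum() == 1

    def test_empty_input(self):
        stats = proteome_pair_stats([])
        assert stats.n_alignments == 0 and stats.frac_gt90 == 0.0
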