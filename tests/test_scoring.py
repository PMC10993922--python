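"""Cleavage ratio/score arithmetic, candidate windows, G-restriction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boseq.counts import StartCountTable
from boseq.reference import ReferenceSet
from boseq.scoring import (
    CandidateSite,
    call_candidates,
    cleavage_ratio,
    cleavage_score,
    compare_conditions,
    score_table,
)


def make_ref(seqs):
    ref = ReferenceSet()
    for cid, seq in seqs.items():
        ref.contigs[cid] = seq
        ref.members[cid] = [cid]
        ref.isoacceptor_of[cid] = cid
    return ref


def make_table(condition, starts, totals):
    """starts: {(contig, pos_1based): n}; internal storage is 0-based."""
    table = StartCountTable(condition=condition)
    table.starts = {(c, p - 1): n for (c, p), n in starts.items()}
    table.raw_starts = dict(table.starts)
    table.totals = dict(totals)
    return table


class TestRatioAndScore:
    @pytest.mark.parametrize(
        "n,total,alpha,expected",
        [(640, 1000, 0.0, 0.64), (0, 1000, 0.5, 0.0005), (1000, 1000, 0.0, 1.0)],
    )
    def test_ratio_values(self, n, total, alpha, expected):
        assert cleavage_ratio(n, total, alpha) == pytest.approx(expected)

    def test_ratio_rejects_zero_total(self):
        with pytest.raises(ValueError):
            cleavage_ratio(1, 0)

    def test_score_values(self):
        assert cleavage_score(0.3, 0.3) == 0.0
        # 0.64 / 0.005 = 128 = 2^7
        assert cleavage_score(0.64, 0.005) == pytest.approx(7.0)

    @given(
        st.floats(1e-6, 1.0),
        st.floats(1e-6, 1.0),
    )
    def test_antisymmetric_under_swap(self, rt, ru):
        assert cleavage_score(rt, ru) == pytest.approx(-cleavage_score(ru, rt))

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            cleavage_score(0.0, 0.5)


class TestScoreTable:
    def test_matches_independent_oracle_on_randomized_tables(self):
        rng = np.random.default_rng(42)
        ref = make_ref({"c": "".join(rng.choice(list("ACGT"), 40)) })
        worst = 0.0
        for _ in range(200):
            alpha = float(rng.choice([0.5, 1.0, 0.25]))
            n_t = rng.integers(0, 200, size=40)
            n_u = rng.integers(0, 200, size=40)
            N_t = int(n_t.sum() + rng.integers(1, 100))
            N_u = int(n_u.sum() + rng.integers(1, 100))
            treated = make_table(
                "treated",
                {("c", p + 1): int(n) for p, n in enumerate(n_t) if n},
                {"c": N_t},
            )
            untreated = make_table(
                "untreated",
                {("c", p + 1): int(n) for p, n in enumerate(n_u) if n},
                {"c": N_u},
            )
            df = score_table(treated, untreated, ref, alpha=alpha)
            oracle = [
                math.log2(((n_t[p] + alpha) / N_t) / ((n_u[p] + alpha) / N_u))
                for p in range(40)
            ]
            worst = max(worst, float(np.abs(df["score"].to_numpy() - oracle).max()))
        assert worst <= 1e-9

    def test_exact_power_of_two_score(self):
        # n_t = 128k, n_u = k, alpha = 0, equal totals -> exactly 7
        ref = make_ref({"c": "ACGT" * 3})
        k = 5
        treated = make_table("treated", {("c", p): 128 * k for p in range(1, 13)}, {"c": 10_000})
        untreated = make_table("untreated", {("c", p): k for p in range(1, 13)}, {"c": 10_000})
        df = score_table(treated, untreated, ref, alpha=0.0)
        assert np.allclose(df["score"], 7.0, atol=1e-12)

    def test_symmetric_pseudocount_gives_zero_on_equal_tables(self):
        ref = make_ref({"c": "ACGTACGT"})
        t = make_table("treated", {}, {"c": 500})
        u = make_table("untreated", {}, {"c": 500})
        df = score_table(t, u, ref, alpha=0.5)
        assert (df["score"] == 0.0).all()

    def test_swap_negates_every_score(self):
        ref = make_ref({"c": "ACGTACGTAC"})
        t = make_table("treated", {("c", 3): 40, ("c", 7): 11}, {"c": 300})
        u = make_table("untreated", {("c", 3): 2}, {"c": 280})
        forward = score_table(t, u, ref)["score"].to_numpy()
        u2 = make_table("treated", {("c", 3): 2}, {"c": 280})
        t2 = make_table("untreated", {("c", 3): 40, ("c", 7): 11}, {"c": 300})
        backward = score_table(u2, t2, ref)["score"].to_numpy()
        assert np.array_equal(forward, -backward)

    def test_monotone_in_treated_count(self):
        ref = make_ref({"c": "ACGTACGT"})
        u = make_table("untreated", {("c", 3): 5}, {"c": 100})
        scores = []
        for n in (0, 5, 20, 60):
            t = make_table("treated", {("c", 3): n}, {"c": 100})
            df = score_table(t, u, ref)
            scores.append(float(df.loc[df["position"] == 3, "score"].iloc[0]))
        assert scores == sorted(scores)

    def test_same_condition_label_rejected(self):
        ref = make_ref({"c": "ACGT"})
        t = make_table("treated", {}, {"c": 10})
        with pytest.raises(ValueError):
            score_table(t, t, ref)

    def test_contig_missing_from_one_condition_is_skipped(self):
        ref = make_ref({"c": "ACGT", "d": "GGTT"})
        t = make_table("treated", {}, {"c": 10, "d": 10})
        u = make_table("untreated", {}, {"c": 10})
        df = score_table(t, u, ref)
        assert set(df["contig"]) == {"c"}

    def test_alpha_zero_with_zero_counts_raises(self):
        ref = make_ref({"c": "ACGT"})
        t = make_table("treated", {("c", 1): 4}, {"c": 10})
        u = make_table("untreated", {}, {"c": 10})
        with pytest.raises(ValueError, match="alpha"):
            score_table(t, u, ref, alpha=0.0)


def table_for_calling(seq, scores, n_treated=50):
    """Score table with given per-position scores on one contig."""
    n = len(seq)
    return pd.DataFrame(
        {
            "contig": "c",
            "position": np.arange(1, n + 1),
            "ref_base": list(seq),
            "n_treated": [n_treated if s > 0 else 0 for s in scores],
            "N_treated": 1000,
            "n_untreated": 0,
            "N_untreated": 1000,
            "ratio_treated": 0.1,
            "ratio_untreated": 0.001,
            "score": scores,
        }
    )


class TestCalling:
    def test_single_qualifying_g_calls_itself(self):
        seq = "AAAAGAAA"
        scores = [0, 0, 0, 0, 8.0, 0, 0, 0]
        [cand] = call_candidates(table_for_calling(seq, scores), threshold=6.5)
        assert cand.g_position == 5 and cand.peak_position == 5

    def test_downstream_window_assigned_to_upstream_g(self):
        # G at 46-analogue (here position 4), qualifying stops at 5 and 6
        seq = "AAAGTTTT"
        scores = [0, 0, 0, 0, 7.2, 7.0, 0, 0]
        [cand] = call_candidates(table_for_calling(seq, scores), threshold=6.5)
        assert cand.g_position == 4
        assert cand.peak_position == 5
        assert cand.window == (5, 6)

    def test_no_g_in_window_discards(self):
        # off-target cleavage with no G at offsets 0..3 upstream of the peak
        seq = "AACTTTTT"
        scores = [0, 0, 0, 0, 8.0, 0, 0, 0]
        assert call_candidates(table_for_calling(seq, scores), threshold=6.5) == []

    def test_peak_tie_breaks_toward_smaller_position(self):
        seq = "AAGTTTTT"
        scores = [0, 0, 0, 7.0, 7.0, 0, 0, 0]
        [cand] = call_candidates(table_for_calling(seq, scores))
        assert cand.peak_position == 4

    def test_gap_splits_windows(self):
        seq = "AGAAAAAAAGAA"
        scores = [0, 7.0, 0, 0, 0, 0, 0, 0, 0, 7.5, 0, 0]
        cands = call_candidates(table_for_calling(seq, scores))
        assert [(c.g_position, c.window) for c in cands] == [(2, (2, 2)), (10, (10, 10))]

    def test_raising_threshold_shrinks_evidence_and_calls(self):
        # qualifying positions are monotone in the threshold, and on a
        # single-peak profile so is the candidate set
        seq = "AAGAAGAAGAAG"
        rng = np.random.default_rng(0)
        scores = list(rng.uniform(0, 10, size=12))
        for lo, hi in ((5.0, 7.5), (3.0, 9.0)):
            loose_q = {p + 1 for p, s in enumerate(scores) if s > lo}
            strict_q = {p + 1 for p, s in enumerate(scores) if s > hi}
            assert strict_q <= loose_q
        single_peak = [0, 0, 0, 0, 6.0, 8.0, 7.0, 0, 0, 0, 0, 0]
        loose = call_candidates(table_for_calling(seq, single_peak), threshold=5.0)
        strict = call_candidates(table_for_calling(seq, single_peak), threshold=7.5)
        assert {(c.contig_id, c.g_position) for c in strict} <= {
            (c.contig_id, c.g_position) for c in loose
        }
        assert len(strict) <= len(loose)

    def test_pseudocount_only_positions_never_qualify(self):
        # score above threshold but zero observed treated starts
        seq = "AAAAGAAA"
        table = table_for_calling(seq, [0, 0, 0, 0, 8.0, 0, 0, 0])
        table["n_treated"] = 0
        assert call_candidates(table, threshold=6.5) == []


class TestCompare:
    def site(self, contig, pos, iso=""):
        return CandidateSite(contig, pos, pos + 1, 7.0, (pos + 1, pos + 1), 40, iso)

    def test_identical_sets_all_both(self):
        calls = [self.site("c1", 46), self.site("c2", 46)]
        df = compare_conditions(calls, calls)
        assert (df["status"] == "both").all()

    def test_knockout_like_empty_set(self):
        df = compare_conditions([self.site("c1", 46), self.site("c2", 46)], [])
        assert (df["status"] == "a_only").all() and len(df) == 2

    def test_simulated_wt_vs_ko_recovers_planted_set(self, small_study, small_counts):
        from boseq.scoring import THRESHOLD_RELAXED

        ref = small_study["ref"]
        tables = small_counts["tables"]
        df = score_table(tables["treated"], tables["untreated"], ref)
        wt_calls = call_candidates(df, threshold=THRESHOLD_RELAXED, ref=ref)
        comp = compare_conditions(wt_calls, [])
        a_only = {(row.contig, row.g_position) for row in comp.itertuples()}
        planted = small_study["truth"].positions({"m7G"})
        assert a_only == planted
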