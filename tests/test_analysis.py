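"""Statistics pipeline: summaries, fits, correlations, and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autcage import analysis, schedule
from autcage.analysis import (
    InsufficientDataError,
    balanced_initiation_vs_hitrate,
    fit_psychometric,
    hit_rate_by_step,
    initiation_likelihood,
    latency_test,
    milestone_summary,
    partial_pearson,
    psi,
    session_summary,
    transition_analysis,
)


def make_frame(rows):
    defaults = dict(session_id="S1", trial_index=0, subject_true_id="A",
                    label_start="A", label_end="A", consistent=True, step=2,
                    milestone="size", sound_kind="none",
                    target_side_of_screen="center", outcome="correct",
                    initiation_time=0.0, response_latency=1.0,
                    reward_volume=0.5)
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestHitRate:
    def test_direct_ratio(self):
        df = make_frame([{"outcome": "correct"}] * 8 + [{"outcome": "wrong"}] * 2)
        out = hit_rate_by_step(df)
        assert out.loc[0, "hit_rate"] == pytest.approx(0.8)
        assert out.loc[0, "n"] == 10

    def test_ignored_trials_excluded(self):
        df = make_frame([{"outcome": "correct"}] * 3 + [{"outcome": "wrong"}]
                        + [{"outcome": "ignored"}] * 6)
        out = hit_rate_by_step(df)
        assert out.loc[0, "hit_rate"] == pytest.approx(0.75)
        assert out.loc[0, "n"] == 4

    def test_pooled_rate_is_weighted_mean_over_steps(self, group_frame):
        out = hit_rate_by_step(group_frame)
        pooled = (out["hit_rate"] * out["n"]).sum() / out["n"].sum()
        sc = group_frame[group_frame["outcome"].isin(["correct", "wrong"])]
        assert pooled == pytest.approx((sc["outcome"] == "correct").mean())


class TestMilestoneSummary:
    def test_toy_counts(self):
        rows = [{"session_id": f"S{1 + i % 2}", "milestone": "size"}
                for i in range(10)]
        out = milestone_summary(make_frame(rows))
        row = out.set_index(["subject_true_id", "milestone"]).loc[("A", "size")]
        assert row["trials"] == 10 and row["sessions"] == 2

    def test_unreached_milestone_absent(self):
        out = milestone_summary(make_frame([{"milestone": "size"}]))
        assert "distractor" not in set(out["milestone"])


class TestInitiationLikelihood:
    def test_every_correct_followed(self):
        rows = [{"trial_index": i, "initiation_time": 40.0 * i,
                 "response_latency": 1.0, "outcome": "correct"}
                for i in range(4)]
        # gaps are 40 s minus ~1 s latency => beyond the 30 s horizon
        out = initiation_likelihood(make_frame(rows), horizon=30.0)
        assert out.set_index("outcome").loc["correct", "likelihood"] == 0.0
        out10 = initiation_likelihood(make_frame(rows), horizon=60.0)
        # the last trial has no follow-up, so 3 of 4
        assert out10.set_index("outcome").loc["correct", "likelihood"] == 0.75

    def test_hand_enumerated_six_trial_log(self):
        # outcomes C W C W C C at t = 0, 10, 20, 100, 110, 200 (latency 1 s)
        # follow-up gaps: 9, 9, 79, 9, 89 -> within 30 s: yes yes no yes no
        # correct trials at 0, 20, 110, 200 -> followed: yes, no, no, (last: no)
        # wrong trials at 10, 100 -> followed: yes, yes
        rows = [
            {"trial_index": 0, "initiation_time": 0.0, "outcome": "correct"},
            {"trial_index": 1, "initiation_time": 10.0, "outcome": "wrong"},
            {"trial_index": 2, "initiation_time": 20.0, "outcome": "correct"},
            {"trial_index": 3, "initiation_time": 100.0, "outcome": "wrong"},
            {"trial_index": 4, "initiation_time": 110.0, "outcome": "correct"},
            {"trial_index": 5, "initiation_time": 200.0, "outcome": "correct"},
        ]
        out = initiation_likelihood(make_frame(rows)).set_index("outcome")
        assert out.loc["correct", "likelihood"] == pytest.approx(1 / 4)
        assert out.loc["wrong", "likelihood"] == pytest.approx(1.0)

    def test_session_boundary_not_crossed(self):
        rows = [
            {"session_id": "S1", "initiation_time": 0.0, "outcome": "correct"},
            {"session_id": "S2", "initiation_time": 5.0, "outcome": "correct"},
        ]
        out = initiation_likelihood(make_frame(rows)).set_index("outcome")
        assert out.loc["correct", "likelihood"] == 0.0


class TestBalancedBlocks:
    def _frame_with_coupling(self, constant=False, n_per_step=120, seed=0):
        # initiation probability an increasing function of performance at
        # the trial level, so blocks with more corrects re-engage sooner
        rng = np.random.default_rng(seed)
        rows = []
        t = 0.0
        for step, p in [(31, 0.95), (40, 0.75), (50, 0.5)]:
            for i in range(n_per_step):
                outcome = "correct" if rng.random() < p else "wrong"
                follow = 0.9 if constant else (0.85 if outcome == "correct" else 0.25)
                gap = 5.0 if rng.random() < follow else 60.0
                rows.append({"trial_index": len(rows), "step": step,
                             "outcome": outcome, "initiation_time": t})
                t += gap
        return make_frame(rows)

    def test_monotone_coupling_gives_positive_correlation(self):
        df = self._frame_with_coupling()
        res = balanced_initiation_vs_hitrate(df, block=30,
                                             rng=np.random.default_rng(1))
        assert res.r > 0.3
        assert res.n_blocks >= 2

    def test_block_larger_than_dataset_errors(self):
        df = self._frame_with_coupling(n_per_step=10)
        with pytest.raises(InsufficientDataError):
            balanced_initiation_vs_hitrate(df, block=10_000)

    def test_blocks_are_step_balanced(self):
        df = self._frame_with_coupling()
        res = balanced_initiation_vs_hitrate(df, block=30,
                                             rng=np.random.default_rng(2))
        assert res.per_step_quota == 10


class TestPartialPearson:
    def test_zero_covariates_equals_plain_pearson(self, rng):
        x, y = rng.normal(size=(2, 40))
        res = partial_pearson(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_orthogonal_covariate_is_a_noop(self, rng):
        n = 400
        x, y = rng.normal(size=(2, n))
        cov = np.tile([1.0, -1.0], n // 2)  # orthogonal in expectation
        res = partial_pearson(x, y, cov)
        r_ref, _ = stats.pearsonr(x, y)
        assert abs(res.r - r_ref) < 0.05

    def test_fully_mediated_correlation_vanishes(self, rng):
        n = 200
        c = rng.normal(size=n)
        y = c.copy()
        x = rng.normal(size=n)
        res = partial_pearson(x, y + 1e-9 * rng.normal(size=n), c)
        assert abs(res.r) < 0.2

    def test_matches_explicit_least_squares(self, rng):
        # independent route: residualize by hand with lstsq and correlate
        n = 10
        x, y, c = rng.normal(size=(3, n))
        res = partial_pearson(x, y, c)
        design = np.column_stack([np.ones(n), c])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert res.r == pytest.approx(float(stats.pearsonr(rx, ry)[0]), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        df = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n),
                           "c": rng.normal(size=n)})
        df["y"] += 0.5 * df["c"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        res = partial_pearson(df["x"], df["y"], df["c"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y, c = rng.normal(size=(3, 30))
        with pytest.raises(ValueError):
            partial_pearson(x, y, np.column_stack([c, c]))

    def test_ci_contains_r(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = partial_pearson(x, y)
        assert res.ci95[0] <= res.r <= res.ci95[1]


class TestPsychometric:
    LEVELS = np.array([schedule.size_difference(s) for s in range(31, 51)])

    def test_psi_midpoint(self):
        assert psi(25.0, 25.0, 10.0, 0.0, 0.5) == pytest.approx(0.75)

    def test_psi_width_convention(self):
        # S reaches 0.95 exactly one width above the threshold
        assert psi(35.0, 25.0, 10.0, 0.0, 0.0) == pytest.approx(0.95, abs=1e-9)

    def test_consistency_at_large_n(self, rng):
        p = psi(self.LEVELS, 25.0, 10.0, 0.0, 0.5)
        n = np.full(len(self.LEVELS), 10_000)
        k = rng.binomial(n, p)
        fit = fit_psychometric(self.LEVELS, k, n, n_boot=0, rng=rng)
        assert abs(fit.m - 25.0) < 0.5

    def test_level_order_invariance(self, rng):
        p = psi(self.LEVELS, 25.0, 10.0, 0.02, 0.5)
        n = np.full(len(self.LEVELS), 500)
        k = rng.binomial(n, p)
        fit1 = fit_psychometric(self.LEVELS, k, n, n_boot=0)
        perm = np.random.default_rng(0).permutation(len(self.LEVELS))
        fit2 = fit_psychometric(self.LEVELS[perm], k[perm], n[perm], n_boot=0)
        assert fit1.m == pytest.approx(fit2.m, abs=1e-4)

    def test_ceiling_data_flagged_degenerate(self, rng):
        n = np.full(len(self.LEVELS), 50)
        fit = fit_psychometric(self.LEVELS, n, n, n_boot=0, rng=rng)
        assert (not fit.converged) or fit.m < self.LEVELS.min()

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_psychometric([1, 2, 3], [5, 5, 5], [10, 10, 10])

    def test_ci_contains_estimate(self, rng):
        p = psi(self.LEVELS, 25.0, 10.0, 0.02, 0.5)
        n = np.full(len(self.LEVELS), 100)
        k = rng.binomial(n, p)
        fit = fit_psychometric(self.LEVELS, k, n, n_boot=100, rng=rng)
        assert fit.ci95_m[0] <= fit.m <= fit.ci95_m[1]


class TestLatency:
    def _frame(self, lat_by_kind, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for kind, (lo, hi) in lat_by_kind.items():
            for i in range(n):
                rows.append({"trial_index": len(rows), "sound_kind": kind,
                             "response_latency": float(rng.uniform(lo, hi))})
        return make_frame(rows)

    def test_disjoint_distributions_detected(self):
        df = self._frame({"vocalization": (0.1, 0.5), "tone": (2.0, 3.0)})
        out = latency_test(df)
        assert out["p_corrected"].iloc[0] < 0.01

    def test_identical_distributions_not_rejected_in_typical_draws(self):
        rejections = 0
        for seed in range(100):
            df = self._frame({"vocalization": (0.5, 1.5), "tone": (0.5, 1.5)},
                             n=30, seed=seed)
            out = latency_test(df)
            rejections += int(out["p"].iloc[0] < 0.05)
        assert rejections / 100 <= 0.12  # ≈ α with Monte-Carlo slack

    def test_single_group_subject_skipped(self):
        df = self._frame({"tone": (0.5, 1.5)})
        assert len(latency_test(df)) == 0

    def test_degenerate_two_singletons(self):
        df = make_frame([
            {"trial_index": 0, "sound_kind": "tone", "response_latency": 1.0},
            {"trial_index": 1, "sound_kind": "vocalization",
             "response_latency": 2.0},
        ])
        out = latency_test(df)
        assert len(out) == 1 and 0 < out["p"].iloc[0] <= 1.0


class TestTransitions:
    def _frame_from_bouts(self, bouts, session="S1", t0=0.0):
        rows = []
        for i, s in enumerate(bouts):
            rows.append({"session_id": session, "trial_index": i,
                         "subject_true_id": s,
                         "initiation_time": t0 + 10.0 * i})
        return make_frame(rows)

    def test_two_subjects_alternating(self):
        df = self._frame_from_bouts(["A", "B"] * 20)
        res = transition_analysis(df, n_perm=50, rng=np.random.default_rng(0))
        assert res.probs.loc["A", "B"] == 1.0
        assert res.probs.loc["B", "A"] == 1.0
        assert res.total_transitions == 39

    def test_counts_equal_bout_changes_and_probs_row_stochastic(self, group_frame):
        res = transition_analysis(group_frame, n_perm=20,
                                  rng=np.random.default_rng(0))
        seqs = 0
        for _, grp in group_frame.groupby("session_id"):
            s = grp.sort_values("initiation_time")["subject_true_id"].to_numpy()
            changes = (s[1:] != s[:-1]).sum()
            seqs += int(changes)
        assert res.total_transitions == seqs
        rows_with_mass = res.counts.sum(axis=1) > 0
        sums = res.probs.sum(axis=1)[rows_with_mass]
        assert np.allclose(sums, 1.0)

    def test_cyclic_sequence_hits_permutation_floor(self):
        df = self._frame_from_bouts(["A", "B", "C"] * 100)
        res = transition_analysis(df, n_perm=1000,
                                  rng=np.random.default_rng(7))
        for a, b in [("A", "B"), ("B", "C"), ("C", "A")]:
            assert res.p_values.loc[a, b] <= 3 / 1001

    def test_single_subject_rejected(self):
        df = self._frame_from_bouts(["A"] * 10)
        with pytest.raises(InsufficientDataError):
            transition_analysis(df, n_perm=10)

    def test_median_interval_measures_subject_changes(self):
        df = self._frame_from_bouts(["A", "A", "B", "B"])
        res = transition_analysis(df, n_perm=10, rng=np.random.default_rng(0))
        assert res.median_interval == pytest.approx(10.0)


class TestSessionSummary:
    def test_median_and_iqr(self):
        rows = []
        for sid, n in [("S1", 10), ("S2", 30), ("S3", 50)]:
            for i in range(n):
                rows.append({"session_id": sid, "trial_index": i,
                             "initiation_time": float(i)})
        out = session_summary(make_frame(rows))
        assert out["median_trials"] == 30.0
        assert out["iqr_trials"] == 20.0

    def test_all_trials_at_start(self):
        rows = [{"trial_index": i, "initiation_time": 0.0} for i in range(5)]
        assert session_summary(make_frame(rows))["time_to_half_trials"] == 0.0

    def test_time_to_half_hand_enumerated(self):
        # 4 trials at 0, 10, 20, 30 s: half the trials are in by t = 10
        rows = [{"trial_index": i, "initiation_time": 10.0 * i} for i in range(4)]
        assert session_summary(make_frame(rows))["time_to_half_trials"] == 10.0
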