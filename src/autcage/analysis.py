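"""Statistical pipeline over trial logs.

All functions operate on a tidy :class:`pandas.DataFrame` of trial records
(one row per trial, columns as written by :mod:`autcage.io`).  The pipeline
covers:

* engagement — trials per session, time-to-half-trials, the likelihood of
  initiating another trial within 30 s of a correct vs. wrong response, and
  a step-balanced resampling of that likelihood against hit rate;
* learning — hit rate per protocol step and per-milestone trial/session
  counts;
* psychophysics — maximum-likelihood cumulative-normal fits of the
  proportion correct against the target-distractor size difference, with
  parametric-bootstrap confidence intervals, plus rank-based latency tests;
* social structure — the Markov transition matrix of which subject takes
  over the device from which, against a within-session permutation null.

Hit rate is always correct / (correct + wrong); aborted ("ignored") trials
are excluded from scoring but keep their timestamps for engagement use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "psi",
    "PsychometricFit",
    "fit_psychometric",
    "PartialCorrResult",
    "partial_pearson",
    "hit_rate_by_step",
    "milestone_summary",
    "initiation_likelihood",
    "BalancedBlocksResult",
    "balanced_initiation_vs_hitrate",
    "latency_test",
    "TransitionTestResult",
    "transition_analysis",
    "session_summary",
    "InsufficientDataError",
]

_SCORED = ("correct", "wrong")

#: z-score of the 0.95 quantile; converts the 0.5→0.95 width w into the
#: standard deviation of the underlying cumulative normal.
_Z95 = float(stats.norm.ppf(0.95))


class InsufficientDataError(ValueError):
    """Raised when an analysis has too little data to be meaningful."""


# --------------------------------------------------------------------------
# psychometric function and fit

def psi(x, m, w, lam, gam):
    """Cumulative-normal psychometric function ψ(x; m, w, λ, γ).

    ψ = γ + (1 − λ − γ)·S(x), with S a normal CDF scaled so S(m) = 0.5 and
    S(m + w) = 0.95: m is the threshold (the level at the midpoint of the
    sigmoid span) and w the width between the 0.5 and 0.95 levels of S.
    γ is the guess rate (lower asymptote; 0.5 in a two-alternative choice)
    and λ the lapse rate (upper asymptote 1 − λ).
    """
    x = np.asarray(x, dtype=float)
    sigma = w / _Z95
    s = special.ndtr((x - m) / sigma)
    return gam + (1.0 - lam - gam) * s


@dataclass
class PsychometricFit:
    """Fitted psychometric parameters with a bootstrap CI on the threshold."""

    m: float
    w: float
    lam: float
    gam: float
    ci95_m: tuple[float, float]
    n_levels: int
    n_trials: int
    converged: bool

    def __call__(self, x):
        return psi(x, self.m, self.w, self.lam, self.gam)


def _neg_log_lik(params, x, k, n):
    m, w, lam, gam = params
    p = np.clip(psi(x, m, w, lam, gam), 1e-9, 1 - 1e-9)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _mle(x, k, n, bounds, starts):
    best = None
    for x0 in starts:
        res = optimize.minimize(_neg_log_lik, x0, args=(x, k, n),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_psychometric(
    levels: Sequence[float],
    n_correct: Sequence[int],
    n_total: Sequence[int],
    *,
    n_boot: int = 500,
    rng: Optional[np.random.Generator] = None,
) -> PsychometricFit:
    """Maximum-likelihood fit of ψ to binomial counts per stimulus level.

    The threshold m and width w are free; the asymptotes are box-constrained
    to λ ∈ [0, 0.1] and γ ∈ [0.4, 0.6] — the task is a two-alternative
    choice, so the lower asymptote is guessing near 0.5.  The 95% CI on m is
    a parametric bootstrap (counts redrawn from the fitted ψ, ``n_boot``
    refits, percentile interval widened if needed to contain the estimate).

    A degenerate or unconverged optimization is returned flagged with
    ``converged=False`` instead of raising.
    """
    x = np.asarray(levels, dtype=float)
    k = np.asarray(n_correct, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if not (x.shape == k.shape == n.shape):
        raise ValueError("levels, n_correct, n_total must have equal length")
    if len(np.unique(x)) < 4:
        raise InsufficientDataError("need at least 4 distinct stimulus levels")
    if (n < 1).any():
        raise ValueError("each level needs at least one trial")
    if (k > n).any() or (k < 0).any():
        raise ValueError("n_correct must lie in [0, n_total]")
    rng = rng if rng is not None else np.random.default_rng()

    lo, hi = float(x.min()), float(x.max())
    span = max(hi - lo, 1e-6)
    bounds = [(lo - span, hi + span), (1e-3, 10 * span), (0.0, 0.1), (0.4, 0.6)]
    starts = [
        (np.median(x), span / 2, 0.02, 0.5),
        (lo + 0.25 * span, span / 4, 0.02, 0.5),
        (lo + 0.75 * span, span, 0.05, 0.5),
    ]
    res = _mle(x, k, n, bounds, starts)
    m_hat, w_hat, lam_hat, gam_hat = res.x
    # no information about the threshold if the data never leave an asymptote
    p_obs = k / n
    degenerate = (p_obs.min() > 0.9) or (p_obs.max() < gam_hat + 0.05)
    converged = bool(res.success) and not degenerate

    boot_m = []
    if n_boot > 0:
        p_hat = np.clip(psi(x, *res.x), 1e-9, 1 - 1e-9)
        start = (tuple(res.x),)
        for _ in range(n_boot):
            kb = rng.binomial(n.astype(int), p_hat)
            rb = _mle(x, kb, n, bounds, start)
            boot_m.append(rb.x[0])
        lo_m, hi_m = np.percentile(boot_m, [2.5, 97.5])
    else:
        lo_m, hi_m = m_hat, m_hat
    ci = (min(float(lo_m), float(m_hat)), max(float(hi_m), float(m_hat)))

    return PsychometricFit(
        m=float(m_hat), w=float(w_hat), lam=float(lam_hat), gam=float(gam_hat),
        ci95_m=ci, n_levels=len(np.unique(x)), n_trials=int(n.sum()),
        converged=converged,
    )


# --------------------------------------------------------------------------
# partial correlation

@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    ci95: tuple[float, float]
    p: float
    n: int
    n_covariates: int


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    return v - design @ coef


def partial_pearson(x, y, covariates=None) -> PartialCorrResult:
    """Pearson correlation of x and y after projecting out covariates.

    Both variables are residualized against the covariates (with an
    intercept) by least squares and the residuals correlated.  With no
    covariates this is exactly the plain Pearson correlation.  The two-sided
    p-value comes from the t distribution on n − k − 2 degrees of freedom
    and the 95% CI from the Fisher z transform with effective size n − k − 3
    (k = number of covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if not (len(x) == len(y) == len(cov)):
        raise ValueError("x, y and covariates must have equal length")
    n, k = len(x), cov.shape[1]
    if n <= k + 3:
        raise InsufficientDataError(f"need n > k + 3 samples (n={n}, k={k})")

    design = np.column_stack([np.ones(n), cov])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("zero variance after residualization")
    r = float(rx @ ry) / denom
    r = max(-1.0, min(1.0, r))

    dof = n - k - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1 - r * r))
        p = 2 * float(stats.t.sf(abs(t), dof))
    z = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, r)))
    se = 1.0 / math.sqrt(n - k - 3)
    zc = float(stats.norm.ppf(0.975))
    ci = (math.tanh(z - zc * se), math.tanh(z + zc * se))
    return PartialCorrResult(r=r, ci95=ci, p=p, n=n, n_covariates=k)


# --------------------------------------------------------------------------
# engagement and learning summaries

def _scored(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["outcome"].isin(_SCORED)]


def hit_rate_by_step(records: pd.DataFrame) -> pd.DataFrame:
    """Hit rate per subject × step over scored trials.

    Returns a frame with columns ``subject_true_id, step, hit_rate, n``;
    subject/step cells without scored trials are absent.
    """
    sc = _scored(records)
    grp = sc.groupby(["subject_true_id", "step"], sort=True)["outcome"]
    out = grp.agg(
        hit_rate=lambda o: float((o == "correct").mean()),
        n="size",
    ).reset_index()
    return out


def milestone_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Scored trials and distinct sessions per subject × milestone."""
    sc = _scored(records)
    out = sc.groupby(["subject_true_id", "milestone"], sort=True).agg(
        trials=("outcome", "size"),
        sessions=("session_id", "nunique"),
    ).reset_index()
    return out


def _response_times(records: pd.DataFrame) -> pd.Series:
    """Moment the subject's response completed, seconds into the session."""
    lat = records["response_latency"].fillna(0.0)
    return records["initiation_time"] + lat


def _followed_within(records: pd.DataFrame, horizon: float) -> pd.Series:
    """Per scored trial: did the same subject initiate again within horizon?

    Evaluated within (session, subject); session boundaries are never
    crossed.  The returned boolean series is indexed like ``records`` and
    is NaN-free only on scored rows.
    """
    followed = pd.Series(False, index=records.index)
    for (_, _), grp in records.groupby(["session_id", "subject_true_id"], sort=False):
        grp = grp.sort_values("initiation_time")
        resp = _response_times(grp).to_numpy()
        init = grp["initiation_time"].to_numpy()
        idx = grp.index.to_numpy()
        for i in range(len(grp) - 1):
            followed[idx[i]] = bool(init[i + 1] - resp[i] <= horizon)
    return followed


def initiation_likelihood(records: pd.DataFrame, horizon: float = 30.0) -> pd.DataFrame:
    """Likelihood of initiating another trial within ``horizon`` seconds.

    For each scored outcome class, the fraction of responses of that class
    after which the same subject initiated its next trial within the horizon
    (session boundaries are not crossed).  Returns a frame with columns
    ``outcome, likelihood, n``.
    """
    followed = _followed_within(records, horizon)
    rows = []
    for outcome in _SCORED:
        mask = records["outcome"] == outcome
        n = int(mask.sum())
        rows.append({
            "outcome": outcome,
            "likelihood": float(followed[mask].mean()) if n else float("nan"),
            "n": n,
        })
    return pd.DataFrame(rows)


@dataclass
class BalancedBlocksResult:
    blocks: pd.DataFrame          # columns: block, hit_rate, initiation_likelihood
    r: float
    p: float
    per_step_quota: int
    n_blocks: int


def balanced_initiation_vs_hitrate(
    records: pd.DataFrame,
    block: int = 100,
    rng: Optional[np.random.Generator] = None,
    horizon: float = 30.0,
) -> BalancedBlocksResult:
    """Hit rate vs. initiation likelihood over step-balanced trial blocks.

    Scored trials are sampled without replacement into blocks of ``block``
    trials with equal representation of every step present (steps with
    fewer trials truncate the number of blocks; nothing is upsampled).
    Per block, the hit rate and the within-horizon initiation likelihood
    are computed and their Pearson correlation reported.
    """
    rng = rng if rng is not None else np.random.default_rng()
    sc = _scored(records).copy()
    if len(sc) < block:
        raise InsufficientDataError(
            f"block of {block} exceeds the {len(sc)} scored trials available")
    sc["_followed"] = _followed_within(records, horizon)[sc.index]

    steps = sorted(sc["step"].unique())
    quota = block // len(steps)
    if quota < 1:
        raise InsufficientDataError(
            f"block of {block} cannot represent all {len(steps)} steps")
    n_blocks = min(len(sc[sc["step"] == s]) // quota for s in steps)
    if n_blocks < 2:
        raise InsufficientDataError("fewer than 2 balanced blocks available")

    per_step_chunks = {}
    for s in steps:
        idx = sc.index[sc["step"] == s].to_numpy()
        rng.shuffle(idx)
        per_step_chunks[s] = idx
    rows = []
    for b in range(n_blocks):
        take = np.concatenate([per_step_chunks[s][b * quota:(b + 1) * quota]
                               for s in steps])
        blk = sc.loc[take]
        rows.append({
            "block": b,
            "hit_rate": float((blk["outcome"] == "correct").mean()),
            "initiation_likelihood": float(blk["_followed"].mean()),
        })
    blocks = pd.DataFrame(rows)
    r, p = stats.pearsonr(blocks["hit_rate"], blocks["initiation_likelihood"])
    return BalancedBlocksResult(blocks=blocks, r=float(r), p=float(p),
                                per_step_quota=quota, n_blocks=n_blocks)


def latency_test(records: pd.DataFrame, group_by: str = "sound_kind") -> pd.DataFrame:
    """Kruskal–Wallis test of response latency between cue types, per subject.

    Subjects lacking latencies in two or more groups are skipped.  The
    returned p-values carry a Bonferroni correction across the tested
    subjects (``p_corrected``, capped at 1).
    """
    sc = _scored(records).dropna(subset=["response_latency"])
    rows = []
    for subject, grp in sc.groupby("subject_true_id", sort=True):
        samples = [g["response_latency"].to_numpy()
                   for _, g in grp.groupby(group_by) if len(g) > 0]
        if len(samples) < 2:
            continue
        stat, p = stats.kruskal(*samples)
        rows.append({"subject_true_id": subject, "statistic": float(stat),
                     "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_corrected"] = np.minimum(out["p"] * len(out), 1.0)
    return out


# --------------------------------------------------------------------------
# turn-taking

@dataclass
class TransitionTestResult:
    """Observed subject-to-subject transitions and their permutation test."""

    subjects: list[str]
    counts: pd.DataFrame          # ordered-pair counts, i→j, diagonal 0
    probs: pd.DataFrame           # row-normalized where the row total > 0
    p_values: pd.DataFrame        # two-sided permutation p per ordered pair
    n_permutations: int
    total_transitions: int
    median_interval: float        # s between the bout-ending and bout-starting trials


def _collapse(seq: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicates, turning a trial sequence into bouts."""
    if len(seq) == 0:
        return seq
    keep = np.ones(len(seq), dtype=bool)
    keep[1:] = seq[1:] != seq[:-1]
    return seq[keep]


def _count_transitions(bouts: np.ndarray, n: int) -> np.ndarray:
    counts = np.zeros((n, n), dtype=np.int64)
    if len(bouts) >= 2:
        np.add.at(counts, (bouts[:-1], bouts[1:]), 1)
    return counts


def _sample_bout_orders(bouts: np.ndarray, n_perm: int,
                        rng: np.random.Generator,
                        batch: int = 4096, max_batches: int = 512) -> np.ndarray:
    """Draw ``n_perm`` uniform re-orderings of a bout sequence.

    The null re-orders a session's bouts while preserving each subject's
    bout count — but a plain shuffle of bout labels is not a realizable
    bout order: it places identical labels next to each other, which in a
    real log would have been a single bout, so naive shuffling
    systematically destroys transitions and inflates the test.  The correct
    reference set is the arrangements with the same composition and no
    adjacent duplicates, sampled uniformly here by generating memoryless
    "next subject differs from the current one" walks (every realizable
    arrangement is equally likely under such a walk) and keeping those that
    match the observed composition.  For compositions so skewed that the
    walk rarely matches, remaining replicates fall back to plain shuffles,
    whose surplus adjacencies are simply not counted.

    Returns an ``(n_perm, len(bouts))`` array of subject codes.
    """
    length = len(bouts)
    syms = np.unique(bouts)
    m = len(syms)
    if m < 2 or length < 2 or n_perm == 0:
        return np.tile(bouts, (max(n_perm, 1), 1))[:n_perm]
    codes = np.searchsorted(syms, bouts)
    target = np.bincount(codes, minlength=m)
    chunks = []
    n_have = 0
    for _ in range(max_batches):
        step = rng.integers(1, m, size=(batch, length))
        step[:, 0] = rng.integers(0, m, size=batch)
        seq = np.cumsum(step, axis=1) % m
        ok = np.ones(batch, dtype=bool)
        for s in range(m):
            ok &= (seq == s).sum(axis=1) == target[s]
        hit = seq[ok]
        if len(hit):
            chunks.append(hit)
            n_have += len(hit)
        if n_have >= n_perm:
            break
    if n_have:
        samples = np.concatenate(chunks)[:n_perm]
    else:
        samples = np.empty((0, length), dtype=np.int64)
    if len(samples) < n_perm:
        extra = np.stack([rng.permutation(codes)
                          for _ in range(n_perm - len(samples))])
        samples = np.concatenate([samples, extra])
    return syms[samples]


def transition_analysis(
    records: pd.DataFrame,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    across_sessions: bool = False,
) -> TransitionTestResult:
    """Markov turn-taking matrix with a bout-permutation null.

    The initiating-subject sequence of each session is collapsed into bouts
    (runs by one subject) and transitions counted between consecutive
    distinct subjects.  The null permutes each session's bout sequence,
    preserving every subject's bout count while keeping the permuted order
    a realizable bout sequence (no adjacent equal labels), and recounts;
    per ordered pair the two-sided p-value is
    ``min(1, 2·min(P(perm ≥ obs), P(perm ≤ obs)))`` with the (r+1)/(n+1)
    correction.  With ``across_sessions`` the transition from one session's
    last bout to the next session's first is also counted (and the bout
    pool permuted per session all the same).
    """
    rng = rng if rng is not None else np.random.default_rng()
    subjects = sorted(records["subject_true_id"].unique())
    code = {s: i for i, s in enumerate(subjects)}
    n = len(subjects)

    session_bouts: list[np.ndarray] = []
    intervals: list[float] = []
    for _, grp in records.groupby("session_id", sort=True):
        grp = grp.sort_values("initiation_time")
        seq = grp["subject_true_id"].map(code).to_numpy()
        bouts = _collapse(seq)
        session_bouts.append(bouts)
        # time gaps at the trials where the initiating subject changes
        t = grp["initiation_time"].to_numpy()
        chg = np.flatnonzero(seq[1:] != seq[:-1])
        intervals.extend((t[chg + 1] - t[chg]).tolist())

    if sum(len(np.unique(b)) > 1 for b in session_bouts) == 0:
        raise InsufficientDataError("need at least 2 subjects with bouts")

    def total_counts(bout_lists):
        c = np.zeros((n, n), dtype=np.int64)
        for b in bout_lists:
            c += _count_transitions(b, n)
        if across_sessions:
            for a, b in zip(bout_lists, bout_lists[1:]):
                if len(a) and len(b) and a[-1] != b[0]:
                    c[a[-1], b[0]] += 1
        return c

    obs = total_counts(session_bouts)
    # one null replicate = an independently re-ordered bout sequence per
    # session; transitions are counted between consecutive distinct bouts
    # (self-adjacencies from the fallback shuffle contribute nothing, which
    # is identical to collapsing them first)
    totals = np.zeros((n_perm, n * n), dtype=np.int64)
    samples = [_sample_bout_orders(b, n_perm, rng) for b in session_bouts]
    for smp in samples:
        if smp.shape[1] < 2:
            continue
        i, j = smp[:, :-1], smp[:, 1:]
        mask = (i != j).ravel()
        flat = (i * n + j).ravel()[mask]
        reps = np.repeat(np.arange(n_perm), smp.shape[1] - 1)[mask]
        np.add.at(totals, (reps, flat), 1)
    if across_sessions:
        for a, b in zip(samples, samples[1:]):
            if a.shape[1] == 0 or b.shape[1] == 0:
                continue
            last, first = a[:, -1], b[:, 0]
            mask = last != first
            np.add.at(totals, (np.arange(n_perm)[mask],
                               (last * n + first)[mask]), 1)
    totals = totals.reshape(n_perm, n, n)
    ge = (totals >= obs).sum(axis=0)
    le = (totals <= obs).sum(axis=0)
    p_ge = (ge + 1) / (n_perm + 1)
    p_le = (le + 1) / (n_perm + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_ge, p_le))
    np.fill_diagonal(p, 1.0)

    row_tot = obs.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_tot > 0, obs / np.where(row_tot == 0, 1, row_tot), 0.0)

    as_df = lambda a: pd.DataFrame(a, index=subjects, columns=subjects)
    return TransitionTestResult(
        subjects=subjects,
        counts=as_df(obs),
        probs=as_df(probs),
        p_values=as_df(p),
        n_permutations=n_perm,
        total_transitions=int(obs.sum()),
        median_interval=float(np.median(intervals)) if intervals else float("nan"),
    )


# --------------------------------------------------------------------------
# session descriptives

def session_summary(records: pd.DataFrame) -> dict:
    """Descriptive engagement summaries across sessions.

    Returns per-(subject, session) trial counts, their median and IQR, and
    the time-to-half-trials: the earliest session time by which at least
    half of all initiated trials (pooled over sessions) had been initiated.
    """
    per = records.groupby(["subject_true_id", "session_id"], sort=True).agg(
        trials=("trial_index", "size")).reset_index()
    counts = per["trials"].to_numpy(float)
    times = np.sort(records["initiation_time"].to_numpy(float))
    if len(times):
        half_idx = math.ceil(len(times) / 2) - 1
        time_to_half = float(times[half_idx])
    else:
        time_to_half = float("nan")
    q1, q3 = (np.percentile(counts, [25, 75]) if len(counts) else (np.nan, np.nan))
    return {
        "trials_per_session": per,
        "median_trials": float(np.median(counts)) if len(counts) else float("nan"),
        "iqr_trials": float(q3 - q1),
        "time_to_half_trials": time_to_half,
    }
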