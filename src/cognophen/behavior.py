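"""Behavioral metrics for the reversal-learning and conditioning tasks.

Implements the -1/0/+1 switch-response scoring, the choice-error and
switch-error trial selectors used to probe social performance monitoring,
accuracy time courses, anticipatory-licking differentiation and ratios, and
gaze region-of-interest proportions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from cognophen.epochs import DEFAULT_EPOCHS, EpochSpec
from cognophen.errors import DataError

NOT_REACHED = "not reached"


def score_switch_response(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every trial against the previous block's contingency and
    aggregate by trial index after the block switch.

    Per trial: score -1 when the chosen target was correct in the preceding
    block (perseveration error), 0 when it is correct in the current block,
    and +1 when it is the remaining target, wrong in both blocks (exploration
    error). Trials of the first block of a session (no preceding contingency)
    are excluded and counted in ``result.attrs["n_excluded_first_block"]``.

    Returns a frame indexed by ``trial_in_block`` with columns
    ``mean_score, sem, n``.
    """
    t = trials.copy()
    has_prev = t["correct_target_previous"].notna()
    n_excluded = int((~has_prev).sum())
    t = t[has_prev]
    score = np.where(
        t["chosen_target"] == t["correct_target_previous"], -1,
        np.where(t["chosen_target"] == t["correct_target_current"], 0, 1),
    )
    t = t.assign(score=score)
    g = t.groupby("trial_in_block")["score"]
    out = pd.DataFrame({
        "mean_score": g.mean(),
        "sem": g.sem(ddof=1),
        "n": g.size(),
    })
    out.attrs["n_excluded_first_block"] = n_excluded
    return out


def _require_social(trials: pd.DataFrame) -> None:
    if set(trials["actor"].unique()) < {"self", "partner"}:
        raise DataError("selector requires a social-mode table with both actors")


def select_choice_error_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Self-actor trials immediately following a partner choice error.

    A trial qualifies when (1) the immediately preceding trial (same day,
    same block, not a switch trial) was a partner action that went
    unrewarded, and (2) the current block's correct target had already been
    selected by either animal earlier in the block — i.e. the contingency
    was in principle known, so the optimal response is to keep choosing the
    current correct target (exploitation).
    """
    _require_social(trials)
    t = trials.reset_index(drop=True)
    picked = []
    for i in range(1, len(t)):
        cur, prev = t.iloc[i], t.iloc[i - 1]
        if cur["actor"] != "self" or cur["session_day"] != prev["session_day"]:
            continue
        if cur["block_id"] != prev["block_id"] or cur["trial_in_block"] == 1:
            continue
        if prev["actor"] != "partner" or prev["rewarded"]:
            continue
        if prev["trial_in_block"] == 1:  # switch error, handled elsewhere
            continue
        block = t[(t["block_id"] == cur["block_id"])
                  & (t.index < i - 1)]
        if not (block["chosen_target"] == cur["correct_target_current"]).any():
            continue  # condition (2): correct target never yet selected
        picked.append(i)
    return t.loc[picked]


def select_switch_error_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Self-actor trials immediately following a partner switch error.

    A trial qualifies when the preceding trial was the block's switch trial
    (first trial after an unsignaled contingency change), taken by the
    partner, and the partner selected the preceding block's correct target.
    The optimal response is either of the two targets the partner did not
    choose (exploration).
    """
    _require_social(trials)
    t = trials.reset_index(drop=True)
    picked = []
    for i in range(1, len(t)):
        cur, prev = t.iloc[i], t.iloc[i - 1]
        if cur["actor"] != "self" or cur["session_day"] != prev["session_day"]:
            continue
        if cur["block_id"] != prev["block_id"]:
            continue
        if prev["trial_in_block"] != 1 or prev["actor"] != "partner" or prev["rewarded"]:
            continue
        if pd.isna(prev["correct_target_previous"]):
            continue
        if prev["chosen_target"] != prev["correct_target_previous"]:
            continue  # not a perseverative switch error
        picked.append(i)
    return t.loc[picked]


def accuracy_after(selected: pd.DataFrame, smoothing_window: int = 1) -> pd.DataFrame:
    """Per-day proportion correct among selected trials, with binomial SEM.

    ``smoothing_window`` > 1 applies a centered rolling mean over days.
    An empty selection yields an empty series, not an error.
    """
    if selected.empty:
        return pd.DataFrame(columns=["accuracy", "sem", "n"])
    g = selected.groupby("session_day")["rewarded"]
    p = g.mean()
    n = g.size()
    out = pd.DataFrame({
        "accuracy": p,
        "sem": np.sqrt(p * (1 - p) / n),
        "n": n,
    })
    if smoothing_window > 1:
        out["accuracy"] = out["accuracy"].rolling(
            smoothing_window, center=True, min_periods=1).mean()
    return out


def licking_differentiation_day(trials: pd.DataFrame, block: str,
                                epoch: EpochSpec | None = None,
                                alpha: float = 0.01) -> int | str:
    """First day of a run of two successive days on which lick magnitude is
    significantly Spearman-correlated with the block's variable reward
    probability (p < ``alpha`` on day d and day d+1).

    ``epoch`` names the lick-integration window and defaults to 401-700 ms
    (self-variable) or 701-1000 ms (partner-variable) after stimulus onset;
    it applies when per-sample lick traces are supplied (column
    ``lick_trace``), otherwise the scalar ``lick_magnitude`` is used as is.
    Returns the day index, or ``"not reached"``.
    """
    if epoch is None:
        epoch = DEFAULT_EPOCHS[
            "lick_self_variable" if block == "self_variable" else "lick_partner_variable"
        ]
    sub = trials[trials["block"] == block]
    days = sorted(sub["day"].unique())
    if len(days) < 2:
        warnings.warn("fewer than 2 days of data: differentiation day undefined")
        return NOT_REACHED
    pcol = "p_self" if block == "self_variable" else "p_partner"
    sig: dict[int, bool] = {}
    for d in days:
        dd = sub[sub["day"] == d]
        lick = _lick_values(dd, epoch)
        x = dd[pcol].to_numpy(dtype=float)
        if np.unique(x).size < 2 or np.allclose(lick, lick[0]):
            sig[d] = False
            continue
        rho, p = _spearman(x, lick)
        sig[d] = bool(p < alpha)
    for d in days:
        if sig.get(d) and sig.get(d + 1):
            return int(d)
    return NOT_REACHED


def _lick_values(day_trials: pd.DataFrame, epoch: EpochSpec) -> np.ndarray:
    if "lick_trace" in day_trials.columns:
        # per-ms traces aligned to stimulus onset: average within the epoch
        lo, hi = int(epoch.start_ms), int(epoch.end_ms)
        return np.array([np.mean(tr[lo:hi]) for tr in day_trials["lick_trace"]])
    return day_trials["lick_magnitude"].to_numpy(dtype=float)


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with large-sample p, exact permutation p below n = 10."""
    res = stats.spearmanr(x, y)
    if len(x) >= 10:
        return float(res.statistic), float(res.pvalue)
    perm = stats.permutation_test(
        (x,), lambda xs: stats.spearmanr(xs, y).statistic,
        permutation_type="pairings", n_resamples=5000,
        alternative="two-sided", random_state=0,
    )
    return float(res.statistic), float(perm.pvalue)


def licking_ratio(trials: pd.DataFrame, block: str) -> tuple[float, float]:
    """Ratio of mean lick magnitude in highest-valued over lowest-valued trials.

    In the self-variable block the highest-valued level is the largest
    P(self); in the partner-variable block it is the *smallest* P(partner)
    (others' reward devalues one's own prospect). Zero lick values are
    dropped, then values beyond 3 SD of the level's mean are excluded in a
    single pass before averaging. The SEM of the ratio is propagated from
    the two level means (delta method).
    """
    sub = trials[trials["block"] == block]
    pcol = "p_self" if block == "self_variable" else "p_partner"
    levels = np.sort(sub[pcol].unique())
    if levels.size < 2:
        raise DataError("licking ratio needs at least two probability levels")
    if block == "self_variable":
        hi_level, lo_level = levels[-1], levels[0]
    else:
        hi_level, lo_level = levels[0], levels[-1]

    def clean_mean(level: float) -> tuple[float, float, int]:
        v = sub.loc[sub[pcol] == level, "lick_magnitude"].to_numpy(dtype=float)
        v = v[v > 0]  # only non-zero values enter
        if v.size == 0:
            return float("nan"), float("nan"), 0
        m, s = v.mean(), v.std(ddof=1) if v.size > 1 else 0.0
        keep = v[np.abs(v - m) <= 3 * s] if s > 0 else v
        if keep.size == 0:
            return float("nan"), float("nan"), 0
        sem = keep.std(ddof=1) / np.sqrt(keep.size) if keep.size > 1 else 0.0
        return float(keep.mean()), float(sem), int(keep.size)

    m_hi, sem_hi, n_hi = clean_mean(hi_level)
    m_lo, sem_lo, n_lo = clean_mean(lo_level)
    if n_lo == 0 or not np.isfinite(m_lo) or m_lo == 0:
        warnings.warn("no surviving lowest-valued lick values: ratio undefined")
        return float("nan"), float("nan")
    ratio = m_hi / m_lo
    sem = abs(ratio) * np.sqrt((sem_hi / m_hi) ** 2 + (sem_lo / m_lo) ** 2) \
        if m_hi != 0 else float("nan")
    return float(ratio), float(sem)


def gaze_roi_proportion(gaze_samples, roi: str, window: EpochSpec) -> float:
    """Fraction of gaze samples inside ``window`` whose ROI label matches.

    ``gaze_samples`` is an iterable of ``(time_ms, roi_label)`` pairs (one
    trial's samples or several trials' pooled). An empty window yields NaN
    with a warning.
    """
    samples = list(gaze_samples)
    in_win = [r for (t, r) in samples if window.start_ms <= t < window.end_ms]
    if not in_win:
        warnings.warn(f"no gaze samples inside window {window.name!r}")
        return float("nan")
    return sum(1 for r in in_win if r == roi) / len(in_win)
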