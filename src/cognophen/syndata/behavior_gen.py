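"""Generators for reversal-learning and Pavlovian-conditioning behavior.

The reversal generator simulates block-structured three-target choice under
named agent policies; the conditioning generator simulates 120-trial blocks
with probabilistic, mutually exclusive rewards, anticipatory licking with
configurable probability slopes, and categorical gaze samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cognophen.errors import ConfigError, PolicyError
from cognophen.syndata.config import POLICIES, SimConfig

TARGETS = ("T1", "T2", "T3")


class _Agent:
    """Behavioral policy with a belief state updated from observed outcomes.

    All policies observe every trial (own and partner actions alike), which
    is what the social task affords: reward feedback is delivered to both
    animals simultaneously.
    """

    def __init__(self, policy: str, cfg: SimConfig, rng: np.random.Generator,
                 lapse_rate: float | None = None):
        if policy not in POLICIES:
            raise PolicyError(f"unknown policy {policy!r}; expected one of {POLICIES}")
        self.policy = policy
        self.cfg = cfg
        self.rng = rng
        self.lapse_rate = cfg.lapse_rate if lapse_rate is None else lapse_rate
        self.believed: str | None = None      # target currently believed correct
        self.ruled_out: set[str] = set()      # failed targets since last reward
        self.last_choice: str | None = None
        self.last_rewarded: bool = False
        self.persev_remaining: int | None = None
        self.wsls_weight: float = 1.0         # P(apply WSLS rule) on this day

    # -- observation ------------------------------------------------------
    def observe(self, chosen: str, rewarded: bool) -> None:
        self.last_choice = chosen
        self.last_rewarded = rewarded
        if rewarded:
            self.believed = chosen
            self.ruled_out.clear()
            self.persev_remaining = None
        else:
            self.ruled_out.add(chosen)

    # -- choice -----------------------------------------------------------
    def choose(self) -> str:
        if self.rng.random() < self.lapse_rate:
            return TARGETS[self.rng.integers(3)]
        if self.policy == "random" or self.last_choice is None:
            return TARGETS[self.rng.integers(3)]
        if self.policy == "win_stay_lose_switch":
            if self.rng.random() < self.wsls_weight:
                return self._choose_wsls()
            return self._choose_optimal()
        if self.policy == "perseverative":
            return self._choose_perseverative()
        return self._choose_optimal()

    def _choose_wsls(self) -> str:
        if self.last_rewarded:
            return self.last_choice
        others = [t for t in TARGETS if t != self.last_choice]
        return others[self.rng.integers(2)]

    def _choose_optimal(self) -> str:
        # Keep the believed-correct target until it fails; then explore
        # uniformly among targets not yet ruled out since the last reward.
        if self.believed is not None and self.believed not in self.ruled_out:
            return self.believed
        candidates = [t for t in TARGETS if t not in self.ruled_out]
        if not candidates:  # all three failed since last reward: reset
            self.ruled_out.clear()
            candidates = list(TARGETS)
        return candidates[self.rng.integers(len(candidates))]

    def _choose_perseverative(self) -> str:
        if self.believed is not None and self.believed in self.ruled_out:
            # believed target has started failing: persist for a geometric run
            if self.persev_remaining is None:
                run = int(self.rng.geometric(1.0 / max(self.cfg.persev_mean_run, 1.0)))
                # truncate so the run always resolves before the next switch
                self.persev_remaining = min(run, self.cfg.persev_max_run)
            if self.persev_remaining > 0:
                self.persev_remaining -= 1
                return self.believed
        return self._choose_optimal()


def gen_reversal_sessions(cfg: SimConfig) -> pd.DataFrame:
    """Simulate reversal-learning sessions as a table of trial records.

    Block lengths are drawn uniformly from ``cfg.block_len_range`` (inclusive);
    the correct target switches at every block boundary to one of the two
    other targets, without notice. In social mode (``cfg.social``) the actor
    role alternates between self and partner every ``cfg.actor_period`` trials;
    the partner always plays the optimal observational policy while self plays
    ``cfg.policy``. A reward is delivered (to both animals in social mode)
    iff the actor pressed the current block's correct target.

    Returns a DataFrame with one row per trial and columns
    ``session_day, block_id, trial_in_block, actor, chosen_target,
    correct_target_current, correct_target_previous, rewarded``.
    """
    rng = cfg.rng("reversal")
    if cfg.n_blocks < 1:
        raise ConfigError("n_blocks must be >= 1")
    lo, hi = cfg.block_len_range

    rows = []
    block_counter = 0
    for day in range(1, cfg.n_days + 1):
        self_agent = _Agent(cfg.policy, cfg, rng)
        if cfg.policy == "win_stay_lose_switch" and cfg.wsls_ramp_days > 0:
            self_agent.wsls_weight = min(1.0, day / cfg.wsls_ramp_days)
        partner = (
            _Agent("optimal_social", cfg, rng, lapse_rate=cfg.partner_lapse_rate)
            if cfg.social else None
        )

        correct = TARGETS[rng.integers(3)]
        previous: str | None = None
        trial_global = 0
        for _ in range(cfg.n_blocks):
            block_counter += 1
            block_len = int(rng.integers(lo, hi + 1))
            for t in range(1, block_len + 1):
                if cfg.social:
                    actor = "self" if (trial_global // cfg.actor_period) % 2 == 0 else "partner"
                else:
                    actor = "self"
                agent = self_agent if actor == "self" else partner
                chosen = agent.choose()
                rewarded = chosen == correct
                self_agent.observe(chosen, rewarded)
                if partner is not None:
                    partner.observe(chosen, rewarded)
                rows.append(
                    (day, block_counter, t, actor, chosen, correct, previous, rewarded)
                )
                trial_global += 1
            previous = correct
            correct = [t for t in TARGETS if t != correct][rng.integers(2)]

    return pd.DataFrame(
        rows,
        columns=[
            "session_day",
            "block_id",
            "trial_in_block",
            "actor",
            "chosen_target",
            "correct_target_current",
            "correct_target_previous",
            "rewarded",
        ],
    )


def gen_conditioning_days(cfg: SimConfig) -> pd.DataFrame:
    """Simulate Pavlovian-conditioning sessions with exclusive reward recipients.

    Each day runs ``cfg.blocks_per_day`` blocks of ``cfg.block_trials`` trials,
    alternating self-variable and partner-variable contexts. In the
    self-variable block each of three stimuli carries a different self-reward
    probability (``cfg.reward_probs_variable``) while the partner probability
    is fixed at ``cfg.reward_prob_invariable``; the partner-variable block is
    the converse. The two animals are never rewarded on the same trial, so a
    trial outcome is exactly one of self_rewarded / partner_rewarded / neither.

    Anticipatory licking is ``baseline + slope_self*P(self) -
    slope_partner*P(partner) + N(0, noise)``, clipped at zero, with the slopes
    switched on from ``cfg.differentiation_day``. Gaze samples are drawn
    categorically over the configured ROI dwell proportions.
    """
    rng = cfg.rng("conditioning")
    if cfg.differentiation_day < 1:
        raise ConfigError("differentiation_day must be >= 1")
    p_inv = cfg.reward_prob_invariable
    for p in cfg.reward_probs_variable:
        if p + p_inv > 1.0:
            raise ConfigError(
                f"P(self)+P(partner)={p + p_inv:.2f} > 1 violates the "
                "exclusive-reward constraint"
            )
    rois = sorted(cfg.gaze_roi_props)
    roi_p = np.array([cfg.gaze_roi_props[r] for r in rois], dtype=float)
    if roi_p.sum() <= 0:
        raise ConfigError("gaze_roi_props must have positive total mass")
    roi_p = roi_p / roi_p.sum()
    w_lo, w_hi = cfg.gaze_window_ms

    rows = []
    for day in range(1, cfg.n_days_conditioning + 1):
        slopes_on = day >= cfg.differentiation_day
        for b in range(cfg.blocks_per_day):
            block = "self_variable" if b % 2 == 0 else "partner_variable"
            stim_levels = rng.integers(0, len(cfg.reward_probs_variable), cfg.block_trials)
            for level in stim_levels:
                p_var = cfg.reward_probs_variable[level]
                if block == "self_variable":
                    p_self, p_partner = p_var, p_inv
                    stim = f"SV{level + 1}"
                else:
                    p_self, p_partner = p_inv, p_var
                    stim = f"PV{level + 1}"
                u = rng.random()
                if u < p_self:
                    outcome = "self_rewarded"
                elif u < p_self + p_partner:
                    outcome = "partner_rewarded"
                else:
                    outcome = "neither"
                lick = cfg.lick_baseline + rng.normal(0.0, cfg.lick_noise_sd)
                if slopes_on:
                    lick += cfg.lick_slope_self * p_self - cfg.lick_slope_partner * p_partner
                lick = max(lick, 0.0)
                gaze_t = np.sort(rng.uniform(w_lo, w_hi, cfg.gaze_samples_per_trial))
                gaze_r = rng.choice(rois, size=cfg.gaze_samples_per_trial, p=roi_p)
                rows.append(
                    (day, block, stim, p_self, p_partner, outcome, lick,
                     list(zip(gaze_t.tolist(), gaze_r.tolist())))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "day", "block", "stimulus_id", "p_self", "p_partner",
            "outcome", "lick_magnitude", "gaze_samples",
        ],
    )
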