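"""Behavioral scoring, trial selection, licking, and gaze metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cognophen import behavior
from cognophen.epochs import DEFAULT_EPOCHS, EpochSpec
from cognophen.errors import DataError
from cognophen.syndata import SimConfig, gen_conditioning_days, gen_reversal_sessions


class TestScoreSwitchResponse:
    def test_perseverator_scores_minus_one(self):
        """A lapse-free perseverative agent always repeats the previous
        block's correct target on trial 2, forcing a mean score of -1."""
        t = gen_reversal_sessions(SimConfig(seed=1, policy="perseverative", n_blocks=50))
        curve = behavior.score_switch_response(t)
        assert curve.loc[2, "mean_score"] == -1.0

    def test_optimal_explorer_expects_plus_half(self):
        """On trial 2 an optimal explorer picks uniformly between the two
        not-previously-correct targets, scoring 0 or +1 with equal odds."""
        t = gen_reversal_sessions(SimConfig(seed=2, policy="optimal_social", n_blocks=400))
        curve = behavior.score_switch_response(t)
        sem = np.sqrt(0.25 / curve.loc[2, "n"])
        assert abs(curve.loc[2, "mean_score"] - 0.5) < 4 * sem

    def test_switch_trial_scores_minus_one_under_optimal_play(self):
        t = gen_reversal_sessions(SimConfig(seed=3, policy="optimal_social", n_blocks=60))
        curve = behavior.score_switch_response(t)
        assert curve.loc[1, "mean_score"] == -1.0

    def test_first_block_excluded_and_counted(self):
        t = gen_reversal_sessions(SimConfig(seed=4, n_blocks=3))
        curve = behavior.score_switch_response(t)
        first_len = (t["block_id"] == 1).sum()
        assert curve.attrs["n_excluded_first_block"] == first_len

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_score_bookkeeping(self, seed):
        """Every scored trial gets exactly one of {-1, 0, +1}; category
        counts sum to the scored-trial total."""
        t = gen_reversal_sessions(SimConfig(seed=seed, policy="random", n_blocks=6))
        curve = behavior.score_switch_response(t)
        scored = len(t) - curve.attrs["n_excluded_first_block"]
        assert curve["n"].sum() == scored
        assert curve["mean_score"].between(-1, 1).all()


class TestTrialSelectors:
    def test_choice_error_toy(self, toy_social_trials):
        sel = behavior.select_choice_error_trials(toy_social_trials)
        assert list(sel.index) == [5]  # the single qualifying trial

    def test_switch_error_toy(self, toy_social_trials):
        sel = behavior.select_switch_error_trials(toy_social_trials)
        assert list(sel.index) == [3]

    def test_condition2_excludes_unsolved_block(self, toy_social_trials):
        """A partner choice error before the current correct target was ever
        selected does not qualify (block 3 of the toy)."""
        sel = behavior.select_choice_error_trials(toy_social_trials)
        assert not (sel["block_id"] == 3).any()

    def test_nonsocial_table_rejected(self):
        t = gen_reversal_sessions(SimConfig(seed=5, n_blocks=3))
        with pytest.raises(DataError):
            behavior.select_choice_error_trials(t)

    def test_selectors_disjoint(self):
        t = gen_reversal_sessions(SimConfig(seed=6, social=True, n_blocks=40,
                                            policy="win_stay_lose_switch"))
        ce = behavior.select_choice_error_trials(t)
        se = behavior.select_switch_error_trials(t)
        assert set(ce.index).isdisjoint(se.index)

    def test_wsls_dissociation_direction(self):
        """Under growing win-stay/lose-switch pressure, accuracy after
        partner choice errors deteriorates while accuracy after partner
        switch errors does not."""
        cfg = SimConfig(seed=7, policy="win_stay_lose_switch", social=True,
                        n_blocks=80, n_days=8, wsls_ramp_days=8)
        t = gen_reversal_sessions(cfg)
        ce = behavior.accuracy_after(behavior.select_choice_error_trials(t))
        se = behavior.accuracy_after(behavior.select_switch_error_trials(t))
        early = ce.loc[ce.index <= 2, "accuracy"].mean()
        late = ce.loc[ce.index >= 7, "accuracy"].mean()
        assert early - late > 0.15
        d_se = se.loc[se.index <= 2, "accuracy"].mean() - se.loc[se.index >= 7, "accuracy"].mean()
        assert d_se < early - late


class TestAccuracy:
    @pytest.mark.parametrize("pattern,expected", [
        ([True] * 6, 1.0), ([False] * 6, 0.0), ([True, False] * 3, 0.5),
    ])
    def test_constant_patterns(self, pattern, expected):
        df = pd.DataFrame({"session_day": [1] * len(pattern), "rewarded": pattern})
        out = behavior.accuracy_after(df)
        assert out.loc[1, "accuracy"] == expected

    def test_empty_selection_is_empty_series(self):
        out = behavior.accuracy_after(pd.DataFrame(columns=["session_day", "rewarded"]))
        assert out.empty


class TestLickingDifferentiation:
    def test_slope_from_day3_detected(self):
        cfg = SimConfig(seed=8, lick_slope_self=3.0, differentiation_day=3,
                        n_days_conditioning=6, lick_noise_sd=0.3)
        t = gen_conditioning_days(cfg)
        assert behavior.licking_differentiation_day(t, "self_variable") == 3

    def test_zero_slope_not_reached(self):
        t = gen_conditioning_days(SimConfig(seed=9, n_days_conditioning=5))
        assert behavior.licking_differentiation_day(t, "self_variable") == \
            behavior.NOT_REACHED

    def test_single_significant_day_insufficient(self):
        """Significance on one day only (not two successive) does not count."""
        cfg = SimConfig(seed=10, lick_slope_self=3.0, differentiation_day=5,
                        n_days_conditioning=5, lick_noise_sd=0.3)
        t = gen_conditioning_days(cfg)
        assert behavior.licking_differentiation_day(t, "self_variable") == \
            behavior.NOT_REACHED

    def test_monotone_spearman_recovery(self):
        """Spearman rho in the self-variable block rises with the generator's
        lick slope at fixed noise."""
        from scipy.stats import spearmanr
        rhos = []
        for slope in (0.0, 1.0, 2.0, 4.0):
            t = gen_conditioning_days(SimConfig(seed=11, lick_slope_self=slope,
                                                n_days_conditioning=2, lick_noise_sd=0.5))
            sv = t[t["block"] == "self_variable"]
            rhos.append(spearmanr(sv["p_self"], sv["lick_magnitude"]).statistic)
        assert all(b > a for a, b in zip(rhos, rhos[1:]))


class TestLickingRatio:
    def _trials(self, hi_mean, lo_mean, extra_hi=()):
        rows = []
        for v in list(np.full(40, hi_mean) + np.linspace(-0.5, 0.5, 40)) + list(extra_hi):
            rows.append(("self_variable", 0.75, 0.2, v))
        for v in np.full(40, lo_mean) + np.linspace(-0.5, 0.5, 40):
            rows.append(("self_variable", 0.2, 0.2, v))
        return pd.DataFrame(rows, columns=["block", "p_self", "p_partner", "lick_magnitude"])

    def test_identical_distributions_ratio_one(self):
        r, _ = behavior.licking_ratio(self._trials(5.0, 5.0), "self_variable")
        assert r == pytest.approx(1.0, abs=0.01)

    def test_doubled_mean_ratio_two(self):
        r, _ = behavior.licking_ratio(self._trials(8.0, 4.0), "self_variable")
        assert r == pytest.approx(2.0, abs=0.02)

    def test_outlier_beyond_3sd_removed(self):
        base = self._trials(5.0, 5.0)
        with_outlier = behavior.licking_ratio(self._trials(5.0, 5.0, extra_hi=[60.0]),
                                              "self_variable")[0]
        clean = behavior.licking_ratio(base, "self_variable")[0]
        assert with_outlier == pytest.approx(clean, abs=0.02)

    def test_partner_block_inverts_value_order(self):
        rows = []
        for p, m in [(0.2, 8.0), (0.75, 4.0)]:  # low P(partner) licked more
            for v in np.full(30, m) + np.linspace(-0.3, 0.3, 30):
                rows.append(("partner_variable", 0.2, p, v))
        t = pd.DataFrame(rows, columns=["block", "p_self", "p_partner", "lick_magnitude"])
        r, _ = behavior.licking_ratio(t, "partner_variable")
        assert r == pytest.approx(2.0, abs=0.02)


class TestGaze:
    W = EpochSpec("w", 100, 500, align="reward_onset")

    def test_all_none_half(self):
        mk = lambda rois: [(150 + 10 * i, r) for i, r in enumerate(rois)]
        assert behavior.gaze_roi_proportion(mk(["partner"] * 10), "partner", self.W) == 1.0
        assert behavior.gaze_roi_proportion(mk(["spout"] * 10), "partner", self.W) == 0.0
        assert behavior.gaze_roi_proportion(
            mk(["partner", "spout"] * 5), "partner", self.W) == 0.5

    def test_empty_window_flagged(self):
        with pytest.warns(UserWarning):
            out = behavior.gaze_roi_proportion([(900, "partner")], "partner", self.W)
        assert np.isnan(out)
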