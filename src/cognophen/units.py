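"""Single-unit response typing for the reversal and conditioning tasks.

Actor-related units (reversal task) are classified by a fixed decision tree:
a two-way ANOVA over agent (self/partner) and outcome (correct/incorrect) on
peri-action firing rates gates entry; a significant agent main effect routes
the unit to self/partner typing via a Tukey-Kramer comparison plus a paired
test against the pre-target control period; otherwise the unit is a mirror
candidate, requiring a significant control-vs-peri difference of the same
sign in both self- and partner-action trials. Reward-related units
(conditioning task) are typed from per-block regression slopes of epoch
firing rate on the block's variable reward probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from cognophen.errors import DataError

ACTOR_LABELS = ("self", "mirror", "partner", "none")
REWARD_LABELS = ("self", "mirror", "partner", "value", "none")


@dataclass
class UnitEpochData:
    """Per-trial firing rates of one unit in named epochs with condition labels.

    ``control_rate`` and ``rate`` are Hz, one entry per trial. Reversal-task
    units carry ``agent`` and ``outcome`` labels; conditioning-task units
    carry ``block`` and ``variable_probability``.
    """

    unit_id: str
    region: str
    task: str  # "reversal" | "conditioning"
    control_rate: np.ndarray
    rate: np.ndarray
    agent: Optional[np.ndarray] = None
    outcome: Optional[np.ndarray] = None
    block: Optional[np.ndarray] = None
    variable_probability: Optional[np.ndarray] = None
    spike_times_ms: Optional[np.ndarray] = None
    true_label: Optional[str] = None  # set by the synthetic generator

    def __post_init__(self) -> None:
        if np.any(self.control_rate < 0) or np.any(self.rate < 0):
            raise DataError(f"unit {self.unit_id}: negative firing rates")

    def frame(self) -> pd.DataFrame:
        cols = {"control_rate": self.control_rate, "rate": self.rate}
        for name in ("agent", "outcome", "block", "variable_probability"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


@dataclass
class UnitLabel:
    """Classification outcome for one unit, with its supporting statistics."""

    unit_id: str
    task: str
    label: str
    sign: str = "n/a"  # excitatory | inhibitory | mixed | n/a
    region: str = ""
    subject: str = ""
    excluded: bool = False
    reason: str = ""
    stats: dict = field(default_factory=dict)


def classify_actor_unit(unit: UnitEpochData, alpha: float = 0.05) -> UnitLabel:
    """Type an actor-related unit (self / mirror / partner / none).

    Decision tree:

    1. Two-way ANOVA (type-II SS) of peri-action rate on agent x outcome.
    2. Agent main effect significant: candidate self or partner by the
       direction of a Tukey-Kramer comparison of the two agents' rates; the
       label is confirmed only if the preferred agent's peri-action rates
       also differ from the control period (paired t-test), else "none".
    3. Agent main effect not significant: mirror iff the paired control
       comparison is significant with the same sign in both agents' trials;
       otherwise "none".

    Units with any empty or single-trial agent x outcome cell are excluded
    with a reason code rather than classified.
    """
    df = unit.frame()
    if "agent" not in df or "outcome" not in df:
        raise DataError(f"unit {unit.unit_id}: missing agent/outcome labels")
    cells = df.groupby(["agent", "outcome"], observed=True).size()
    if len(cells) < 4 or (cells < 2).any():
        return UnitLabel(unit.unit_id, "reversal", "none", excluded=True,
                         region=unit.region, reason="empty_condition_cell")

    model = ols("rate ~ C(agent) * C(outcome)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_agent = float(table.loc["C(agent)", "PR(>F)"])
    info = {
        "anova_F_agent": float(table.loc["C(agent)", "F"]),
        "anova_p_agent": p_agent,
        "anova_p_outcome": float(table.loc["C(outcome)", "PR(>F)"]),
    }

    rate_self = df.loc[df.agent == "self", "rate"].to_numpy()
    rate_partner = df.loc[df.agent == "partner", "rate"].to_numpy()

    def paired_vs_control(agent: str):
        sub = df[df.agent == agent]
        t, p = stats.ttest_rel(sub["rate"], sub["control_rate"])
        sign = "excitatory" if sub["rate"].mean() > sub["control_rate"].mean() else "inhibitory"
        return float(t), float(p), sign

    if p_agent < alpha:
        tk = stats.tukey_hsd(rate_self, rate_partner)
        p_tk = float(tk.pvalue[0, 1])
        info["tukey_p"] = p_tk
        if p_tk < alpha:
            # the preferred agent is the one whose peri-action rate departs
            # from control (covers inhibitory as well as excitatory units);
            # with both departing, the larger modulation wins
            cands = []
            for agent in ("self", "partner"):
                t, p, sign = paired_vs_control(agent)
                info.update({f"paired_t_{agent}": t, f"paired_p_{agent}": p})
                sub = df[df.agent == agent]
                depth = abs(sub["rate"].mean() - sub["control_rate"].mean())
                if p < alpha:
                    cands.append((depth, agent, sign))
            if cands:
                _, preferred, sign = max(cands)
                return UnitLabel(unit.unit_id, "reversal", preferred, sign,
                                 region=unit.region, stats=info)
        # significant gateway but unconfirmed direction/baseline: not typed
        return UnitLabel(unit.unit_id, "reversal", "none", region=unit.region, stats=info)

    t_s, p_s, sign_s = paired_vs_control("self")
    t_p, p_p, sign_p = paired_vs_control("partner")
    info.update({"paired_p_self": p_s, "paired_p_partner": p_p})
    if p_s < alpha and p_p < alpha and sign_s == sign_p:
        return UnitLabel(unit.unit_id, "reversal", "mirror", sign_s,
                         region=unit.region, stats=info)
    return UnitLabel(unit.unit_id, "reversal", "none", region=unit.region, stats=info)


def classify_reward_unit(unit: UnitEpochData, alpha: float = 0.01) -> UnitLabel:
    """Type a reward-related unit (self / mirror / partner / value / none).

    Fits an ordinary least-squares regression of epoch firing rate on the
    block's variable reward probability, separately in the self-variable and
    partner-variable blocks. A block "encodes" probability when its slope is
    significant at ``alpha``. Self/partner: only one block significant;
    mirror: both significant with the same sign; value: both significant
    with opposite signs.
    """
    df = unit.frame()
    if "block" not in df or "variable_probability" not in df:
        raise DataError(f"unit {unit.unit_id}: missing block/probability labels")
    info: dict = {}
    slopes: dict[str, tuple[float, float]] = {}
    for block in ("self_variable", "partner_variable"):
        sub = df[df.block == block]
        if sub.empty:
            raise DataError(f"unit {unit.unit_id}: block {block} absent")
        x = sub["variable_probability"].to_numpy(dtype=float)
        if np.unique(x).size < 3:
            raise DataError(
                f"unit {unit.unit_id}: <3 probability levels in {block}"
            )
        res = stats.linregress(x, sub["rate"].to_numpy(dtype=float))
        slopes[block] = (res.slope, res.pvalue)
        info[f"slope_{block}"] = float(res.slope)
        info[f"slope_p_{block}"] = float(res.pvalue)
        info[f"intercept_{block}"] = float(res.intercept)

    (b_s, p_s), (b_p, p_p) = slopes["self_variable"], slopes["partner_variable"]
    sig_s, sig_p = p_s < alpha, p_p < alpha
    if sig_s and sig_p:
        label = "mirror" if np.sign(b_s) == np.sign(b_p) else "value"
        sign = ("excitatory" if b_s > 0 else "inhibitory") if label == "mirror" else "mixed"
    elif sig_s:
        label, sign = "self", "excitatory" if b_s > 0 else "inhibitory"
    elif sig_p:
        label, sign = "partner", "excitatory" if b_p > 0 else "inhibitory"
    else:
        label, sign = "none", "n/a"
    return UnitLabel(unit.unit_id, "conditioning", label, sign,
                     region=unit.region, stats=info)


def isi_violation_flag(spike_times_ms: np.ndarray,
                       threshold_ms: float = 2.0) -> tuple[bool, float]:
    """Flag a unit whose spike train contains any inter-spike interval below
    ``threshold_ms``; also return the fraction of violating intervals so a
    tolerance policy can be applied downstream.

    With fewer than two spikes the fraction is undefined (NaN) and the unit
    is not flagged.
    """
    t = np.sort(np.asarray(spike_times_ms, dtype=float))
    if t.size < 2:
        return False, float("nan")
    isi = np.diff(t)
    frac = float(np.mean(isi < threshold_ms))
    return bool(np.any(isi < threshold_ms)), frac


def _round_half_up(x: float, ndigits: int = 1) -> float:
    factor = 10.0 ** ndigits
    return float(np.floor(x * factor + 0.5) / factor)


def type_proportion_table(labels: list[UnitLabel],
                          by: tuple[str, ...] = ("region", "subject")) -> pd.DataFrame:
    """Counts of unit types per group with percentages of total typed units.

    For actor-related units the columns are self / mirror / partner counts,
    the total of typed (actor-related) units, the total sampled, and each
    type's percentage of the typed total rounded half-up to one decimal —
    the layout used for across-subject type-proportion comparisons.
    """
    if not labels:
        return pd.DataFrame(
            columns=[*by, "self", "mirror", "partner", "total_typed",
                     "total_sampled", "pct_self", "pct_mirror", "pct_partner"]
        )
    df = pd.DataFrame(
        [{**{k: getattr(l, k) for k in by}, "label": l.label, "excluded": l.excluded}
         for l in labels]
    )
    type_cols = [t for t in ("self", "mirror", "partner", "value") if (df.label == t).any()
                 or t in ("self", "mirror", "partner")]
    rows = []
    for keys, grp in df.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        counts = {t: int((grp.label == t).sum()) for t in type_cols}
        total_typed = sum(counts.values())
        row = dict(zip(by, keys))
        row.update(counts)
        row["total_typed"] = total_typed
        row["total_sampled"] = int(len(grp))
        for t in type_cols:
            row[f"pct_{t}"] = (
                _round_half_up(100.0 * counts[t] / total_typed) if total_typed else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def modulation_magnitude(unit: UnitEpochData) -> dict[str, float]:
    """Absolute control-vs-peri-action rate difference per correct condition.

    Returns ``{"self": |mean peri - mean control| in correct self-action
    trials, "partner": same for correct partner-action trials}`` for Welch
    comparisons of response modulation across subjects.
    """
    df = unit.frame()
    out: dict[str, float] = {}
    for agent in ("self", "partner"):
        sub = df[(df.agent == agent) & (df.outcome == "correct")]
        if sub.empty:
            out[agent] = float("nan")
        else:
            out[agent] = float(abs(sub["rate"].mean() - sub["control_rate"].mean()))
    return out
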