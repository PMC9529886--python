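"""Synthetic single units with Poisson spiking and known response types."""

from __future__ import annotations

import numpy as np

from cognophen.errors import ConfigError
from cognophen.syndata.config import SimConfig
from cognophen.units import UnitEpochData


def _true_actor_label(off_self: float, off_partner: float) -> str:
    if off_self != 0.0 and off_partner != 0.0:
        return "mirror" if np.sign(off_self) == np.sign(off_partner) else "none"
    if off_self != 0.0:
        return "self"
    if off_partner != 0.0:
        return "partner"
    return "none"


def _true_reward_label(s_self: float, s_partner: float) -> str:
    if s_self != 0.0 and s_partner != 0.0:
        return "mirror" if np.sign(s_self) == np.sign(s_partner) else "value"
    if s_self != 0.0:
        return "self"
    if s_partner != 0.0:
        return "partner"
    return "none"


def gen_units(cfg: SimConfig, n_units: int = 1, task: str = "reversal",
              region: str = "PMv") -> list[UnitEpochData]:
    """Generate units with Poisson spike counts and a stored true type label.

    Reversal task: per-trial control and peri-action rates are Poisson counts
    over 600-ms epochs; the peri-action rate is ``baseline + offset(agent)``
    with offsets from ``cfg.rate_offset_self`` / ``cfg.rate_offset_partner``
    (equal nonzero offsets of the same sign define a mirror unit).
    Conditioning task: the epoch rate is ``baseline + slope * P(variable)``
    per block, slopes from ``cfg.reward_slope_self`` / ``cfg.reward_slope_partner``.

    The ground-truth label is stored on each unit as ``true_label`` for
    recovery testing.
    """
    rng = cfg.rng("units")
    base = cfg.unit_baseline_hz
    n = cfg.n_trials_per_condition
    epoch_s = 0.6  # both control and analysis epochs span 600 ms

    units: list[UnitEpochData] = []
    for u in range(n_units):
        if task == "reversal":
            agents = np.repeat(["self", "partner"], 2 * n)
            outcomes = np.tile(np.repeat(["correct", "incorrect"], n), 2)
            offs = np.where(agents == "self", cfg.rate_offset_self, cfg.rate_offset_partner)
            lam_peri = base + offs
            if np.any(lam_peri < 0) or base < 0:
                raise ConfigError("negative firing rate requested")
            peri = rng.poisson(lam_peri * epoch_s) / epoch_s
            control = rng.poisson(base * epoch_s, size=agents.size) / epoch_s
            unit = UnitEpochData(
                unit_id=f"u{u:04d}",
                region=region,
                task="reversal",
                control_rate=control.astype(float),
                rate=peri.astype(float),
                agent=agents,
                outcome=outcomes,
            )
            unit.true_label = _true_actor_label(cfg.rate_offset_self, cfg.rate_offset_partner)
        elif task == "conditioning":
            probs = np.asarray(cfg.reward_probs_variable, dtype=float)
            blocks = np.repeat(["self_variable", "partner_variable"], n)
            p_var = np.tile(probs, int(np.ceil(n / probs.size)))[:n]
            p_var = np.concatenate([p_var, p_var])
            slope = np.where(blocks == "self_variable",
                             cfg.reward_slope_self, cfg.reward_slope_partner)
            lam = base + slope * p_var
            if np.any(lam < 0):
                raise ConfigError("negative firing rate requested")
            epoch_cond_s = 0.3  # 300-ms stimulus epochs
            rate = rng.poisson(lam * epoch_cond_s) / epoch_cond_s
            control = rng.poisson(base * epoch_cond_s, size=lam.size) / epoch_cond_s
            unit = UnitEpochData(
                unit_id=f"u{u:04d}",
                region=region,
                task="conditioning",
                control_rate=control.astype(float),
                rate=rate.astype(float),
                block=blocks,
                variable_probability=p_var,
            )
            unit.true_label = _true_reward_label(cfg.reward_slope_self, cfg.reward_slope_partner)
        else:
            raise ConfigError(f"unknown task {task!r}")
        units.append(unit)
    return units
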