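"""Simulation configuration shared by all synthetic-data generators."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from cognophen.errors import ConfigError

POLICIES = ("optimal_social", "win_stay_lose_switch", "perseverative", "random")
COUPLING_DIRECTIONS = ("top_down", "bottom_up", "none")
RELATIONSHIPS = (
    "duplicate",
    "parent_offspring",
    "full_sib",
    "half_sib",
    "first_cousin",
    "unrelated",
)


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators, with study-condition defaults.

    The defaults encode the task structure the analyses assume: reversal
    blocks of 11-17 trials with the actor role alternating every three trials
    in the social task, conditioning blocks of 120 trials with variable
    reward probabilities {0.2, 0.5, 0.75} against an invariable 0.2, 16-contact
    probes sampled at 1 kHz. Effect-size fields default to the "effect present"
    regime used by the recovery tests; set them to zero for null data.
    """

    seed: int = 0

    # ---- reversal-learning task ----
    n_blocks: int = 40
    block_len_range: tuple[int, int] = (11, 17)
    policy: str = "optimal_social"
    lapse_rate: float = 0.0
    social: bool = False
    n_days: int = 1
    actor_period: int = 3           # role alternation, trials
    partner_lapse_rate: float = 0.1  # partner's occasional mid-block errors
    persev_mean_run: float = 4.0    # geometric mean of perseverative runs
    persev_max_run: int = 6         # cap; keeps runs resolvable within a block
    wsls_ramp_days: int = 0         # >0: WSLS rule probability ramps 0->1 over days

    # ---- Pavlovian conditioning ----
    n_days_conditioning: int = 8
    blocks_per_day: int = 2
    block_trials: int = 120
    reward_probs_variable: tuple[float, ...] = (0.2, 0.5, 0.75)
    reward_prob_invariable: float = 0.2
    lick_baseline: float = 5.0       # sensor units
    lick_slope_self: float = 0.0     # sensor units per unit probability
    lick_slope_partner: float = 0.0
    lick_noise_sd: float = 0.5
    differentiation_day: int = 1     # slopes switched on from this day
    gaze_roi_props: dict = field(
        default_factory=lambda: {"stimulus": 0.5, "partner": 0.2, "self_spout": 0.2, "other": 0.1}
    )
    gaze_samples_per_trial: int = 40
    gaze_window_ms: tuple[float, float] = (0.0, 1000.0)

    # ---- single units ----
    n_trials_per_condition: int = 60
    unit_baseline_hz: float = 10.0
    rate_offset_self: float = 0.0    # Hz added in self-agent trials (peri-action)
    rate_offset_partner: float = 0.0
    reward_slope_self: float = 0.0   # Hz per unit P(self), conditioning task
    reward_slope_partner: float = 0.0

    # ---- LFP ----
    n_lfp_trials: int = 60
    n_contacts: int = 16
    fs_hz: float = 1000.0
    trial_dur_ms: float = 2000.0
    event_ms: float = 1000.0         # alignment event within the trial
    band_gain: float = 1.0           # multiplicative gain on the target band
    band_hz: tuple[float, float] = (23.0, 30.0)
    band_window_ms: tuple[float, float] = (0.0, 600.0)  # rel. to event
    evoked_amplitude_sd: float = 0.0  # in baseline-SD units
    evoked_latency_ms: float = 80.0
    evoked_dur_ms: float = 120.0

    # ---- coupled LFP regions ----
    coupling_direction: str = "none"
    coupling_strength: float = 0.0
    coupling_lag: int = 5            # samples
    ar_coefs: tuple[float, float] = (0.55, -0.2)
    stim_window_ms: tuple[float, float] = (0.0, 1000.0)

    # ---- pedigree genotypes ----
    relationship: str = "first_cousin"
    n_snps: int = 50_000
    maf_law: tuple[float, float] = (0.1, 0.9)  # Uniform bounds on founder allele freq

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ConfigError(
                f"unknown policy {self.policy!r}; expected one of {POLICIES}"
            )
        if self.coupling_direction not in COUPLING_DIRECTIONS:
            raise ConfigError(
                f"unknown coupling direction {self.coupling_direction!r}; "
                f"expected one of {COUPLING_DIRECTIONS}"
            )
        if self.relationship not in RELATIONSHIPS:
            raise ConfigError(
                f"unknown relationship {self.relationship!r}; "
                f"expected one of {RELATIONSHIPS}"
            )
        lo, hi = self.block_len_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ConfigError("block_len_range must be an integer interval")
        if lo < 1 or hi < lo:
            raise ConfigError(f"block_len_range {self.block_len_range} is empty or non-positive")
        for name in ("lapse_rate", "reward_prob_invariable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.reward_probs_variable):
            raise ConfigError("reward_probs_variable outside [0, 1]")
        if self.fs_hz <= 0:
            raise ConfigError(f"fs_hz must be positive, got {self.fs_hz}")

    def rng(self, stream: str = "") -> np.random.Generator:
        """Fresh, named PRNG stream derived from the config seed.

        Every generator draws from its own stream so that generators can be
        called in any order without perturbing each other's output.
        """
        key = zlib.crc32(stream.encode("utf-8"))  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    def to_dict(self) -> dict:
        return asdict(self)
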