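"""Named analysis windows relative to task events.

All windows used by the behavioral and electrophysiological analyses are
expressed as :class:`EpochSpec` objects: a (start, end) interval in
milliseconds relative to a named alignment event. The module-level
``DEFAULT_EPOCHS`` table collects the windows the pipeline uses by default;
every analysis accepts an explicit ``EpochSpec`` to override them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EpochSpec:
    """A half-open analysis window ``[start_ms, end_ms)`` relative to an event.

    Parameters
    ----------
    name : str
        Human-readable label of the window.
    start_ms, end_ms : float
        Window bounds in milliseconds relative to ``align``. ``start_ms``
        must be strictly less than ``end_ms``; negative values denote time
        before the event.
    align : str
        Name of the alignment event (e.g. ``"target_onset"``).
    """

    name: str
    start_ms: float
    end_ms: float
    align: str = "event"

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(
                f"EpochSpec {self.name!r}: start_ms ({self.start_ms}) must be "
                f"< end_ms ({self.end_ms})"
            )

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def sample_slice(self, fs_hz: float, event_sample: int) -> slice:
        """Convert the window to a sample-index slice of a recorded trace."""
        lo = event_sample + int(round(self.start_ms * fs_hz / 1000.0))
        hi = event_sample + int(round(self.end_ms * fs_hz / 1000.0))
        return slice(lo, hi)


# Windows stated by the analysis protocol. Units: ms relative to the named event.
DEFAULT_EPOCHS: dict[str, EpochSpec] = {
    # single-unit analysis, reversal task
    "control": EpochSpec("control", -600, 0, align="target_onset"),
    "peri_action": EpochSpec("peri_action", -400, 200, align="button_press"),
    # conditioning task stimulus epochs
    "stimulus_early": EpochSpec("stimulus_early", 151, 450, align="stimulus_onset"),
    "stimulus_late": EpochSpec("stimulus_late", 701, 1000, align="stimulus_onset"),
    # licking differentiation windows
    "lick_self_variable": EpochSpec("lick_self_variable", 401, 700, align="stimulus_onset"),
    "lick_partner_variable": EpochSpec("lick_partner_variable", 701, 1000, align="stimulus_onset"),
    # LFP baselines and indices
    "lfp_baseline": EpochSpec("lfp_baseline", -500, 0, align="target_onset"),
    "high_beta_window": EpochSpec("high_beta_window", -600, 0, align="button_press"),
    # gaze windows
    "gaze_partner_press": EpochSpec("gaze_partner_press", -400, -200, align="partner_press"),
    "gaze_post_reward": EpochSpec("gaze_post_reward", 100, 500, align="reward_onset"),
}
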