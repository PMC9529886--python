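"""Synthetic multi-contact LFPs: event-locked band modulation, evoked
deflections, and directionally coupled autoregressive region pairs."""

from __future__ import annotations

import numpy as np

from cognophen.errors import ConfigError, UnstableModelError
from cognophen.lfp import LfpArray
from cognophen.syndata.config import SimConfig


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs_hz: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise along the last axis."""
    white = rng.standard_normal(shape + (n_samples,))
    Xf = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(Xf * scale, n=n_samples, axis=-1)
    return x / x.std()


def _bandpass_fft(x: np.ndarray, f_lo: float, f_hi: float, fs_hz: float) -> np.ndarray:
    Xf = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs_hz)
    Xf[..., ~((f >= f_lo) & (f <= f_hi))] = 0.0
    return np.fft.irfft(Xf, n=x.shape[-1], axis=-1)


def gen_lfp_event(cfg: SimConfig) -> LfpArray:
    """Event-aligned LFP with configurable band gain and evoked deflection.

    The background is pink noise on ``cfg.n_contacts`` contacts at
    ``cfg.fs_hz``. Within ``cfg.band_window_ms`` (relative to the event) the
    content of ``cfg.band_hz`` is multiplied by ``cfg.band_gain`` (gain < 1
    simulates mu-like suppression, > 1 enhancement). A deflection of
    ``cfg.evoked_amplitude_sd`` (in units of the trial/contact-averaged
    baseline SD) with a sharp onset at ``cfg.evoked_latency_ms`` and
    exponential decay is added to every contact.
    """
    if cfg.fs_hz <= 0:
        raise ConfigError("fs_hz must be positive")
    rng = cfg.rng("lfp_event")
    n = int(round(cfg.trial_dur_ms * cfg.fs_hz / 1000.0))
    event = int(round(cfg.event_ms * cfg.fs_hz / 1000.0))
    x = _pink_noise(rng, (cfg.n_lfp_trials, cfg.n_contacts), n, cfg.fs_hz) * 50.0  # ~uV scale

    if cfg.band_gain != 1.0:
        band = _bandpass_fft(x, cfg.band_hz[0], cfg.band_hz[1], cfg.fs_hz)
        t_rel = (np.arange(n) - event) * 1000.0 / cfg.fs_hz
        env = ((t_rel >= cfg.band_window_ms[0]) & (t_rel < cfg.band_window_ms[1])).astype(float)
        x = x + (cfg.band_gain - 1.0) * band * env

    if cfg.evoked_amplitude_sd != 0.0:
        t_rel = (np.arange(n) - event) * 1000.0 / cfg.fs_hz
        onset = cfg.evoked_latency_ms
        # flat-top pulse: sharp onset, sustained for evoked_dur_ms, brief decay
        pulse = np.zeros(n)
        flat = (t_rel >= onset) & (t_rel < onset + cfg.evoked_dur_ms)
        pulse[flat] = 1.0
        tail = t_rel >= onset + cfg.evoked_dur_ms
        pulse[tail] = np.exp(-(t_rel[tail] - onset - cfg.evoked_dur_ms) / 10.0)
        # baseline SD of the channel/trial-averaged trace, the unit the
        # downstream z-scored detector sees
        avg = x.mean(axis=(0, 1))
        base_sd = avg[:event].std(ddof=1)
        x = x + cfg.evoked_amplitude_sd * base_sd * pulse

    return LfpArray(x, cfg.fs_hz, event, alignment_event="event")


def _companion_spectral_radius(a1: np.ndarray, a2: np.ndarray) -> float:
    k = a1.shape[0]
    top = np.hstack([a1, a2])
    bottom = np.hstack([np.eye(k), np.zeros((k, k))])
    comp = np.vstack([top, bottom])
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def gen_coupled_lfp(cfg: SimConfig) -> tuple[LfpArray, LfpArray]:
    """Two multi-contact regions driven by stable AR(2) processes with
    one-directional lagged coupling applied only in the stimulus window.

    Contact ``k`` of the target region receives ``cfg.coupling_strength``
    times the lag-``cfg.coupling_lag`` activity of contact ``k`` of the
    source region. ``coupling_direction`` selects the source: ``top_down``
    couples region A onto region B, ``bottom_up`` the reverse, ``none``
    leaves the regions independent. Raises :class:`UnstableModelError` for
    an unstable autoregression.
    """
    rng = cfg.rng("coupled_lfp")
    a1c, a2c = cfg.ar_coefs
    k = cfg.n_contacts
    # stability screen of the bivariate (source, target) system per pair:
    # block-triangular, so the radius equals the univariate AR radius
    radius = _companion_spectral_radius(np.array([[a1c]]), np.array([[a2c]]))
    if radius >= 1.0:
        raise UnstableModelError(
            f"AR coefficients {cfg.ar_coefs} give spectral radius {radius:.3f} >= 1"
        )

    n = int(round(cfg.trial_dur_ms * cfg.fs_hz / 1000.0))
    event = int(round(cfg.event_ms * cfg.fs_hz / 1000.0))
    t_rel = (np.arange(n) - event) * 1000.0 / cfg.fs_hz
    in_stim = (t_rel >= cfg.stim_window_ms[0]) & (t_rel < cfg.stim_window_ms[1])
    lag = cfg.coupling_lag
    c = cfg.coupling_strength

    shape = (cfg.n_lfp_trials, k)
    ea = rng.standard_normal(shape + (n,))
    eb = rng.standard_normal(shape + (n,))
    a = np.zeros(shape + (n,))
    b = np.zeros(shape + (n,))
    for t in range(n):
        xa = ea[..., t].copy()
        xb = eb[..., t].copy()
        if t >= 1:
            xa += a1c * a[..., t - 1]
            xb += a1c * b[..., t - 1]
        if t >= 2:
            xa += a2c * a[..., t - 2]
            xb += a2c * b[..., t - 2]
        if c != 0.0 and t >= lag and in_stim[t]:
            if cfg.coupling_direction == "top_down":
                xb += c * a[..., t - lag]
            elif cfg.coupling_direction == "bottom_up":
                xa += c * b[..., t - lag]
        a[..., t] = xa
        b[..., t] = xb

    region_a = LfpArray(a * 20.0, cfg.fs_hz, event, alignment_event="stimulus_onset")
    region_b = LfpArray(b * 20.0, cfg.fs_hz, event, alignment_event="stimulus_onset")
    return region_a, region_b
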