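"""Event-aligned LFP analysis: z-scored Morlet spectrograms, band indices
(mu suppression in the high-beta band), evoked amplitude/latency detection,
and PCA of per-contact LFP response features.

The spectral estimator is a complex Morlet wavelet (7 cycles) evaluated at
1-Hz centers, matching the 1-ms / 1-Hz analysis grid. Z-normalization is per
frequency against a pre-event baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
import pandas as pd

from cognophen.epochs import EpochSpec
from cognophen.errors import DataError


@dataclass
class LfpArray:
    """Trials x contacts x samples voltage array with event alignment.

    ``data`` is in microvolts; ``event_sample`` is the index of the
    alignment event within each trial. Contacts are ordered from the most
    superficial contact downward (linear probe geometry).
    """

    data: np.ndarray
    fs_hz: float
    event_sample: int
    alignment_event: str = "event"
    contact_spacing_um: float = 200.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError("LfpArray.data must be trials x contacts x samples")
        if not np.all(np.isfinite(self.data)):
            raise DataError("LfpArray contains non-finite values")
        if self.fs_hz <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs_hz}")
        if not 0 <= self.event_sample < self.data.shape[2]:
            raise DataError("alignment event outside the sample range")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Per-sample times in ms relative to the alignment event."""
        idx = np.arange(self.n_samples) - self.event_sample
        return idx * 1000.0 / self.fs_hz


@dataclass
class BandSpec:
    """An inclusive frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo <= self.f_hi:
            raise DataError(f"band {self.name!r}: need 0 < f_lo <= f_hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.f_lo) & (freqs <= self.f_hi)


HIGH_BETA = BandSpec("high_beta", 23.0, 30.0)
GAMMA = BandSpec("gamma", 31.0, 55.0)

COHERENCE_BANDS = (
    BandSpec("delta", 1, 3),
    BandSpec("theta", 4, 7),
    BandSpec("alpha", 8, 12),
    BandSpec("low_beta", 13, 20),
    BandSpec("high_beta", 21, 30),
    BandSpec("low_gamma", 31, 49),
    BandSpec("high_gamma", 50, 128),
)


@dataclass
class DetectionParams:
    """Threshold-crossing rule for evoked-response latency detection."""

    z_threshold: float = 1.5
    n_consecutive: int = 3
    search_window: Optional[EpochSpec] = None
    exclusion_ms: float = 30.0  # ignore bins this soon after the event

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise DataError("z_threshold must be positive")
        if self.n_consecutive < 1:
            raise DataError("n_consecutive must be >= 1")


# Detection/amplitude parameter sets per task flavor.
REVERSAL_DETECTION = DetectionParams(z_threshold=1.5, n_consecutive=3, exclusion_ms=30.0)
CONDITIONING_DETECTION_DMN = DetectionParams(z_threshold=3.0, n_consecutive=30, exclusion_ms=51.0)
CONDITIONING_DETECTION_MPFC = DetectionParams(z_threshold=3.0, n_consecutive=30, exclusion_ms=26.0)


def morlet_tfr(x: np.ndarray, freqs: Sequence[float], fs_hz: float,
               n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet transform of ``x`` along its last axis.

    Returns an array with a frequency axis inserted before the time axis:
    ``x`` of shape (..., n) maps to (..., n_freqs, n). FFT-based circular
    convolution; callers should keep analysis windows away from the edges.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    # reflect-pad both sides to keep long low-frequency wavelets from
    # dragging circular-convolution edge taper into the analysis window
    pad = n
    xp = np.concatenate([x[..., pad - 1::-1], x, x[..., :-pad - 1:-1]], axis=-1)
    npad = xp.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(npad)))
    Xf = np.fft.fft(xp, n=nfft, axis=-1)
    t = (np.arange(nfft) - nfft // 2) / fs_hz
    out = np.empty(x.shape[:-1] + (len(freqs), n), dtype=complex)
    for k, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        w = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))  # unit-energy normalization
        Wf = np.fft.fft(np.fft.ifftshift(w), n=nfft)
        conv = np.fft.ifft(Xf * Wf, axis=-1)[..., pad:pad + n]
        out[..., k, :] = conv
    return out


def spectrogram_z(lfp: LfpArray, baseline: EpochSpec,
                  f_range: tuple[float, float] = (1.0, 50.0),
                  f_step: float = 1.0, n_cycles: float = 7.0,
                  average_trials: bool = True):
    """Z-scored time-frequency power of an event-aligned LFP.

    Power is computed with complex Morlet wavelets on a 1-Hz grid over
    ``f_range`` at the native 1-ms resolution, averaged across contacts (and
    trials when ``average_trials``), then z-normalized per frequency against
    the baseline window's bins. With ``average_trials=False`` the per-trial
    spectrograms are z-scored against baseline statistics pooled over the
    baseline bins of all trials.

    Returns ``(z, freqs, times_ms)``.
    """
    f_lo, f_hi = f_range
    if f_hi > lfp.fs_hz / 2:
        raise DataError(f"f_range upper bound {f_hi} Hz above Nyquist")
    if not (baseline.sample_slice(lfp.fs_hz, lfp.event_sample).start >= 0
            and baseline.sample_slice(lfp.fs_hz, lfp.event_sample).stop <= lfp.n_samples):
        raise DataError("baseline window extends outside the data window")
    freqs = np.arange(f_lo, f_hi + f_step / 2, f_step)
    # accumulate contact-averaged power trial by trial to bound memory
    power = np.zeros((lfp.n_trials, len(freqs), lfp.n_samples))
    for tr in range(lfp.n_trials):
        W = morlet_tfr(lfp.data[tr], freqs, lfp.fs_hz, n_cycles)
        power[tr] = np.mean(np.abs(W) ** 2, axis=0)
    sl = baseline.sample_slice(lfp.fs_hz, lfp.event_sample)
    times = lfp.times_ms()
    if average_trials:
        avg = power.mean(axis=0)
        mu = avg[:, sl].mean(axis=1, keepdims=True)
        sd = avg[:, sl].std(axis=1, ddof=1, keepdims=True)
        z = (avg - mu) / sd
        return z, freqs, times
    base = power[:, :, sl]  # pooled baseline bins of all trials
    mu = base.mean(axis=(0, 2))[None, :, None]
    sd = base.std(axis=(0, 2), ddof=1)[None, :, None]
    return (power - mu) / sd, freqs, times


def band_index(z: np.ndarray, freqs: np.ndarray, times_ms: np.ndarray,
               band: BandSpec, window: EpochSpec) -> float:
    """Mean z-scored power over a band x time window (one session's index).

    A significantly negative index in the high-beta band over the pre-press
    window is the operational definition of mu suppression.
    """
    fmask = band.mask(np.asarray(freqs))
    if not fmask.any():
        raise DataError(f"band {band.name!r} outside the computed frequency range")
    tmask = (times_ms >= window.start_ms) & (times_ms < window.end_ms)
    if not tmask.any():
        raise DataError(f"window {window.name!r} outside the data range")
    return float(z[np.ix_(fmask, tmask)].mean())


def band_index_significance(session_values: Sequence[float],
                            method: str = "wilcoxon") -> tuple[float, float]:
    """Test session-level band indices against zero.

    ``method`` is ``"wilcoxon"`` (signed-rank, the default) or ``"ttest"``
    (one-sample Student's t); both two-tailed. Returns (statistic, p).
    """
    v = np.asarray(session_values, dtype=float)
    if method == "wilcoxon":
        res = stats.wilcoxon(v, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "ttest":
        res = stats.ttest_1samp(v, 0.0)
        return float(res.statistic), float(res.pvalue)
    raise DataError(f"unknown method {method!r}")


def _first_run(mask: np.ndarray, n_consecutive: int,
               allow_truncated: bool = False) -> int | None:
    """Index of the first run of >= n_consecutive True values, else None."""
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= n_consecutive:
            return i - n_consecutive + 1
    # a trailing shorter run is truncated by the data end and not counted
    return None


def evoked_amplitude_latency(lfp: LfpArray, baseline: EpochSpec,
                             det: DetectionParams, amp_window: EpochSpec,
                             amplitude_mode: str = "mean"
                             ) -> tuple[float, float | None]:
    """Evoked-response amplitude and onset latency of an event-aligned LFP.

    The raw signals are averaged across contacts and trials, z-normalized
    against the baseline window, and the latency is the first bin of the
    first run of at least ``det.n_consecutive`` bins with |z| above
    ``det.z_threshold``, ignoring bins within ``det.exclusion_ms`` of the
    event. Amplitude is the mean (``amplitude_mode="mean"``) or the integral
    (``"integral"``, |z|·ms) of |z| over ``amp_window``. Returns
    ``(amplitude, latency_ms)`` with ``latency_ms=None`` when no qualifying
    run exists.
    """
    avg = lfp.data.mean(axis=(0, 1))
    sl = baseline.sample_slice(lfp.fs_hz, lfp.event_sample)
    mu, sd = avg[sl].mean(), avg[sl].std(ddof=1)
    if sd == 0:
        raise DataError("flat baseline: z-normalization undefined")
    z = (avg - mu) / sd
    times = lfp.times_ms()

    amask = (times >= amp_window.start_ms) & (times < amp_window.end_ms)
    absz = np.abs(z)
    if amplitude_mode == "mean":
        amplitude = float(absz[amask].mean())
    elif amplitude_mode == "integral":
        amplitude = float(absz[amask].sum() * 1000.0 / lfp.fs_hz)
    else:
        raise DataError(f"unknown amplitude_mode {amplitude_mode!r}")

    search = np.ones_like(times, dtype=bool)
    search &= times >= det.exclusion_ms
    if det.search_window is not None:
        search &= (times >= det.search_window.start_ms) & (times < det.search_window.end_ms)
    idx = np.where(search)[0]
    if idx.size == 0:
        return amplitude, None
    hit = _first_run(absz[idx] > det.z_threshold, det.n_consecutive)
    latency = float(times[idx[hit]]) if hit is not None else None
    return amplitude, latency


def dopamine_peak_latency(density: np.ndarray, times_ms: np.ndarray,
                          window: EpochSpec | None = None
                          ) -> tuple[float, bool]:
    """Latency of the peak of a trial-averaged spike-density function.

    The latency is the bin with the maximum amplitude within the response
    window at the native 1-ms resolution. Returns ``(latency_ms, ambiguous)``
    where ``ambiguous`` flags ties (the earliest tied bin is reported) and
    flat densities.
    """
    d = np.asarray(density, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    if window is not None:
        m = (t >= window.start_ms) & (t < window.end_ms)
        d, t = d[m], t[m]
    if d.size == 0:
        raise DataError("empty response window")
    peak = d.max()
    ties = np.where(d == peak)[0]
    return float(t[ties[0]]), bool(ties.size > 1)


def lfp_feature_pca(features: pd.DataFrame,
                    subject_col: str = "subject",
                    n_components: int = 2) -> tuple[pd.DataFrame, PCA]:
    """First principal-component scores of per-contact LFP response features.

    ``features`` has one row per contact with amplitude and latency columns
    per condition plus a subject label; rows with any missing feature
    (e.g. undetected latency) are dropped and counted in
    ``scores.attrs["n_dropped"]``. Columns are centered and scaled to unit
    variance before PCA since amplitudes and latencies are on incommensurate
    scales. Returns (scores with subject labels, fitted PCA).
    """
    feat_cols = [c for c in features.columns if c != subject_col]
    complete = features.dropna(subset=feat_cols)
    n_dropped = len(features) - len(complete)
    if len(complete) < 3:
        raise DataError("PCA needs at least 3 complete feature rows")
    X = complete[feat_cols].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    pca = PCA(n_components=min(n_components, Xs.shape[1]))
    scores = pca.fit_transform(Xs)
    out = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        index=complete.index,
    )
    out[subject_col] = complete[subject_col].values
    out.attrs["n_dropped"] = n_dropped
    return out, pca
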