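"""Spectrogram normalization, band indices, evoked detection, PCA."""

import numpy as np
import pandas as pd
import pytest

from cognophen.epochs import EpochSpec
from cognophen.errors import DataError
from cognophen.lfp import (GAMMA, HIGH_BETA, BandSpec, DetectionParams,
                           LfpArray, band_index, band_index_significance,
                           dopamine_peak_latency, evoked_amplitude_latency,
                           lfp_feature_pca, spectrogram_z)
from cognophen.syndata import SimConfig, gen_lfp_event

BASE = EpochSpec("base", -500, 0)
POST = EpochSpec("post", 0, 600)


def _noise_lfp(seed=0, trials=30, contacts=2, n=2000, event=1000):
    rng = np.random.default_rng(seed)
    return LfpArray(rng.standard_normal((trials, contacts, n)), 1000.0, event)


class TestSpectrogramZ:
    def test_baseline_mean_zero_sd_one(self):
        z, freqs, times = spectrogram_z(_noise_lfp(seed=1), BASE)
        bmask = (times >= -500) & (times < 0)
        np.testing.assert_allclose(z[:, bmask].mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z[:, bmask].std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_stationary_noise_near_zero_everywhere(self):
        z, freqs, times = spectrogram_z(_noise_lfp(seed=2, trials=200), BASE)
        inner = (times >= -800) & (times < 800)  # avoid convolution edges
        assert abs(z[:, inner].mean()) < 0.1

    def test_band_limited_drop_confined(self):
        """A 23-30 Hz power drop after the event produces negative z in the
        high-beta rows and not in distant bands."""
        cfg = SimConfig(seed=3, band_gain=0.3, n_lfp_trials=40, n_contacts=3)
        z, freqs, times = spectrogram_z(gen_lfp_event(cfg), BASE)
        idx_beta = band_index(z, freqs, times, HIGH_BETA, POST)
        idx_theta = band_index(z, freqs, times, BandSpec("theta", 4, 7), POST)
        assert idx_beta < -2
        assert idx_beta < idx_theta - 2

    def test_broadband_gain_positive_everywhere(self):
        cfg = SimConfig(seed=4, band_gain=2.0, band_hz=(1.0, 400.0),
                        n_lfp_trials=30, n_contacts=2)
        z, freqs, times = spectrogram_z(gen_lfp_event(cfg), BASE)
        tmask = (times >= 100) & (times < 500)
        assert (z[:, tmask].mean(axis=1) > 0).mean() > 0.95

    def test_above_nyquist_rejected(self):
        with pytest.raises(DataError):
            spectrogram_z(_noise_lfp(), BASE, f_range=(1.0, 600.0))


class TestBandIndex:
    def test_band_outside_range_rejected(self):
        z, freqs, times = spectrogram_z(_noise_lfp(seed=5, trials=10), BASE,
                                        f_range=(1.0, 30.0))
        with pytest.raises(DataError):
            band_index(z, freqs, times, BandSpec("hf", 60, 80), POST)

    def test_gamma_band_requires_extended_grid(self):
        z, freqs, times = spectrogram_z(_noise_lfp(seed=6, trials=10), BASE,
                                        f_range=(1.0, 55.0))
        assert np.isfinite(band_index(z, freqs, times, GAMMA, POST))

    def test_significance_methods(self):
        vals = [-0.8, -1.2, -0.5, -0.9, -1.1, -0.7, -1.0, -0.6]
        _, p_w = band_index_significance(vals, "wilcoxon")
        _, p_t = band_index_significance(vals, "ttest")
        assert p_w < 0.05 and p_t < 0.05
        with pytest.raises(DataError):
            band_index_significance(vals, "anova")


class TestEvokedDetection:
    def test_step_at_80ms_detected_at_80(self):
        cfg = SimConfig(seed=7, evoked_amplitude_sd=5.0, evoked_latency_ms=80.0,
                        n_lfp_trials=40, n_contacts=3)
        amp, lat = evoked_amplitude_latency(
            gen_lfp_event(cfg), BASE,
            DetectionParams(3.0, 30, exclusion_ms=26.0), EpochSpec("a", 26, 125))
        assert lat == pytest.approx(80.0, abs=2.0)
        assert amp > 1.0

    def test_flat_signal_no_latency(self):
        amp, lat = evoked_amplitude_latency(
            _noise_lfp(seed=8), BASE,
            DetectionParams(3.0, 30, exclusion_ms=30.0), EpochSpec("a", 31, 180))
        assert lat is None

    def test_short_excursion_under_consecutive_rule(self):
        """A 2-bin excursion does not satisfy a 3-consecutive-bin rule.

        The background is a deterministic 4-Hz sinusoid (a whole number of
        cycles inside the baseline window) whose z-scored trace peaks at
        sqrt(2) < 1.5, so the only threshold crossings are the 2-bin
        injected excursion — which the rule must skip."""
        t = np.arange(2000) / 1000.0
        trace = 0.5 * np.sin(2 * np.pi * 4 * t)
        data = np.tile(trace, (10, 2, 1))
        data[:, :, 1100:1102] += 30.0
        lfp = LfpArray(data, 1000.0, 1000)
        _, lat = evoked_amplitude_latency(
            lfp, BASE, DetectionParams(1.5, 3, exclusion_ms=30.0),
            EpochSpec("a", 31, 180))
        assert lat is None
        # the same excursion widened to 3 bins is detected
        data[:, :, 1102] += 30.0
        _, lat3 = evoked_amplitude_latency(
            LfpArray(data, 1000.0, 1000), BASE,
            DetectionParams(1.5, 3, exclusion_ms=30.0), EpochSpec("a", 31, 180))
        assert lat3 == 100.0

    def test_truncated_run_at_data_end_not_counted(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((20, 2, 1200)) * 0.01
        data[:, :, -10:] += 5.0  # 10-bin run truncated by the data end
        lfp = LfpArray(data, 1000.0, 1000)
        _, lat = evoked_amplitude_latency(
            lfp, BASE, DetectionParams(3.0, 30, exclusion_ms=30.0),
            EpochSpec("a", 31, 180))
        assert lat is None

    def test_latency_never_precedes_onset(self):
        """Threshold crossing cannot precede the true onset; it converges to
        the onset as amplitude grows."""
        lats = []
        for amp_sd in (4.0, 8.0, 16.0):
            cfg = SimConfig(seed=11, evoked_amplitude_sd=amp_sd,
                            evoked_latency_ms=120.0, n_lfp_trials=30, n_contacts=3)
            _, lat = evoked_amplitude_latency(
                gen_lfp_event(cfg), BASE,
                DetectionParams(3.0, 30, exclusion_ms=26.0), EpochSpec("a", 26, 300))
            lats.append(lat)
        assert all(l is not None and l >= 119.0 for l in lats)
        assert lats[-1] <= lats[0]


class TestDopaminePeak:
    def test_gaussian_bump_peak(self):
        t = np.arange(0, 400.0)
        d = np.exp(-((t - 120) ** 2) / (2 * 15 ** 2))
        lat, amb = dopamine_peak_latency(d, t)
        assert lat == 120.0 and not amb

    def test_flat_flagged_ambiguous(self):
        t = np.arange(0, 100.0)
        lat, amb = dopamine_peak_latency(np.ones_like(t), t)
        assert lat == 0.0 and amb

    def test_tie_earlier_bin(self):
        t = np.arange(0, 100.0)
        d = np.zeros_like(t)
        d[[30, 60]] = 1.0
        lat, amb = dopamine_peak_latency(d, t)
        assert lat == 30.0 and amb


class TestFeaturePca:
    def test_separated_clusters_silhouette(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(12)
        rows = []
        for subj, (amp, lat) in {"A": (2.0, 60.0), "B": (8.0, 140.0)}.items():
            for _ in range(30):
                rows.append({"subject": subj,
                             "amp_self": amp + rng.normal(0, 0.2),
                             "amp_partner": amp + rng.normal(0, 0.2),
                             "lat_self": lat + rng.normal(0, 3),
                             "lat_partner": lat + rng.normal(0, 3)})
        scores, _ = lfp_feature_pca(pd.DataFrame(rows))
        s = silhouette_score(scores[["PC1", "PC2"]], scores["subject"])
        assert s > 0.5

    def test_identical_rows_zero_scores(self):
        df = pd.DataFrame({"subject": ["A"] * 5, "f1": 3.0, "f2": 7.0})
        scores, _ = lfp_feature_pca(df)
        np.testing.assert_allclose(scores[["PC1", "PC2"]].to_numpy(), 0.0, atol=1e-12)

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame({"subject": list("AAAB"),
                           "f1": [1.0, 2.0, np.nan, 4.0],
                           "f2": [1.0, 2.0, 3.0, 4.0]})
        scores, _ = lfp_feature_pca(df)
        assert scores.attrs["n_dropped"] == 1 and len(scores) == 3

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"subject": ["A", "B"], "f1": [1.0, 2.0], "f2": [0.0, 1.0]})
        with pytest.raises(DataError):
            lfp_feature_pca(df)
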