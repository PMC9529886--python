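"""Inter-areal LFP analyses.

Bipolar re-referencing, baseline-subtracted Morlet wavelet coherence between
two regions, time-domain pairwise-conditional Granger causality (GC) from
OLS-fitted vector autoregressions with AIC order selection and
Benjamini-Hochberg FDR over channel pairs, and the causal flow-bias
statistic: the proportion of channel pairs with significant top-down GC
minus the proportion with significant bottom-up GC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.stattools import adfuller

from cognophen.epochs import EpochSpec
from cognophen.errors import DataError
from cognophen.lfp import COHERENCE_BANDS, BandSpec, LfpArray, morlet_tfr


def bipolar_derive(lfp: LfpArray) -> LfpArray:
    """First spatial derivative of adjacent contacts, toward the superficial end.

    Bipolar channel ``k`` is ``contact k − contact k+1`` (contact 0 is the
    most superficial), removing signal common to neighbouring contacts before
    connectivity analysis. An n-contact probe yields n−1 bipolar channels.
    """
    if lfp.n_contacts < 2:
        raise DataError("bipolar derivation needs at least 2 contacts")
    diff = lfp.data[:, :-1, :] - lfp.data[:, 1:, :]
    return LfpArray(diff, lfp.fs_hz, lfp.event_sample,
                    alignment_event=lfp.alignment_event,
                    contact_spacing_um=lfp.contact_spacing_um)


def default_coherence_freqs(n: int = 24) -> np.ndarray:
    """24 log-spaced wavelet center frequencies from 1 to 128 Hz."""
    return np.logspace(np.log10(1.0), np.log10(128.0), n)


def wavelet_coherence(region_a: LfpArray, region_b: LfpArray,
                      baseline: EpochSpec,
                      freqs: Optional[np.ndarray] = None,
                      pairs: Optional[Sequence[tuple[int, int]]] = None,
                      n_cycles: float = 7.0) -> dict:
    """Trial-averaged magnitude-squared wavelet coherence per channel pair.

    Single-trial traces are concatenated per channel, convolved with complex
    Morlet wavelets, and split back into trials. For channels x and y the
    coherence is ``|<Wx Wy*>|^2 / (<|Wx|^2><|Wy|^2>)`` with the averages
    over trials, giving a freq x time map in [0, 1]; the per-frequency mean
    over the baseline window is then subtracted. Band averages over the
    seven canonical bands (delta through high gamma) are included.

    Returns a dict with ``pairs, freqs, times_ms, raw, coherence`` (the
    baseline-subtracted maps, shape pairs x freqs x time) and ``bands``
    (DataFrame of stimulus-window band averages).
    """
    if region_a.n_trials != region_b.n_trials:
        raise DataError("regions must have equal trial counts")
    if region_a.n_trials < 8:
        raise DataError("coherence needs at least 8 trials for stable estimates")
    if region_a.event_sample != region_b.event_sample \
            or region_a.n_samples != region_b.n_samples:
        raise DataError("regions must share alignment and sample count")
    if freqs is None:
        freqs = default_coherence_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if pairs is None:
        pairs = [(i, j) for i in range(region_a.n_contacts)
                 for j in range(region_b.n_contacts)]

    ntr, nw = region_a.n_trials, region_a.n_samples

    def tfr(region: LfpArray) -> np.ndarray:
        # concatenate trials -> (contacts, ntr*nw), convolve, split back
        concat = np.transpose(region.data, (1, 0, 2)).reshape(region.n_contacts, ntr * nw)
        W = morlet_tfr(concat, freqs, region.fs_hz, n_cycles)
        return W.reshape(region.n_contacts, len(freqs), ntr, nw)

    Wa, Wb = tfr(region_a), tfr(region_b)
    sl = baseline.sample_slice(region_a.fs_hz, region_a.event_sample)
    times = region_a.times_ms()

    raw = np.empty((len(pairs), len(freqs), nw))
    norm = np.empty_like(raw)
    for k, (i, j) in enumerate(pairs):
        Sxy = np.mean(Wa[i].transpose(1, 0, 2) * np.conj(Wb[j].transpose(1, 0, 2)), axis=0)
        Sxx = np.mean(np.abs(Wa[i]) ** 2, axis=1)
        Syy = np.mean(np.abs(Wb[j]) ** 2, axis=1)
        coh = np.abs(Sxy) ** 2 / (Sxx * Syy)
        raw[k] = coh
        norm[k] = coh - coh[:, sl].mean(axis=1, keepdims=True)

    stim_mask = times >= 0
    band_rows = []
    for band in COHERENCE_BANDS:
        fmask = band.mask(freqs)
        if not fmask.any():
            continue
        vals = norm[:, fmask][:, :, stim_mask].mean(axis=(1, 2))
        for k, (i, j) in enumerate(pairs):
            band_rows.append({"band": band.name, "pair": (i, j), "coherence": vals[k]})
    return {
        "pairs": list(pairs),
        "freqs": freqs,
        "times_ms": times,
        "raw": raw,
        "coherence": norm,
        "bands": pd.DataFrame(band_rows),
    }


@dataclass
class GCParams:
    """Estimation parameters of the pairwise Granger-causality analysis."""

    max_order: int = 50          # samples (ms at 1 kHz)
    criterion: str = "aic"
    fdr_q: float = 0.05
    adf_alpha: float = 0.05      # unit-root screen: exclude when p > alpha
    cond_max: float = 1e8        # regressor condition-number cap

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise DataError("max_order must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise DataError("fdr_q must lie in (0, 1)")


def _segments(region: LfpArray, window: EpochSpec) -> np.ndarray:
    sl = window.sample_slice(region.fs_hz, region.event_sample)
    if sl.start < 0 or sl.stop > region.n_samples:
        raise DataError(f"window {window.name!r} outside the data range")
    return region.data[:, :, sl]  # trials x contacts x nw


def _stack_lags(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled response/lag matrices from multi-trial segments (ntr, nw)."""
    y = x[:, p:].reshape(-1)
    lags = np.stack([x[:, p - l:x.shape[1] - l].reshape(-1) for l in range(1, p + 1)], axis=1)
    return y, lags


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _fit_pair(x: np.ndarray, y: np.ndarray, p: int) -> dict:
    """Full and restricted OLS fits of the bivariate VAR(p) for one pair."""
    yx, Lx = _stack_lags(x, p)
    yy, Ly = _stack_lags(y, p)
    N = yx.size
    ones = np.ones((N, 1))
    X_full = np.hstack([ones, Lx, Ly])
    rss = {
        "x_full": _ols_rss(yx, X_full),
        "x_restr": _ols_rss(yx, np.hstack([ones, Lx])),
        "y_full": _ols_rss(yy, X_full),
        "y_restr": _ols_rss(yy, np.hstack([ones, Ly])),
        "N": N,
        "cond": float(np.linalg.cond(X_full)),
    }
    return rss


def _aic_order(x: np.ndarray, y: np.ndarray, max_order: int) -> int:
    """AIC-selected bivariate VAR order, fitted on pooled trial segments."""
    nw = x.shape[1]
    best_p, best_aic = 1, np.inf
    upper = min(max_order, nw // 3)
    for p in range(1, max(upper, 1) + 1):
        yx, Lx = _stack_lags(x, p)
        yy, Ly = _stack_lags(y, p)
        N = yx.size
        X = np.hstack([np.ones((N, 1)), Lx, Ly])
        bx, _, _, _ = np.linalg.lstsq(X, yx, rcond=None)
        by, _, _, _ = np.linalg.lstsq(X, yy, rcond=None)
        E = np.stack([yx - X @ bx, yy - X @ by], axis=1)
        sigma = (E.T @ E) / N
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        k_params = 2 * (2 * p + 1)
        aic = N * logdet + 2 * k_params
        if aic < best_aic:
            best_aic, best_p = aic, p
    return best_p


def _adf_stationary(x: np.ndarray, alpha: float) -> bool:
    """Augmented unit-root screen: majority of the first 3 trial segments
    must reject a unit root (concatenating segments would mask drifting
    trials through the demeaning jumps at segment boundaries)."""
    ps = []
    for seg in x[:3]:
        try:
            ps.append(adfuller(seg, maxlag=10, autolag=None)[1])
        except Exception:
            ps.append(1.0)
    return float(np.median(ps)) < alpha


def pairwise_gc(region_a: LfpArray, region_b: LfpArray, window: EpochSpec,
                params: GCParams | None = None) -> pd.DataFrame:
    """Time-domain Granger causality for every cross-region channel pair.

    For each pair a bivariate VAR is fitted on the pooled per-trial window
    segments (order by AIC up to ``params.max_order``, OLS estimation), and
    the GC in each direction is ``ln(sigma^2_restricted / sigma^2_full)`` of
    the target channel's equation, tested with the nested-model F statistic.
    P-values are Benjamini-Hochberg adjusted over all pair x direction tests
    at ``params.fdr_q``. Pairs failing the unit-root screen or whose
    regressor matrix is ill-conditioned are excluded with a reason.

    Returns a frame with one row per pair and direction: ``chan_a, chan_b,
    direction ("top_down" = a->b, "bottom_up" = b->a), order, gc, F, p, q,
    significant, excluded, reason``.
    """
    params = params or GCParams()
    A = _segments(region_a, window)
    B = _segments(region_b, window)
    if A.shape[0] != B.shape[0]:
        raise DataError("regions must have equal trial counts")

    ok_a = [_adf_stationary(A[:, i, :], params.adf_alpha) for i in range(A.shape[1])]
    ok_b = [_adf_stationary(B[:, j, :], params.adf_alpha) for j in range(B.shape[1])]

    rows = []
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            base = {"chan_a": i, "chan_b": j}
            if not (ok_a[i] and ok_b[j]):
                for direction in ("top_down", "bottom_up"):
                    rows.append({**base, "direction": direction, "order": 0,
                                 "gc": np.nan, "F": np.nan, "p": np.nan,
                                 "excluded": True, "reason": "non-stationary"})
                continue
            x = A[:, i, :]
            y = B[:, j, :]
            p_ord = _aic_order(x, y, params.max_order)
            try:
                fit = _fit_pair(x, y, p_ord)
            except np.linalg.LinAlgError:
                for direction in ("top_down", "bottom_up"):
                    rows.append({**base, "direction": direction, "order": p_ord,
                                 "gc": np.nan, "F": np.nan, "p": np.nan,
                                 "excluded": True, "reason": "singular"})
                continue
            if fit["cond"] > params.cond_max:
                for direction in ("top_down", "bottom_up"):
                    rows.append({**base, "direction": direction, "order": p_ord,
                                 "gc": np.nan, "F": np.nan, "p": np.nan,
                                 "excluded": True, "reason": "ill-conditioned"})
                continue
            N = fit["N"]
            df2 = N - (2 * p_ord + 1)
            for direction, (r, f) in (
                ("top_down", (fit["y_restr"], fit["y_full"])),   # a -> b: b's equation
                ("bottom_up", (fit["x_restr"], fit["x_full"])),  # b -> a: a's equation
            ):
                gc = float(np.log(r / f)) if f > 0 else np.inf
                F = ((r - f) / p_ord) / (f / df2) if f > 0 and df2 > 0 else np.nan
                pval = float(stats.f.sf(F, p_ord, df2)) if np.isfinite(F) else np.nan
                rows.append({**base, "direction": direction, "order": p_ord,
                             "gc": max(gc, 0.0), "F": F, "p": pval,
                             "excluded": False, "reason": ""})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["q"] = np.nan
    out["significant"] = False
    if tested.any():
        rej, q, _, _ = multipletests(out.loc[tested, "p"], alpha=params.fdr_q,
                                     method="fdr_bh")
        out.loc[tested, "q"] = q
        out.loc[tested, "significant"] = rej
    return out


@dataclass
class FlowBiasResult:
    """Proportions of significantly causal channel pairs per direction."""

    prop_top_down: float
    prop_bottom_up: float
    bias: float
    n_pairs: int
    per_pair: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.n_pairs > 0:
            assert abs(self.bias - (self.prop_top_down - self.prop_bottom_up)) < 1e-12


def flow_bias(gc_results: pd.DataFrame) -> FlowBiasResult:
    """Causal flow bias of one session's pairwise GC table.

    Bias = (proportion of valid channel pairs with significant top-down GC)
    − (proportion with significant bottom-up GC), in [−1, 1]. Positive bias
    means predominantly top-down information flow. Excluded pairs do not
    enter the denominator; with no valid pairs the result is flagged NaN.
    """
    valid = gc_results[~gc_results["excluded"]]
    pair_ids = valid.groupby(["chan_a", "chan_b"]).size()
    n_pairs = len(pair_ids)
    if n_pairs == 0:
        return FlowBiasResult(float("nan"), float("nan"), float("nan"), 0, gc_results)
    ptd = valid[(valid.direction == "top_down") & valid.significant] \
        .groupby(["chan_a", "chan_b"]).size().size / n_pairs
    pbu = valid[(valid.direction == "bottom_up") & valid.significant] \
        .groupby(["chan_a", "chan_b"]).size().size / n_pairs
    return FlowBiasResult(float(ptd), float(pbu), float(ptd - pbu), n_pairs, gc_results)


def flow_bias_tests(session_biases: Sequence[float],
                    other_subject_biases: Optional[Sequence[float]] = None) -> dict:
    """Across-session tests of the flow bias: Wilcoxon signed-rank against
    zero, and (optionally) a Welch t comparison with another subject's
    session biases. Returns a dict of statistics and two-tailed p-values."""
    v = np.asarray(session_biases, dtype=float)
    out: dict = {"n_sessions": int(v.size)}
    if np.any(v != 0):
        w = stats.wilcoxon(v, alternative="two-sided")
        out["wilcoxon_W"], out["wilcoxon_p"] = float(w.statistic), float(w.pvalue)
    else:
        out["wilcoxon_W"], out["wilcoxon_p"] = 0.0, 1.0
    if other_subject_biases is not None:
        t = stats.ttest_ind(v, np.asarray(other_subject_biases, dtype=float),
                            equal_var=False)
        out["welch_t"], out["welch_p"] = float(t.statistic), float(t.pvalue)
    return out
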