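"""Welch band-power spectra and minimum-norm source estimation.

Spectral band power is estimated with Welch's periodogram (Hamming tapers,
50% overlap, segments of a quarter of the analysis window) on matched
stimulation and baseline windows, reported as the base-2 log power ratio.
Source time courses come from the Tikhonov-regularized minimum-L2-norm
inverse of a (synthetic) leadfield; run-wise averages are recombined with
trial-count weights, which reproduces the pooled-trial mean exactly.
"""

from __future__ import annotations

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import check_window, window_slice
from .simulate import Leadfield
from .timefreq import Band

__all__ = [
    "welch_psd", "welch_band_ratio", "MinimumNormInverse", "minnorm_inverse",
    "weighted_run_average", "default_lambda",
]


def welch_psd(x: np.ndarray, fs: float, nperseg: int | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hamming tapers and 50% overlap along the last axis."""
    n = x.shape[-1]
    if nperseg is None:
        nperseg = max(8, n // 4)
    nperseg = min(nperseg, n)
    return scipy.signal.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                              noverlap=nperseg // 2, axis=-1)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: Band) -> np.ndarray:
    sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if sel.sum() < 2:
        # integrate over at least two bins around the band
        sel = np.abs(freqs - 0.5 * (band.f_lo + band.f_hi)) <= max(
            np.diff(freqs).mean(), 0.5 * (band.f_hi - band.f_lo))
    return np.trapezoid(psd[..., sel], freqs[sel], axis=-1)


def welch_band_ratio(signal: np.ndarray, fs: float, times: np.ndarray,
                     stim_window: tuple[float, float],
                     base_window: tuple[float, float], band: Band
                     ) -> np.ndarray:
    """Base-2 log ratio of band-integrated Welch power, stimulation over
    baseline, for time courses with a trailing sample axis.

    Both windows must have (nearly) the same length so the two PSDs share
    their frequency resolution.
    """
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    check_window(times, stim_window, "stimulation window")
    check_window(times, base_window, "baseline window")
    s_sl = window_slice(times, stim_window)
    b_sl = window_slice(times, base_window)
    n_s = s_sl.stop - s_sl.start
    n_b = b_sl.stop - b_sl.start
    if abs(n_s - n_b) > 1:
        raise ValueError("stimulation and baseline windows must have equal length")
    n = min(n_s, n_b)
    f_s, p_s = welch_psd(signal[..., s_sl][..., :n], fs)
    f_b, p_b = welch_psd(signal[..., b_sl][..., :n], fs)
    bp_s = _band_power(f_s, p_s, band)
    bp_b = _band_power(f_b, p_b, band)
    if np.any(bp_b <= 0):
        raise ValueError("zero baseline band power")
    return np.log2(bp_s / bp_b)


# ---------------------------------------------------------------------------
# minimum-norm inverse
# ---------------------------------------------------------------------------

def default_lambda(gain: np.ndarray, snr: float = 3.0) -> float:
    """Regularization from the usual SNR rule: trace(G G^T)/(n_sensors SNR^2)."""
    n = gain.shape[0]
    return float(np.trace(gain @ gain.T) / (n * snr**2))


class MinimumNormInverse(BaseEstimator, TransformerMixin):
    """Minimum-L2-norm inverse operator (scikit-learn transformer).

    ``fit`` precomputes the kernel ``G^T (G G^T + lam I)^{-1}``;
    ``transform`` maps sensor epochs (trials x sensors x samples, or a
    single sensors x samples array) to source time courses.

    ``lam=None`` applies the SNR-3 default rule.  ``lam=0`` is allowed only
    when ``G G^T`` is well-conditioned.
    """

    def __init__(self, leadfield: Leadfield | None = None,
                 lam: float | None = None, snr: float = 3.0):
        self.leadfield = leadfield
        self.lam = lam
        self.snr = snr

    def fit(self, X=None, y=None):
        if self.leadfield is None:
            raise ValueError("a Leadfield is required")
        g = np.asarray(self.leadfield.gain, dtype=float)
        lam = default_lambda(g, self.snr) if self.lam is None else float(self.lam)
        if lam < 0:
            raise ValueError("lam must be non-negative")
        gram = g @ g.T + lam * np.eye(g.shape[0])
        cond = np.linalg.cond(gram)
        if lam == 0 and cond > 1e12:
            raise np.linalg.LinAlgError(
                "G G^T is singular; a positive regularization lam is required")
        self.lam_ = lam
        self.kernel_ = np.linalg.solve(gram, g).T  # sources x sensors
        return self

    def transform(self, X) -> np.ndarray:
        data = X.data if hasattr(X, "data") and hasattr(X, "times") else np.asarray(X)
        if data.ndim == 2:
            return self.kernel_ @ data
        if data.ndim == 3:
            return np.einsum("qs,tsn->tqn", self.kernel_, data)
        raise ValueError("expected (trials x) sensors x samples input")


def minnorm_inverse(leadfield: Leadfield, lam: float | None, epochs
                    ) -> np.ndarray:
    """Apply the minimum-norm kernel to every trial; thin wrapper."""
    return MinimumNormInverse(leadfield, lam).fit().transform(epochs)


def weighted_run_average(run_means: np.ndarray, trial_counts) -> np.ndarray:
    """Trial-count-weighted average of per-run means.

    Equals the grand mean of all trials pooled across runs; runs with zero
    trials contribute nothing.
    """
    run_means = np.asarray(run_means, dtype=float)
    counts = np.asarray(trial_counts, dtype=float)
    if counts.ndim != 1 or counts.shape[0] != run_means.shape[0]:
        raise ValueError("need one trial count per run")
    if (counts < 0).any():
        raise ValueError("trial counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all trial counts are zero")
    w = counts / total
    return np.tensordot(w, run_means, axes=(0, 0))
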