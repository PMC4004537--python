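"""Single-trial percept decoding with Common Spatial Patterns.

The decoder band-pass filters raw sensor signals (default 17-22 Hz, the
wavelet-resolution-shrunk beta band), computes per-class trial-averaged
normalized covariances over a post-onset window, and solves the two-class
simultaneous-diagonalization problem.  The five spatial filters whose
generalized eigenvalues deviate most from 0.5 project each trial onto
log-variance features, which a linear discriminant classifies.

Classification rates come from stratified 90/10 train/test splits repeated
ten times; significance is assessed against a reference distribution of a
hundred rates computed after pooling (permuting) the class labels, the
observed mean rate counting as significant only when it beats the 95th
percentile of that reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.signal
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from ._utils import substream, window_slice
from .epochs import Epochs

__all__ = [
    "CSPDecoder", "DecodingResult", "balance_classes", "fit_csp",
    "crossval_rate", "permutation_significance",
]

logger = logging.getLogger(__name__)


@dataclass
class DecodingResult:
    """Cross-validated decoding rates and their permutation reference."""

    rate_per_repeat: np.ndarray
    mean_rate: float
    null_rates: np.ndarray | None = None
    significant: bool | None = None
    n_trials_used: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.mean_rate, np.mean(self.rate_per_repeat)):
            raise ValueError("mean_rate must equal mean(rate_per_repeat)")


def _bandpass_fir(data: np.ndarray, fs: float, band: tuple[float, float]
                  ) -> np.ndarray:
    """Zero-phase (forward-backward) FIR band-pass along the last axis."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError("band must lie below Nyquist")
    numtaps = int(3.3 * fs / max(lo, 1.0)) | 1  # odd, ~3 cycles of f_lo
    taps = scipy.signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                               window="hamming")
    padlen = min(3 * numtaps, data.shape[-1] - 1)
    return scipy.signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


class CSPDecoder(BaseEstimator, ClassifierMixin):
    """CSP + linear-discriminant percept classifier (scikit-learn style).

    Parameters
    ----------
    band : (float, float)
        Band-pass passband in Hz applied to the raw trials.
    window : (float, float)
        Feature window in ms relative to motion onset (default 100-1100 ms).
    n_filters : int
        Number of retained spatial filters, most discriminative first.
    shrinkage : float
        Weight of the scaled-identity shrinkage applied to each class
        covariance before the eigendecomposition.
    fs : float
        Sampling rate; overridden by ``Epochs`` input.
    times : array or None
        Per-sample times in ms for plain-array input (defaults to sample
        index * 1000/fs).

    Fitted attributes: ``filters_`` (n_filters x sensors), ``eigenvalues_``
    (class-A variance ratios in (0,1)), ``lda_``, ``classes_``.
    """

    def __init__(self, band: tuple[float, float] = (17.0, 22.0),
                 window: tuple[float, float] = (100.0, 1100.0),
                 n_filters: int = 5, shrinkage: float = 0.05,
                 fs: float = 250.0, times=None,
                 assume_preprocessed: bool = False,
                 cov_norm: str = "pooled"):
        self.band = band
        self.window = window
        self.n_filters = n_filters
        self.shrinkage = shrinkage
        self.fs = fs
        self.times = times
        self.assume_preprocessed = assume_preprocessed
        self.cov_norm = cov_norm

    # -- helpers ------------------------------------------------------------
    def _prepare(self, X) -> np.ndarray:
        if self.assume_preprocessed:
            data = X.data if isinstance(X, Epochs) else np.asarray(X, dtype=float)
            if data.ndim != 3:
                raise ValueError("expected trials x sensors x samples")
            return data
        if isinstance(X, Epochs):
            data, times, fs = X.data, X.times, X.fs
        else:
            data = np.asarray(X, dtype=float)
            fs = self.fs
            times = (np.asarray(self.times, dtype=float) if self.times is not None
                     else np.arange(data.shape[-1]) * 1000.0 / fs)
        if data.ndim != 3:
            raise ValueError("expected trials x sensors x samples")
        filt = _bandpass_fir(data, fs, self.band)
        return filt[:, :, window_slice(times, self.window)]

    def _cov(self, trials: np.ndarray, scale: float = 1.0) -> np.ndarray:
        covs = np.einsum("tsn,tun->tsu", trials, trials)
        if self.cov_norm == "trace":
            covs = covs / np.trace(covs, axis1=1, axis2=2)[:, None, None]
            c = covs.mean(axis=0)
        elif self.cov_norm == "pooled":
            # single scalar conditioning: preserves the absolute power
            # differences between classes that carry the percept effect
            c = covs.mean(axis=0) / scale
        else:
            raise ValueError("cov_norm must be 'pooled' or 'trace'")
        n = c.shape[0]
        return (1.0 - self.shrinkage) * c + self.shrinkage * np.trace(c) / n * np.eye(n)

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("CSP decoding is two-class")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("need at least 2 trials per class")
        trials = self._prepare(X)
        scale = float(np.einsum("tsn,tsn->", trials, trials) / trials.shape[0])
        ca = self._cov(trials[y == self.classes_[0]], scale)
        cb = self._cov(trials[y == self.classes_[1]], scale)
        # generalized eigenproblem: Ca w = lambda (Ca + Cb) w
        evals, evecs = scipy.linalg.eigh(ca, ca + cb)
        order = np.argsort(-np.abs(evals - 0.5), kind="stable")[:self.n_filters]
        self.eigenvalues_ = evals[order]
        self.filters_ = evecs[:, order].T
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.fit(self._features(trials), y)
        return self

    def _features(self, trials: np.ndarray) -> np.ndarray:
        proj = np.einsum("fs,tsn->tfn", self.filters_, trials)
        var = proj.var(axis=2, ddof=0)
        return np.log(np.clip(var, 1e-30, None))

    def predict(self, X):
        return self.lda_.predict(self._features(self._prepare(X)))

    def decision_function(self, X):
        return self.lda_.decision_function(self._features(self._prepare(X)))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def balance_classes(labels, seed: int = 0) -> np.ndarray:
    """Indices downsampling each class to the minority count, drawn
    uniformly at random (reproducible from ``seed``).

    Returned indices are sorted, so trial order is preserved.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("expected exactly two classes")
    if counts.min() == 0:
        raise ValueError("a class has zero trials")
    rng = substream(seed, "class-balance")
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


def fit_csp(X, labels, band=(17.0, 22.0), window=(100.0, 1100.0),
            n_filters: int = 5, fs: float = 250.0, times=None) -> CSPDecoder:
    """Fit a :class:`CSPDecoder` on (balanced) trials; thin wrapper."""
    dec = CSPDecoder(band=band, window=window, n_filters=n_filters,
                     fs=fs, times=times)
    return dec.fit(X, labels)


def crossval_rate(X, labels, decoder: CSPDecoder | None = None,
                  n_repeats: int = 10, test_frac: float = 0.1,
                  seed: int = 0) -> DecodingResult:
    """Mean accuracy over stratified random train/test splits.

    The CSP filters and the classifier are fit on the training split only;
    each of the ``n_repeats`` splits holds out ``test_frac`` of the trials.
    """
    labels = np.asarray(labels)
    if decoder is None:
        decoder = CSPDecoder()
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 10:
        raise ValueError("need at least 10 trials per class for 90/10 splits")
    rng = substream(seed, "crossval-splits")
    splitter = StratifiedShuffleSplit(n_splits=n_repeats, test_size=test_frac,
                                      random_state=int(rng.integers(2**31)))
    decoder = clone(decoder)
    if isinstance(X, Epochs):
        decoder.fs = X.fs
        decoder.times = X.times
    # the band-pass filter and window crop are per-trial operations, so they
    # can be applied once up front without any train/test leakage
    data = decoder._prepare(X)
    decoder.assume_preprocessed = True
    rates = []
    for train, test in splitter.split(np.zeros(len(labels)), labels):
        if np.unique(labels[test]).size < 2:
            logger.info("re-drawing a single-class test split")
            continue
        est = clone(decoder).fit(data[train], labels[train])
        rates.append(est.score(data[test], labels[test]))
    rates = np.asarray(rates)
    return DecodingResult(rates, float(rates.mean()),
                          n_trials_used=len(labels))


def permutation_significance(X, labels, decoder: CSPDecoder | None = None,
                             n_null: int = 100, n_repeats: int = 10,
                             test_frac: float = 0.1, seed: int = 0,
                             null_scheme: str = "permutation"
                             ) -> DecodingResult:
    """Observed cross-validated rate against a reference distribution.

    ``null_scheme="permutation"`` (default): the reference rates are
    cross-validated accuracies under independent random permutations of the
    class labels.  ``null_scheme="self"``: labels are permuted and the
    classifier is scored on its own training set (the
    train-equals-test reading of a pooled-trial reference).
    The observed rate is significant iff it exceeds the 95th percentile of
    the ``n_null`` reference rates.
    """
    if null_scheme not in ("permutation", "self"):
        raise ValueError("null_scheme must be 'permutation' or 'self'")
    labels = np.asarray(labels)
    base = clone(decoder) if decoder is not None else CSPDecoder()
    if isinstance(X, Epochs):
        base.fs = X.fs
        base.times = X.times
    data = base._prepare(X)
    base.assume_preprocessed = True
    observed = crossval_rate(data, labels, base, n_repeats, test_frac, seed)
    rng = substream(seed, "decoding-null")
    null_rates = np.empty(n_null)
    for i in range(n_null):
        perm = rng.permutation(labels)
        if null_scheme == "permutation":
            r = crossval_rate(data, perm, base, n_repeats, test_frac,
                              seed=int(rng.integers(2**31)))
            null_rates[i] = r.mean_rate
        else:
            est = clone(base).fit(data, perm)
            null_rates[i] = est.score(data, perm)
    significant = observed.mean_rate > np.percentile(null_rates, 95.0)
    return DecodingResult(observed.rate_per_repeat, observed.mean_rate,
                          null_rates, bool(significant), len(labels))
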