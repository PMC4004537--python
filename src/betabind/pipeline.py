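"""End-to-end analysis pipeline on simulated sessions.

Order of stages: artifact rejection -> Morlet time-frequency maps ->
data-driven band identification (alpha/beta/gamma) -> per-band spatio-
temporal cluster permutation tests contrasting bound vs unbound reports
(cluster alpha 0.01, since three bands are tested) -> CSP decoding on the
sensors and window flagged by the beta cluster -> Welch spectra and
minimum-norm source contrast.  Unclassified trials are excluded from every
percept contrast.  All randomness flows from one master seed through named
substreams, so a (config, seed) pair fully determines the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict

import numpy as np
import pandas as pd

from ._utils import substream, window_slice
from .cluster import ClusterResult, cluster_test
from .config import SessionConfig
from .csp import CSPDecoder, balance_classes, permutation_significance
from .epochs import Epochs
from .layout import make_layout
from .simulate import (DEFAULT_PTP_THRESHOLD, make_leadfield, reject_artifacts,
                       simulate_session)
from .spectra import MinimumNormInverse, weighted_run_average, welch_band_ratio
from .timefreq import (ALPHA_BAND, BETA_BAND, DEFAULT_BASELINE, GAMMA_BAND,
                       Band, MorletTFR, TFPower, band_average,
                       baseline_log2ratio, identify_band, shrink_band)

__all__ = ["run_pipeline", "band_power_trials", "pooled_tf"]

logger = logging.getLogger(__name__)

_STIM_WINDOW = (0.0, 1200.0)
_DECODE_WINDOW = (100.0, 1100.0)


def _log_stage(name, t0):
    logger.info("stage %-10s %6.1f s", name, time.perf_counter() - t0)


def _auto_chunk(epochs: Epochs, n_freqs: int) -> int:
    # bound the per-chunk TF array to ~2e8 float32 values (~800 MB)
    per_trial = epochs.n_sensors * n_freqs * epochs.n_samples
    return max(4, int(2e8 / max(per_trial, 1)))


def pooled_tf(epochs: Epochs, freqs: np.ndarray, m: float = 10.0,
              chunk: int | None = None) -> TFPower:
    """Trial-averaged raw TF power (single pseudo-trial), chunked to bound
    memory."""
    if chunk is None:
        chunk = _auto_chunk(epochs, len(freqs))
    tfr = MorletTFR(m=m, freqs=freqs, fs=epochs.fs)
    acc = None
    for lo in range(0, epochs.n_trials, chunk):
        tf = tfr.transform(epochs.select(np.arange(lo, min(lo + chunk, epochs.n_trials))))
        s = tf.values.sum(axis=0)
        acc = s if acc is None else acc + s
        template = tf
    template.values = (acc / epochs.n_trials)[None]
    return template


def band_power_trials(epochs: Epochs, band: Band, m: float = 10.0,
                      baseline: tuple[float, float] = DEFAULT_BASELINE,
                      chunk: int | None = None, normalize: bool = True
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial band-averaged (optionally log2-baseline-normalized) power.

    Returns ``(power, times)`` with power trials x sensors x samples;
    samples outside every band frequency's valid range are NaN.  The
    baseline is estimated from all trials (two passes over the data).
    """
    freqs = np.arange(np.floor(band.f_lo), np.ceil(band.f_hi) + 1.0)
    if chunk is None:
        chunk = _auto_chunk(epochs, len(freqs))
    tfr = MorletTFR(m=m, freqs=freqs, fs=epochs.fs)
    # Band-averaging the per-frequency log2 baseline ratio equals
    # band-averaging log2 power and subtracting the band-averaged log2
    # baseline, so one streaming pass suffices: accumulate the trial-mean
    # baseline power per sensor and frequency alongside the band averages,
    # and apply the baseline correction at the end.
    out = []
    base_acc = None
    tf_meta = None
    for lo in range(0, epochs.n_trials, chunk):
        idx = np.arange(lo, min(lo + chunk, epochs.n_trials))
        tf = tfr.transform(epochs.select(idx))
        tf_meta = tf
        if normalize:
            sl = window_slice(tf.times, baseline)
            s = np.empty((tf.values.shape[1], tf.freqs.size))
            for j in range(tf.freqs.size):
                ok = tf.valid_mask[j, sl]
                s[:, j] = tf.values[:, :, j, sl][:, :, ok].sum(axis=(0, 2)) / max(ok.sum(), 1)
            base_acc = s * idx.size if base_acc is None else base_acc + s * idx.size
            tf.values = np.log2(np.clip(tf.values, np.finfo(np.float32).tiny,
                                        None))
        out.append(band_average(tf, band))
    bp = np.concatenate(out, axis=0)
    if normalize:
        base = base_acc / epochs.n_trials  # sensors x freqs
        if (base <= 0).any():
            raise ValueError("zero baseline power")
        sel = (tf_meta.freqs >= band.f_lo) & (tf_meta.freqs <= band.f_hi)
        w = tf_meta.valid_mask[sel, :].astype(float)  # band freqs x samples
        denom = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.einsum("sf,fn->sn", np.log2(base[:, sel]), w) / denom
        bp = bp - corr[None, :, :]
    return bp, tf_meta.times


def _identify_bands(epochs: Epochs, freqs: np.ndarray, m: float) -> dict[str, Band]:
    """Data-driven alpha/beta/gamma bands from the pooled (all-trial) TF.

    Alpha from raw baseline power over occipito-parietal sensors; beta from
    the left-motor stimulation-window deactivation; gamma from the
    occipital stimulation-window activation (both baseline-corrected).
    Falls back to the canonical bands when no sustained band is found.
    """
    raw = pooled_tf(epochs, freqs, m)
    norm = baseline_log2ratio(raw, DEFAULT_BASELINE)
    bands = {}
    specs = {
        "alpha": (raw, "occipito-parietal", DEFAULT_BASELINE, "increase",
                  (5.0, 15.0), ALPHA_BAND),
        "beta": (norm, "left-motor", _STIM_WINDOW, "decrease",
                 (10.0, 40.0), BETA_BAND),
        "gamma": (norm, "occipital", _STIM_WINDOW, "increase",
                  (40.0, 100.0), GAMMA_BAND),
    }
    for name, (tf, group, window, pol, rng_hz, fallback) in specs.items():
        try:
            b = identify_band(tf, group, window, pol, rng_hz,
                              layout=epochs.layout, name=name)
        except ValueError as err:
            logger.warning("band identification for %s failed (%s); using "
                           "canonical [%g, %g] Hz", name, err,
                           fallback.f_lo, fallback.f_hi)
            b = fallback
        bands[name] = b
    return bands


def _cluster_summary(band: Band, res: ClusterResult, times: np.ndarray) -> dict:
    return {
        "band": [band.f_lo, band.f_hi],
        "n_clusters": len(res.clusters),
        "n_significant": len(res.significant),
        "clusters": [
            {"sum_t": c.sum_t, "p": c.p, "size": int(c.size),
             "sensors": sorted(map(int, set(c.sensors.tolist()))),
             "t_min_ms": float(times[c.samples.min()]),
             "t_max_ms": float(times[c.samples.max()])}
            for c in res.clusters[:10]
        ],
    }


def run_pipeline(config: SessionConfig, seed: int | None = None,
                 out_dir=None, n_sensors: int = 151,
                 freqs: np.ndarray | None = None,
                 n_permutations: int = 1000, decode_n_null: int = 100,
                 ptp_threshold: float = DEFAULT_PTP_THRESHOLD,
                 alpha_cluster: float = 0.01, n_sources: int = 200) -> dict:
    """Run the full analysis on one simulated session; returns the report.

    When ``out_dir`` is given, intermediate artifacts (epochs HDF5, layout
    JSON, per-band cluster CSVs) and the JSON report are written there.
    """
    if seed is None:
        seed = config.seed
    if freqs is None:
        freqs = np.arange(1.0, min(101.0, config.fs / 2))
    out = None
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": asdict(config), "seed": int(seed),
                    "alpha_cluster": alpha_cluster}

    t0 = time.perf_counter()
    layout = make_layout(n_sensors)
    epochs = simulate_session(config, layout, seed=seed)
    if out:
        layout.to_json(out / "layout.json")
        epochs.save(out / "session.h5", seed=seed)
    _log_stage("simulate", t0)

    t0 = time.perf_counter()
    clean, rejected = reject_artifacts(epochs, ptp_threshold)
    report["rejection"] = {
        "threshold": ptp_threshold,
        "n_rejected": int(rejected.sum()),
        "fraction_rejected": float(rejected.mean()),
    }
    _log_stage("reject", t0)

    t0 = time.perf_counter()
    bands = _identify_bands(clean, freqs, m=10.0)
    report["bands"] = {k: [b.f_lo, b.f_hi] for k, b in bands.items()}
    _log_stage("bands", t0)

    # percept contrast: bound vs unbound, unclassified excluded
    contrast = clean.select(clean.percept_mask("bound")
                            | clean.percept_mask("unbound"))
    is_bound = contrast.percept_mask("bound")
    report["n_trials"] = {"total": epochs.n_trials, "clean": clean.n_trials,
                          "bound": int(is_bound.sum()),
                          "unbound": int((~is_bound).sum())}

    t0 = time.perf_counter()
    report["cluster_tests"] = {}
    beta_cluster_sensors: list[int] = []
    times_used = None
    for name, band in bands.items():
        bp, times = band_power_trials(contrast, band)
        sl = window_slice(times, _STIM_WINDOW)
        valid = ~np.isnan(bp[0]).any(axis=0)
        keep = np.zeros(times.size, bool)
        keep[sl] = True
        keep &= valid
        x = bp[:, :, keep]
        res = cluster_test(x[is_bound], x[~is_bound], layout.adjacency,
                           design="independent", n_permutations=n_permutations,
                           seed=int(substream(seed, f"cluster-{name}").integers(2**31)),
                           alpha=alpha_cluster)
        times_used = times[keep]
        report["cluster_tests"][name] = _cluster_summary(band, res, times_used)
        if out and res.clusters:
            rows = [(int(s), float(times_used[t]), float(res.t_map[s, t]), k)
                    for k, c in enumerate(res.clusters)
                    for s, t in zip(c.sensors, c.samples)]
            pd.DataFrame(rows, columns=["sensor", "time_ms", "t", "cluster"]) \
                .to_csv(out / f"clusters_{name}.csv", index=False)
        if name == "beta":
            pos_sig = [c for c in res.significant if c.sum_t > 0]
            if pos_sig:
                best = max(pos_sig, key=lambda c: c.sum_t)
                beta_cluster_sensors = sorted(map(int, set(best.sensors.tolist())))
    _log_stage("cluster", t0)

    t0 = time.perf_counter()
    if not beta_cluster_sensors:
        logger.warning("no significant positive beta cluster; decoding falls "
                       "back to the central-parietal region tag")
        beta_cluster_sensors = sorted(map(int, layout.region_sensors("central-parietal")))
    decode_band = shrink_band(bands["beta"])
    bal = balance_classes(np.where(is_bound, "bound", "unbound"),
                          seed=int(substream(seed, "balance").integers(2**31)))
    sub = contrast.select(bal)
    dec = CSPDecoder(band=(decode_band.f_lo, decode_band.f_hi),
                     window=_DECODE_WINDOW, fs=sub.fs, times=sub.times)
    dres = permutation_significance(
        sub.data[:, beta_cluster_sensors, :], sub.percept_mask("bound"),
        dec, n_null=decode_n_null,
        seed=int(substream(seed, "decode").integers(2**31)))
    report["decoding"] = {
        "sensors_of_interest": beta_cluster_sensors,
        "band": [decode_band.f_lo, decode_band.f_hi],
        "window_ms": list(_DECODE_WINDOW),
        "n_trials_used": dres.n_trials_used,
        "mean_rate": dres.mean_rate,
        "rate_per_repeat": dres.rate_per_repeat.tolist(),
        "null_95th": float(np.percentile(dres.null_rates, 95.0)),
        "significant": bool(dres.significant),
    }
    _log_stage("decode", t0)

    t0 = time.perf_counter()
    lead = make_leadfield(layout, n_sources,
                          seed=int(substream(seed, "leadfield").integers(2**31)))
    inv = MinimumNormInverse(lead).fit()
    runs = sorted(contrast.trialinfo["run"].unique())
    run_means, counts = [], []
    for r in runs:
        m_run = {}
        for lab in ("bound", "unbound"):
            sel = (contrast.trialinfo["run"] == r).to_numpy() & contrast.percept_mask(lab)
            if sel.sum() == 0:
                m_run[lab] = None
                continue
            src = inv.transform(contrast.data[sel].mean(axis=0))
            m_run[lab] = welch_band_ratio(src, contrast.fs, contrast.times,
                                          _STIM_WINDOW, DEFAULT_BASELINE,
                                          bands["beta"])
        if m_run["bound"] is None or m_run["unbound"] is None:
            continue
        run_means.append(m_run["bound"] - m_run["unbound"])
        counts.append(int(((contrast.trialinfo["run"] == r).to_numpy()).sum()))
    src_contrast = weighted_run_average(np.asarray(run_means), counts)
    top = np.argsort(-src_contrast)[:10]
    report["sources"] = {
        "n_sources": n_sources,
        "lambda": inv.lam_,
        "top_beta_contrast_sources": [int(i) for i in top],
        "top_beta_contrast_values": [float(src_contrast[i]) for i in top],
    }
    _log_stage("sources", t0)

    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
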