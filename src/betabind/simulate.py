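"""Synthetic session generator.

Generates epoched multi-sensor trials whose oscillatory structure mirrors
the phenomenology the analysis pipeline is built to detect:

* spatially mixed 1/f background noise,
* posterior alpha (default 10 Hz) that is strong during the pre-stimulus
  baseline and drops after motion onset, identically for both percepts,
* occipital gamma (default 70 Hz) that rises during stimulation,
  identically for both percepts,
* central-parietal beta (default 20 Hz) whose post-onset power is larger
  on "bound" than "unbound" trials by a configurable standardized effect
  size, emerging ``beta_onset_ms`` after motion onset,
* a left-motor beta decrease on every trial (response-hand preparation),
* phase-locked steady-state sinusoids at the bar frequencies f1, f2, their
  first harmonics 2*f1, 2*f2 on posterior sensors, and the 2*f1 + 2*f2
  intermodulation component on frontal sensors on bound trials only,
* on a configurable fraction of trials, high-amplitude artifacts
  (100-ms transients or low-frequency drifts) for the peak-to-peak
  rejection stage to remove.

All band-limited components except the steady-state sinusoids are
amplitude-modulated narrowband Gaussian noise (spectral FWHM 20% of the
center frequency): the time-frequency analysis measures induced, not
phase-locked, power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import substream
from .config import SessionConfig
from .epochs import Epochs
from .layout import SensorLayout, make_layout

__all__ = [
    "simulate_session", "simulate_study", "make_leadfield", "reject_artifacts",
    "Leadfield", "DEFAULT_PTP_THRESHOLD",
]

#: Peak-to-peak rejection threshold calibrated to the generator's amplitude
#: scale: clean trials stay below it, planted artifacts exceed 3x this value.
DEFAULT_PTP_THRESHOLD = 20.0

# Component amplitudes (arbitrary field units, matched to DEFAULT_PTP_THRESHOLD).
_AMP = {
    "noise_source": 0.7,     # per spatial noise source (1/f)
    "sensor_noise": 0.3,     # independent white noise per sensor
    "alpha": 1.5,
    "beta": 1.5,
    "motor_beta": 1.2,
    "gamma": 1.0,
    "ss_fundamental": 0.4,   # f1, f2 steady-state sinusoids
    "ss_harmonic": 0.25,     # 2*f1, 2*f2
    # kept small: the intermodulation component must be visible in
    # phase-locked averages but not move single-trial alpha-band power,
    # which is percept-independent by construction
    "ss_intermod": 0.15,     # 2*f1 + 2*f2, frontal, bound only
    "artifact": 3.0 * DEFAULT_PTP_THRESHOLD,
}

_N_NOISE_SOURCES = 24
#: Gaussian spatial scale of signal and noise source topographies.
_SOURCE_KERNEL_WIDTH = 0.35
#: Lognormal sigma of the per-trial beta power jitter.
_BETA_POWER_JITTER = 0.4
#: Calibrated power boost per unit of beta_effect_d: the bound-trial
#: post-onset beta power is multiplied by 1 + beta_effect_d * this value.
#: The constant absorbs the across-trial CV of measured band power under
#: the generator's defaults (amplitude jitter plus single-trial estimation
#: noise) and the variance inflation the boost itself adds to the bound
#: group, so that the standardized (mean difference / pooled SD) effect of
#: central-parietal 15-25 Hz power equals beta_effect_d at the default
#: effect size.
_BETA_POWER_CV = 1.15


@dataclass
class Leadfield:
    """Synthetic forward model: smooth distance-decaying sensor gains."""

    gain: np.ndarray            # sensors x sources
    source_positions: np.ndarray  # sources x 3

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


# ---------------------------------------------------------------------------
# elementary signal generators
# ---------------------------------------------------------------------------

def _one_over_f(rng: np.random.Generator, shape: tuple, n: int, fs: float,
                exponent: float) -> np.ndarray:
    """Unit-variance 1/f^a noise, shaped in the frequency domain."""
    white = rng.standard_normal(shape + (n,))
    w = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = (f + 0.5) ** (-exponent / 2.0)
    amp[0] = 0.0
    x = np.fft.irfft(w * amp, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _narrowband(rng: np.random.Generator, shape: tuple, n: int, fs: float,
                fc: float, rel_bw: float = 0.2) -> np.ndarray:
    """Unit-variance Gaussian noise with a Gaussian spectrum centered at
    ``fc`` (FWHM = rel_bw * fc)."""
    white = rng.standard_normal(shape + (n,))
    w = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma_f = rel_bw * fc / 2.3548
    amp = np.exp(-((f - fc) ** 2) / (2.0 * sigma_f**2))
    x = np.fft.irfft(w * amp, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _sigmoid(t_ms: np.ndarray, t0: float, width_ms: float = 25.0) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t_ms - t0) / width_ms))


def _region_topo(layout: SensorLayout, tag: str) -> np.ndarray:
    """Gaussian spatial kernel centered on a region centroid (zero if the
    region has no sensors at the requested layout size)."""
    idx = layout.region_sensors(tag)
    if idx.size == 0:
        return np.zeros(layout.n_sensors)
    centroid = layout.positions[idx].mean(axis=0)
    centroid /= max(np.linalg.norm(centroid), 1e-12)
    d2 = ((layout.positions - centroid) ** 2).sum(axis=1)
    # fixed source extent: the cortical patch size does not depend on how
    # densely the sensor array samples it
    return np.exp(-d2 / (2.0 * _SOURCE_KERNEL_WIDTH**2))


# ---------------------------------------------------------------------------
# session synthesis
# ---------------------------------------------------------------------------

def _draw_labels(cfg: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_cond = cfg.trials_per_run // cfg.n_conditions
    conditions, runs = [], []
    for r in range(cfg.n_runs):
        order = np.repeat(np.arange(1, cfg.n_conditions + 1), per_cond)
        rng.shuffle(order)
        conditions.append(order)
        runs.append(np.full(cfg.trials_per_run, r))
    conditions = np.concatenate(conditions)
    runs = np.concatenate(runs)
    probs = np.asarray(cfg.bound_prob_per_condition)[conditions - 1]
    bound = rng.random(conditions.size) < probs
    percept = np.where(bound, "bound", "unbound").astype(object)
    percept[rng.random(conditions.size) < cfg.unclassified_rate] = "unclassified"
    artifact = rng.random(conditions.size) < cfg.artifact_rate
    return pd.DataFrame({"condition": conditions, "percept": percept,
                         "run": runs, "artifact": artifact})


def simulate_session(config: SessionConfig, layout: SensorLayout | None = None,
                     seed: int | None = None) -> Epochs:
    """Generate one subject's session of epoched trials.

    Fully reproducible: identical (config, layout, seed) give bit-identical
    output.  ``seed`` defaults to ``config.seed``.
    """
    cfg = config
    if layout is None:
        layout = make_layout()
    if seed is None:
        seed = cfg.seed
    rng = substream(seed, "session")

    fs, (t0, t1) = cfg.fs, cfg.epoch_window
    dt = 1000.0 / fs
    n_samples = int(round((t1 - t0) / dt))
    times = t0 + np.arange(n_samples) * dt
    ts = times / 1000.0
    n_trials = cfg.n_trials

    trialinfo = _draw_labels(cfg, rng)
    is_bound = (trialinfo["percept"] == "bound").to_numpy()
    # note: labels drawn before relabelling drive the physiology; the planted
    # effect follows the *reported* percept, which is what the analysis
    # contrasts (unclassified trials carry the unbound-like baseline signal).

    f_alpha, f_beta, f_gamma = cfg.band_centers

    topo = {tag: _region_topo(layout, tag) for tag in
            ("occipital", "occipito-parietal", "central-parietal",
             "left-motor", "frontal")}
    posterior = topo["occipital"] + 0.6 * topo["occipito-parietal"]

    # envelopes (shared across trials)
    env_alpha = 1.0 - 0.65 * _sigmoid(times, 0.0)
    env_gamma = 0.3 + 0.7 * _sigmoid(times, 0.0)
    env_motor = 1.0 - 0.5 * _sigmoid(times, 0.0)
    env_boost = _sigmoid(times, cfg.beta_onset_ms)
    env_ss = np.clip(times / 50.0, 0.0, 1.0)  # 50-ms ramp at motion onset

    # per-trial beta amplitude jitter (lognormal power jitter) and bound boost
    g = np.exp(_BETA_POWER_JITTER * rng.standard_normal(n_trials)
               - _BETA_POWER_JITTER**2 / 2.0)
    boost_power = 1.0 + cfg.beta_effect_d * _BETA_POWER_CV
    amp_beta = _AMP["beta"] * np.sqrt(g)
    # bound trials: amplitude rises after beta_onset_ms by sqrt(boost)
    boost_amp = np.where(is_bound, np.sqrt(boost_power), 1.0)

    # spatial noise sources
    src_pos = _fibonacci_jitter(rng, _N_NOISE_SOURCES)
    d2 = ((layout.positions[:, None, :] - src_pos[None, :, :]) ** 2).sum(-1)
    noise_gain = np.exp(-d2 / (2.0 * _SOURCE_KERNEL_WIDTH**2))  # sensors x sources

    data = np.empty((n_trials, layout.n_sensors, n_samples), dtype=np.float32)
    run_len = cfg.trials_per_run
    for r in range(cfg.n_runs):
        sl = slice(r * run_len, (r + 1) * run_len)
        nt = run_len
        x = np.zeros((nt, layout.n_sensors, n_samples))

        noise = _one_over_f(rng, (nt, _N_NOISE_SOURCES), n_samples, fs,
                            cfg.noise_exponent) * _AMP["noise_source"]
        x += np.einsum("sk,tkn->tsn", noise_gain, noise)
        x += _AMP["sensor_noise"] * rng.standard_normal((nt, layout.n_sensors, n_samples))

        alpha = _narrowband(rng, (nt,), n_samples, fs, f_alpha) * env_alpha
        x += _AMP["alpha"] * np.einsum("s,tn->tsn", topo["occipito-parietal"], alpha)

        gamma = _narrowband(rng, (nt,), n_samples, fs, f_gamma) * env_gamma
        x += _AMP["gamma"] * np.einsum("s,tn->tsn", topo["occipital"], gamma)

        beta = _narrowband(rng, (nt,), n_samples, fs, f_beta)
        amp_t = amp_beta[sl, None] * (1.0 + (boost_amp[sl, None] - 1.0) * env_boost)
        x += np.einsum("s,tn->tsn", topo["central-parietal"], amp_t * beta)

        mbeta = _narrowband(rng, (nt,), n_samples, fs, f_beta) * env_motor
        x += _AMP["motor_beta"] * np.einsum("s,tn->tsn", topo["left-motor"], mbeta)

        # steady-state components, phase-locked (fixed phase on every trial)
        ss = np.zeros(n_samples)
        for f, a in ((cfg.f1, _AMP["ss_fundamental"]), (cfg.f2, _AMP["ss_fundamental"]),
                     (2 * cfg.f1, _AMP["ss_harmonic"]), (2 * cfg.f2, _AMP["ss_harmonic"])):
            ss += a * np.sin(2 * np.pi * f * ts)
        x += np.einsum("s,n->sn", posterior, ss * env_ss)
        im = _AMP["ss_intermod"] * np.sin(2 * np.pi * cfg.intermod_freq * ts) * env_ss
        x[is_bound[sl]] += np.einsum("s,n->sn", topo["frontal"], im)

        # artifacts
        for t_local in np.nonzero(trialinfo["artifact"].to_numpy()[sl])[0]:
            x[t_local] += _make_artifact(rng, layout, times, fs)

        data[sl] = x.astype(np.float32)

    return Epochs(data, times, trialinfo, layout, fs)


def _fibonacci_jitter(rng: np.random.Generator, n: int) -> np.ndarray:
    """Noise-source positions: quasi-uniform hemisphere points with jitter."""
    k = np.arange(n)
    z = (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0)) + rng.uniform(0, 2 * np.pi)
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    pts += 0.05 * rng.standard_normal(pts.shape)
    return pts


def _make_artifact(rng: np.random.Generator, layout: SensorLayout,
                   times: np.ndarray, fs: float) -> np.ndarray:
    """One trial's contamination: a 100-ms transient on a sensor
    neighbourhood, or a low-frequency drift over anterior sensors.
    Peak amplitude is 3x the calibrated rejection threshold."""
    amp = _AMP["artifact"]
    n = times.size
    out = np.zeros((layout.n_sensors, n))
    if rng.random() < 0.5:  # muscle/blink-like transient
        center = rng.integers(0, layout.n_sensors)
        tc = rng.uniform(times[0] + 200.0, times[-1] - 200.0)
        pulse = np.exp(-((times - tc) ** 2) / (2.0 * 25.0**2))  # sigma 25 ms
        weights = np.where(layout.adjacency[center], 0.5, 0.0)
        weights[center] = 1.0
        out += np.sign(rng.random() - 0.5) * amp * weights[:, None] * pulse[None, :]
    else:  # slow ocular drift
        anterior = np.clip(layout.positions[:, 1], 0.0, None) ** 2
        anterior /= max(anterior.max(), 1e-12)
        drift = np.sin(2 * np.pi * 0.3 * times / 1000.0 + rng.uniform(0, 2 * np.pi))
        # guarantee the per-sensor peak-to-peak exceeds 3x the threshold
        drift = drift - drift.min()
        out += amp * anterior[:, None] * drift[None, :] / max(drift.max(), 1e-12)
    return out


def simulate_study(config: SessionConfig, layout: SensorLayout | None = None,
                   seed: int | None = None) -> list[Epochs]:
    """Generate ``config.n_subjects`` independent sessions."""
    if seed is None:
        seed = config.seed
    if layout is None:
        layout = make_layout()
    return [simulate_session(config, layout,
                             seed=substream(seed, f"subject-{i}").integers(2**31))
            for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# leadfield and artifact rejection
# ---------------------------------------------------------------------------

def make_leadfield(layout: SensorLayout, n_sources: int, seed: int = 0) -> Leadfield:
    """Random smooth gain matrix mapping cortical-depth sources to sensors.

    Sources sit on a sphere of radius 0.8 under the sensor shell; each gain
    column decays with sensor-source distance (Gaussian kernel) and carries
    a mild random strength factor.  Reproducible from ``seed``.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    if n_sources >= layout.n_sensors:
        warnings.warn("n_sources >= n_sensors: the inverse problem is "
                      "rank-deficient", stacklevel=2)
    rng = substream(seed, "leadfield")
    k = np.arange(n_sources)
    z = rng.uniform(0.05, 0.95, n_sources)
    phi = rng.uniform(0, 2 * np.pi, n_sources)
    r = np.sqrt(1.0 - z**2)
    src = 0.8 * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    del k
    d2 = ((layout.positions[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    gain = np.exp(-d2 / (2.0 * 0.3**2))
    gain *= np.exp(0.1 * rng.standard_normal(n_sources))[None, :]
    if not np.all(np.isfinite(gain)):
        raise FloatingPointError("non-finite leadfield gains")
    return Leadfield(gain, src)


def reject_artifacts(epochs: Epochs, ptp_threshold: float = DEFAULT_PTP_THRESHOLD
                     ) -> tuple[Epochs, np.ndarray]:
    """Drop trials whose peak-to-peak amplitude exceeds ``ptp_threshold`` on
    any sensor.

    Returns the cleaned epochs and the boolean rejection mask (True =
    rejected).  Raises if every trial is rejected.
    """
    if not ptp_threshold > 0:
        raise ValueError("ptp_threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x sensors
    rejected = (ptp > ptp_threshold).any(axis=1)
    if rejected.all():
        raise ValueError("all trials exceed the peak-to-peak threshold")
    return epochs.select(~rejected), rejected
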