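"""Session configuration for the synthetic generator.

The defaults describe one recording session of the form/motion binding
protocol this package analyses: 8 runs of 60 trials (15 per contrast
condition, so 120 trials per condition over the session), epochs of
-1800..+1200 ms around motion onset, two bar-oscillation frequencies
f1 = 2.3 Hz and f2 = 3.0 Hz, roughly 9% "unclassified" perceptual reports
and roughly 30% artifact-contaminated trials.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

__all__ = ["SessionConfig", "PERCEPT_CODES", "PERCEPT_NAMES"]

#: Integer codes used in trial metadata and on disk.
PERCEPT_CODES = {"bound": 0, "unbound": 1, "unclassified": 2}
PERCEPT_NAMES = {v: k for k, v in PERCEPT_CODES.items()}


@dataclass
class SessionConfig:
    """Parameters of one synthetic recording session.

    Parameters
    ----------
    n_subjects : int
        Number of subjects when generating a study (each gets an
        independent substream of the seed).
    n_runs, trials_per_run, n_conditions : int
        Session layout; ``trials_per_run`` must be divisible by
        ``n_conditions`` so condition counts are exactly balanced.
    fs : float
        Sampling rate in Hz.  Must support analysis up to 100 Hz.
    epoch_window : (float, float)
        Epoch limits in ms; time zero is motion onset and must lie inside.
    f1, f2 : float
        Bar oscillation frequencies in Hz (steady-state components are
        planted at f1, f2, 2*f1, 2*f2 and at the 2*f1 + 2*f2
        intermodulation frequency).
    bound_prob_per_condition : tuple of 4 floats
        Probability of a "bound" report per contrast condition.  The
        default is a monotone-decreasing profile with a discontinuity
        between conditions 2 and 3.
    unclassified_rate : float
        Fraction of trials relabelled "unclassified" after the percept draw.
    artifact_rate : float
        Fraction of trials contaminated by high-amplitude transients or
        low-frequency drifts.
    beta_effect_d : float
        Planted standardized bound-vs-unbound difference of central-parietal
        beta (15-25 Hz) power after the effect onset, in units of the
        across-trial power SD.
    beta_onset_ms : float
        Latency (ms after motion onset) at which the percept-dependent beta
        difference emerges.
    band_centers : (float, float, float)
        Center frequencies of the planted alpha/beta/gamma components.
    noise_exponent : float
        Slope of the 1/f^a background noise.
    seed : int
        Master seed for the session.
    """

    n_subjects: int = 1
    n_runs: int = 8
    trials_per_run: int = 60
    n_conditions: int = 4
    fs: float = 250.0
    epoch_window: tuple[float, float] = (-1800.0, 1200.0)
    f1: float = 2.3
    f2: float = 3.0
    bound_prob_per_condition: tuple[float, ...] = (0.90, 0.75, 0.25, 0.10)
    unclassified_rate: float = 0.09
    artifact_rate: float = 0.30
    beta_effect_d: float = 1.0
    beta_onset_ms: float = 230.0
    band_centers: tuple[float, float, float] = (10.0, 20.0, 70.0)
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions != 4:
            raise ValueError("the protocol has exactly 4 contrast conditions")
        if self.trials_per_run % self.n_conditions:
            raise ValueError("trials_per_run must be divisible by n_conditions")
        if len(self.bound_prob_per_condition) != self.n_conditions:
            raise ValueError("need one bound probability per condition")
        if not all(0.0 <= p <= 1.0 for p in self.bound_prob_per_condition):
            raise ValueError("bound probabilities must lie in [0, 1]")
        if not (0.0 <= self.unclassified_rate < 1.0 and 0.0 <= self.artifact_rate < 1.0):
            raise ValueError("rates must lie in [0, 1)")
        t0, t1 = self.epoch_window
        if not (t0 < 0.0 < t1):
            raise ValueError("epoch_window must span t = 0 (motion onset)")
        if self.fs < 200.0:
            raise ValueError("fs must be at least 200 Hz (2 x the 100 Hz analysis limit)")
        if self.beta_onset_ms >= t1:
            raise ValueError("epoch too short for beta_onset_ms")
        if self.beta_effect_d < 0:
            raise ValueError("beta_effect_d must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    @property
    def intermod_freq(self) -> float:
        """The 2*f1 + 2*f2 intermodulation frequency (10.6 Hz at defaults)."""
        return 2.0 * self.f1 + 2.0 * self.f2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SessionConfig":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("epoch_window", "bound_prob_per_condition", "band_centers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)
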