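# Methods

`betabind` analyses percept-dependent oscillatory power in epoched
multi-sensor (MEG-like) recordings of a visual form/motion binding task:
observers view four bars oscillating at f1 = 2.3 Hz (horizontal pair) and
f2 = 3.0 Hz (vertical pair) and report whether they perceived one rigidly
moving shape ("bound") or independent bar pairs ("unbound").  The package
implements the full analysis chain — artifact rejection, Morlet
time-frequency maps, data-driven band identification, spatio-temporal
cluster permutation statistics, CSP single-trial decoding, and
Welch/minimum-norm spectral source analysis — together with a synthetic
session generator that plants the oscillatory structure the chain is meant
to detect, so every stage is testable end to end without recordings.

## Synthetic sessions

A session is 8 runs of 60 trials (15 per contrast condition, 120 per
condition in total), each trial an epoch of −1800…+1200 ms around motion
onset sampled at 250 Hz.  The percept label is drawn per trial from a
condition-specific bound probability (defaults 0.90/0.75/0.25/0.10, a
monotone profile with the characteristic discontinuity between conditions
2 and 3), then relabelled "unclassified" with probability 0.09.

Signal content, all in arbitrary field units on a 151-sensor hemispheric
layout (Fibonacci lattice; regions assigned by position; adjacency =
3-D distance threshold tuned to ~6 neighbours):

| component | region | frequency | behaviour |
|---|---|---|---|
| 1/f background | 24 spatially mixed sources + sensor noise | broadband | stationary |
| alpha | occipito-parietal | 10 Hz | high baseline, drops to 35% after onset, percept-independent |
| gamma | occipital | 70 Hz | 30% baseline, full after onset, percept-independent |
| beta | central-parietal | 20 Hz | sustained; bound trials boosted after 230 ms |
| beta | left-motor | 20 Hz | halves after onset on every trial (response hand) |
| steady-state | posterior | f1, f2, 2f1, 2f2 | phase-locked sinusoids during motion |
| intermodulation | frontal | 2f1+2f2 = 10.6 Hz | phase-locked, bound trials only |
| artifacts | varies | — | 100-ms transients or 0.3-Hz drifts, ≥3× the rejection threshold |

Band-limited components are amplitude-modulated narrowband Gaussian noise
(spectral FWHM 20% of the center frequency) rather than sinusoids, because
the time-frequency analysis measures induced, non-phase-locked power; only
the steady-state components are fixed-phase sinusoids.  Spatial mixing
uses Gaussian kernels of fixed width 0.35 (hemisphere units) centred on
region centroids: a cortical patch has a physical extent that should not
depend on how densely the sensor array samples it, so the kernel width is
deliberately *not* tied to the adjacency radius.

**Planted effect size.** `beta_effect_d` is defined as the standardized
(mean difference / pooled SD) bound-vs-unbound difference of measured
central-parietal 15–25 Hz power in the 300–1100 ms window.  Internally the
bound-trial post-onset beta power is multiplied by `1 + d × 1.15`; the
1.15 is a one-off calibration constant absorbing the across-trial CV of
measured band power (lognormal amplitude jitter with σ = 0.4 plus
single-trial spectral-estimation noise) and the extra variance the boost
itself adds to the bound group.  Direct measurement on generated sessions
recovers d = 1.0 as 0.98 ± 0.15 across seeds.

**Intermodulation amplitude.** The 10.6 Hz component is kept small (0.15)
on purpose: in real recordings it is only measurable in phase-locked
trial averages, and it must not move single-trial alpha-band (8–12 Hz)
power, which is percept-independent by construction — otherwise the alpha
cluster test would (correctly!) detect a frontal narrowband difference
that the emulated study does not contain at the band level.

**What the generator does not emulate:** head movement and coregistration
error, heterogeneous sensor noise and bad channels, non-stationary alpha
rhythms and eye-movement spectra with realistic 1/f knees, inter-subject
variability of band peaks, and any genuine forward model (the leadfield is
a smooth random Gaussian-gain surrogate).  Passing tests therefore show
that the *analysis chain* is correct and calibrated, not that it would
have the same power on real MEG data.

## Time-frequency analysis

Complex Morlet wavelets with m = 10 cycles, frequencies 1–100 Hz in 1-Hz
steps, give the resolution law Wf = 2√(2 ln 2)·f/m ≈ 0.235 f (spectral
FWHM) and Wt = 2√(2 ln 2)·m/(2πf) ≈ 3.75/f s (temporal FWHM of the
amplitude envelope; at two decimals this is often printed truncated as
3.74/f).  Kernels are energy-normalized (∫|ψ|² dt = 1), so white noise
has frequency-flat expected raw power and the 1/f correction is carried
entirely by the baseline ratio.  Convolution is done in the frequency
domain with zero padding; samples within half a wavelet support of either
epoch edge are flagged invalid rather than reflection-padded (reflection
manufactures spurious oscillatory continuity).  Kernels are truncated at
±3.5 σ (spectral-FWHM bias < 0.1%); frequencies whose support exceeds the
epoch (1–3 Hz at the default epoch) are dropped with a warning.

Power is normalized as log2 of the ratio to the trial-averaged mean
baseline power per sensor and frequency, baseline −1800…−600 ms.  Note
that the *single-trial* log ratio has the usual negative χ² bias
(E[log2(P/EP)] = ψ(1)/ln 2 ≈ −0.83 for two-degree-of-freedom power); flat
maps at zero are a property of the log of the trial-averaged ratio, which
is what pooled displays use.  Band averaging of the log2 ratio commutes
with a per-sensor constant, which the streaming implementation exploits.

Bands of interest are identified from pooled all-trial data: alpha from
raw baseline power over occipito-parietal sensors (search 5–15 Hz),
beta from the baseline-corrected left-motor deactivation (10–40 Hz),
gamma from the baseline-corrected occipital activation (40–100 Hz); the
band is the widest contiguous frequency run above (or below) half the
extremum — a FWHM criterion, the least arbitrary reproducible choice where
no explicit rule exists.  `shrink_band` tightens a wavelet-identified band
by Wf/2 at each edge for direct filtering: [15, 25] → [17, 22] Hz.

## Cluster permutation test

Band-power time courses (observations × sensors × samples, window
0–1200 ms) are contrasted with samplewise two-sample (or paired) t-tests;
samples beyond the two-tail p < 0.05 critical value are clustered by
consecutive-sample time adjacency and sensor-graph space adjacency, with
positive and negative t kept apart.  Cluster mass is the sum of t over
members.  The null distribution is the maximum |mass| over random
relabelings (label shuffles, or per-pair sign flips for paired designs);
p = (1 + #{null ≥ observed})/(1 + N) with +1 smoothing so p > 0.  When
fewer distinct relabelings exist than requested, all are enumerated.  With
three bands tested, the corrected cluster threshold is lowered to 0.01.
A relative tolerance of 10⁻⁹ in the exceedance count keeps the identity
relabeling counted despite the running-sums fast path.  The trial-level
(within-session) design is the default; the paired design serves
multi-subject contrasts.

## CSP decoding

Raw trials are zero-phase FIR band-pass filtered (Hamming-window design,
default 17–22 Hz from `shrink_band`), cropped to 100–1100 ms, and the two
percept classes' trial-averaged covariances are jointly diagonalized
(generalized eigenproblem C_bound w = λ(C_bound + C_unbound) w, 5%
scaled-identity shrinkage).  The five filters with |λ − 0.5| largest feed
log-variance features to a linear discriminant.

Two deliberate choices where the emulated method is underspecified:

* **Covariance scaling.** Covariances are scaled by a single pooled-trace
  scalar, *not* per-trial trace normalization.  The percept effect is an
  absolute band-power change of one dominant spatial component; per-trial
  normalization divides that component's power by a trace it itself
  dominates and can cancel the effect entirely (we observed exactly this
  at small sensor counts).  Per-trial normalization remains available as
  `cov_norm="trace"`.
* **Reference distribution.** Significance compares the observed mean of
  ten stratified 90/10 cross-validated accuracies against the 95th
  percentile of 100 reference rates.  The reference is computed by
  label-permutation cross-validation by default; a train-equals-test
  "self-classification" reading is exposed as `null_scheme="self"`.

The filter/classifier fit touches only the training split of each
repeat; the band-pass filter and window crop are per-trial operations and
are applied once up front (no cross-trial leakage is possible there).
Class imbalance is removed beforehand by downsampling to the minority
count.

## Spectra and sources

Welch periodograms use Hamming tapers, 50% overlap and segments of a
quarter of the analysis window; band power is trapezoid-integrated and
reported as log2(stimulation/baseline) on windows of equal length
(0–1200 ms vs −1800…−600 ms).  Source time courses come from the
minimum-L2-norm kernel Gᵀ(GGᵀ + λI)⁻¹ on the synthetic leadfield, with
λ = trace(GGᵀ)/(n_sensors·SNR²) at SNR = 3 by default; no noise-covariance
whitening is applied (a documented limitation).  Per-run source averages
are recombined with trial-count weights, which reproduces the pooled
trial mean exactly.

## Pipeline

`run_pipeline` chains reject → band identification → per-band cluster
tests (bound vs unbound, unclassified excluded, α = 0.01) → CSP decoding
on the sensors of the strongest significant positive beta cluster
(fallback: the central-parietal region tag, logged) → source-level beta
contrast.  All randomness derives from one master seed through named
substreams, so reports are byte-identical across reruns.  Artifacts are
written as HDF5 (epochs), JSON (layout, config, report) and CSV (cluster
members).

## Problem sizes in the test suite

The statistical calibration tests run at reduced scale chosen as the
smallest sizes at which the properties are well-powered: 20-sensor
layouts, 120-trial sessions (~60 per percept), beta-band-only transforms
on cropped epochs, 500 permutations for the cluster test (200 null + 50
effect sessions) and 100-permutation references for the decoder (10 null +
10 effect sessions).  Full-size sessions (151 sensors, 480 trials) are
exercised for bookkeeping and the worked example.

## Known limitations

* The generator's effect-size calibration constant is exact only near the
  default conditions; at d = 1.5 the measured standardized effect is
  mildly compressed (≈1.3) by the variance the boost adds to the bound
  group.
* Band identification assumes a unimodal band within the search range;
  overlapping rhythms would merge.
* The min-norm stage inherits the usual depth bias and the synthetic
  leadfield carries no dipole orientation structure.
* At 20-sensor layouts some region tags hold very few sensors; the
  generator simply skips empty regions.
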