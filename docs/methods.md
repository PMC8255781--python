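# Methods

This note documents the models, numerical choices and simulation
conditions behind `pharmaeeg`, in the spirit of a package methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral pipeline

**Down-sampling.** Raw recordings (canonically 1000 Hz) are reduced to the
200-Hz analysis rate by an anti-alias linear-phase FIR (Kaiser design,
cutoff 0.8 × the new Nyquist = 80 Hz, ≥ 65 dB stopband by 100 Hz) followed
by decimation. Non-integer decimation factors are rejected rather than
resampled.

**Filter bank.** 70 band-pass channels on an arithmetic grid: low cutoffs
1.0 + 1.4k Hz (k = 0…69), high cutoffs low + 1.6 Hz, so adjacent channels
overlap by 0.2 Hz and centers are 1.8 + 1.4k Hz. Kernels are 401-tap
Hamming-window linear-phase FIR filters at 200 Hz (2-s support). This
order was chosen so the narrowest (1.6-Hz) low-frequency bands still reach
their passband: the first kernel is at 0 dB at its 1.8-Hz center and below
−45 dB at 0.2 Hz. Group delay is compensated by index shift (zero-phase
output).

**Instantaneous power.** Power is defined as the squared magnitude of the
analytic signal (envelope²). The production path computes, from a single
forward FFT of the signal, the filtered analytic signal of all 70 channels
at once (kernel spectrum × analytic-signal weights, one batched inverse
FFT); a per-channel convolve + Hilbert reference path exists in the tests
and agrees with it on interior epoch medians to < 0.5%. Since both
normalizations are ratio-based, the envelope-vs-envelope² convention
cancels out of all normalized outputs for narrowband signals.

**Epoching and artifacts.** Power is summarized per 4-s epoch (800 samples)
by the median, robust to brief transients. Epochs are half-open [4k, 4k+4)
s from recording start; a final partial epoch is dropped. Artifact removal
happens at this stage — flagged epochs keep their index but are excluded
from every downstream mean — rather than by excising raw signal, which
would break filter continuity. Record edges are not trimmed: the 1-s
edge-contaminated region lies inside the first/last 4-s epoch, where the
median is insensitive to it. The automated detector flags an epoch when
the EEG peak deviation exceeds k_eeg = 6 robust SDs (1.4826 × MAD) or the
epoch EMG RMS exceeds k_emg = 6 × the median epoch RMS; externally
supplied masks take precedence when given.

## Bands and normalization

Band membership is decided by channel center frequency with half-open
ranges [lo, hi). The centers 1.8 + 1.4k never land on a band edge, so the
half-open convention is safe but fixed. Sigma (10–15 Hz) shares channels
with alpha and beta by design; consequently the "total power over all
bands" used for baseline normalization counts shared channels once per
band. Baseline tables are binned at 1 h from recording start; treatment
tables at 10 min from injection (both configurable — scaled-down studies
use the same code with smaller widths). Window summaries (acute 0–2 h,
subacute 2–5 h post-injection) are epoch-weighted means over the bins in
the window. Bins with no surviving epochs propagate as missing
observations into the statistics — never interpolated — where
available-case handling deals with them explicitly.

## Rank-based longitudinal tests

All observations are midranked globally (ties get mean covered rank). The
relative treatment effect of a cell is p̂ = (mean midrank − ½)/N; its
observation-weighted mean over cells is exactly ½. The covariance of the
cell-effect vector is estimated from subject-level rank vectors,
block-diagonal over whole-plot groups (each block S_g/n_g); with missing
cells the covariance is pairwise-complete and entries are scaled by the
per-cell counts. Contrast matrices are Kronecker products of centering
and averaging blocks over the factors (one or two between-unit factors ×
time).

Two statistics are computed for every effect:

* **WTS** — quadratic form with Moore–Penrose inverse, χ² reference,
  df = rank(C). Matches the χ²/df = levels − 1 reporting convention common
  in pharmaco-EEG papers, but is liberal for within-unit effects at small
  n (our own null simulations put the 2-group × 3-time interaction near
  10% at nominal 5%).
* **ATS** — trace-normalized form with Box-approximated numerator df
  f = tr(TV̂)²/tr(TV̂TV̂). Within-unit effects (those involving time) use
  the χ²_f/f reference. Purely between-unit effects use the Box-modified
  F(f, f₀) reference with a denominator df estimated from the per-group
  diagonal blocks of TV̂, f₀ = tr(TV̂)² / Σ_g tr((TV̂)_gg)²/(n_g−1); for two
  groups this reduces exactly to the Welch–Satterthwaite df of the rank
  Welch test. With 8–9 units per group the plain χ² reference is
  measurably liberal for between effects, which the F tail corrects. The
  ATS is the default headline statistic.

Treatment sessions are treated as independent experimental units
((subject, session) pairs), consistent with reported unit counts of
n ≈ subjects × treatments in this design family; the unit column is
caller-controlled, so subject-level analyses are a configuration choice.
Multiple testing uses Bonferroni only (p_c = min(1, m·p), capped at 1,
family sizes: 7 bands for per-band headline tests, number of time bins for
per-bin post-hocs, number of pairwise comparisons for treatment matrices).
Other procedures are deliberately out of scope.

## Synthetic data generator

The generator emulates the recording sessions the pipeline is built for,
with every estimated quantity an explicit parameter:

* **Oscillators** — one per band, band-limited white noise (8th-order
  Butterworth to center ± 0.4 × band width; steep edges keep < 1% of an
  oscillator's power outside its band, so band-selective effects stay
  band-selective). Amplitude scaling is calibrated so mean envelope² =
  amplitude²; default amplitudes fall off 1/f-like (delta 40 down to
  gamma2 4 µV-equivalent).
* **Background** — 1/f^a noise (a = 1) by spectral shaping, RMS 12 µV.
* **Genotype** — per-band amplitude multipliers for knockouts (delta and
  gamma2 up ~15%, alpha/sigma/beta down ~15–18%, theta and gamma1
  unchanged), emulating a delta-subunit-knockout baseline phenotype.
* **Drug effects** — per-band amplitude-gain trajectories: linear rise
  from onset to peak, plateau to offset, exponential relaxation back to 1;
  multiplied by an injection-stress transient (low-band suppression ×0.8,
  gamma increment ×1.25) decaying exponentially with a 10-min time
  constant, hence maximal in the first 10-min bin. The bundled profiles
  are a superagonist (delta ×2.0, theta ×1.5 amplitude at peak) and a
  stimulant-like broadband suppressant (×0.65 everywhere except gamma1);
  blunted-responder genotypes receive a different profile per treatment.
* **Subjects** — one log-normal amplitude multiplier per subject (SD 0.2
  on the log scale), stable across that subject's sessions.
* **Artifacts** — Poisson events (0.3–1 s) adding ±500 µV excursions to
  both EEG channels and a simultaneous EMG burst; the ground-truth mask
  flags every epoch overlapping an event.
* **Determinism** — one master seed; per-recording and per-channel streams
  derived by stable hashing of (subject, session, channel), so identical
  specs give bit-identical output and skipping a channel never perturbs
  the others.

What the generator does **not** emulate: vigilance states and their
spectral signatures, pharmacokinetic realism beyond gain trajectories,
receptor mechanisms, electrode drift, or line noise. Passing tests
therefore demonstrate that the pipeline recovers known band-power
structure under realistic variance and artifact contamination — not that
it handles every failure mode of real recordings.

## Simulation sizes

Monte-Carlo experiments (calibration and power) run the complete analysis
chain on a scaled-down session: recordings generated directly at the
200-Hz analysis rate, 48-s pretreatment + 96-s post-injection (96-s
drug-free recordings for null studies), 24-s time bins (6 epochs each, 2
pre + 4 post), with drug-gain time courses compressed by the same factor
(×150) that maps the 6-h session onto 144 s. Study size is always 9 + 8
subjects. Type-I error uses 200 replicate null studies (no genotype or
drug effect) testing the genotype ATS; the p-value uniformity check uses
500 replicates of a null longitudinal-data generator (iid log-normal band
values), since the rank tests see only per-bin band values and
signal-level replication adds nothing to that check. Power uses 50
replicates per drug scenario. Full-scale sessions (1000 Hz, 1 h + 5 h,
10-min bins) run through the identical code path; only durations and bin
widths change.

## Known limitations

* The WTS is intentionally reported alongside the ATS despite its
  small-sample liberality; headline inference should use the ATS.
* Available-case covariance with entirely empty cells drops the affected
  contrasts (named in the result) — hypotheses then refer to the observed
  cells only.
* EDF output quantizes to 16 bits over a per-channel symmetric range;
  round-trips are exact only to that quantization step.
* The per-bin post-hoc rank test at a single time point reduces to a
  two-sample rank comparison whose small-sample behavior (groups of 8–9)
  is adequate but not exact; severity tiers (0.05 / 0.001 / 0.0001) follow
  the conventional three-tier reporting style.
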