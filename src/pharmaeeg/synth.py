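"""Synthetic rodent EEG/EMG generator with known ground truth.

Emulates the recording sessions of a mouse pharmaco-EEG study: two EEG
channels (frontal, parietal) plus neck EMG sampled at 1000 Hz; band-limited
oscillatory activity over a 1/f background; genotype-dependent baseline
band amplitudes; drug-specific, time-varying band gains after an
intraperitoneal injection; an injection-handling stress transient that
peaks within the first 10 minutes; and sporadic high-amplitude artifacts
with coincident EMG bursts.

Every quantity that downstream analysis estimates (band amplitudes,
genotype scaling, drug gain trajectories, artifact event times) is an
explicit parameter here, so recovery can be checked against ground truth.
Oscillators are realized as white noise band-pass filtered to
(center +/- bandwidth/2) rather than pure tones, giving bands realistic
spectral spread.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as ssig

from .bands import BAND_RANGES, check_band
from .spectral import ArtifactMask, EPOCH_LEN_S

#: Default band oscillator amplitudes (uV-equivalent), loosely following the
#: 1/f-like decline of rodent cortical EEG band amplitudes.
DEFAULT_AMPLITUDES = {
    "delta": 40.0, "theta": 28.0, "alpha": 16.0, "sigma": 12.0,
    "beta": 9.0, "gamma1": 6.0, "gamma2": 4.0,
}

#: Baseline band-amplitude multipliers emulating a delta-subunit-knockout
#: phenotype: elevated delta and gamma2, suppressed alpha/sigma/beta,
#: unchanged theta and gamma1.
KO_BAND_SCALE = {
    "delta": 1.15, "theta": 1.0, "alpha": 0.85, "sigma": 0.82,
    "beta": 0.85, "gamma1": 1.0, "gamma2": 1.15,
}

STRESS_TAU_MIN = 10.0  # injection-stress transient time constant


@dataclass(frozen=True)
class OscillatorSpec:
    """One band-limited oscillator: noise filtered to center +/- bandwidth/2."""

    center_freq: float
    bandwidth: float
    amplitude: float
    band_label: str

    def __post_init__(self) -> None:
        check_band(self.band_label)
        if self.center_freq <= 0 or self.bandwidth <= 0:
            raise ValueError("center_freq and bandwidth must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        lo, hi = BAND_RANGES[self.band_label]
        if not (lo <= self.center_freq < hi):
            raise ValueError(
                f"center {self.center_freq} Hz outside band {self.band_label} [{lo},{hi})"
            )


def default_oscillators(amplitudes: dict[str, float] | None = None) -> list[OscillatorSpec]:
    """One oscillator per band, centered in the band, spanning most of it."""
    amplitudes = amplitudes or DEFAULT_AMPLITUDES
    specs = []
    for band, (lo, hi) in BAND_RANGES.items():
        center = (lo + hi) / 2.0
        bw = 0.8 * (hi - lo)
        specs.append(OscillatorSpec(center, bw, amplitudes.get(band, 0.0), band))
    return specs


@dataclass(frozen=True)
class DrugEffectProfile:
    """Multiplicative per-band amplitude-gain trajectory after injection.

    The band trajectory rises linearly from 1 at ``onset_min`` to its peak
    gain at ``peak_min``, plateaus until ``offset_min``, then relaxes
    exponentially back to 1 (time constant ``decay_tau_min``). On top of it
    a stress transient (injection handling) decays exponentially from t=0
    with a 10-min time constant, so its effect is maximal in the first
    10-min bin. All gains are amplitude gains; band power scales as gain^2.
    """

    band_gains: dict[str, float] = field(default_factory=dict)
    onset_min: float = 0.0
    peak_min: float = 10.0
    offset_min: float = 120.0
    decay_tau_min: float = 30.0
    stress_transient_gain: dict[str, float] = field(default_factory=dict)
    stress_tau_min: float = STRESS_TAU_MIN

    def __post_init__(self) -> None:
        for d in (self.band_gains, self.stress_transient_gain):
            for band, g in d.items():
                check_band(band)
                if g <= 0:
                    raise ValueError(f"gain for {band} must be positive, got {g}")
        if not (self.onset_min <= self.peak_min <= self.offset_min):
            raise ValueError("require onset_min <= peak_min <= offset_min")


def drug_gain(profile: DrugEffectProfile, band: str, t_since_injection_min) -> np.ndarray | float:
    """Evaluate the total (trajectory x stress) amplitude gain for a band.

    Continuous in t; bands absent from the profile have trajectory gain 1.
    Accepts scalar or array minutes; negative times (pre-injection) give 1.
    """
    check_band(band)
    t = np.asarray(t_since_injection_min, dtype=np.float64)
    shape = np.zeros_like(t)
    on, pk, off = profile.onset_min, profile.peak_min, profile.offset_min
    rising = (t >= on) & (t < pk)
    if pk > on:
        shape[rising] = (t[rising] - on) / (pk - on)
    plateau = (t >= pk) & (t < off)
    shape[plateau] = 1.0
    tail = t >= off
    shape[tail] = np.exp(-(t[tail] - off) / profile.decay_tau_min)
    shape[t < 0] = 0.0

    g = profile.band_gains.get(band, 1.0)
    traj = 1.0 + (g - 1.0) * shape

    s = profile.stress_transient_gain.get(band, 1.0)
    stress = np.ones_like(t)
    pos = t >= 0
    stress[pos] = 1.0 + (s - 1.0) * np.exp(-t[pos] / profile.stress_tau_min)
    out = traj * stress
    return float(out) if out.ndim == 0 else out


def saline_profile() -> DrugEffectProfile:
    """Injection-stress-only profile: low-band suppression, gamma increment."""
    return DrugEffectProfile(
        band_gains={},
        stress_transient_gain={
            "delta": 0.8, "theta": 0.8, "alpha": 0.8, "sigma": 0.8,
            "beta": 0.85, "gamma1": 1.25, "gamma2": 1.25,
        },
    )


def thip_like_profile(delta_gain: float = 2.0, theta_gain: float = 1.5) -> DrugEffectProfile:
    """Delta/theta amplitude increment, as for a delta-receptor superagonist."""
    base = saline_profile()
    return replace(base, band_gains={"delta": delta_gain, "theta": theta_gain},
                   onset_min=0.0, peak_min=10.0, offset_min=120.0)


def mmc_like_profile(suppression: float = 0.65) -> DrugEffectProfile:
    """Broadband amplitude suppression sparing gamma1, stimulant-like."""
    base = saline_profile()
    gains = {b: suppression for b in BAND_RANGES if b != "gamma1"}
    return replace(base, band_gains=gains, onset_min=0.0, peak_min=5.0, offset_min=120.0)


DRUG_PROFILES = {
    "SAL": saline_profile,
    "THIP": thip_like_profile,
    "4MMC": mmc_like_profile,
}


def compress_profile(profile: DrugEffectProfile, factor: float) -> DrugEffectProfile:
    """Speed up a gain trajectory by ``factor`` (for scaled-down sessions).

    Divides every time parameter (onset, peak, offset, decay and stress time
    constants) by ``factor`` so that a profile spanning a 6-h session spans a
    seconds-scale session with the same shape relative to session length.
    """
    if factor <= 0:
        raise ValueError("compression factor must be positive")
    return replace(profile,
                   onset_min=profile.onset_min / factor,
                   peak_min=profile.peak_min / factor,
                   offset_min=profile.offset_min / factor,
                   decay_tau_min=profile.decay_tau_min / factor,
                   stress_tau_min=profile.stress_tau_min / factor)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterization of one synthetic recording."""

    duration_s: float
    fs: float = 1000.0
    oscillators: tuple = field(default_factory=lambda: tuple(default_oscillators()))
    noise_exponent: float = 1.0
    noise_floor: float = 12.0  # RMS of the 1/f background, uV
    genotype_band_scale: dict[str, float] = field(default_factory=dict)
    drug: DrugEffectProfile | None = None
    injection_time_s: float | None = None
    artifact_rate_per_h: float = 0.0
    artifact_amplitude: float = 500.0  # uV, >> background
    light_onset_h: float = 0.0   # Zeitgeber 0 = lights on
    light_offset_h: float = 12.0
    channels: tuple[str, ...] = ("eeg_frontal", "eeg_parietal", "emg")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.artifact_rate_per_h < 0:
            raise ValueError("artifact_rate_per_h must be non-negative")
        for band in self.genotype_band_scale:
            check_band(band)
        if self.drug is not None and self.injection_time_s is None:
            raise ValueError("drug profile given but no injection_time_s")


@dataclass
class RawRecording:
    """Uniformly sampled multichannel recording with session metadata."""

    channels: dict[str, np.ndarray]
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("channels have unequal lengths")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        # non-finite samples are tolerated here so that validate_session can
        # report them as diagnostics; the spectral chain rejects them later

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Derive a deterministic child RNG from a master seed and string keys."""
    hashed = [zlib.crc32(k.encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *hashed]))


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz.

    8th-order Butterworth band-pass: steep enough edges that a band's
    oscillator leaks <1% of its power into neighboring bands, keeping
    band-selective effects band-selective.
    """
    hi = min(hi, 0.999 * fs / 2.0)
    sos = ssig.butter(8, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = ssig.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, rms: float) -> np.ndarray:
    """1/f^a background via spectral shaping of white noise."""
    if rms <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)  # d cancels in the relative shaping
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    x_rms = np.sqrt(np.mean(x**2))
    return x * (rms / x_rms) if x_rms > 0 else x


def _eeg_channel(spec: GeneratorSpec, rng: np.random.Generator, n: int,
                 t_min_since_inj: np.ndarray | None) -> np.ndarray:
    eeg = np.zeros(n)
    for osc in spec.oscillators:
        if osc.amplitude == 0:
            continue
        base = _bandlimited_noise(rng, n, spec.fs,
                                  osc.center_freq - osc.bandwidth / 2.0,
                                  osc.center_freq + osc.bandwidth / 2.0)
        # unit-RMS noise carries mean envelope^2 = 2*RMS^2; scale so the mean
        # instantaneous power equals amplitude^2 (sinusoid convention)
        amp = osc.amplitude / np.sqrt(2.0)
        scale = amp * spec.genotype_band_scale.get(osc.band_label, 1.0)
        x = base * scale
        if spec.drug is not None and t_min_since_inj is not None:
            x = x * drug_gain(spec.drug, osc.band_label, t_min_since_inj)
        eeg += x
    eeg += _pink_noise(rng, n, spec.noise_exponent, spec.noise_floor)
    return eeg


def generate_recording(spec: GeneratorSpec) -> tuple[RawRecording, ArtifactMask]:
    """Generate one recording plus its ground-truth artifact mask.

    Deterministic for a fixed spec (including seed). The frontal and
    parietal EEG channels are independent realizations of the same band
    structure; EMG is low-amplitude broadband noise with bursts coinciding
    with every injected EEG artifact.
    """
    n = int(round(spec.duration_s * spec.fs))
    t_s = np.arange(n) / spec.fs
    t_min = None
    if spec.injection_time_s is not None:
        t_min = (t_s - spec.injection_time_s) / 60.0

    # independent named streams per channel: skipping a channel never
    # perturbs the others, and equal (spec, seed) gives identical output
    channels: dict[str, np.ndarray] = {}
    for name in spec.channels:
        rng = _stream(spec.seed, name)
        if name == "emg":
            channels[name] = 5.0 * rng.standard_normal(n)
        else:
            channels[name] = _eeg_channel(spec, rng, n, t_min)
    rng_a = _stream(spec.seed, "artifacts")
    eeg_f = channels.get("eeg_frontal")
    eeg_p = channels.get("eeg_parietal")
    emg = channels.get("emg")

    # sporadic high-amplitude artifacts with EMG coincidence
    events = []
    n_events = rng_a.poisson(spec.artifact_rate_per_h * spec.duration_s / 3600.0)
    for _ in range(n_events):
        start = rng_a.uniform(0.0, max(spec.duration_s - 1.0, 0.0))
        dur = rng_a.uniform(0.3, 1.0)
        i0, i1 = int(start * spec.fs), min(int((start + dur) * spec.fs), n)
        burst = rng_a.standard_normal(i1 - i0)
        window = np.hanning(i1 - i0) if i1 - i0 > 2 else np.ones(i1 - i0)
        if eeg_f is not None:
            eeg_f[i0:i1] += spec.artifact_amplitude * window * np.sign(burst)
        if eeg_p is not None:
            eeg_p[i0:i1] += 0.7 * spec.artifact_amplitude * window * np.sign(burst)
        if emg is not None:
            emg[i0:i1] += 80.0 * window * burst
        events.append((start, start + dur))

    n_epochs = int(spec.duration_s // EPOCH_LEN_S)
    flags = np.zeros(n_epochs, dtype=bool)
    for start, end in events:
        first = int(start // EPOCH_LEN_S)
        last = min(int(end // EPOCH_LEN_S), n_epochs - 1)
        flags[first : last + 1] = True

    rec = RawRecording(
        channels=channels,
        fs=spec.fs,
        meta={
            "injection_time_s": spec.injection_time_s,
            "artifact_events_s": events,
            "light_onset_h": spec.light_onset_h,
            "light_offset_h": spec.light_offset_h,
            "seed": spec.seed,
        },
    )
    return rec, ArtifactMask(flags)


@dataclass(frozen=True)
class StudyProtocol:
    """Session geometry for a simulated study (durations in seconds)."""

    baseline_s: float = 24 * 3600.0
    pre_s: float = 3600.0
    post_s: float = 5 * 3600.0
    fs: float = 1000.0
    artifact_rate_per_h: float = 4.0
    channels: tuple[str, ...] = ("eeg_frontal", "eeg_parietal", "emg")
    #: factor by which drug-gain time courses are sped up relative to the
    #: canonical 1-h-pre + 5-h-post session (1.0 = real time)
    time_compression: float = 1.0

    @property
    def session_s(self) -> float:
        return self.pre_s + self.post_s


def reduced_protocol() -> StudyProtocol:
    """Scaled-down protocol for simulation studies (see docs/methods.md)."""
    # 144-s sessions stand in for the 6-h originals: the drug/stress time
    # axis is compressed by the same 360 min / 144 s = 150x factor
    return StudyProtocol(baseline_s=96.0, pre_s=48.0, post_s=96.0, fs=200.0,
                         artifact_rate_per_h=0.0,
                         channels=("eeg_frontal", "emg"),
                         time_compression=150.0)


@dataclass
class SessionRecord:
    subject: str
    session: str        # "baseline" or a treatment label
    genotype: str
    treatment: str | None
    recording: RawRecording
    mask: ArtifactMask
    injection_time_s: float | None


def make_study(design, seed: int = 0, protocol: StudyProtocol | None = None,
               drug_profiles: dict[str, DrugEffectProfile] | None = None,
               ko_drug_profiles: dict[str, DrugEffectProfile] | None = None,
               ko_band_scale: dict[str, float] | None = None,
               include_baseline: bool = False,
               amplitudes: dict[str, float] | None = None) -> list[SessionRecord]:
    """Simulate a whole study from a design table.

    ``design`` is a pandas DataFrame with columns subject, genotype,
    treatment (one row per treatment session). Per subject a single
    log-normal amplitude multiplier (SD 0.2 on the log scale) models stable
    between-animal differences; per-recording noise streams are derived by
    stable hashing of (subject, session) from the master seed. KO subjects
    receive ``ko_band_scale`` baseline multipliers, and — when
    ``ko_drug_profiles`` is given — genotype-specific drug responses (e.g.
    a blunted superagonist response). With ``include_baseline`` each
    subject additionally gets one long drug-free recording labeled
    session "baseline".
    """
    import pandas as pd

    protocol = protocol or StudyProtocol()
    drug_profiles = drug_profiles if drug_profiles is not None else {
        name: fn() for name, fn in DRUG_PROFILES.items()
    }
    design = pd.DataFrame(design)
    if design.duplicated(["subject", "treatment"]).any():
        raise ValueError("duplicate subject/session keys in design")

    subjects = design[["subject", "genotype"]].drop_duplicates("subject")
    subj_effect = {}
    for subject in subjects["subject"]:
        rng = _stream(seed, str(subject), "subject_effect")
        subj_effect[subject] = float(np.exp(0.2 * rng.standard_normal()))

    base_amps = amplitudes or DEFAULT_AMPLITUDES
    records: list[SessionRecord] = []

    def _spec(subject, genotype, session, duration, injection, drug):
        amps = {b: a * subj_effect[subject] for b, a in base_amps.items()}
        scale = dict(ko_band_scale if ko_band_scale is not None else KO_BAND_SCALE) \
            if genotype == "KO" else {}
        rec_seed = _stream(seed, str(subject), str(session)).integers(2**31 - 1)
        return GeneratorSpec(
            duration_s=duration, fs=protocol.fs,
            oscillators=tuple(default_oscillators(amps)),
            genotype_band_scale=scale,
            drug=drug, injection_time_s=injection,
            artifact_rate_per_h=protocol.artifact_rate_per_h,
            channels=protocol.channels,
            seed=int(rec_seed),
        )

    if include_baseline:
        for _, row in subjects.iterrows():
            s = _spec(row["subject"], row["genotype"], "baseline",
                      protocol.baseline_s, None, None)
            rec, mask = generate_recording(s)
            rec.meta.update(subject=row["subject"], genotype=row["genotype"],
                            treatment=None, session="baseline")
            records.append(SessionRecord(row["subject"], "baseline", row["genotype"],
                                         None, rec, mask, None))

    for _, row in design.iterrows():
        treatment = row["treatment"]
        if row["genotype"] == "KO" and ko_drug_profiles and treatment in ko_drug_profiles:
            profile = ko_drug_profiles[treatment]
        else:
            profile = drug_profiles.get(treatment, saline_profile())
        if profile is not None and protocol.time_compression != 1.0:
            profile = compress_profile(profile, protocol.time_compression)
        s = _spec(row["subject"], row["genotype"], treatment,
                  protocol.session_s, protocol.pre_s, profile)
        rec, mask = generate_recording(s)
        rec.meta.update(subject=row["subject"], genotype=row["genotype"],
                        treatment=treatment, session=treatment)
        records.append(SessionRecord(row["subject"], treatment, row["genotype"],
                                     treatment, rec, mask, protocol.pre_s))
    return records


def spec_to_dict(spec: GeneratorSpec) -> dict:
    """Plain-dict form of a GeneratorSpec (for YAML/JSON configs)."""
    from dataclasses import asdict

    d = asdict(spec)
    d["oscillators"] = [asdict(o) for o in spec.oscillators]
    if spec.drug is not None:
        d["drug"] = asdict(spec.drug)
    d["channels"] = list(spec.channels)
    return d


def spec_from_dict(d: dict) -> GeneratorSpec:
    """Rebuild a GeneratorSpec from its plain-dict form."""
    d = dict(d)
    d["oscillators"] = tuple(OscillatorSpec(**o) for o in d.get("oscillators", ()))
    if d.get("drug") is not None:
        d["drug"] = DrugEffectProfile(**d["drug"])
    if "channels" in d:
        d["channels"] = tuple(d["channels"])
    return GeneratorSpec(**d)


def default_design(n_wt: int = 9, n_ko: int = 8,
                   treatments: tuple[str, ...] = ("SAL", "THIP")):
    """Study design table: n_wt WT + n_ko KO subjects x the given treatments."""
    import pandas as pd

    rows = []
    for i in range(n_wt):
        for t in treatments:
            rows.append({"subject": f"WT{i+1:02d}", "genotype": "WT", "treatment": t})
    for i in range(n_ko):
        for t in treatments:
            rows.append({"subject": f"KO{i+1:02d}", "genotype": "KO", "treatment": t})
    return pd.DataFrame(rows)
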