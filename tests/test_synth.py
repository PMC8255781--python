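"""Generator contracts: determinism, spectral structure, ground truth."""

import numpy as np
import pandas as pd
import pytest

from pharmaeeg import synth
from pharmaeeg.bands import BAND_RANGES
from pharmaeeg.spectral import compute_epoch_power
from pharmaeeg.synth import (DrugEffectProfile, GeneratorSpec, OscillatorSpec,
                             drug_gain, generate_recording, make_study)


def single_band_spec(band="delta", amplitude=30.0, **kw):
    lo, hi = BAND_RANGES[band]
    osc = OscillatorSpec((lo + hi) / 2, 0.8 * (hi - lo), amplitude, band)
    defaults = dict(duration_s=48.0, fs=200.0, oscillators=(osc,),
                    noise_floor=0.0, channels=("eeg_frontal", "emg"), seed=3)
    defaults.update(kw)
    return GeneratorSpec(**defaults)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        GeneratorSpec(duration_s=-1.0)
    with pytest.raises(ValueError):
        GeneratorSpec(duration_s=10.0, fs=0.0)
    with pytest.raises(ValueError):
        OscillatorSpec(2.5, 1.0, 10.0, "theta")  # 2.5 Hz is not in theta
    with pytest.raises(ValueError):
        DrugEffectProfile(band_gains={"delta": -0.5})


def test_determinism_bit_identical():
    spec = single_band_spec(artifact_rate_per_h=20.0, noise_floor=10.0)
    rec1, mask1 = generate_recording(spec)
    rec2, mask2 = generate_recording(spec)
    for name in rec1.channels:
        np.testing.assert_array_equal(rec1.channels[name], rec2.channels[name])
    np.testing.assert_array_equal(mask1.is_artifact, mask2.is_artifact)


def test_delta_oscillator_dominates_delta_channels():
    """A lone 2.5-Hz-band oscillator puts the spectral peak inside 1-4 Hz."""
    lo, hi = 1.0, 4.0
    osc = OscillatorSpec(2.5, 2.0, 30.0, "delta")
    rec, mask = generate_recording(GeneratorSpec(
        duration_s=48.0, fs=200.0, oscillators=(osc,), noise_floor=0.0,
        channels=("eeg_frontal", "emg"), seed=1))
    epm = compute_epoch_power(rec)
    mean_power = epm.values.mean(axis=0)
    peak_center = epm.centers[np.argmax(mean_power)]
    assert lo <= peak_center < hi
    in_band = (epm.centers >= lo) & (epm.centers < hi)
    assert mean_power[in_band].sum() / mean_power.sum() >= 0.90


def test_gain_linearity_amplitude_squares_to_power():
    """Doubling oscillator amplitude quadruples band epoch median power."""
    epm1 = compute_epoch_power(generate_recording(single_band_spec(amplitude=20.0))[0])
    epm2 = compute_epoch_power(generate_recording(single_band_spec(amplitude=40.0))[0])
    ratio = epm2.values[:, :3] / epm1.values[:, :3]
    np.testing.assert_allclose(ratio, 4.0, rtol=0.01)


def test_artifact_events_logged_and_flagged():
    """Rate 10/h over 2 h: ~20 events, all covered, large excursions."""
    spec = single_band_spec(duration_s=7200.0, artifact_rate_per_h=10.0,
                            noise_floor=5.0, amplitude=20.0, seed=11)
    rec, mask = generate_recording(spec)
    events = rec.meta["artifact_events_s"]
    assert 10 <= len(events) <= 32  # Poisson(20), generous bounds
    flagged = set(mask.flagged.tolist())
    eeg = rec.channels["eeg_frontal"]
    clean = np.delete(np.arange(mask.n_epochs), mask.flagged)
    spe = int(4.0 * spec.fs)
    clean_sd = np.std(np.concatenate(
        [eeg[i * spe:(i + 1) * spe] for i in clean[:50]]))
    for start, end in events:
        covering = set(range(int(start // 4), int(end // 4) + 1)) & flagged
        assert covering, f"event at {start:.1f}s not covered by mask"
    for e in mask.flagged:
        seg = eeg[e * spe:(e + 1) * spe]
        assert np.max(np.abs(seg)) >= 5 * clean_sd


def test_drug_gain_profiles():
    null = DrugEffectProfile()
    assert drug_gain(null, "delta", 42.0) == 1.0

    thip = DrugEffectProfile(band_gains={"delta": 2.0}, onset_min=0,
                             peak_min=10, offset_min=120)
    assert drug_gain(thip, "delta", 10.0) == pytest.approx(2.0)
    assert drug_gain(thip, "beta", 10.0) == 1.0  # unspecified band
    assert drug_gain(thip, "delta", -5.0) == 1.0  # pre-injection

    mmc = DrugEffectProfile(band_gains={"beta": 0.6}, onset_min=0,
                            peak_min=0, offset_min=120)
    assert drug_gain(mmc, "beta", 60.0) == pytest.approx(0.6)
    # returns to 1 after offset
    assert drug_gain(mmc, "beta", 1e6) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        drug_gain(mmc, "lowgamma", 1.0)


def test_drug_gain_continuous_and_stress_peaks_early():
    prof = synth.saline_profile()
    t = np.linspace(0, 60, 601)
    g = drug_gain(prof, "delta", t)
    assert np.all(np.abs(np.diff(g)) < 0.01)  # no jumps
    # stress effect is maximal in the first 10 minutes
    assert abs(g[0] - 1) > abs(g[-1] - 1)
    dev = np.abs(drug_gain(prof, "gamma1", t) - 1.0)
    assert dev[:100].max() == dev.max()


def test_make_study_counts_and_determinism():
    design = pd.DataFrame([
        {"subject": "s1", "genotype": "WT", "treatment": "SAL"},
        {"subject": "s1", "genotype": "WT", "treatment": "THIP"},
        {"subject": "s2", "genotype": "KO", "treatment": "SAL"},
        {"subject": "s2", "genotype": "KO", "treatment": "THIP"},
    ])
    protocol = synth.reduced_protocol()
    study = make_study(design, seed=5, protocol=protocol, include_baseline=True)
    assert len(study) == 2 + 4
    assert sum(r.session == "baseline" for r in study) == 2
    study2 = make_study(design, seed=5, protocol=protocol, include_baseline=True)
    for a, b in zip(study, study2):
        np.testing.assert_array_equal(a.recording.channels["eeg_frontal"],
                                      b.recording.channels["eeg_frontal"])

    dup = pd.concat([design, design.iloc[[0]]])
    with pytest.raises(ValueError):
        make_study(dup, seed=5, protocol=protocol)


def test_subject_effect_stable_within_subject():
    """The same subject keeps its amplitude offset across sessions."""
    design = synth.default_design(n_wt=2, n_ko=0, treatments=("S1", "S2"))
    null = DrugEffectProfile()
    study = make_study(design, seed=9, protocol=synth.reduced_protocol(),
                       drug_profiles={"S1": null, "S2": null})
    rms = {}
    for r in study:
        rms.setdefault(r.subject, []).append(
            float(np.sqrt(np.mean(r.recording.channels["eeg_frontal"] ** 2))))
    for subject, values in rms.items():
        assert abs(values[0] - values[1]) / values[0] < 0.25
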