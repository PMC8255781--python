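"""Filter bank, Hilbert power, epoch medians, artifact detector."""

import numpy as np
import pytest
from scipy import signal as ssig

from conftest import make_tone_recording
from pharmaeeg.spectral import (ArtifactMask, FilterBankSpec, build_filterbank,
                                compute_epoch_power, detect_artifacts,
                                downsample, epoch_median_power,
                                filterbank_hilbert_power, hilbert_power,
                                FS_ANALYSIS)
from pharmaeeg.synth import RawRecording


class TestFilterBank:
    def test_structure(self):
        spec = FilterBankSpec()
        assert spec.n_channels == 70
        assert len(spec.low_cutoffs) == (97.6 - 1.0) / 1.4 + 1
        np.testing.assert_allclose(spec.low_cutoffs[0], 1.0)
        np.testing.assert_allclose(spec.low_cutoffs[-1], 97.6)
        np.testing.assert_allclose(spec.high_cutoffs[0], 2.6)
        np.testing.assert_allclose(spec.high_cutoffs[-1], 99.2)
        np.testing.assert_allclose(np.diff(spec.low_cutoffs), 1.4)
        np.testing.assert_allclose(spec.high_cutoffs - spec.low_cutoffs, 1.6)
        assert np.all(np.diff(spec.centers) > 0)

    def test_kernel_zero_response(self):
        bank = build_filterbank()
        assert bank.shape == (70, 401)
        w, H = ssig.freqz(bank[0], worN=np.array([0.2, 1.8]), fs=FS_ANALYSIS)
        resp_db = 20 * np.log10(np.abs(H))
        assert resp_db[1] >= -1.0   # center of first passband
        assert resp_db[0] <= -20.0  # deep in the stopband

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            build_filterbank(FilterBankSpec(), fs=150.0)


class TestDownsample:
    def test_length(self):
        x = np.zeros(10_000)
        rec = RawRecording({"eeg_frontal": x, "emg": x.copy()}, fs=1000.0)
        out = downsample(rec, 200.0)
        assert out.fs == 200.0
        assert out.n_samples == 2000

    def test_inband_tone_amplitude_preserved(self):
        t = np.arange(20_000) / 1000.0
        x = np.sin(2 * np.pi * 50.0 * t)
        rec = RawRecording({"eeg_frontal": x, "emg": np.zeros_like(x)}, fs=1000.0)
        out = downsample(rec, 200.0)
        y = out.channels["eeg_frontal"][400:-400]  # interior
        t200 = np.arange(out.n_samples)[400:-400] / 200.0
        expected = np.sin(2 * np.pi * 50.0 * t200)
        amp = np.sqrt(2 * np.mean(y**2))
        assert abs(amp - 1.0) < 0.01
        assert np.corrcoef(y, expected)[0, 1] > 0.999

    def test_alias_suppressed(self):
        t = np.arange(20_000) / 1000.0
        x = np.sin(2 * np.pi * 150.0 * t)  # above the new Nyquist of 100 Hz
        rec = RawRecording({"eeg_frontal": x, "emg": np.zeros_like(x)}, fs=1000.0)
        y = downsample(rec, 200.0).channels["eeg_frontal"]
        f, P = ssig.periodogram(y, fs=200.0)
        alias_power = P[np.argmin(np.abs(f - 50.0))]
        assert 10 * np.log10(alias_power / 0.5 + 1e-300) <= -40.0

    def test_non_integer_factor_rejected(self):
        rec = RawRecording({"eeg_frontal": np.zeros(100)}, fs=300.0)
        with pytest.raises(ValueError):
            downsample(rec, 200.0)


class TestHilbertPower:
    def test_sinusoid_envelope(self):
        t = np.arange(4000) / 200.0
        p = hilbert_power(np.sin(2 * np.pi * 10 * t))
        interior = p[200:-200]
        np.testing.assert_allclose(interior, 1.0, atol=0.02)

    def test_zero_signal(self):
        assert np.all(hilbert_power(np.zeros(1000)) == 0)

    def test_am_tone_recovers_envelope(self):
        t = np.arange(8000) / 200.0
        A = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        p = hilbert_power(A * np.sin(2 * np.pi * 20 * t))
        rel_err = np.abs(p[400:-400] - A[400:-400] ** 2) / A[400:-400] ** 2
        assert np.max(rel_err) < 0.02

    def test_nonfinite_rejected(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(ValueError):
            hilbert_power(x)


class TestEpochMedian:
    def test_constant(self):
        med, kept = epoch_median_power(np.full(8000, 2.0))
        np.testing.assert_allclose(med, 2.0)
        assert len(kept) == 10

    def test_ramp_median(self):
        ramp = np.linspace(0, 1, 800)  # one 4-s epoch at 200 Hz
        med, _ = epoch_median_power(ramp)
        assert med == pytest.approx(0.5, abs=0.01)

    def test_masked_epochs_removed_from_kept(self):
        flags = np.zeros(100, dtype=bool)
        flags[[0, 99]] = True
        med, kept = epoch_median_power(np.ones(100 * 800),
                                       mask=ArtifactMask(flags))
        assert len(kept) == 98
        assert 0 not in kept and 99 not in kept
        assert np.atleast_1d(med).shape[-1] == 100  # indexing preserved

    def test_short_mask_rejected(self):
        with pytest.raises(ValueError):
            epoch_median_power(np.ones(10 * 800),
                               mask=ArtifactMask(np.zeros(5, bool)))


class TestDetector:
    def test_all_zero_no_flags(self):
        mask = detect_artifacts(np.zeros(8000), np.zeros(8000), fs=200.0)
        assert mask.flagged.size == 0

    def test_spike_and_emg_burst_flagged(self):
        rng = np.random.default_rng(0)
        eeg = rng.standard_normal(100 * 800)
        emg = rng.standard_normal(100 * 800)
        eeg[10 * 800 + 100] = 50.0          # EEG spike in epoch 10
        emg[20 * 800: 20 * 800 + 400] *= 30  # EMG burst in epoch 20
        mask = detect_artifacts(eeg, emg, fs=200.0)
        assert 10 in mask.flagged and 20 in mask.flagged
        assert mask.flagged.size <= 4  # no blanket flagging


class TestComputeEpochPower:
    def test_tone_localized_to_matching_channel(self):
        rec = make_tone_recording(6.0)
        epm = compute_epoch_power(rec)
        peak = epm.centers[np.argmax(epm.values.mean(axis=0))]
        assert abs(peak - 6.0) <= 1.4

    def test_amplitude_power_scaling(self):
        e1 = compute_epoch_power(make_tone_recording(6.0, amplitude=1.0))
        e2 = compute_epoch_power(make_tone_recording(6.0, amplitude=2.0))
        strong = e1.values.mean(axis=0) > 1e-3 * e1.values.mean()
        ratio = e2.values[:, strong] / e1.values[:, strong]
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-6)

    def test_determinism(self):
        rec = make_tone_recording(20.0)
        a = compute_epoch_power(rec)
        b = compute_epoch_power(rec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_energy_monotone_in_added_component(self):
        """Adding an in-band component never decreases that channel's power."""
        t = np.arange(int(24 * FS_ANALYSIS)) / FS_ANALYSIS
        base = np.sin(2 * np.pi * 10.2 * t)
        extra = np.sin(2 * np.pi * 10.6 * t + 1.0)
        rec1 = RawRecording({"eeg_frontal": base}, fs=FS_ANALYSIS)
        rec2 = RawRecording({"eeg_frontal": base + extra}, fs=FS_ANALYSIS)
        ch = np.argmin(np.abs(FilterBankSpec().centers - 10.4))
        p1 = compute_epoch_power(rec1).values[:, ch].mean()
        p2 = compute_epoch_power(rec2).values[:, ch].mean()
        assert p2 >= p1

    def test_wrong_rate_rejected(self):
        rec = RawRecording({"eeg_frontal": np.zeros(1000)}, fs=1000.0)
        with pytest.raises(ValueError):
            compute_epoch_power(rec)


def test_fast_path_matches_naive_convolution_hilbert():
    """Batched FFT path equals per-channel convolve + analytic signal.

    The two paths take the analytic signal over slightly different finite
    supports, so samplewise agreement degrades near the record edges; the
    comparison is on the interior 4-s epoch medians the pipeline consumes.
    """
    rng = np.random.default_rng(5)
    x = rng.standard_normal(int(60 * FS_ANALYSIS))
    bank = build_filterbank()[::10]  # subset of channels for speed
    fast = filterbank_hilbert_power(x, bank)
    delay = (bank.shape[1] - 1) // 2
    spe = int(4 * FS_ANALYSIS)
    n_epochs = x.size // spe
    for i, h in enumerate(bank):
        y = np.convolve(x, h, mode="full")[delay:delay + x.size]
        naive = np.abs(ssig.hilbert(y)) ** 2
        med_fast = np.median(fast[i][:n_epochs * spe].reshape(n_epochs, spe),
                             axis=1)[2:-2]
        med_naive = np.median(naive[:n_epochs * spe].reshape(n_epochs, spe),
                              axis=1)[2:-2]
        np.testing.assert_allclose(med_fast, med_naive, rtol=5e-3)
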