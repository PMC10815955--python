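"""Morlet kernel contracts, PLF statistics against circular-statistics closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammassr import (
    ContrastSpec,
    MorletParams,
    compute_tfr,
    morlet_kernel,
    percent_of_reference,
    phase_locking,
    plf,
    plf_contrast,
    plf_map,
    population_plf,
    rayleigh_expected_plf,
)
from gammassr.errors import ConfigurationError, NormalizationError
from gammassr.io_epoch import EpochSet

import pandas as pd

FS = 1000.0
PARAMS = MorletParams(fs=FS)


def _epochs(arr):
    arr = np.asarray(arr, dtype=float)
    return EpochSet(window=(-0.5, 1.0), fs=FS, channels=["c"], data=arr)


class TestKernel:
    def test_half_length_at_48_hz_is_94_ms(self):
        hl_ms = PARAMS.half_length(48.0) * 1000
        assert hl_ms == pytest.approx(93.75)
        assert round(hl_ms) == 94

    def test_unit_energy_and_odd_length(self):
        for f in (48.0, 50.0, 52.0):
            g = morlet_kernel(f, PARAMS)
            assert len(g) % 2 == 1
            assert np.sum(np.abs(g) ** 2) / FS == pytest.approx(1.0)

    def test_spectrum_peaks_at_center_frequency(self):
        g = morlet_kernel(50.0, PARAMS)
        n_fft = 8192
        spec = np.abs(np.fft.fft(g, n_fft))
        freqs = np.fft.fftfreq(n_fft, 1 / FS)
        assert abs(freqs[np.argmax(spec)] - 50.0) < 0.5

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            morlet_kernel(600.0, MorletParams(fs=FS, freqs=(50.0,)))


class TestTFR:
    def test_sinusoid_is_eigenfunction(self):
        t = np.arange(1500) / FS
        x = np.cos(2 * np.pi * 50.0 * t)
        tfr = compute_tfr(_epochs(x[None, None, :]), PARAMS)
        i50 = list(tfr.freqs).index(50.0)
        interior = np.abs(tfr.data[0, 0, i50, tfr.valid[i50]])
        assert interior.std() / interior.mean() < 1e-3

    def test_linearity_in_amplitude(self):
        t = np.arange(1500) / FS
        x = np.cos(2 * np.pi * 50.0 * t)
        tfr = compute_tfr(_epochs(np.stack([x, 2 * x])[:, None, :]), PARAMS)
        i50 = list(tfr.freqs).index(50.0)
        ratio = np.abs(tfr.data[1, 0, i50, tfr.valid[i50]]) / np.abs(
            tfr.data[0, 0, i50, tfr.valid[i50]]
        )
        assert np.allclose(ratio, 2.0)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp

        t = np.arange(1500) / FS
        # 46 -> 54 Hz linear chirp across the 1.5-s epoch
        x = chirp(t, f0=46.0, t1=1.5, f1=54.0, method="linear")
        tfr = compute_tfr(_epochs(x[None, None, :]), PARAMS)
        inst_f = 46.0 + (54.0 - 46.0) * t / 1.5
        sel = (inst_f > 48.5) & (inst_f < 51.5) & tfr.valid.all(axis=0)
        ridge = tfr.freqs[np.argmax(np.abs(tfr.data[0, 0, :, sel]), axis=1)]
        assert np.max(np.abs(ridge - inst_f[sel])) <= 1.0  # within grid resolution


class TestPLF:
    def test_identical_epochs_give_plf_one(self, rng):
        x = rng.normal(size=(1, 1, 1500)) * 30
        es = _epochs(np.repeat(x, 10, axis=0))
        pm = plf(compute_tfr(es, PARAMS))
        vals = pm.values[0][pm.valid & np.isfinite(pm.values[0])]
        assert np.allclose(vals, 1.0)

    def test_plf_in_unit_interval(self, small_session):
        _, rec, ev = small_session
        from gammassr import extract_epochs, offset_correct, reject_epochs

        es = reject_epochs(offset_correct(extract_epochs(rec, ev)))
        pm = plf_map(es, PARAMS)
        vals = pm.values[np.isfinite(pm.values)]
        assert np.all((vals >= 0) & (vals <= 1.0 + 1e-12))

    def test_streaming_and_batch_plf_agree(self, small_session):
        _, rec, ev = small_session
        from gammassr import extract_epochs, offset_correct, reject_epochs

        es = reject_epochs(offset_correct(extract_epochs(rec, ev)))
        pm_stream = plf_map(es, PARAMS, chunk_size=7)
        pm_batch = plf(compute_tfr(es, PARAMS))
        assert np.allclose(pm_stream.values, pm_batch.values, equal_nan=True)

    def test_rayleigh_expectation_small_n(self, rng):
        n, reps = 8, 4000
        phasors = np.exp(1j * rng.uniform(-np.pi, np.pi, size=(n, reps)))
        est = phase_locking(phasors, axis=0)
        target = rayleigh_expected_plf(n)
        se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - target) < 3 * se

    def test_von_mises_recovery_single_kappa(self, rng):
        kappa, n = 2.0, 1500
        reps = 50
        phases = rng.vonmises(0.0, kappa, size=(n, reps))
        est = phase_locking(np.exp(1j * phases), axis=0)
        se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - population_plf(kappa)) < 3 * se

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_amplitude_rescaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        phasors = rng.normal(size=(20, 5)) + 1j * rng.normal(size=(20, 5))
        scales = rng.uniform(0.1, 10.0, size=(20, 1))
        assert np.allclose(phase_locking(phasors), phase_locking(phasors * scales))


class TestContrast:
    def test_fully_locked_signal_has_zero_contrast(self):
        t = np.arange(1500) / FS
        x = np.cos(2 * np.pi * 50.0 * t)  # same sinusoid in BL and ROI, every epoch
        es = _epochs(np.repeat(x[None, None, :], 5, axis=0))
        pm = plf(compute_tfr(es, PARAMS))
        assert plf_contrast(pm)[0] == pytest.approx(0.0, abs=1e-9)

    def test_trimmed_windows(self):
        """Trim of 0.100 s turns [−0.5,0]/[0,0.5] into [−0.4,−0.1]/[0.1,0.4]."""
        spec = ContrastSpec()
        assert spec.trim == pytest.approx(0.100)
        t0, t1 = spec.bl_window
        assert (t0 + spec.trim, t1 - spec.trim) == (-0.4, -0.1)
        t0, t1 = spec.roi_window
        assert (t0 + spec.trim, t1 - spec.trim) == pytest.approx((0.1, 0.4))

    def test_excessive_trim_rejected(self, small_session):
        _, rec, ev = small_session
        from gammassr import extract_epochs

        pm = plf_map(extract_epochs(rec, ev), PARAMS)
        with pytest.raises(ConfigurationError):
            plf_contrast(pm, ContrastSpec(trim=0.30))

    def test_stationary_process_contrast_mean_zero(self, rng):
        """Same law pre- and post-stimulus: contrast averages to zero over repeats."""
        contrasts = []
        for _ in range(12):
            es = _epochs(rng.normal(scale=20.0, size=(60, 1, 1500)))
            contrasts.append(plf_contrast(plf_map(es, PARAMS))[0])
        contrasts = np.asarray(contrasts)
        se = contrasts.std(ddof=1) / np.sqrt(len(contrasts))
        assert abs(contrasts.mean()) < 3.5 * se + 1e-3

    def test_locked_roi_noise_baseline_matches_closed_form(self, rng):
        """Contrast ≈ population PLF − Rayleigh floor for post-stimulus locking only."""
        n_ep = 400
        t = np.arange(1500) / FS
        roi_on = (t - 0.5 >= 0) & (t - 0.5 < 0.5)  # absolute epoch time of ROI
        kappa = 4.0
        phases = rng.vonmises(0.0, kappa, size=n_ep)
        data = rng.normal(scale=20.0, size=(n_ep, 1, 1500))
        for i in range(n_ep):
            data[i, 0, roi_on] += 200.0 * np.cos(2 * np.pi * 50.0 * (t[roi_on] - 0.5) + phases[i])
        pm = plf_map(_epochs(data), PARAMS)
        expected = population_plf(kappa) - rayleigh_expected_plf(n_ep)
        assert plf_contrast(pm)[0] == pytest.approx(expected, abs=0.04)


class TestPercentOfReference:
    def test_arithmetic_and_self_normalization(self):
        vals = pd.Series([0.20, 0.20, 0.08])
        arms = pd.Series(["veh", "veh", "drug"])
        pct = percent_of_reference(vals, arms, "veh")
        assert pct.iloc[2] == pytest.approx(40.0)
        assert np.allclose(pct[arms == "veh"], 100.0)

    def test_nonpositive_reference_flagged(self):
        vals = pd.Series([-0.1, 0.1, 0.5])
        arms = pd.Series(["veh", "veh", "drug"])
        with pytest.raises(NormalizationError):
            percent_of_reference(vals, arms, "veh")
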