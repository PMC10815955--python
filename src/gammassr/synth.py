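"""Synthetic telemetry-EEG and behavior generator with closed-form expected values.

The generator emulates a rodent pharmaco-EEG session: a click-train protocol
entrains a steady-state response whose trial-to-trial phase is von Mises
distributed around zero, so the population phase-locking factor of the evoked
component is the Bessel ratio I1(kappa)/I0(kappa) — an analytic target the
estimation pipeline can be validated against. The background is 1/f^alpha
("pink") noise plus a band-limited 32–80 Hz component whose RMS amplitude is
the spontaneous-gamma knob, plus occasional large biphasic artifacts meant to
trip the amplitude-rejection rules. Behavioral endpoints (beam-break activity
counts, paired social-interaction time) are drawn from negative-binomial and
truncated-normal laws respectively.

All draws are keyed off a single integer seed through ``numpy`` seed
sequences: identical inputs and seed give bit-identical output, and each
signal component uses its own stream so changing one component's parameters
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .io_epoch import EventSeries, Recording

GAMMA_BAND = (32.0, 80.0)  # Hz, band of the spontaneous-gamma component
DEFAULT_FS = 1000.0  # Hz
DEFAULT_CHANNELS = ("global_cortex", "auditory_cortex")


@dataclass(frozen=True)
class StimulusProtocol:
    """Click-train stimulation protocol.

    Defaults encode the standard gamma-ASSR session: 1500 stimuli, each a
    500-ms 50-Hz click train followed by 700 ms of silence (1.2-s cycle,
    30-min session).
    """

    n_stimuli: int = 1500
    train_duration: float = 0.5
    silence_duration: float = 0.7
    click_rate: float = 50.0
    session_start_offset: float = 2.0

    def __post_init__(self) -> None:
        if self.n_stimuli < 1:
            raise ConfigurationError("n_stimuli must be >= 1")
        if self.train_duration <= 0 or self.silence_duration < 0:
            raise ConfigurationError("train/silence durations invalid")
        if self.click_rate <= 0:
            raise ConfigurationError("click_rate must be positive")
        if self.session_start_offset < 0:
            raise ConfigurationError("session_start_offset must be >= 0")

    @property
    def cycle(self) -> float:
        """Stimulus cycle length in seconds (train + silence)."""
        return self.train_duration + self.silence_duration

    @property
    def session_duration(self) -> float:
        """Total session length, including lead-in/out margins."""
        return self.n_stimuli * self.cycle + 2 * self.session_start_offset


@dataclass(frozen=True)
class EvokedModel:
    """Phase-jittered steady-state evoked component.

    ``phase_concentration`` (kappa) is the sole phase-synchrony knob: trial
    phases are von Mises(0, kappa), so the population PLF of the noise-free
    evoked component equals I1(kappa)/I0(kappa); kappa = 0 gives uniform
    phases.
    """

    carrier_freq: float = 50.0
    amplitude: float = 25.0  # µV
    phase_concentration: float = 4.0
    onset_latency: float = 0.0
    response_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.phase_concentration < 0:
            raise ConfigurationError("phase concentration must be >= 0")
        if self.carrier_freq <= 0 or self.response_duration < 0:
            raise ConfigurationError("carrier/response parameters invalid")

    @property
    def population_plf(self) -> float:
        """I1(kappa)/I0(kappa), the mean resultant of the trial-phase law."""
        k = self.phase_concentration
        if k == 0:
            return 0.0
        # i1e/i0e: exponentially scaled Bessel ratio, stable for large kappa
        from scipy.special import i0e, i1e

        return float(i1e(k) / i0e(k))


@dataclass(frozen=True)
class BackgroundModel:
    """1/f background + band-limited spontaneous gamma + Poisson artifacts.

    ``pink_scale`` and ``gamma_band_power_scale`` are RMS amplitudes in µV of
    the respective components; doubling ``gamma_band_power_scale`` quadruples
    the 32–80 Hz band power. Artifacts are 200-ms biphasic transients with
    peak amplitude ``artifact_amplitude`` and Poisson timing at
    ``artifact_rate`` events/minute.
    """

    pink_exponent: float = 1.0
    pink_scale: float = 20.0  # µV RMS
    gamma_band_power_scale: float = 5.0  # µV RMS of the 32–80 Hz component
    artifact_rate: float = 0.0  # events / minute
    artifact_amplitude: float = 600.0  # µV peak

    def __post_init__(self) -> None:
        if min(self.pink_scale, self.gamma_band_power_scale, self.artifact_rate) < 0:
            raise ConfigurationError("background scales/rates must be >= 0")
        if self.artifact_amplitude < 0:
            raise ConfigurationError("artifact amplitude must be >= 0")


@dataclass(frozen=True)
class BehaviorModel:
    """Locomotor-activity and social-interaction generative parameters.

    ``activity_mean_profile`` gives the expected beam-break counts per
    ``activity_bin_minutes`` bin as a function of time since dosing; counts
    are negative-binomial with overdispersion ``activity_dispersion``
    (variance = m + m^2/theta). Social time per pair is normal
    (``social_mean``, ``social_sd``) truncated to [0, test_duration].
    """

    activity_bin_minutes: float = 10.0
    activity_mean_profile: tuple[float, ...] = (30.0,) * 9
    activity_dispersion: float = 8.0
    social_mean: float = 57.0
    social_sd: float = 11.0
    test_duration: float = 600.0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.activity_mean_profile):
            raise ConfigurationError("activity means must be >= 0")
        if self.social_mean < 0 or self.social_sd < 0:
            raise ConfigurationError("social parameters must be >= 0")
        if self.activity_dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")


@dataclass(frozen=True)
class ArmSpec:
    label: str
    n_subjects: int
    evoked: EvokedModel
    background: BackgroundModel
    behavior: BehaviorModel

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("each arm needs >= 2 subjects")


@dataclass(frozen=True)
class StudyDesign:
    """Multi-arm study layout: one reference (vehicle) arm plus treatment arms.

    ``subject_cv`` is a lognormal coefficient of variation applied per subject
    to the arm-level effect parameters (phase concentration, gamma amplitude,
    behavioral means) to emulate between-animal variability.
    """

    arms: tuple[ArmSpec, ...]
    reference_arm: str
    seed: int
    subject_cv: float = 0.15

    def __post_init__(self) -> None:
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("arm labels must be unique")
        if labels.count(self.reference_arm) != 1:
            raise ConfigurationError(f"exactly one reference arm required, got {self.reference_arm!r}")
        if self.subject_cv < 0:
            raise ConfigurationError("subject_cv must be >= 0")


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, exponent: float, rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise with the requested RMS, via spectral shaping."""
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[1:] /= f[1:] ** (exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_noise(n: int, fs: float, band: tuple[float, float], rms: float,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise (flat in band) with the requested RMS."""
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _artifacts(n: int, fs: float, rate_per_min: float, amplitude: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-timed 200-ms biphasic transients; returns (signal, onset times)."""
    x = np.zeros(n)
    duration = n / fs
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    width = int(round(0.2 * fs))
    t = np.arange(width) / fs
    shape = amplitude * np.sin(2 * np.pi * t / 0.2)  # +lobe then −lobe, peak ±amplitude
    onsets = np.sort(rng.uniform(0, duration - 0.2, size=n_events)) if n_events else np.empty(0)
    for on in onsets:
        i0 = int(round(on * fs))
        x[i0 : i0 + width] += shape[: max(0, min(width, n - i0))]
    return x, onsets


def _background_channel(n: int, fs: float, bg: BackgroundModel,
                        ss: np.random.SeedSequence) -> tuple[np.ndarray, np.ndarray]:
    """One channel of background signal from a per-channel seed sequence."""
    pink_ss, gamma_ss, art_ss = ss.spawn(3)
    x = _pink_noise(n, fs, bg.pink_exponent, bg.pink_scale, np.random.default_rng(pink_ss))
    x += _band_noise(n, fs, GAMMA_BAND, bg.gamma_band_power_scale, np.random.default_rng(gamma_ss))
    art, art_onsets = _artifacts(n, fs, bg.artifact_rate, bg.artifact_amplitude,
                                 np.random.default_rng(art_ss))
    return x + art, art_onsets


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_session(
    protocol: StimulusProtocol,
    evoked: EvokedModel,
    background: BackgroundModel,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    return_artifact_onsets: bool = False,
):
    """Simulate a stimulation session; returns ``(Recording, EventSeries)``.

    Each channel carries independent background noise and an independent set
    of von Mises trial phases. The evoked sinusoid at ``carrier_freq`` is
    active on ``[onset+latency, onset+latency+response_duration]`` per trial.
    """
    nyq_need = 2 * max(evoked.carrier_freq, GAMMA_BAND[1])
    if fs < nyq_need:
        raise ConfigurationError(f"fs={fs} below Nyquist requirement {nyq_need} Hz")
    if evoked.onset_latency + evoked.response_duration > protocol.cycle:
        raise ConfigurationError("evoked response does not fit inside the stimulus cycle")

    duration = protocol.session_duration
    n = int(round(duration * fs))
    onsets = protocol.session_start_offset + np.arange(protocol.n_stimuli) * protocol.cycle
    t = np.arange(n) / fs

    root = np.random.SeedSequence(seed)
    ch_seqs = root.spawn(len(channels))
    data = np.empty((len(channels), n))
    artifact_onsets = []
    resp_len = int(round(evoked.response_duration * fs))
    for c, ch_ss in enumerate(ch_seqs):
        bg_ss, phase_ss = ch_ss.spawn(2)
        x, art_on = _background_channel(n, fs, background, bg_ss)
        phase_rng = np.random.default_rng(phase_ss)
        if evoked.phase_concentration > 0:
            phases = phase_rng.vonmises(0.0, evoked.phase_concentration,
                                        size=protocol.n_stimuli)
        else:
            phases = phase_rng.uniform(-np.pi, np.pi, size=protocol.n_stimuli)
        if evoked.amplitude > 0 and resp_len > 0:
            for onset, phi in zip(onsets, phases):
                i0 = int(round((onset + evoked.onset_latency) * fs))
                seg = slice(i0, min(i0 + resp_len, n))
                tt = t[seg] - (onset + evoked.onset_latency)
                x[seg] += evoked.amplitude * np.cos(
                    2 * np.pi * evoked.carrier_freq * tt + phi
                )
        data[c] = x
        artifact_onsets.append(art_on)

    rec = Recording(channels=list(channels), fs=fs, data=data)
    ev = EventSeries(onsets=onsets)
    if return_artifact_onsets:
        return rec, ev, artifact_onsets
    return rec, ev


def generate_spontaneous(
    background: BackgroundModel,
    duration: float,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> Recording:
    """Simulate a stimulus-free recording with the same background composition."""
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if fs < 2 * GAMMA_BAND[1]:
        raise ConfigurationError(f"fs={fs} below Nyquist for the gamma band")
    n = int(round(duration * fs))
    root = np.random.SeedSequence(seed)
    data = np.empty((len(channels), n))
    for c, ch_ss in enumerate(root.spawn(len(channels))):
        bg_ss, _ = ch_ss.spawn(2)  # same stream layout as generate_session
        data[c], _ = _background_channel(n, fs, background, bg_ss)
    return Recording(channels=list(channels), fs=fs, data=data)


def _subject_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal multiplicative factors with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1 + cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def generate_behavior(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw activity and social tables for every arm of a study design.

    Returns ``(activity, social)``. Activity rows: subject, arm,
    bin_start_min, bin_minutes, counts. Social rows: pair, arm, social_s,
    test_duration_s (one pair per subject slot).
    """
    root = np.random.SeedSequence(design.seed).spawn(len(design.arms))
    act_rows, soc_rows = [], []
    for arm, arm_ss in zip(design.arms, root):
        bm = arm.behavior
        rng = np.random.default_rng(arm_ss)
        means = np.asarray(bm.activity_mean_profile, dtype=float)
        act_factors = _subject_factors(rng, design.subject_cv, arm.n_subjects)
        soc_factors = _subject_factors(rng, design.subject_cv, arm.n_subjects)
        for s in range(arm.n_subjects):
            sid = f"{arm.label}_{s+1:02d}"
            mu = means * act_factors[s]
            theta = bm.activity_dispersion
            p = theta / (theta + np.maximum(mu, 1e-12))
            counts = np.where(mu > 0, rng.negative_binomial(theta, p), 0)
            for b, cnt in enumerate(counts):
                act_rows.append(
                    {
                        "subject": sid,
                        "arm": arm.label,
                        "bin_start_min": b * bm.activity_bin_minutes,
                        "bin_minutes": bm.activity_bin_minutes,
                        "counts": int(cnt),
                    }
                )
            mean_s = bm.social_mean * soc_factors[s]
            if bm.social_sd == 0:
                val = min(mean_s, bm.test_duration)
            else:
                a = (0 - mean_s) / bm.social_sd
                b_ = (bm.test_duration - mean_s) / bm.social_sd
                val = float(
                    sps.truncnorm.rvs(a, b_, loc=mean_s, scale=bm.social_sd,
                                      random_state=rng)
                )
            soc_rows.append(
                {
                    "pair": sid,
                    "arm": arm.label,
                    "social_s": val,
                    "test_duration_s": bm.test_duration,
                }
            )
    return pd.DataFrame(act_rows), pd.DataFrame(soc_rows)
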