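"""Morlet time–frequency decomposition, phase-locking factor and ROI−baseline contrast.

The phase-locking factor (PLF, also called inter-trial coherence) at a
(time, frequency) cell is the magnitude of the average across epochs of the
unit-normalized complex wavelet coefficient: 1 for perfectly reproducible
phase, tending to the Rayleigh floor sqrt(pi)/(2 sqrt(N)) for N uniform
phases. The study endpoint is the mean PLF over a post-stimulus
region-of-interest box minus the mean over the pre-stimulus baseline box,
both trimmed by 100 ms to keep wavelet smearing out of the windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    EmptyInputError,
    NormalizationError,
)
from .io_epoch import EpochSet

DEFAULT_FREQS = tuple(np.arange(48.0, 52.0 + 0.25, 0.5))  # 48..52 Hz, 0.5-Hz steps
DEFAULT_N_CYCLES = 9
DEFAULT_BL_WINDOW = (-0.5, 0.0)
DEFAULT_ROI_WINDOW = (0.0, 0.5)
DEFAULT_TRIM = 0.100  # seconds: wavelet half-length at 48 Hz (93.75 ms) rounded up


@dataclass(frozen=True)
class MorletParams:
    """Morlet wavelet family: ``n_cycles`` at each analysis frequency.

    The kernel support is ``n_cycles / f`` seconds (half-length
    ``n_cycles / (2 f)``); the Gaussian envelope sigma is support/7 so the
    envelope is essentially zero at the kernel ends.
    """

    fs: float
    freqs: tuple[float, ...] = DEFAULT_FREQS
    n_cycles: int = DEFAULT_N_CYCLES

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if any(f <= 0 or f >= self.fs / 2 for f in self.freqs):
            raise ConfigurationError("analysis frequencies must lie in (0, fs/2)")

    def half_length(self, f: float) -> float:
        """Kernel half-length in seconds at frequency ``f``."""
        return self.n_cycles / (2.0 * f)


def morlet_kernel(f: float, p: MorletParams) -> np.ndarray:
    """Complex Morlet kernel at ``f`` Hz: odd length, unit energy (sum |g|^2 dt = 1)."""
    if f >= p.fs / 2:
        raise ConfigurationError(f"frequency {f} Hz at or above Nyquist {p.fs / 2}")
    support = p.n_cycles / f
    n_half = int(round(support / 2 * p.fs))
    t = np.arange(-n_half, n_half + 1) / p.fs
    sigma = support / 7.0
    g = np.exp(-(t**2) / (2 * sigma**2)) * np.exp(2j * np.pi * f * t)
    dt = 1.0 / p.fs
    g /= np.sqrt(np.sum(np.abs(g) ** 2) * dt)
    return g


@dataclass
class TFR:
    """Per-epoch complex wavelet coefficients.

    ``data`` has shape ``(n_epochs, n_channels, n_freqs, n_times)``; ``valid``
    is a ``(n_freqs, n_times)`` mask, False where the kernel overhangs the
    epoch edge.
    """

    times: np.ndarray
    freqs: np.ndarray
    channels: list[str]
    data: np.ndarray
    valid: np.ndarray


@dataclass
class PLFMap:
    """Phase-locking factor per (channel, frequency, time) with validity mask."""

    times: np.ndarray
    freqs: np.ndarray
    channels: list[str]
    values: np.ndarray  # (n_channels, n_freqs, n_times), in [0, 1]
    valid: np.ndarray  # (n_freqs, n_times)
    n_epochs_used: int

    def to_frame(self) -> pd.DataFrame:
        """Long-form export: channel, time_s, freq_hz, plf."""
        rows = []
        for c, ch in enumerate(self.channels):
            fi, ti = np.nonzero(self.valid)
            rows.append(
                pd.DataFrame(
                    {
                        "channel": ch,
                        "time_s": self.times[ti],
                        "freq_hz": self.freqs[fi],
                        "plf": self.values[c, fi, ti],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ContrastSpec:
    """ROI−baseline contrast definition, trimmed by ``trim`` s at both ends of both boxes."""

    bl_window: tuple[float, float] = DEFAULT_BL_WINDOW
    roi_window: tuple[float, float] = DEFAULT_ROI_WINDOW
    trim: float = DEFAULT_TRIM


def _epoch_tfr(epochs: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    """Convolve (n_ep, n_ch, n_t) with each kernel -> (n_ep, n_ch, n_f, n_t)."""
    out = np.empty(epochs.shape[:2] + (len(kernels), epochs.shape[-1]), dtype=complex)
    for j, g in enumerate(kernels):
        out[:, :, j, :] = fftconvolve(epochs[:, :, None, :], g[None, None, None, :],
                                      mode="same", axes=-1)[:, :, 0, :]
    return out


def _valid_mask(n_times: int, freqs, p: MorletParams) -> np.ndarray:
    valid = np.ones((len(freqs), n_times), dtype=bool)
    for j, f in enumerate(freqs):
        n_half = int(round(p.n_cycles / f / 2 * p.fs))
        valid[j, :n_half] = False
        if n_half > 0:
            valid[j, -n_half:] = False
    return valid


def compute_tfr(es: EpochSet, p: MorletParams) -> TFR:
    """Per-epoch complex TFR of the retained epochs (loads everything in memory).

    For long epoch sets prefer :func:`plf_map`, which streams.
    """
    if es.n_retained == 0:
        raise EmptyInputError("no retained epochs")
    kernels = [morlet_kernel(f, p) for f in p.freqs]
    data = _epoch_tfr(es.retained(), kernels)
    return TFR(
        times=es.times,
        freqs=np.asarray(p.freqs, dtype=float),
        channels=list(es.channels),
        data=data,
        valid=_valid_mask(es.n_samples, p.freqs, p),
    )


def plf(tfr: TFR) -> PLFMap:
    """PLF from a per-epoch TFR: unit-normalize, average over epochs, take magnitude."""
    return _plf_from_phasors(tfr.data, tfr.times, tfr.freqs, tfr.channels, tfr.valid)


def phase_locking(coeffs: np.ndarray, axis: int = 0) -> np.ndarray:
    """Magnitude of the mean unit phasor of complex ``coeffs`` along ``axis``.

    Zero-magnitude entries are excluded from the average. This is the
    statistic's core, usable on raw phasor arrays as well as full TFRs.
    """
    mag = np.abs(coeffs)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, coeffs / np.where(mag > 0, mag, 1.0), 0.0)
    counts = (mag > 0).sum(axis=axis)
    s = unit.sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, np.abs(s) / np.maximum(counts, 1), np.nan)
    return out


def _negligible(mag: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Cells whose magnitude is numerically zero relative to the epoch's maximum.

    Convolution roundoff leaves ~1e-16-scale coefficients in truly silent
    stretches; their phases are meaningless and must not enter the average.
    """
    return mag <= rtol * mag.max(axis=(-2, -1), keepdims=True)


def _plf_from_phasors(data, times, freqs, channels, valid) -> PLFMap:
    n_ep = data.shape[0]
    if n_ep < 2:
        raise DegenerateInputError("PLF requires at least 2 epochs")
    data = np.where(_negligible(np.abs(data)), 0.0, data)
    values = phase_locking(data, axis=0)
    return PLFMap(times=times, freqs=np.asarray(freqs, dtype=float),
                  channels=list(channels), values=values, valid=valid,
                  n_epochs_used=n_ep)


def plf_map(es: EpochSet, p: MorletParams, chunk_size: int = 128) -> PLFMap:
    """PLF of an epoch set, streaming over epochs to bound memory."""
    if es.n_retained < 2:
        raise DegenerateInputError("PLF requires at least 2 retained epochs")
    kernels = [morlet_kernel(f, p) for f in p.freqs]
    retained = es.retained()
    n_ep = retained.shape[0]
    acc = np.zeros((len(es.channels), len(p.freqs), es.n_samples), dtype=complex)
    counts = np.zeros_like(acc, dtype=int)
    for i0 in range(0, n_ep, chunk_size):
        chunk = _epoch_tfr(retained[i0 : i0 + chunk_size], kernels)
        mag = np.abs(chunk)
        nz = (mag > 0) & ~_negligible(mag)
        acc += np.where(nz, chunk / np.where(nz, mag, 1.0), 0.0).sum(axis=0)
        counts += nz.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, np.abs(acc) / np.maximum(counts, 1), np.nan)
    return PLFMap(times=es.times, freqs=np.asarray(p.freqs, dtype=float),
                  channels=list(es.channels), values=values,
                  valid=_valid_mask(es.n_samples, p.freqs, p), n_epochs_used=n_ep)


def plf_contrast(pmap: PLFMap, spec: ContrastSpec = ContrastSpec()) -> np.ndarray:
    """ROI−baseline PLF contrast per channel.

    Both windows are trimmed by ``spec.trim`` seconds at both ends; the
    contrast is the mean PLF over the trimmed ROI box (all frequencies) minus
    the mean over the trimmed baseline box. Cells invalidated by kernel
    overhang are excluded from the means.
    """
    out = np.empty(len(pmap.channels))
    eps = 1e-9
    for name, (t0, t1) in (("bl", spec.bl_window), ("roi", spec.roi_window)):
        if spec.trim >= (t1 - t0) / 2:
            raise ConfigurationError(f"trim {spec.trim}s leaves the {name} window empty")
    for c in range(len(pmap.channels)):
        means = {}
        for name, (t0, t1) in (("bl", spec.bl_window), ("roi", spec.roi_window)):
            sel_t = (pmap.times >= t0 + spec.trim - eps) & (pmap.times <= t1 - spec.trim + eps)
            box = pmap.values[c][:, sel_t]
            box_valid = pmap.valid[:, sel_t] & np.isfinite(box)
            if not box_valid.any():
                raise ConfigurationError(f"no valid cells in the {name} window")
            means[name] = float(box[box_valid].mean())
        out[c] = means["roi"] - means["bl"]
    return out


def percent_of_reference(values: pd.Series, arms: pd.Series, reference_arm: str) -> pd.Series:
    """Each value divided by the reference-arm mean, ×100.

    Raises :class:`NormalizationError` when the reference mean is not
    positive; callers should then report raw values instead.
    """
    ref = values[arms == reference_arm]
    if len(ref) == 0:
        raise NormalizationError(f"reference arm {reference_arm!r} is empty")
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise NormalizationError(f"reference mean {ref_mean:.4g} is not positive")
    return values / ref_mean * 100.0
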