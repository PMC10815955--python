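"""Quantitative EEG: fixed 4-s epoching, peak-to-peak rejection, Hanning periodogram, band power.

Spectra use a Hanning-windowed FFT per epoch with power = complex spectrum ×
its conjugate, scaled so that (a) a unit-amplitude sinusoid at a bin center
carries total power amplitude²/2 summed over its leakage bins, and (b) the
sum over all bins approximates the epoch's mean-square amplitude (Parseval
with window-gain compensation). At the default 4-s epochs the grid spacing
is 0.25 Hz over 0..fs/2. Gamma band power is the sum of bins with
32 ≤ f ≤ 80 Hz (both ends inclusive), averaged over retained epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .errors import ConfigurationError, EmptyInputError
from .io_epoch import EpochSet, Recording

import logging

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_S = 4.0
DEFAULT_P2P_UV = 400.0
DEFAULT_BAND = (32.0, 80.0)


def segment_fixed(rec: Recording, epoch_s: float = DEFAULT_EPOCH_S) -> EpochSet:
    """Cut a recording into contiguous non-overlapping epochs of ``epoch_s`` seconds.

    The remainder after the last whole epoch is discarded (and logged).
    """
    if epoch_s <= 0:
        raise ConfigurationError("epoch length must be positive")
    n_per = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise EmptyInputError(
            f"recording of {rec.duration:.3f}s shorter than one {epoch_s}s epoch"
        )
    leftover = rec.n_samples - n_epochs * n_per
    if leftover:
        logger.info("segment_fixed: discarding %.3f s remainder", leftover / rec.fs)
    data = rec.data[:, : n_epochs * n_per].reshape(len(rec.channels), n_epochs, n_per)
    return EpochSet(
        window=(0.0, epoch_s),
        fs=rec.fs,
        channels=list(rec.channels),
        data=np.transpose(data, (1, 0, 2)).copy(),
    )


def reject_p2p(es: EpochSet, threshold: float = DEFAULT_P2P_UV) -> EpochSet:
    """Reject epochs whose peak-to-peak amplitude strictly exceeds ``threshold`` on any channel."""
    if threshold <= 0:
        raise ConfigurationError("p2p threshold must be positive")
    p2p = es.data.max(axis=2) - es.data.min(axis=2)  # (n_ep, n_ch)
    bad = (p2p > threshold).any(axis=1)
    rejected = es.rejected | bad
    reasons = es.reject_reason.copy()
    reasons[bad & ~es.rejected] = "p2p"
    n_new = int((bad & ~es.rejected).sum())
    if n_new:
        logger.info("reject_p2p: rejected %d/%d epochs at %g µV p2p", n_new, es.n_epochs, threshold)
    return replace(es, data=es.data, rejected=rejected, reject_reason=reasons)


@dataclass
class SpectrumSet:
    """Per-epoch, per-channel power spectra in µV² per bin."""

    freqs: np.ndarray
    channels: list[str]
    power: np.ndarray  # (n_epochs_used, n_channels, n_freqs)
    n_epochs_used: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in range(self.power.shape[0]):
            for c, ch in enumerate(self.channels):
                rows.append(pd.DataFrame({"channel": ch, "epoch": e,
                                          "freq_hz": self.freqs,
                                          "power": self.power[e, c]}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class BandPower:
    """Summed band power per channel: per retained epoch and session mean."""

    band: tuple[float, float]
    channels: list[str]
    per_epoch: np.ndarray  # (n_epochs_used, n_channels)
    value: np.ndarray  # (n_channels,), mean over retained epochs


def power_spectrum(es: EpochSet) -> SpectrumSet:
    """Hanning-windowed one-sided power spectrum of each retained epoch.

    Scaling: P_k = s·|X_k|² with s = 1/(N·Σw²), doubled for interior bins, so
    the bin sum matches the mean-square signal and a bin-centered sinusoid of
    amplitude A sums to A²/2 over its leakage bins.
    """
    if es.n_retained == 0:
        raise EmptyInputError("no retained epochs for spectral analysis")
    x = es.retained()
    n = es.n_samples
    w = hann(n, sym=False)
    scale = 1.0 / (n * np.sum(w**2))
    spec = np.fft.rfft(x * w, axis=2)
    power = (spec * np.conj(spec)).real * scale
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, 1.0 / es.fs)
    return SpectrumSet(freqs=freqs, channels=list(es.channels), power=power,
                       n_epochs_used=x.shape[0])


def band_power(ss: SpectrumSet, band: tuple[float, float] = DEFAULT_BAND) -> BandPower:
    """Sum spectrum bins with band[0] ≤ f ≤ band[1] (inclusive ends)."""
    lo, hi = band
    if hi < lo:
        raise ConfigurationError(f"empty band {band}")
    if lo < ss.freqs[0] or hi > ss.freqs[-1]:
        raise ConfigurationError(f"band {band} outside spectrum range")
    sel = (ss.freqs >= lo - 1e-9) & (ss.freqs <= hi + 1e-9)
    if not sel.any():
        raise ConfigurationError(f"no spectrum bins inside band {band}")
    per_epoch = ss.power[:, :, sel].sum(axis=2)
    return BandPower(band=band, channels=list(ss.channels), per_epoch=per_epoch,
                     value=per_epoch.mean(axis=0))
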