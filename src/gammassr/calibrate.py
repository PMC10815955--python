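"""Closed-form calibration helpers for the von Mises phase-jitter model.

For trial phases drawn von Mises(0, kappa), the mean resultant length — and
therefore the asymptotic phase-locking factor of a noise-free steady-state
response — is the Bessel ratio A(kappa) = I1(kappa)/I0(kappa). These helpers
invert that map so study designs can be specified directly in terms of a
target population PLF or an attenuation ratio between arms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .errors import ConfigurationError


def population_plf(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), the population PLF of von Mises phases."""
    if kappa < 0:
        raise ConfigurationError("kappa must be >= 0")
    if kappa == 0:
        return 0.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_plf(target: float) -> float:
    """Invert A(kappa): the concentration giving population PLF ``target`` in [0, 1)."""
    if not 0 <= target < 1:
        raise ConfigurationError("target PLF must lie in [0, 1)")
    if target == 0:
        return 0.0
    hi = 2.0
    while population_plf(hi) < target:
        hi *= 2.0
        if hi > 1e6:
            raise ConfigurationError(f"target PLF {target} too close to 1")
    return float(brentq(lambda k: population_plf(k) - target, 1e-12, hi, xtol=1e-10))


def pink_band_fraction(exponent: float, duration: float, fs: float,
                       band: tuple[float, float] = (32.0, 80.0)) -> float:
    """Fraction of 1/f^exponent noise power falling inside ``band``.

    Computed on the discrete rfft grid the generator shapes the noise on, so
    it is exact for the synthetic background (up to the sample noise of one
    realization).
    """
    n = int(round(duration * fs))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    w = np.zeros_like(f)
    w[1:] = f[1:] ** (-exponent)
    sel = (f >= band[0]) & (f <= band[1])
    return float(w[sel].sum() / w.sum())


def expected_band_power(pink_scale: float, pink_exponent: float, gamma_scale: float,
                        duration: float, fs: float,
                        band: tuple[float, float] = (32.0, 80.0)) -> float:
    """Expected summed band power (µV²) of the synthetic background in ``band``.

    The band-limited gamma component lies entirely in band; the 1/f component
    contributes its in-band fraction.
    """
    return pink_scale**2 * pink_band_fraction(pink_exponent, duration, fs, band) + gamma_scale**2


def gamma_scale_for_band_power_ratio(pink_scale: float, pink_exponent: float,
                                     gamma_scale_ref: float, ratio: float,
                                     duration: float, fs: float,
                                     band: tuple[float, float] = (32.0, 80.0)) -> float:
    """Gamma RMS making the measured band power ``ratio`` × the reference arm's.

    Accounts for the shared 1/f floor inside the band, so the ratio of
    *measured* band powers — not of generator amplitudes — hits the target.
    """
    pb = pink_scale**2 * pink_band_fraction(pink_exponent, duration, fs, band)
    target = ratio * (pb + gamma_scale_ref**2) - pb
    if target <= 0:
        raise ConfigurationError(
            f"band-power ratio {ratio} unreachable below the 1/f floor")
    return float(np.sqrt(target))


def rayleigh_expected_plf(n: int) -> float:
    """E[PLF] of n uniform phases: sqrt(pi) / (2 sqrt(n)) — the chance floor."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n)))
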