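"""Brick-wall Fourier low-pass smoothing.

High-frequency sensor noise is removed by taking the discrete Fourier
transform of the full record, zeroing every component whose frequency
strictly exceeds the cut-off, and reconstructing by the inverse transform.
The default cut-off of 2.23 Hz corresponds to a period of ~0.45 s; with
stroke periods of 2-4 s this retains the fundamental and at least four
higher harmonics of the stroke waveform, which carry essentially all of the
curve shape, while discarding broadband noise.

The cut is a hard rectangular window applied symmetrically to positive and
negative frequencies (the real-input transform handles the negative half by
conjugate symmetry), with no taper, zero-padding or detrending: components
at exactly the cut-off frequency are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .series import AngularVelocitySeries

#: Default cut-off frequency in Hz.
DEFAULT_F_CUTOFF = 2.23


@dataclass(frozen=True)
class SmoothingConfig:
    """Low-pass configuration; ``f_cutoff_hz`` must lie below Nyquist."""

    f_cutoff_hz: float = DEFAULT_F_CUTOFF

    def __post_init__(self) -> None:
        if not (self.f_cutoff_hz > 0):
            raise ConfigError(f"f_cutoff_hz must be positive, got {self.f_cutoff_hz}")


def lowpass_fourier(
    series: AngularVelocitySeries,
    config: SmoothingConfig | float | None = None,
) -> AngularVelocitySeries:
    """Return a series with all Fourier components above the cut-off zeroed.

    The output has identical length, step and metadata; components at
    frequencies <= f_cutoff are passed through bit-exactly in the spectral
    domain, so the operation is idempotent and linear.
    """
    if config is None:
        config = SmoothingConfig()
    elif not isinstance(config, SmoothingConfig):
        config = SmoothingConfig(f_cutoff_hz=float(config))
    f_cut = config.f_cutoff_hz
    if f_cut >= series.nyquist:
        raise ConfigError(
            f"f_cutoff {f_cut} Hz must be below the Nyquist frequency "
            f"{series.nyquist} Hz of the series"
        )
    n = series.n
    spectrum = np.fft.rfft(series.values)
    freqs = np.fft.rfftfreq(n, series.dt)
    spectrum[freqs > f_cut] = 0.0
    smoothed = np.fft.irfft(spectrum, n=n)
    return series.with_values(smoothed)


def cutoff_period(f_cutoff_hz: float = DEFAULT_F_CUTOFF) -> float:
    """Period (s) corresponding to the cut-off frequency, 1/f."""
    return 1.0 / f_cutoff_hz


def retained_harmonics(stroke_period: float, f_cutoff_hz: float = DEFAULT_F_CUTOFF) -> int:
    """Number of harmonics of a stroke of the given period that survive the
    cut (harmonic m survives iff m/T <= f_cutoff)."""
    return int(math.floor(f_cutoff_hz * stroke_period + 1e-12))
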