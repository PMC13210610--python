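"""Whole-stroke instability index.

The index condenses the point-wise scatter of individual strokes around the
mean stroke profile into one number:

    STD(omega_x)/|omega_x| = (1/<T>) * integral_0^<T> STD(omega_x)(t) / |<omega_x>(t)| dt

i.e. the period-normalized integral of the point-wise standard deviation
divided by the absolute mean curve, reported as a percentage.  Zeros of the
mean curve make the integrand singular, so the grid points where the mean
curve vanishes are excluded: both endpoints of the integration interval
(the mean curve is zero at stroke boundaries by the crossing convention)
plus, for each interior sign change, the two samples bracketing it (for the
generic single interior zero this is the "three excluded points" case).
Each exclusion splits the domain and the trapezoidal rule is applied
piecewise over the remaining contiguous sub-intervals; normalization is by
the full <T>, not by the retained measure.

Values well above 100% are meaningful — they arise when the phase boundary
of an individual stroke is delayed or advanced relative to the mean phase
transition, so the small |<omega_x>| near the transition meets a large
individual deviation — and are deliberately not clipped or regularized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .stroke_stats import MeanStrokeProfile


@dataclass(frozen=True)
class StabilityIndex:
    """Result of the instability integral for one trial."""

    value: float                 # percent
    excluded_points: np.ndarray  # grid times removed from the integration
    mean_period: float           # <T> (s)
    n_strokes: int


def stability_index(
    profile: MeanStrokeProfile,
    exclusion: str = "bracket",
) -> StabilityIndex:
    """Evaluate the instability index on a mean stroke profile.

    Parameters
    ----------
    profile : MeanStrokeProfile
        Mean and SD curves on the [0, <T>] grid (needs n_strokes >= 2).
    exclusion : {"bracket", "nearest"}
        How to remove interior zeros of the mean curve: drop both samples
        bracketing each sign change (default), or only the single sample
        nearest the interpolated zero.

    Raises
    ------
    DataError
        If the profile has fewer than 2 strokes or its mean curve is
        identically zero.
    """
    if profile.n_strokes < 2:
        raise DataError("stability index needs a profile built from >= 2 strokes")
    m = profile.mean_curve
    s = profile.std_curve
    if np.all(m == 0.0):
        raise DataError("degenerate mean profile: mean curve identically zero")
    if exclusion not in ("bracket", "nearest"):
        raise ValueError(f"unknown exclusion mode {exclusion!r}")

    n = m.size
    keep = np.ones(n, dtype=bool)
    keep[0] = keep[-1] = False
    keep[m == 0.0] = False  # exact zeros can never enter the integrand

    changes = np.flatnonzero(m[:-1] * m[1:] < 0)
    if changes.size == 0:
        warnings.warn("mean curve has no interior sign change", stacklevel=2)
    elif changes.size > 1:
        warnings.warn(
            f"mean curve has {changes.size} interior sign changes "
            "(ripple in the mean profile?)",
            stacklevel=2,
        )
    for i in changes:
        if exclusion == "bracket":
            keep[i] = keep[i + 1] = False
        else:
            # sample nearest the interpolated zero
            frac = m[i] / (m[i] - m[i + 1])
            keep[i if frac < 0.5 else i + 1] = False

    integrand = np.zeros(n)
    integrand[keep] = s[keep] / np.abs(m[keep])

    # piecewise trapezoid over contiguous runs of retained samples
    total = 0.0
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size >= 2:
        breaks = np.flatnonzero(np.diff(kept_idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [kept_idx.size - 1]))
        for a, b in zip(run_starts, run_ends):
            if b > a:
                run = kept_idx[a : b + 1]
                total += float(np.trapezoid(integrand[run], dx=profile.dt))

    value = 100.0 * total / profile.mean_period
    return StabilityIndex(
        value=value,
        excluded_points=profile.grid[~keep],
        mean_period=profile.mean_period,
        n_strokes=profile.n_strokes,
    )
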