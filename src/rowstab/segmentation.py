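"""Zero-crossing stroke segmentation of smoothed angular-velocity records.

A stroke boundary is a transition of the (smoothed) angular velocity from
negative to positive between successive samples; the crossing instant is
located by linear interpolation between the bracketing samples, giving
sub-sample precision.  Data before the first and after the last crossing are
incomplete strokes and are discarded.

Within one stroke, phase 1 (the drive) is the total time the signal is
negative and phase 2 (the recovery) the total time it is positive, each
measured between interpolated sign-change points, so the two always sum to
the stroke period.  Because boundaries are negative-to-positive crossings,
the positive (recovery) sub-interval comes first chronologically inside a
segmented stroke; phase labels follow the sign convention, not time order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SegmentationError
from .series import AngularVelocitySeries, SeriesMeta

logger = logging.getLogger(__name__)

#: Strokes shorter than this period (s) — the cut-off period of the 2.23 Hz
#: low-pass — are flagged in the log as suspicious but never deleted.
MIN_STROKE_PERIOD = 0.45


@dataclass(frozen=True)
class Stroke:
    """One complete stroke between two successive upward zero crossings."""

    onset_time: float
    period: float
    phase1_duration: float  # drive: total time with omega_x < 0
    phase2_duration: float  # recovery: total time with omega_x > 0
    sample_slice: tuple[int, int]  # index range into the parent series


@dataclass
class StrokeEnsemble:
    """Ordered, contiguous strokes segmented from one trial record."""

    strokes: list[Stroke]
    dt: float
    source_meta: SeriesMeta = field(default_factory=SeriesMeta)

    def __len__(self) -> int:
        return len(self.strokes)

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([s.onset_time for s in self.strokes])

    @property
    def periods(self) -> np.ndarray:
        return np.array([s.period for s in self.strokes])

    @property
    def phase1_durations(self) -> np.ndarray:
        return np.array([s.phase1_duration for s in self.strokes])

    @property
    def phase2_durations(self) -> np.ndarray:
        return np.array([s.phase2_duration for s in self.strokes])


def find_upcrossings(series: AngularVelocitySeries) -> np.ndarray:
    """Times of all negative-to-positive zero crossings.

    A pair of successive samples (v_i < 0, v_{i+1} > 0) yields a crossing at
    the linearly interpolated zero between them.  Samples that are exactly
    zero terminate the preceding sign run: a zero between a negative and a
    positive sample yields one crossing at the zero sample's time (for a run
    of zeros, at the run's midpoint).  May return an empty array.
    """
    v = series.values
    t0, dt = series.t0, series.dt
    nz = np.flatnonzero(v != 0.0)
    if nz.size < 2:
        return np.empty(0)
    sgn = np.sign(v[nz])
    trans = np.flatnonzero((sgn[:-1] < 0) & (sgn[1:] > 0))
    times = np.empty(trans.size)
    for k, idx in enumerate(trans):
        i, j = nz[idx], nz[idx + 1]
        if j == i + 1:
            times[k] = t0 + dt * (i + v[i] / (v[i] - v[j]))
        else:  # run of exact zeros between the sign change
            times[k] = t0 + dt * 0.5 * ((i + 1) + (j - 1))
    return times


def _interp_at(v: np.ndarray, t0: float, dt: float, t: float) -> float:
    """Linear interpolation of the sample sequence at one time (clamped)."""
    x = (t - t0) / dt
    i = int(np.floor(x))
    if i < 0:
        return float(v[0])
    if i >= v.size - 1:
        return float(v[-1])
    frac = x - i
    return float(v[i] * (1.0 - frac) + v[i + 1] * frac)


def _phase_split(series: AngularVelocitySeries, a: float, b: float) -> tuple[float, float]:
    """Measures of {t in [a,b]: v(t) < 0} and {> 0} for the piecewise-linear
    interpolant of the samples.  Returns (negative, positive) durations."""
    t0, dt, v = series.t0, series.dt, series.values
    eps = 1e-9 * dt
    i0 = int(np.ceil((a - t0) / dt - 1e-9))
    i1 = int(np.floor((b - t0) / dt + 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, v.size - 1)
    inner_t = t0 + dt * np.arange(i0, i1 + 1)
    ts = np.concatenate(([a], inner_t, [b]))
    # interior breakpoints are exact samples; only a and b need interpolation
    ys = np.concatenate((
        [_interp_at(v, t0, dt, a)], v[i0 : i1 + 1], [_interp_at(v, t0, dt, b)]
    ))
    keep = np.concatenate(([True], np.diff(ts) > eps))
    ts = ts[keep]
    ys = ys[keep]
    y0, y1 = ys[:-1], ys[1:]
    seg = np.diff(ts)

    crossing = y0 * y1 < 0
    frac = np.where(crossing, y0 / np.where(crossing, y0 - y1, 1.0), 0.0)
    # same-sign segments (including one zero endpoint): sign of y0 + y1
    s = np.sign(y0 + y1)
    neg = np.sum(seg[~crossing & (s < 0)])
    pos = np.sum(seg[~crossing & (s > 0)])
    # both endpoints exactly zero: a degenerate plateau, split evenly so the
    # phase durations still sum to the period
    plateau = ~crossing & (s == 0)
    neg += 0.5 * np.sum(seg[plateau])
    pos += 0.5 * np.sum(seg[plateau])
    # crossing segments: the part adjacent to y0 carries y0's sign
    first = seg * frac
    neg += np.sum(np.where(crossing & (y0 < 0), first, 0.0))
    pos += np.sum(np.where(crossing & (y0 > 0), first, 0.0))
    second = seg * (1.0 - frac)
    neg += np.sum(np.where(crossing & (y1 < 0), second, 0.0))
    pos += np.sum(np.where(crossing & (y1 > 0), second, 0.0))
    return float(neg), float(pos)


def segment_strokes(
    series: AngularVelocitySeries,
    min_period: float = MIN_STROKE_PERIOD,
) -> StrokeEnsemble:
    """Segment a smoothed series into complete strokes.

    One stroke per consecutive pair of upward zero crossings.  Strokes with a
    period below ``min_period`` are flagged in the log but retained — there
    is no stroke-rejection rule in the pipeline.

    Raises
    ------
    SegmentationError
        If fewer than two crossings are found (no complete stroke).
    """
    crossings = find_upcrossings(series)
    if crossings.size < 2:
        raise SegmentationError(
            f"no complete stroke in {series.meta.label()}: "
            f"{crossings.size} upward zero crossing(s) found"
        )
    strokes = []
    n_short = 0
    for a, b in zip(crossings[:-1], crossings[1:]):
        period = b - a
        neg, pos = _phase_split(series, a, b)
        i_lo = int(np.ceil((a - series.t0) / series.dt - 1e-9))
        i_hi = int(np.ceil((b - series.t0) / series.dt - 1e-9))
        if period < min_period:
            n_short += 1
        strokes.append(
            Stroke(
                onset_time=float(a),
                period=float(period),
                phase1_duration=neg,
                phase2_duration=pos,
                sample_slice=(i_lo, i_hi),
            )
        )
    if n_short:
        logger.warning(
            "%s: %d stroke(s) shorter than %.2f s flagged (retained)",
            series.meta.label(), n_short, min_period,
        )
    return StrokeEnsemble(strokes=strokes, dt=series.dt, source_meta=series.meta)
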