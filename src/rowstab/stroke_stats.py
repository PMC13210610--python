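"""Duration statistics and the ensemble mean stroke profile.

Per-trial summaries are arithmetic means and sample standard deviations
(n-1 denominator) of the stroke period and phase durations over the strokes
of one trial.  Group summaries aggregate the per-participant *means* — not
pooled strokes — so a group n is the number of participants, matching how
the longitudinal tests treat the cohort.

The mean stroke profile realizes "aligned subsets of individual strokes" as
fixed-length windows of duration <T> (the mean period) anchored at each
stroke onset, so every grid point averages over the full ensemble; windows
that would overrun the record are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .segmentation import StrokeEnsemble
from .series import AngularVelocitySeries, SeriesMeta


@dataclass(frozen=True)
class DurationSummary:
    """Mean +/- SD of full-stroke and phase durations (s).

    ``n`` counts strokes for a trial-scope summary and participants for a
    group-scope one.  SDs are ``None`` (undefined, not zero) when n < 2.
    """

    scope: str  # "trial" or "group"
    n: int
    full_mean: float
    full_sd: float | None
    phase1_mean: float
    phase1_sd: float | None
    phase2_mean: float
    phase2_sd: float | None
    meta: SeriesMeta = SeriesMeta()


@dataclass(frozen=True)
class MeanStrokeProfile:
    """Point-wise mean and SD of aligned stroke windows on [0, <T>]."""

    grid: np.ndarray          # time offsets from stroke onset (s)
    mean_curve: np.ndarray    # <omega_x>(t) (rad/s)
    std_curve: np.ndarray     # STD(omega_x)(t) (rad/s)
    mean_period: float        # <T> (s)
    n_strokes: int            # windows actually averaged
    dt: float
    meta: SeriesMeta = SeriesMeta()


def _mean_sd(x: np.ndarray) -> tuple[float, float | None]:
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
    return m, sd


def summarize_durations(ensemble: StrokeEnsemble) -> DurationSummary:
    """Trial-level duration summary over the strokes of one ensemble."""
    if ensemble.n_strokes < 1:
        raise DataError("cannot summarize an empty ensemble")
    fm, fs = _mean_sd(ensemble.periods)
    p1m, p1s = _mean_sd(ensemble.phase1_durations)
    p2m, p2s = _mean_sd(ensemble.phase2_durations)
    return DurationSummary(
        scope="trial", n=ensemble.n_strokes,
        full_mean=fm, full_sd=fs,
        phase1_mean=p1m, phase1_sd=p1s,
        phase2_mean=p2m, phase2_sd=p2s,
        meta=ensemble.source_meta,
    )


def group_summary(per_trial: list[DurationSummary]) -> DurationSummary:
    """Group-level summary: mean and SD over the participants' per-trial
    means (n = number of participants).  All inputs must share one stage and
    grade."""
    if len(per_trial) < 2:
        raise DataError("group summary needs at least 2 participants")
    stages = {s.meta.stage for s in per_trial}
    grades = {s.meta.grade for s in per_trial}
    if len(stages) > 1 or len(grades) > 1:
        raise DataError(
            f"mixed stages {stages} / grades {grades} in group summary input"
        )
    full = np.array([s.full_mean for s in per_trial])
    p1 = np.array([s.phase1_mean for s in per_trial])
    p2 = np.array([s.phase2_mean for s in per_trial])
    fm, fs = _mean_sd(full)
    p1m, p1s = _mean_sd(p1)
    p2m, p2s = _mean_sd(p2)
    meta = SeriesMeta(stage=stages.pop(), grade=grades.pop())
    return DurationSummary(
        scope="group", n=len(per_trial),
        full_mean=fm, full_sd=fs,
        phase1_mean=p1m, phase1_sd=p1s,
        phase2_mean=p2m, phase2_sd=p2s,
        meta=meta,
    )


def summaries_to_frame(summaries: list[DurationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "participant": s.meta.participant,
            "stage": s.meta.stage,
            "grade": s.meta.grade,
            "scope": s.scope,
            "n": s.n,
            "full_mean": s.full_mean, "full_sd": s.full_sd,
            "phase1_mean": s.phase1_mean, "phase1_sd": s.phase1_sd,
            "phase2_mean": s.phase2_mean, "phase2_sd": s.phase2_sd,
        })
    return pd.DataFrame(rows)


def mean_profile(
    series: AngularVelocitySeries,
    ensemble: StrokeEnsemble,
) -> MeanStrokeProfile:
    """Ensemble mean curve <omega_x>(t) and point-wise sample SD.

    For each stroke onset a window of round(<T>/dt)+1 samples starting at the
    (fractional) onset time is extracted by linear interpolation of the
    parent series; the profile is the point-wise mean and SD across windows.

    Raises
    ------
    DataError
        If fewer than 2 windows fit inside the record.
    """
    if ensemble.n_strokes < 2:
        raise DataError("mean profile needs at least 2 strokes")
    dt = series.dt
    t_bar = float(np.mean(ensemble.periods))
    n_grid = int(round(t_bar / dt)) + 1
    offsets = dt * np.arange(n_grid)
    t_end = series.t_end
    time = series.time
    windows = []
    for onset in ensemble.onsets:
        if onset + offsets[-1] > t_end + 1e-9 * dt:
            continue  # window would overrun the record
        windows.append(np.interp(onset + offsets, time, series.values))
    if len(windows) < 2:
        raise DataError("fewer than 2 stroke windows fit inside the record")
    stack = np.vstack(windows)
    return MeanStrokeProfile(
        grid=offsets,
        mean_curve=stack.mean(axis=0),
        std_curve=stack.std(axis=0, ddof=1),
        mean_period=t_bar,
        n_strokes=stack.shape[0],
        dt=dt,
        meta=ensemble.source_meta,
    )
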