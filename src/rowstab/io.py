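"""Reading phyphox-style gyroscope exports and writing pipeline tables.

Sensor apps export delimited text with a header row, one time column and one
column per gyroscope axis.  Only the time and x-axis columns are consumed;
other columns are ignored.  Comma, semicolon and tab delimiters are
auto-detected from the header row.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .series import AngularVelocitySeries, SeriesMeta

#: Default column labels of a phyphox gyroscope export.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "time": "Time (s)",
    "omega_x": "Gyroscope x (rad/s)",
}

_DELIMITERS = (",", ";", "\t")

#: Relative deviation of timestamp steps from their median above which the
#: record is considered non-uniform and is resampled by linear interpolation.
UNIFORMITY_TOLERANCE = 0.10


def _sniff_delimiter(header: str) -> str:
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def read_gyro_export(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    resample_dt: float | None = None,
    meta: SeriesMeta | None = None,
) -> AngularVelocitySeries:
    """Read a delimited gyroscope export into an :class:`AngularVelocitySeries`.

    Timestamps must be strictly increasing.  If their steps deviate from the
    median step by more than 10%, the values are linearly interpolated onto a
    uniform grid of step ``resample_dt`` (default: the median source step);
    otherwise the samples pass through unchanged with dt set to the median
    step.

    Raises
    ------
    FormatError
        If a mapped column is absent.
    DataError
        If time is non-increasing or fewer than 2 rows are present.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    with open(path, "r", encoding="utf-8-sig") as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    frame = pd.read_csv(path, sep=sep, encoding="utf-8-sig")

    for role in ("time", "omega_x"):
        if cmap[role] not in frame.columns:
            raise FormatError(
                f"column {cmap[role]!r} (role {role!r}) not found in {path}; "
                f"available: {list(frame.columns)}"
            )
    t = frame[cmap["time"]].to_numpy(dtype=float)
    v = frame[cmap["omega_x"]].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: fewer than 2 data rows")
    steps = np.diff(t)
    bad = np.flatnonzero(steps <= 0)
    if bad.size:
        raise DataError(f"{path}: time not strictly increasing at row {bad[0] + 1}")

    med = float(np.median(steps))
    if np.max(np.abs(steps - med)) > UNIFORMITY_TOLERANCE * med:
        dt = float(resample_dt) if resample_dt is not None else med
        n = int(round((t[-1] - t[0]) / dt)) + 1
        grid = t[0] + dt * np.arange(n)
        # keep the grid inside the observed span (no extrapolation)
        grid = grid[grid <= t[-1] + 1e-12 * max(1.0, abs(t[-1]))]
        v = np.interp(grid, t, v)
        t0 = float(t[0])
    else:
        dt = med
        t0 = float(t[0])

    if meta is None:
        meta = SeriesMeta(source=str(path))
    return AngularVelocitySeries(values=v, dt=dt, t0=t0, meta=meta)


def write_series(
    series: AngularVelocitySeries,
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> None:
    """Write a series as delimited text that round-trips through
    :func:`read_gyro_export` (values to 9 significant digits)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    frame = pd.DataFrame({cmap["time"]: series.time, cmap["omega_x"]: series.values})
    frame.to_csv(path, sep=sep, index=False, float_format="%.9g")


def write_table(table: pd.DataFrame, path: str | os.PathLike, sep: str = ",") -> None:
    """Write a pipeline artifact table as delimited text with a header.

    Refuses to write an empty table (nothing is created on error).
    """
    if not isinstance(table, pd.DataFrame):
        raise DataError(f"expected a DataFrame artifact, got {type(table).__name__}")
    if table.empty:
        raise DataError("refusing to write an empty table")
    table.to_csv(path, sep=sep, index=False, float_format="%.9g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8-sig") as fh:
        header = fh.readline()
    return pd.read_csv(path, sep=_sniff_delimiter(header), encoding="utf-8-sig")
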