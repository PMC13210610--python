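"""Exact small-sample rank tests and the longitudinal significance matrix.

With seven participants per stage, normal approximations to the rank-sum and
signed-rank null distributions can flip borderline significance calls, so
both tests are computed from their *exact* permutation null distributions:

* rank-sum — all C(n1+n2, n1) equally likely assignments of the combined
  mid-ranks to the first sample;
* signed-rank — all 2^m equally likely sign patterns on the m non-zero
  differences (zeros dropped before ranking).

Ties are handled with mid-ranks; because mid-ranks are multiples of 1/2,
doubling them gives integer weights and the null distribution of the
statistic is built by an exact integer dynamic program (no enumeration
needed, and counts stay exact in 64-bit integers for the sample sizes
supported).  Two-sided p-values are twice the smaller tail probability,
capped at 1.

The significance matrix mirrors the longitudinal design: for every stage
pair and power grade, both tests are applied to the participants' mean
durations and to their duration SDs, for the full stroke and each phase.
No multiple-testing correction is applied (mirrored from the study design);
output metadata flags this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError

#: Largest combined sample size for which exact distributions are computed.
MAX_EXACT_N = 40

QUANTITIES = ("full", "phase1", "phase2")
METRICS = ("mean", "sd")


@dataclass(frozen=True)
class PairedSample:
    """Within-participant values at two stages, aligned by participant."""

    labels: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.size != b.size or a.size != len(self.labels):
            raise DataError("paired sample arrays must have equal length")
        if a.size < 2:
            raise DataError("paired sample needs at least 2 entries")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise DataError("paired sample contains non-finite values")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.b - self.a


def _int_weights(ranks: np.ndarray) -> tuple[int, ...]:
    """Mid-ranks doubled to exact integers."""
    w = np.rint(2.0 * ranks).astype(np.int64)
    if not np.allclose(2.0 * ranks, w, atol=1e-9):
        raise AssertionError("mid-ranks are not multiples of 1/2")
    return tuple(int(x) for x in w)


@lru_cache(maxsize=256)
def _ranksum_null(weights: tuple[int, ...], n1: int) -> np.ndarray:
    """Counts of subsets of size n1 by weight sum.

    ``counts[w]`` = number of n1-subsets of ``weights`` with sum w; the total
    is C(len(weights), n1).
    """
    total = sum(weights)
    counts = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    counts[0, 0] = 1
    for w in weights:
        for k in range(n1, 0, -1):
            counts[k, w:] += counts[k - 1, : total + 1 - w]
    return counts[n1]


@lru_cache(maxsize=256)
def _signed_rank_null(weights: tuple[int, ...]) -> np.ndarray:
    """Counts of subsets (any size) of ``weights`` by weight sum; total 2^m."""
    total = sum(weights)
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for w in weights:
        counts[w:] = counts[w:] + counts[: total + 1 - w]
    return counts


def _two_sided_p(counts: np.ndarray, stat: int) -> float:
    total = counts.sum()
    lo = counts[: stat + 1].sum()
    hi = counts[stat:].sum()
    return float(min(1.0, 2.0 * min(lo, hi) / total))


def ranksum_exact(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided rank-sum (Wilcoxon/Mann-Whitney) p-value.

    Mid-ranks for ties; exact permutation null for combined n <= 40.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("rank-sum test needs at least 2 values per sample")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError("rank-sum input contains non-finite values")
    n1, n2 = a.size, b.size
    if n1 + n2 > MAX_EXACT_N:
        raise DataError(
            f"combined sample size {n1 + n2} exceeds the exact-test limit "
            f"{MAX_EXACT_N}"
        )
    ranks = rankdata(np.concatenate([a, b]))
    weights = _int_weights(ranks)
    stat = int(round(2.0 * ranks[:n1].sum()))
    counts = _ranksum_null(weights, n1)
    return _two_sided_p(counts, stat)


def signed_rank_exact(
    paired: PairedSample | Sequence[float],
    b: Sequence[float] | None = None,
) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value for paired data.

    Accepts a :class:`PairedSample`, two aligned sequences, or (with ``b``
    omitted) a sequence of differences.  Zero differences are dropped before
    ranking; if all differences are zero the p-value is 1.0 with a warning.
    """
    if isinstance(paired, PairedSample):
        d = paired.differences
    elif b is not None:
        a = np.asarray(paired, dtype=float)
        bb = np.asarray(b, dtype=float)
        if a.size != bb.size:
            raise DataError("paired arrays must have equal length")
        d = bb - a
    else:
        d = np.asarray(paired, dtype=float)
    if d.size < 2:
        raise DataError("signed-rank test needs at least 2 pairs")
    if not np.all(np.isfinite(d)):
        raise DataError("signed-rank input contains non-finite values")
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 1.0
    if d.size > 30:
        raise DataError(
            f"{d.size} non-zero differences exceed the exact-test limit 30"
        )
    ranks = rankdata(np.abs(d))
    weights = _int_weights(ranks)
    stat = int(round(2.0 * ranks[d > 0].sum()))
    counts = _signed_rank_null(weights)
    return _two_sided_p(counts, stat)


@dataclass
class TestMatrix:
    """Per (stage pair x grade x quantity) significance calls with exact p.

    ``frame`` is long-format with one row per (test, stage pair, grade,
    quantity) and columns ``p_duration`` / ``p_sd`` (raw exact p-values for
    the participants' mean durations and duration SDs) plus the 0/1
    indicators at ``alpha``.
    """

    frame: pd.DataFrame
    alpha: float = 0.05
    stages: tuple = ()
    multiple_testing_correction: str = "none"
    notes: dict = field(default_factory=dict)

    def grid(self, test: str) -> pd.DataFrame:
        """Table-shaped view: rows (stage pair, grade), columns full stroke /
        phase 1 / phase 2 with 'duration/sd' 0-1 entries."""
        sub = self.frame[self.frame["test"] == test]
        if sub.empty:
            raise KeyError(f"no rows for test {test!r}")
        rows = []
        for (sa, sb, g), cells in sub.groupby(
            ["stage_a", "stage_b", "grade"], sort=False
        ):
            row = {"stage_pair": f"{sa}->{sb}", "grade": g}
            for q in QUANTITIES:
                c = cells[cells["quantity"] == q].iloc[0]
                row[q] = f"{c['significant_duration']}/{c['significant_sd']}"
            rows.append(row)
        return pd.DataFrame(rows)

    def significance_counts(
        self, test: str, sequential_only: bool = True
    ) -> dict[str, int]:
        """Counts of significant phase-duration and phase-SD cells.

        With ``sequential_only`` the universe is the two consecutive stage
        pairs x grades x the two phases (12 cells for a 3-stage, 3-grade
        design); the long-span first-to-last pair is excluded.
        """
        sub = self.frame[
            (self.frame["test"] == test)
            & (self.frame["quantity"].isin(["phase1", "phase2"]))
        ]
        if sequential_only and len(self.stages) > 2:
            seq = {
                (self.stages[i], self.stages[i + 1])
                for i in range(len(self.stages) - 1)
            }
            sub = sub[
                [(r.stage_a, r.stage_b) in seq for r in sub.itertuples()]
            ]
        return {
            "cells": len(sub),
            "duration_significant": int(sub["significant_duration"].sum()),
            "sd_significant": int(sub["significant_sd"].sum()),
        }


def build_test_matrix(
    per_participant: pd.DataFrame,
    stages: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TestMatrix:
    """Build the longitudinal significance matrix from per-trial summaries.

    Parameters
    ----------
    per_participant : DataFrame
        One row per (participant, stage, grade) with columns
        ``full_mean, full_sd, phase1_mean, phase1_sd, phase2_mean,
        phase2_sd`` (the per-trial :class:`~rowstab.stroke_stats.DurationSummary`
        fields).  Every cell of the participant x stage x grade cube must be
        present.
    stages : ordered stage labels
        Defaults to order of first appearance.  Stage pairs tested are the
        consecutive pairs plus (first, last) when there are more than two
        stages.
    alpha : float
        Significance level for the 0/1 indicators.
    """
    required = {"participant", "stage", "grade",
                "full_mean", "full_sd", "phase1_mean", "phase1_sd",
                "phase2_mean", "phase2_sd"}
    missing_cols = required - set(per_participant.columns)
    if missing_cols:
        raise DataError(f"per-participant table lacks columns {sorted(missing_cols)}")
    if stages is None:
        stages = tuple(dict.fromkeys(per_participant["stage"]))
    else:
        stages = tuple(stages)
    grades = tuple(sorted(per_participant["grade"].unique()))
    participants = tuple(sorted(per_participant["participant"].unique()))

    indexed = per_participant.set_index(["participant", "stage", "grade"])
    missing = [
        (p, s, g)
        for p in participants for s in stages for g in grades
        if (p, s, g) not in indexed.index
    ]
    if missing:
        raise DataError(f"missing manifest cells: {missing}")

    pairs = [(stages[i], stages[i + 1]) for i in range(len(stages) - 1)]
    if len(stages) > 2:
        pairs.append((stages[0], stages[-1]))

    rows = []
    for sa, sb in pairs:
        for g in grades:
            for q in QUANTITIES:
                cells = {}
                for metric in METRICS:
                    col = f"{q}_{metric}"
                    va = np.array([indexed.loc[(p, sa, g), col] for p in participants])
                    vb = np.array([indexed.loc[(p, sb, g), col] for p in participants])
                    p_rs = ranksum_exact(va, vb)
                    p_sr = signed_rank_exact(
                        PairedSample(labels=participants, a=va, b=vb)
                    )
                    cells[metric] = {"ranksum": p_rs, "signed_rank": p_sr}
                for test in ("ranksum", "signed_rank"):
                    p_dur = cells["mean"][test]
                    p_sd = cells["sd"][test]
                    rows.append({
                        "test": test, "stage_a": sa, "stage_b": sb,
                        "grade": g, "quantity": q,
                        "p_duration": p_dur,
                        "significant_duration": int(p_dur < alpha),
                        "p_sd": p_sd,
                        "significant_sd": int(p_sd < alpha),
                    })
    frame = pd.DataFrame(rows)
    return TestMatrix(
        frame=frame, alpha=alpha, stages=stages,
        notes={"n_participants": len(participants), "grades": grades},
    )
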