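import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata, wilcoxon

from rowstab import (
    DataError,
    PairedSample,
    build_test_matrix,
    ranksum_exact,
    signed_rank_exact,
)


def ranksum_enumeration_oracle(a, b):
    """Brute force: enumerate all C(n1+n2, n1) group assignments of the
    combined mid-ranks; two-sided p = 2 * min tail of the rank-sum."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1 = a.size
    ranks = rankdata(np.concatenate([a, b]))
    observed = ranks[:n1].sum()
    sums = np.array([
        sum(ranks[list(c)]) for c in itertools.combinations(range(ranks.size), n1)
    ])
    total = sums.size
    lo = np.sum(sums <= observed + 1e-9)
    hi = np.sum(sums >= observed - 1e-9)
    return min(1.0, 2.0 * min(lo, hi) / total)


def signed_rank_enumeration_oracle(diffs):
    """Brute force: enumerate all 2^m sign patterns on the non-zero
    differences; two-sided p = 2 * min tail of W+."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    m = d.size
    sums = np.array([
        sum(ranks[i] for i in range(m) if pattern & (1 << i))
        for pattern in range(2**m)
    ])
    lo = np.sum(sums <= observed + 1e-9)
    hi = np.sum(sums >= observed - 1e-9)
    return min(1.0, 2.0 * min(lo, hi) / 2**m)


def test_complete_separation_ranksum():
    p = ranksum_exact(np.arange(1, 8), np.arange(8, 15))
    assert p == pytest.approx(2 / 3432, rel=1e-12)


def test_identical_samples_ranksum_p_one():
    assert ranksum_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0


def test_tied_ranksum_matches_enumeration():
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    assert ranksum_exact(a, b) == pytest.approx(
        ranksum_enumeration_oracle(a, b), rel=1e-12
    )


def test_all_positive_signed_rank():
    # 7 positive differences, distinct magnitudes: p = 2/2^7
    p = signed_rank_exact(np.arange(1.0, 8.0))
    assert p == pytest.approx(2 / 128, rel=1e-12)


def test_symmetric_differences_p_one():
    p = signed_rank_exact(np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 0.0]))
    assert p == 1.0


def test_mixed_signs_signed_rank_matches_enumeration():
    d = np.array([0.5, 0.9, 1.3, 2.0, 2.5, -0.1, -0.2])
    assert signed_rank_exact(d) == pytest.approx(
        signed_rank_enumeration_oracle(d), rel=1e-12
    )


def test_ranksum_agrees_with_enumeration_on_random_instances():
    rng = np.random.default_rng(101)
    for _ in range(50):
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 5))
        if rng.random() < 0.5:  # force ties half the time
            a = rng.integers(0, 4, size=n1).astype(float)
            b = rng.integers(0, 4, size=n2).astype(float)
        else:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
        assert ranksum_exact(a, b) == pytest.approx(
            ranksum_enumeration_oracle(a, b), rel=1e-12
        ), (a, b)


def test_signed_rank_agrees_with_enumeration_on_random_instances():
    rng = np.random.default_rng(102)
    for _ in range(50):
        m = int(rng.integers(2, 9))
        if rng.random() < 0.5:
            d = rng.integers(-3, 4, size=m).astype(float)
            if np.all(d == 0):
                d[0] = 1.0
        else:
            d = rng.normal(size=m)
        assert signed_rank_exact(d) == pytest.approx(
            signed_rank_enumeration_oracle(d), rel=1e-12
        ), d


def test_tie_free_cases_cross_checked_against_scipy():
    rng = np.random.default_rng(103)
    for _ in range(20):
        a = rng.normal(size=7)
        b = rng.normal(size=7)
        assert ranksum_exact(a, b) == pytest.approx(
            mannwhitneyu(a, b, method="exact").pvalue, rel=1e-9
        )
        assert signed_rank_exact(b - a) == pytest.approx(
            wilcoxon(b - a, mode="exact").pvalue, rel=1e-9
        )


def test_monotone_transform_invariance():
    rng = np.random.default_rng(104)
    a = rng.normal(size=7)
    b = rng.normal(size=7) + 0.5
    assert ranksum_exact(np.exp(a), np.exp(b)) == pytest.approx(
        ranksum_exact(a, b), rel=1e-12
    )


def test_swap_symmetry_and_range():
    rng = np.random.default_rng(105)
    for _ in range(10):
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        p = ranksum_exact(a, b)
        assert 0.0 < p <= 1.0
        assert ranksum_exact(b, a) == pytest.approx(p, rel=1e-12)


def test_all_zero_differences_warn_p_one():
    with pytest.warns(UserWarning, match="zero"):
        assert signed_rank_exact(np.zeros(5)) == 1.0


def test_input_validation():
    with pytest.raises(DataError):
        ranksum_exact([1.0], [1.0, 2.0])
    with pytest.raises(DataError):
        signed_rank_exact([1.0])
    with pytest.raises(DataError):
        PairedSample(labels=("a", "b"), a=[1.0, 2.0], b=[1.0])


def make_cohort_frame(rng, effect=(0.0, 0.0), stages=("March", "April"),
                      sd=0.05, n=7):
    rows = []
    subj = rng.normal(0, sd, size=(n, 2))
    for i in range(n):
        for k, stage in enumerate(stages):
            s1, s2 = (0.0, 0.0) if k == 0 else effect
            for g in (1,):
                p1 = 2.1 + subj[i, 0] + s1 + rng.normal(0, 0.01)
                p2 = 1.2 + subj[i, 1] + s2 + rng.normal(0, 0.01)
                rows.append({
                    "participant": f"P{i}", "stage": stage, "grade": g,
                    "full_mean": p1 + p2, "full_sd": 0.1 + rng.normal(0, 0.005),
                    "phase1_mean": p1, "phase1_sd": 0.1 + rng.normal(0, 0.005),
                    "phase2_mean": p2, "phase2_sd": 0.1 + rng.normal(0, 0.005),
                })
    return pd.DataFrame(rows)


def test_matrix_phase_shift_detected_full_stroke_constant():
    rng = np.random.default_rng(106)
    frame = make_cohort_frame(rng, effect=(0.3, -0.3))
    tm = build_test_matrix(frame, stages=("March", "April"))
    f = tm.frame
    full = f[f["quantity"] == "full"]
    phases = f[f["quantity"].isin(["phase1", "phase2"])]
    assert full["significant_duration"].sum() == 0
    assert phases["significant_duration"].sum() >= 3


def test_matrix_identical_stages_all_null():
    rng = np.random.default_rng(107)
    frame = make_cohort_frame(rng, effect=(0.0, 0.0))
    # make the two stages bit-identical
    a = frame[frame["stage"] == "March"].copy()
    b = a.copy()
    b["stage"] = "April"
    frame = pd.concat([a, b], ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tm = build_test_matrix(frame, stages=("March", "April"))
    assert (tm.frame["p_duration"] == 1.0).all()
    assert (tm.frame["p_sd"] == 1.0).all()
    assert tm.frame["significant_duration"].sum() == 0


def test_matrix_missing_cells_listed():
    rng = np.random.default_rng(108)
    frame = make_cohort_frame(rng).iloc[:-1]
    with pytest.raises(DataError, match="missing"):
        build_test_matrix(frame, stages=("March", "April"))


def test_matrix_shape_and_counts_for_three_stage_design():
    rng = np.random.default_rng(109)
    rows = []
    for i in range(7):
        for stage in ("March", "April", "June"):
            for g in (1, 2, 3):
                rows.append({
                    "participant": f"P{i}", "stage": stage, "grade": g,
                    "full_mean": rng.normal(3.3, 0.1),
                    "full_sd": abs(rng.normal(0.1, 0.01)),
                    "phase1_mean": rng.normal(2.1, 0.1),
                    "phase1_sd": abs(rng.normal(0.1, 0.01)),
                    "phase2_mean": rng.normal(1.2, 0.1),
                    "phase2_sd": abs(rng.normal(0.1, 0.01)),
                })
    tm = build_test_matrix(pd.DataFrame(rows), stages=("March", "April", "June"))
    # 3 stage pairs x 3 grades x 3 quantities per test
    for test in ("ranksum", "signed_rank"):
        grid = tm.grid(test)
        assert grid.shape == (9, 5)  # stage_pair, grade + 3 quantity columns
        counts = tm.significance_counts(test, sequential_only=True)
        assert counts["cells"] == 12
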