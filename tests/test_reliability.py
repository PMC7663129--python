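"""ICC machinery, Spearman-Brown prophecy, CV/SEM/MDC and the report."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from copmat.reference_values import load_reference_table
from copmat.reliability import (
    cv_within,
    icc_2_1,
    icc_2_k,
    mdc,
    reliability_report,
    required_k,
    sample_size_icc,
    sem,
    spearman_brown,
    two_way_anova,
)
from copmat.synthetic import generate_parameter_matrix

WORKED = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


def brute_force_mean_squares(m):
    """Independent sums-of-squares oracle written as explicit loops."""
    n, k = m.shape
    grand = sum(m[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(m[i]) / k for i in range(n)]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((m[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def test_worked_matrix_mean_squares_and_iccs():
    a = two_way_anova(WORKED)
    assert a.msr == pytest.approx(8.0)
    assert a.msc == pytest.approx(1.5)
    assert a.mse == pytest.approx(0.0, abs=1e-12)
    est, _ = icc_2_1(a.msr, a.msc, a.mse, a.n, a.k)
    assert est == pytest.approx(8.0 / 9.0, abs=1e-12)
    assert icc_2_k(a.msr, a.msc, a.mse, a.n) == pytest.approx(16.0 / 17.0, abs=1e-12)


def test_constant_matrix_reports_missing_f():
    a = two_way_anova(np.full((4, 3), 2.5))
    assert a.msr == a.msc == a.mse == 0.0
    assert math.isnan(a.f_columns) and math.isnan(a.p_columns)


def test_anova_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        m = rng.normal(5, 2, size=(10, 7)) + rng.normal(0, 1, size=(10, 1))
        a = two_way_anova(m)
        msr, msc, mse = brute_force_mean_squares(m)
        assert a.msr == pytest.approx(msr, abs=1e-10)
        assert a.msc == pytest.approx(msc, abs=1e-10)
        assert a.mse == pytest.approx(mse, abs=1e-10)
        # decomposition SST = SSR + SSC + SSE is implicit in the oracle


def test_icc_and_ci_match_pingouin():
    rng = np.random.default_rng(7)
    m = rng.normal(10, 2, size=(12, 5)) + rng.normal(0, 1.5, size=(12, 1))
    a = two_way_anova(m)
    est, (lo, hi) = icc_2_1(a.msr, a.msc, a.mse, a.n, a.k)
    kest = icc_2_k(a.msr, a.msc, a.mse, a.n)
    df = pd.DataFrame(
        {
            "s": np.repeat(range(12), 5),
            "r": list(range(5)) * 12,
            "v": m.ravel(),
        }
    )
    ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="v").set_index("Type")
    assert est == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
    assert kest == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-9)
    ref_lo, ref_hi = ref.loc["ICC(A,1)", "CI95"]
    assert lo == pytest.approx(ref_lo, abs=5e-3)  # pingouin rounds its CI
    assert hi == pytest.approx(ref_hi, abs=5e-3)
    assert a.f_rows == pytest.approx(ref.loc["ICC(A,1)", "F"], abs=1e-9)


def test_icc2k_is_spearman_brown_of_icc21():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n, k = rng.integers(3, 15), rng.integers(2, 9)
        m = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
        a = two_way_anova(m)
        est, _ = icc_2_1(a.msr, a.msc, a.mse, a.n, a.k)
        if est <= 0:
            continue
        assert icc_2_k(a.msr, a.msc, a.mse, a.n) == pytest.approx(
            spearman_brown(est, k), abs=1e-12
        )


def test_perfect_agreement_matrix():
    m = np.tile(np.arange(5.0).reshape(-1, 1), (1, 4))
    a = two_way_anova(m)
    est, (lo, hi) = icc_2_1(a.msr, a.msc, a.mse, a.n, a.k)
    assert est == 1.0 and lo == 1.0 and hi == 1.0
    assert icc_2_k(a.msr, a.msc, a.mse, a.n) == 1.0


# ----------------------------------------------------------------------
# prophecy and required footfalls


@pytest.mark.parametrize(
    "r,k,expected_2dp",
    [(0.79, 7, 0.96), (0.87, 7, 0.98), (0.46, 7, 0.86), (0.55, 7, 0.90)],
)
def test_spearman_brown_reproduces_reported_pairs(r, k, expected_2dp):
    assert round(spearman_brown(r, k), 2) == expected_2dp


def test_spearman_brown_edge_cases():
    assert spearman_brown(0.4, 1) == pytest.approx(0.4)
    assert spearman_brown(1.0, 5) == 1.0
    with pytest.raises(ValueError):
        spearman_brown(-0.1, 5)
    # strictly increasing in both arguments
    assert spearman_brown(0.5, 3) < spearman_brown(0.6, 3) < spearman_brown(0.6, 4)


@pytest.mark.parametrize(
    "r,target,expected",
    [(0.13, 0.50, 7), (0.50, 0.50, 1), (0.20, 0.90, 36)],
)
def test_required_k(r, target, expected):
    assert required_k(r, target) == expected


def test_required_k_closed_form_consistency():
    assert spearman_brown(0.20, 36) == pytest.approx(0.90, abs=1e-12)
    k = required_k(0.33, 0.7)
    assert spearman_brown(0.33, k) >= 0.7
    assert spearman_brown(0.33, k - 1) < 0.7
    with pytest.raises(ValueError):
        required_k(0.0, 0.5)


def test_required_footfalls_from_reference_table_is_seven():
    ref = load_reference_table()
    ks = [required_k(r, 0.50) for r in ref["icc21"]]
    assert max(ks) == 7


# ----------------------------------------------------------------------
# absolute reliability


def test_cv_within_examples():
    assert cv_within(np.array([[10.0, 10.0, 10.0], [2.0, 4.0, 3.0]])) > 0
    assert cv_within(np.array([[10.0, 10.0, 10.0]])) == 0.0
    assert cv_within(np.array([[2.0, 4.0]])) == pytest.approx(100 * math.sqrt(2) / 3)
    assert math.isnan(cv_within(np.array([[1.0, -1.0], [2.0, 3.0]])))  # zero mean
    pooled = cv_within(np.array([[2.0, 4.0], [9.0, 11.0]]), mode="pooled")
    assert pooled == pytest.approx(100 * math.sqrt(2) / 6.5)


def test_sem_and_mdc():
    assert sem(10.0, 0.75) == pytest.approx(5.0)
    assert sem(10.0, 1.0) == 0.0
    assert sem(10.0, 0.0) == 10.0
    assert mdc(3.84) == pytest.approx(8.91, abs=5e-3)
    assert mdc(1.64) == pytest.approx(3.80, abs=5e-3)
    assert mdc(0.0) == 0.0
    # the MDC/SEM ratio is the constant sqrt(2) * 1.64
    assert mdc(7.31) / 7.31 == pytest.approx(math.sqrt(2) * 1.64)
    with pytest.raises(ValueError):
        sem(10.0, 1.2)


def test_sample_size_near_design_point():
    n = sample_size_icc(0.5, 0.6, alpha_one_tailed=0.05, power=0.80, k=16)
    assert 89 <= n <= 92
    # monotone: easier alternatives need fewer subjects
    assert sample_size_icc(0.5, 0.7, k=16) < n
    assert sample_size_icc(0.5, 0.6, k=8) > 0
    with pytest.raises(ValueError):
        sample_size_icc(0.6, 0.5)


# ----------------------------------------------------------------------
# estimator calibration on known variance components


def test_icc_estimator_bias_small_at_design_point():
    est = []
    for rep in range(300):
        m, true_icc = generate_parameter_matrix(
            90, 7, mu=50.0, sigma_between=math.sqrt(0.6),
            sigma_within=math.sqrt(0.4), seed=20_000 + rep,
        )
        a = two_way_anova(m)
        est.append(icc_2_1(a.msr, a.msc, a.mse, a.n, a.k)[0])
    assert true_icc == pytest.approx(0.6)
    assert abs(np.mean(est) - 0.6) < 0.02


def test_icc_ci_coverage_at_design_point():
    hits = 0
    reps = 200
    for rep in range(reps):
        m, _ = generate_parameter_matrix(
            90, 7, mu=0.0, sigma_between=math.sqrt(0.6),
            sigma_within=math.sqrt(0.4), seed=50_000 + rep,
        )
        a = two_way_anova(m)
        _, (lo, hi) = icc_2_1(a.msr, a.msc, a.mse, a.n, a.k)
        if lo <= 0.6 <= hi:
            hits += 1
    assert hits / reps >= 0.93


# ----------------------------------------------------------------------
# report assembly


def _cohort_params(values_fn, n=6, k=7):
    rows = []
    for s in range(n):
        for side in ("left", "right"):
            for j in range(k):
                rows.append(
                    {
                        "subject": f"S{s}",
                        "condition": "comfortable",
                        "side": side,
                        "footfall": j + 1,
                        "stance_ms": values_fn(s, j, side),
                        "ICP_mlocML_pct": values_fn(s, j, side) / 100.0,
                    }
                )
    return pd.DataFrame(rows)


def test_report_on_perfect_replication():
    df = _cohort_params(lambda s, j, side: 600.0 + 10 * s)
    rep = reliability_report(df, ["stance_ms"], dominant="right", k=7)
    row = rep.iloc[0]
    assert row["icc21"] == 1.0 and row["icc2k"] == 1.0
    assert row["sem"] == 0.0 and row["mdc"] == 0.0
    assert row["cv_dom"] == 0.0 and row["cv_nondom"] == 0.0
    assert row["required_k"] == 1


def test_report_structure_and_mloc_cv_policy():
    rng = np.random.default_rng(0)
    df = _cohort_params(lambda s, j, side: 600.0 + 10 * s + rng.normal(0, 5))
    rep = reliability_report(df, dominant="right", k=7)
    assert set(rep["parameter"]) == {"stance_ms", "mlocML_pct"}
    mloc = rep[rep["parameter"] == "mlocML_pct"].iloc[0]
    assert math.isnan(mloc["cv_dom"]) and math.isnan(mloc["cv_nondom"])
    stance = rep[rep["parameter"] == "stance_ms"].iloc[0]
    assert stance["subphase"] == ""
    assert mloc["subphase"] == "ICP"
    assert np.isfinite(stance["cv_dom"]) and np.isfinite(stance["cv_nondom"])
    assert stance["n"] == 6


def test_report_insufficient_data_marked():
    df = _cohort_params(lambda s, j, side: 1.0, n=1)
    rep = reliability_report(df, ["stance_ms"], dominant="right", k=7)
    assert rep.iloc[0]["reason"] == "insufficient data"
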