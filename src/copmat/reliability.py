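"""Relative and absolute intra-session reliability of repeated footfalls.

The measurement design is subjects x footfalls: each subject contributes k
repeated footfalls of the same parameter.  Relative reliability uses the
two-way random-effects, absolute-agreement intraclass correlations

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

with MSR/MSC/MSE the between-subject, between-footfall and residual mean
squares of the unreplicated two-way ANOVA.  ICC(2,k) is algebraically the
Spearman-Brown prophecy of ICC(2,1):  R_k = k R / (1 + (k-1) R), whose
inversion k = R_k (1-R) / (R (1-R_k)) gives the number of footfalls needed
to reach a target reliability.

Absolute reliability: the within-subject coefficient of variation CV% (mean
over subjects of 100*SD_i/|mean_i|; undefined for signed mean-location
parameters), the standard error of measurement of the k-footfall average
SEM = SD * sqrt(1 - ICC(2,k)) with SD the standard deviation of subject
means, and the minimal detectable change MDC = SEM * sqrt(2) * z with
z = 1.64 (90% confidence).

Confidence intervals for ICC(2,1) use the F-based approximation of
McGraw & Wong for two-way random absolute agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTable",
    "two_way_anova",
    "icc_2_1",
    "icc_2_k",
    "spearman_brown",
    "required_k",
    "cv_within",
    "sem",
    "mdc",
    "sample_size_icc",
    "reliability_report",
]

MDC_Z_90 = 1.64  # z score at the 90% confidence level


@dataclass(frozen=True)
class AnovaTable:
    """Mean squares of the unreplicated two-way (subjects x footfalls) ANOVA."""

    msr: float  # between subjects (rows)
    msc: float  # between footfalls (columns)
    mse: float  # residual
    n: int
    k: int
    f_columns: float  # MSC/MSE — systematic bias between footfalls
    p_columns: float
    f_rows: float  # MSR/MSE — subject discrimination (tests ICC > 0)
    p_rows: float


def two_way_anova(matrix) -> AnovaTable:
    """Two-way ANOVA without replication on an n x k complete matrix.

    Raises ``ValueError`` on missing values or zero residual degrees of
    freedom.  With a constant matrix the F ratios are undefined and
    reported as NaN.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x footfalls)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 and k >= 2, got {n} x {k}")
    if np.isnan(m).any():
        raise ValueError("matrix contains missing values; filter rows first")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    df_r, df_c = n - 1, k - 1
    df_e = df_r * df_c
    msr, msc, mse = ssr / df_r, ssc / df_c, max(sse, 0.0) / df_e

    if mse > 0:
        f_cols = msc / mse
        p_cols = float(stats.f.sf(f_cols, df_c, df_e))
        f_rows = msr / mse
        p_rows = float(stats.f.sf(f_rows, df_r, df_e))
    else:
        f_cols = p_cols = f_rows = p_rows = float("nan")
    return AnovaTable(msr, msc, mse, n, k, f_cols, p_cols, f_rows, p_rows)


def icc_2_1(
    msr: float,
    msc: float,
    mse: float,
    n: int,
    k: int,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) point estimate and F-based confidence interval.

    Returns ``(nan, (nan, nan))`` when the denominator degenerates (all
    mean squares zero).
    """
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan"), (float("nan"), float("nan"))
    est = (msr - mse) / denom
    lo, hi = _icc21_ci(est, msr, msc, mse, n, k, confidence)
    return est, (lo, hi)


def _icc21_ci(est, msr, msc, mse, n, k, confidence):
    if mse == 0 and msc == 0:
        return est, est
    alpha = 1.0 - confidence
    a = k * est / (n * (1.0 - est)) if est < 1.0 else float("inf")
    b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est)) if est < 1.0 else float("inf")
    if not math.isfinite(a):
        return est, est
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    if den == 0:
        return est, est
    v = num / den
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_hi * msr
    )
    return float(lower), float(upper)


def icc_2_k(msr: float, msc: float, mse: float, n: int) -> float:
    """ICC(2,k): reliability of the mean of the k footfalls."""
    denom = msr + (msc - mse) / n
    if denom == 0:
        return float("nan")
    return (msr - mse) / denom


def spearman_brown(r: float, k: float) -> float:
    """Prophesied reliability of the mean of k replicates, R_k = kR/(1+(k-1)R)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if r < 0:
        raise ValueError("cannot prophesy a negative reliability")
    if r >= 1.0:
        return 1.0
    return k * r / (1.0 + (k - 1.0) * r)


def required_k(r: float, r_target: float = 0.50) -> int:
    """Smallest whole number of footfalls whose mean reaches ``r_target``.

    Inverts the Spearman-Brown formula, k = R_k(1-R) / (R(1-R_k)), and
    rounds up to whole footfalls.
    """
    if not 0.0 < r < 1.0:
        raise ValueError(f"single-footfall reliability must be in (0, 1), got {r}")
    if not 0.0 < r_target < 1.0:
        raise ValueError(f"target reliability must be in (0, 1), got {r_target}")
    k = r_target * (1.0 - r) / (r * (1.0 - r_target))
    return max(1, math.ceil(k - 1e-12))


def cv_within(matrix, mode: str = "mean_of_subjects") -> float:
    """Within-subject coefficient of variation, in percent.

    ``mean_of_subjects`` (default): each subject's CV_i = 100 SD_i/|mean_i|
    across their k footfalls, averaged over subjects.  ``pooled``: the root
    mean square within-subject SD divided by the mean absolute subject mean.
    Returns NaN if any subject mean is zero.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must be n x k with k >= 2")
    means = m.mean(axis=1)
    if (means == 0).any():
        return float("nan")
    sds = m.std(axis=1, ddof=1)
    if mode == "mean_of_subjects":
        return float(np.mean(100.0 * sds / np.abs(means)))
    if mode == "pooled":
        pooled_sd = math.sqrt(float(np.mean(sds**2)))
        return 100.0 * pooled_sd / float(np.mean(np.abs(means)))
    raise ValueError(f"unknown mode {mode!r}")


def sem(sd: float, icc2k: float) -> float:
    """Standard error of measurement of the k-footfall average.

    ``sd`` is the standard deviation of the subject means.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if icc2k > 1:
        raise ValueError("ICC cannot exceed 1")
    return sd * math.sqrt(1.0 - icc2k)


def mdc(sem_value: float, z: float = MDC_Z_90) -> float:
    """Minimal detectable change, MDC = SEM * sqrt(2) * z."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    return sem_value * math.sqrt(2.0) * z


def sample_size_icc(
    rho0: float,
    rho1: float,
    alpha_one_tailed: float = 0.05,
    power: float = 0.80,
    k: int = 2,
) -> int:
    """Subjects needed to show reliability rho1 exceeds the floor rho0.

    Fisher-type variance-stabilising approximation for the ICC of k
    replicates: Z(rho) = 0.5 ln[(1 + (k-1) rho) / (1 - rho)], and

        n = 2 + k (z_a + z_b)^2 / (2 (k-1) (Z(rho1) - Z(rho0))^2).

    Advisory design aid; exact small-sample conventions vary between
    implementations by a subject or two.
    """
    if not 0.0 < rho0 < rho1 < 1.0:
        raise ValueError("need 0 < rho0 < rho1 < 1")
    if k < 2:
        raise ValueError("k must be >= 2")

    def z_transform(rho: float) -> float:
        return 0.5 * math.log((1.0 + (k - 1.0) * rho) / (1.0 - rho))

    za = stats.norm.ppf(1.0 - alpha_one_tailed)
    zb = stats.norm.ppf(power)
    dz = z_transform(rho1) - z_transform(rho0)
    n = 2.0 + k * (za + zb) ** 2 / (2.0 * (k - 1.0) * dz**2)
    return math.ceil(n)


# ----------------------------------------------------------------------
# report assembly

_SUBPHASE_PREFIXES = ("ICP", "LCP", "FFP", "CbP", "IPP", "LPP")


def _split_parameter(col: str) -> tuple[str, str]:
    head, _, tail = col.partition("_")
    if head in _SUBPHASE_PREFIXES:
        return tail, head
    return col, ""


def _pivot_matrix(df: pd.DataFrame, value: str, subject: str, footfall: str, k: int | None):
    """Subjects x first-k-footfalls matrix, complete-case over rows."""
    ordered = df.sort_values([subject, footfall])
    ordered = ordered.groupby(subject, sort=True).head(k) if k else ordered
    ordered = ordered.assign(
        _rep=ordered.groupby(subject).cumcount()
    )
    wide = ordered.pivot(index=subject, columns="_rep", values=value)
    if k:
        wide = wide.reindex(columns=range(k))
    wide = wide.dropna(axis=0, how="any")
    return wide


def reliability_report(
    params: pd.DataFrame,
    value_cols: list[str] | None = None,
    subject: str = "subject",
    footfall: str = "footfall",
    condition: str | None = "condition",
    side: str | None = "side",
    dominant: dict[str, str] | str | None = None,
    k: int | None = 7,
    r_target: float = 0.50,
    z: float = MDC_Z_90,
    confidence: float = 0.95,
    cv_exclude_substrings: tuple[str, ...] = ("mloc",),
) -> pd.DataFrame:
    """Per-parameter reliability table over a long-form parameter DataFrame.

    For each parameter column (and condition, when present) the dominant
    side's subjects x footfalls matrix yields descriptive mean/SD over
    subject means, ICC(2,1) with CI, ICC(2,k), the between-footfall ANOVA
    F/p (systematic bias), SEM, MDC, and the number of footfalls required
    to reach ``r_target``.  CV% is computed for the dominant and the
    non-dominant side, except for signed mean-location parameters (NA).

    ``dominant`` selects the analysed side per subject (mapping), globally
    (a single label), or not at all (None: every footfall is used and the
    non-dominant CV column stays empty).  Subjects with fewer than ``k``
    complete footfalls are dropped case-wise per parameter.
    """
    if value_cols is None:
        meta = {subject, footfall, condition, side}
        value_cols = [
            c
            for c in params.columns
            if c not in meta and pd.api.types.is_numeric_dtype(params[c])
        ]
    conditions = (
        sorted(params[condition].dropna().unique())
        if condition and condition in params.columns
        else [None]
    )

    def dominant_mask(df: pd.DataFrame) -> pd.Series:
        if dominant is None or side not in df.columns:
            return pd.Series(True, index=df.index)
        if isinstance(dominant, str):
            return df[side] == dominant
        return df.apply(lambda row: row[side] == dominant.get(row[subject]), axis=1)

    rows = []
    for cond in conditions:
        sub = params if cond is None else params[params[condition] == cond]
        dom = sub[dominant_mask(sub)]
        nondom = sub[~dominant_mask(sub)] if dominant is not None else sub.iloc[0:0]
        for col in value_cols:
            name, subphase = _split_parameter(col)
            row: dict = {
                "parameter": name,
                "subphase": subphase,
                "condition": cond,
                "k": k,
            }
            wide = _pivot_matrix(dom.dropna(subset=[col]), col, subject, footfall, k)
            if wide.shape[0] < 2 or wide.shape[1] < 2:
                row["reason"] = "insufficient data"
                rows.append(row)
                continue
            m = wide.to_numpy()
            anova = two_way_anova(m)
            subj_means = m.mean(axis=1)
            est, (lo, hi) = icc_2_1(
                anova.msr, anova.msc, anova.mse, anova.n, anova.k, confidence
            )
            icc_k = icc_2_k(anova.msr, anova.msc, anova.mse, anova.n)
            sd = float(np.std(subj_means, ddof=1))
            sem_val = sem(sd, icc_k) if np.isfinite(icc_k) and icc_k <= 1 else np.nan
            cv_applicable = not any(s in col for s in cv_exclude_substrings)
            cv_dom = cv_within(m) if cv_applicable else np.nan
            cv_nd = np.nan
            if cv_applicable and len(nondom):
                wide_nd = _pivot_matrix(
                    nondom.dropna(subset=[col]), col, subject, footfall, k
                )
                if wide_nd.shape[0] >= 1 and wide_nd.shape[1] >= 2:
                    cv_nd = cv_within(wide_nd.to_numpy())
            if est >= 1.0:
                req: float = 1  # already perfectly reliable with one footfall
            elif est > 0:
                req = required_k(est, r_target)
            else:
                req = np.nan
            row.update(
                n=anova.n,
                mean=float(np.mean(subj_means)),
                sd=sd,
                icc21=est,
                icc21_lo=lo,
                icc21_hi=hi,
                icc2k=icc_k,
                F=anova.f_columns,
                p=anova.p_columns,
                icc_p=anova.p_rows,
                cv_dom=cv_dom,
                cv_nondom=cv_nd,
                sem=sem_val,
                mdc=mdc(sem_val, z) if np.isfinite(sem_val) else np.nan,
                required_k=req,
                reason=None,
            )
            rows.append(row)
    cols = [
        "parameter",
        "subphase",
        "condition",
        "k",
        "n",
        "mean",
        "sd",
        "icc21",
        "icc21_lo",
        "icc21_hi",
        "icc2k",
        "F",
        "p",
        "icc_p",
        "cv_dom",
        "cv_nondom",
        "sem",
        "mdc",
        "required_k",
        "reason",
    ]
    return pd.DataFrame(rows, columns=cols)
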