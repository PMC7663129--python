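"""Published normative reliability values for mat-based COP excursion.

Intra-session reliability reference table for the COP stance-phase
parameters measured on a 240 Hz pressure-sensitive walkway in 90 healthy
young adults walking barefoot at a comfortable and at a fast pace.  Per
parameter and condition it lists the cohort mean and SD (over subject
means of seven footfalls), the single-footfall ICC(2,1), the seven-footfall
ICC(2,7), and the SEM and MDC of the seven-footfall average.

These are measured reference data, not quantities this package computes;
they serve as normative inputs — e.g. for prophesying the reliability of
k-footfall averages, deriving the number of footfalls a protocol needs, or
checking MDC arithmetic — and as the scale reference for the synthetic
generator defaults.

Categories: ``dur`` subphase duration (% stance), ``stance`` stance
duration (ms), ``tp`` time point (% stance), ``rangeML``/``rangeAP``
displacement range (mm), ``velML``/``velAP``/``velTot`` velocity (cm/s),
``mlocML``/``mlocAP`` mean location (% foot width/length; signed, no CV).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_reference_table", "REQUIRED_RELIABILITY"]

#: the customary cut-off for the reliability of a k-footfall average
REQUIRED_RELIABILITY = 0.50

# (category, subphase,
#  comfortable: mean, sd, icc21, icc2k, sem, mdc,
#  fast:        mean, sd, icc21, icc2k, sem, mdc)
_ROWS = [
    ("dur", "ICP", 8.83, 2.19, 0.79, 0.96, 0.46, 1.08, 9.71, 2.45, 0.74, 0.95, 0.61, 1.41),
    ("dur", "LCP", 32.02, 7.12, 0.46, 0.86, 3.84, 8.91, 31.19, 6.89, 0.44, 0.84, 3.94, 9.14),
    ("dur", "FFP", 18.52, 5.73, 0.42, 0.83, 3.46, 8.02, 13.50, 5.84, 0.40, 0.82, 3.73, 8.64),
    ("dur", "CbP", 50.49, 7.01, 0.76, 0.96, 1.65, 3.84, 44.41, 6.27, 0.75, 0.96, 1.50, 3.48),
    ("dur", "IPP", 27.69, 5.67, 0.62, 0.92, 2.01, 4.65, 29.38, 4.52, 0.48, 0.86, 2.33, 5.41),
    ("dur", "LPP", 12.98, 3.45, 0.55, 0.90, 1.46, 3.39, 16.51, 4.50, 0.55, 0.89, 1.93, 4.48),
    ("stance", "", 613.7, 46.4, 0.87, 0.98, 7.02, 16.27, 528.6, 46.4, 0.88, 0.98, 6.71, 15.57),
    ("tp", "MON", 8.83, 2.19, 0.79, 0.96, 0.46, 1.08, 9.71, 2.45, 0.74, 0.95, 0.61, 1.41),
    ("tp", "FFT", 40.85, 7.33, 0.47, 0.86, 3.79, 8.79, 40.90, 7.30, 0.45, 0.85, 4.00, 9.29),
    ("tp", "HOT", 59.32, 7.07, 0.77, 0.96, 1.63, 3.77, 54.11, 6.23, 0.76, 0.96, 1.48, 3.44),
    ("tp", "MOF", 87.02, 3.45, 0.55, 0.90, 1.46, 3.39, 83.48, 4.50, 0.55, 0.89, 1.92, 4.46),
    ("rangeML", "ICP", 4.89, 0.99, 0.13, 0.50, 1.64, 3.80, 4.97, 1.11, 0.17, 0.58, 1.53, 3.56),
    ("rangeML", "LCP", 10.37, 3.50, 0.49, 0.87, 1.76, 4.08, 10.05, 3.27, 0.46, 0.86, 1.74, 4.04),
    ("rangeML", "FFP", 3.57, 1.13, 0.23, 0.68, 1.21, 2.80, 3.31, 1.11, 0.22, 0.66, 1.26, 2.91),
    ("rangeML", "CbP", 12.11, 3.51, 0.46, 0.86, 1.89, 4.39, 11.40, 3.42, 0.48, 0.86, 1.76, 4.09),
    ("rangeML", "IPP", 9.85, 3.50, 0.51, 0.88, 1.64, 3.80, 11.59, 3.45, 0.49, 0.87, 1.73, 4.01),
    ("rangeML", "LPP", 16.16, 3.93, 0.39, 0.82, 2.56, 5.93, 13.99, 3.59, 0.42, 0.84, 2.15, 4.98),
    ("rangeAP", "ICP", 21.43, 4.02, 0.46, 0.86, 2.14, 4.96, 21.98, 4.14, 0.53, 0.89, 1.85, 4.28),
    ("rangeAP", "LCP", 78.04, 14.29, 0.48, 0.87, 7.20, 16.70, 87.09, 18.78, 0.49, 0.87, 9.42, 21.84),
    ("rangeAP", "FFP", 55.87, 12.59, 0.41, 0.83, 7.74, 17.95, 49.57, 13.59, 0.34, 0.78, 10.19, 23.64),
    ("rangeAP", "CbP", 133.1, 10.7, 0.78, 0.96, 2.37, 5.50, 133.5, 10.9, 0.73, 0.95, 2.82, 6.53),
    ("rangeAP", "IPP", 28.86, 8.05, 0.71, 0.95, 2.18, 5.05, 30.44, 7.84, 0.69, 0.94, 2.27, 5.27),
    ("rangeAP", "LPP", 39.65, 6.97, 0.60, 0.91, 2.60, 6.03, 40.04, 5.57, 0.59, 0.91, 2.12, 4.93),
    ("velML", "ICP", 20.02, 4.11, 0.22, 0.67, 4.54, 10.52, 20.35, 4.65, 0.25, 0.70, 4.64, 10.76),
    ("velML", "LCP", 10.06, 1.81, 0.45, 0.85, 1.01, 2.33, 11.21, 2.59, 0.47, 0.86, 1.35, 3.12),
    ("velML", "FFP", 8.05, 1.21, 0.25, 0.70, 1.22, 2.82, 9.83, 1.95, 0.24, 0.69, 2.02, 4.69),
    ("velML", "CbP", 9.06, 1.37, 0.52, 0.88, 0.63, 1.47, 10.34, 1.65, 0.51, 0.88, 0.77, 1.78),
    ("velML", "IPP", 10.27, 1.12, 0.26, 0.71, 1.11, 2.57, 11.80, 1.76, 0.38, 0.81, 1.17, 2.71),
    ("velML", "LPP", 36.45, 9.16, 0.32, 0.77, 7.27, 16.86, 31.63, 7.37, 0.34, 0.78, 5.56, 12.89),
    ("velAP", "ICP", 46.75, 7.79, 0.43, 0.84, 4.56, 10.59, 50.32, 9.57, 0.51, 0.88, 4.52, 10.48),
    ("velAP", "LCP", 48.61, 10.69, 0.63, 0.92, 3.67, 8.51, 60.00, 11.95, 0.59, 0.91, 4.61, 10.70),
    ("velAP", "FFP", 54.23, 10.99, 0.50, 0.87, 5.32, 12.34, 74.84, 18.39, 0.55, 0.90, 7.77, 18.02),
    ("velAP", "CbP", 49.16, 9.09, 0.72, 0.95, 2.43, 5.64, 62.32, 10.76, 0.71, 0.94, 2.99, 6.94),
    ("velAP", "IPP", 19.82, 4.04, 0.63, 0.92, 1.38, 3.19, 22.18, 4.49, 0.63, 0.92, 1.53, 3.56),
    ("velAP", "LPP", 55.97, 11.15, 0.40, 0.82, 7.10, 16.46, 52.20, 10.97, 0.45, 0.85, 6.00, 13.91),
    ("velTot", "ICP", 54.15, 8.85, 0.46, 0.85, 4.81, 11.16, 57.45, 10.84, 0.51, 0.88, 5.10, 11.83),
    ("velTot", "LCP", 50.45, 10.71, 0.62, 0.92, 3.74, 8.68, 61.87, 12.07, 0.58, 0.91, 4.70, 10.91),
    ("velTot", "FFP", 55.55, 10.97, 0.50, 0.88, 5.26, 12.20, 76.25, 18.40, 0.55, 0.90, 7.71, 17.87),
    ("velTot", "CbP", 50.78, 9.09, 0.71, 0.95, 2.47, 5.72, 63.96, 10.73, 0.70, 0.94, 3.00, 6.96),
    ("velTot", "IPP", 23.78, 3.81, 0.55, 0.90, 1.61, 3.74, 26.78, 4.47, 0.56, 0.90, 1.83, 4.23),
    ("velTot", "LPP", 72.82, 14.27, 0.36, 0.80, 10.03, 23.25, 66.20, 13.20, 0.41, 0.83, 8.13, 18.85),
    ("mlocML", "ICP", -2.19, 1.40, 0.40, 0.82, 0.89, 2.06, -1.81, 1.27, 0.36, 0.80, 0.89, 2.07),
    ("mlocML", "LCP", 5.59, 2.00, 0.46, 0.86, 1.07, 2.49, 5.46, 2.10, 0.49, 0.87, 1.04, 2.40),
    ("mlocML", "FFP", 8.09, 2.94, 0.37, 0.80, 2.04, 4.72, 7.75, 2.85, 0.41, 0.83, 1.74, 4.04),
    ("mlocML", "CbP", 6.49, 2.13, 0.43, 0.84, 1.24, 2.88, 6.07, 2.12, 0.50, 0.88, 1.02, 2.37),
    ("mlocML", "IPP", 3.63, 2.80, 0.45, 0.85, 1.56, 3.63, 1.91, 2.52, 0.40, 0.82, 1.59, 3.68),
    ("mlocML", "LPP", -6.03, 3.05, 0.50, 0.87, 1.49, 3.46, -6.59, 2.39, 0.41, 0.83, 1.49, 3.45),
    ("mlocAP", "ICP", -7.45, 1.17, 0.40, 0.82, 0.74, 1.73, -7.12, 1.07, 0.36, 0.80, 0.76, 1.75),
    ("mlocAP", "LCP", 16.19, 2.86, 0.47, 0.86, 1.48, 3.44, 17.35, 3.32, 0.45, 0.85, 1.83, 4.25),
    ("mlocAP", "FFP", 40.34, 3.71, 0.54, 0.89, 1.63, 3.79, 42.27, 4.24, 0.48, 0.87, 2.17, 5.04),
    ("mlocAP", "CbP", 25.22, 2.28, 0.52, 0.88, 1.05, 2.43, 24.63, 2.32, 0.54, 0.89, 1.02, 2.37),
    ("mlocAP", "IPP", 59.21, 2.51, 0.72, 0.95, 0.66, 1.53, 60.42, 2.38, 0.70, 0.94, 0.66, 1.54),
    ("mlocAP", "LPP", 70.55, 3.35, 0.74, 0.95, 0.84, 1.94, 71.56, 2.93, 0.72, 0.95, 0.79, 1.83),
]

_VALUE_COLS = ["mean", "sd", "icc21", "icc2k", "sem", "mdc"]


def load_reference_table() -> pd.DataFrame:
    """Normative reliability values, long form over both walking conditions.

    Columns: ``category, subphase, condition, mean, sd, icc21, icc2k, sem,
    mdc`` with condition in ``{"comfortable", "fast"}``; ICCs refer to the
    dominant foot, SEM/MDC to the seven-footfall average.
    """
    records = []
    for row in _ROWS:
        cat, sub = row[0], row[1]
        comfortable, fast = row[2:8], row[8:14]
        for cond, vals in (("comfortable", comfortable), ("fast", fast)):
            records.append(
                {"category": cat, "subphase": sub, "condition": cond,
                 **dict(zip(_VALUE_COLS, vals))}
            )
    return pd.DataFrame.from_records(records)
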