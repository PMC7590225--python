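"""Published county-level summary statistics shipped as input data.

Urban/rural group summaries (mean, SD, group sizes) of county-level
percentages from round five (2010-2014) of the Illinois County
Behavioral Risk Factor Surveys, with green-space exposure summaries for
the six boundary schemes: 20 urban and 74 rural county units. These are
*inputs* to the summary-statistic t-test reconstruction — the underlying
county table was never deposited, but the printed group summaries are
sufficient to re-derive every mean difference, SE and t statistic.

The ``method`` column records which test formula (pooled vs Welch)
reproduces the published SE of the difference; ``published_se_diff`` and
``published_p`` are kept alongside for cross-checking, never as
computation inputs.
"""

from __future__ import annotations

import pandas as pd

N_URBAN = 20
N_RURAL = 74

# variable, urban mean, urban sd, rural mean, rural sd, method,
# published diff, published SE(diff), published p (0 = printed as 0.000)
_ROWS = [
    ("female", 52.47, 3.82, 51.01, 4.02, "pooled", 1.46, 1.00, 0.150),
    ("elderly", 17.19, 2.82, 22.66, 3.37, "pooled", -5.47, 0.82, 0.000),
    ("white", 79.53, 7.97, 95.88, 4.20, "welch", -16.35, 1.85, 0.000),
    ("poverty", 8.81, 4.61, 8.84, 3.83, "pooled", -0.04, 1.01, 0.969),
    ("employed", 57.65, 5.63, 55.08, 6.40, "pooled", 2.57, 1.58, 0.107),
    ("education", 65.09, 7.90, 54.31, 5.90, "pooled", 10.78, 1.60, 0.000),
    ("smoking", 41.65, 6.20, 45.40, 6.37, "pooled", -3.76, 1.60, 0.021),
    ("alcohol", 4.67, 1.60, 6.41, 3.49, "welch", -1.74, 0.55, 0.002),
    ("obesity", 29.40, 5.52, 31.81, 5.50, "welch", -2.42, 1.39, 0.084),
    ("exercise", 76.90, 6.21, 74.02, 4.90, "pooled", 2.88, 1.31, 0.031),
    ("physical_health", 39.72, 5.04, 36.72, 5.44, "pooled", 3.00, 1.35, 0.029),
    ("mental_health", 39.27, 5.97, 34.10, 5.31, "pooled", 5.17, 1.37, 0.000),
    ("MXN-IL", 70.18, 4.27, 72.70, 1.80, "welch", -2.52, 0.98, 0.018),
    ("MXN-1H/1HA", 65.83, 3.00, 67.91, 3.75, "pooled", -2.08, 0.91, 0.025),
    ("MXN-1H/10HAs", 68.60, 3.81, 70.42, 4.04, "pooled", -1.83, 1.01, 0.073),
    ("MXN-CP", 65.95, 2.91, 68.23, 3.81, "pooled", -2.28, 0.92, 0.015),
    ("MXN-UA", 65.53, 2.89, 66.90, 3.57, "pooled", -1.36, 0.87, 0.123),
    ("MXN-CP+UA", 66.21, 3.02, 68.30, 3.74, "pooled", -2.09, 0.91, 0.024),
    ("TIN-IL", 17.75, 2.95, 18.60, 2.41, "pooled", -0.85, 0.64, 0.187),
    ("TIN-1H/1HA", 14.26, 1.90, 14.02, 2.13, "pooled", 0.24, 0.53, 0.654),
    ("TIN-1H/10HAs", 16.52, 2.56, 16.70, 2.46, "pooled", -0.18, 0.63, 0.776),
    ("TIN-CP", 14.59, 2.21, 14.67, 1.86, "pooled", -0.08, 0.49, 0.875),
    ("TIN-UA", 14.20, 1.98, 13.48, 2.06, "pooled", 0.72, 0.52, 0.169),
    ("TIN-CP+UA", 14.80, 2.20, 14.73, 1.83, "pooled", 0.07, 0.48, 0.881),
]


def illinois_county_summaries() -> pd.DataFrame:
    """The published urban/rural group summaries as a tidy DataFrame."""
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "variable",
            "urban_mean",
            "urban_sd",
            "rural_mean",
            "rural_sd",
            "method",
            "published_diff",
            "published_se_diff",
            "published_p",
        ],
    )
    df["n_urban"] = N_URBAN
    df["n_rural"] = N_RURAL
    return df
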