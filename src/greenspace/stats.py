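"""County-level statistical battery.

Everything here operates on unweighted county observations (ecological
design): Levene-gated two-sample urban/rural comparisons, the same
comparisons reconstructed from published group summary statistics,
Pearson correlation of the exposure columns, and ordinary least squares
with unstandardized (B) and standardized (beta) coefficients.

The variance-equality gate is the classic mean-centered Levene test at
alpha = 0.05: when it rejects, Welch's t-test (Welch-Satterthwaite
degrees of freedom) replaces the pooled two-sample t-test. No
multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .boundaries import BUFFERS_M, SCHEMES
from .exposure import METRICS

LEVENE_ALPHA = 0.05

#: Covariates of every adjusted model, in reporting order.
ADJUSTMENT_COVARIATES = [
    "urban",
    "female",
    "elderly",
    "white",
    "poverty",
    "employed",
    "education",
    "smoking",
    "alcohol",
    "obesity",
]


def stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def classify_bmi(bmi: float) -> str:
    """WHO-style BMI category with lower-inclusive boundaries.

    [0, 18.5) underweight, [18.5, 25) normal, [25, 30) overweight,
    [30, inf) obese.
    """
    if bmi <= 0 or not np.isfinite(bmi):
        raise ValueError(f"BMI must be a positive number, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"


def levene(a, b) -> tuple[float, float]:
    """Mean-centered Levene statistic W with an F(1, n1+n2-2) reference.

    Two identical flat samples give (0, 1) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    za = np.abs(a - a.mean())
    zb = np.abs(b - b.mean())
    n1, n2 = a.size, b.size
    zbar = (za.sum() + zb.sum()) / (n1 + n2)
    between = n1 * (za.mean() - zbar) ** 2 + n2 * (zb.mean() - zbar) ** 2
    within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    if within == 0:
        return 0.0, 1.0
    w = (n1 + n2 - 2) * between / within
    p = float(sps.f.sf(w, 1, n1 + n2 - 2))
    return float(w), p


@dataclass
class TTestResult:
    method: str  # "pooled" or "welch"
    mean_diff: float
    se_diff: float
    t: float
    df: float
    p: float
    levene_stat: float = float("nan")
    levene_p: float = float("nan")


def _t_core(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, method: str
) -> TTestResult:
    diff = m1 - m2
    if method == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif method == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        if v1 + v2 == 0:
            df = n1 + n2 - 2
        else:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    if se == 0:
        t = 0.0 if diff == 0 else np.copysign(np.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(
        method=method, mean_diff=diff, se_diff=float(se), t=float(t), df=float(df), p=p
    )


def two_sample_t(a, b, method: str = "auto") -> TTestResult:
    """Two-sample t-test; ``method='auto'`` applies the Levene gate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    lw, lp = levene(a, b)
    if method == "auto":
        method = "welch" if lp < LEVENE_ALPHA else "pooled"
    res = _t_core(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, method
    )
    res.levene_stat, res.levene_p = lw, lp
    return res


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, method: str
) -> TTestResult:
    """Two-sample t from published group means/SDs/sizes.

    The Levene gate needs raw data, so ``method`` must be ``pooled`` or
    ``welch`` explicitly.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if method not in ("pooled", "welch"):
        raise ValueError("method must be 'pooled' or 'welch' for summary input")
    return _t_core(m1, sd1, n1, m2, sd2, n2, method)


def urban_rural_compare(
    table: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Urban-vs-rural comparison of every county-level variable.

    One row per variable: group means/SDs, urban-minus-rural difference
    with its SE, the Levene-gated test method, t, df, p and significance
    stars. No variable is dropped.
    """
    if variables is None:
        variables = [
            c
            for c in table.columns
            if c not in ("county_id", "urban")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    urban = table[table["urban"].astype(bool)]
    rural = table[~table["urban"].astype(bool)]
    if len(urban) < 2 or len(rural) < 2:
        raise ValueError("both the urban and the rural group need >= 2 counties")

    rows = []
    for var in variables:
        a = urban[var].dropna().to_numpy()
        b = rural[var].dropna().to_numpy()
        res = two_sample_t(a, b, method="auto")
        rows.append(
            {
                "variable": var,
                "n_urban": a.size,
                "n_rural": b.size,
                "urban_mean": a.mean(),
                "urban_sd": a.std(ddof=1),
                "rural_mean": b.mean(),
                "rural_sd": b.std(ddof=1),
                "mean_diff": res.mean_diff,
                "se_diff": res.se_diff,
                "method": res.method,
                "levene_p": res.levene_p,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "stars": stars(res.p),
            }
        )
    return pd.DataFrame(rows)


def reconstruct_summary_tests(summaries: pd.DataFrame) -> pd.DataFrame:
    """Re-derive t statistics from a table of published group summaries.

    ``summaries`` needs columns: variable, urban_mean, urban_sd,
    rural_mean, rural_sd, n_urban, n_rural, method ('pooled'/'welch').
    """
    rows = []
    for _, r in summaries.iterrows():
        res = t_from_summary(
            r["urban_mean"],
            r["urban_sd"],
            int(r["n_urban"]),
            r["rural_mean"],
            r["rural_sd"],
            int(r["n_rural"]),
            r["method"],
        )
        rows.append(
            {
                "variable": r["variable"],
                "method": res.method,
                "mean_diff": res.mean_diff,
                "se_diff": res.se_diff,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "stars": stars(res.p),
            }
        )
    return pd.DataFrame(rows)


def pearson_matrix(wide: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of exposure columns with pairwise deletion.

    Zero-variance columns yield NaN entries. Requires >= 3 complete
    pairs per entry (sparser pairs are NaN).
    """
    cols = [c for c in wide.columns if c != "county_id"]
    return wide[cols].corr(method="pearson", min_periods=3)


@dataclass
class RegressionResult:
    """OLS fit summary: per-predictor table plus model-level statistics.

    ``coefficients`` columns: predictor, B, SE, beta, t, p (the intercept
    row has beta = NaN).
    """

    coefficients: pd.DataFrame
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    n: int
    sigma2: float


def ols(y, predictors: pd.DataFrame, names: list[str] | None = None) -> RegressionResult:
    """Ordinary least squares with listwise deletion of incomplete rows.

    B and SE come from the normal equations (SE from sigma^2 (X'X)^-1),
    standardized beta = B * sd(x) / sd(y). A rank-deficient design is a
    hard failure naming the offending columns.
    """
    X = pd.DataFrame(predictors).copy()
    if names is not None:
        X.columns = names
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} complete rows, have {n}")

    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        offenders = [
            col
            for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; offending columns: {offenders}")

    yv = y.to_numpy()
    xtx_inv = np.linalg.inv(design.T @ design)
    b = xtx_inv @ design.T @ yv
    resid = yv - design @ b
    dof = n - p - 1
    sigma2 = float(resid @ resid / dof)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tvals = np.divide(b, se, out=np.zeros_like(b), where=se > 0)
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)

    sy = yv.std(ddof=1)
    betas = np.full(p + 1, np.nan)
    if sy > 0:
        betas[1:] = b[1:] * X.to_numpy(dtype=float).std(axis=0, ddof=1) / sy

    tss = ((yv - yv.mean()) ** 2).sum()
    rss = float(resid @ resid)
    r2 = 1 - rss / tss if tss > 0 else float("nan")
    adj_r2 = 1 - (1 - r2) * (n - 1) / dof if np.isfinite(r2) else float("nan")
    if p > 0 and rss > 0 and np.isfinite(r2):
        f = (tss - rss) / p / (rss / dof)
        f_p = float(sps.f.sf(f, p, dof))
    elif rss == 0:
        f, f_p = float("inf"), 0.0
    else:
        f, f_p = float("nan"), float("nan")

    coef = pd.DataFrame(
        {
            "predictor": ["intercept", *X.columns],
            "B": b,
            "SE": se,
            "beta": betas,
            "t": tvals,
            "p": pvals,
        }
    )
    return RegressionResult(
        coefficients=coef, r2=float(r2), adj_r2=float(adj_r2), f_stat=float(f),
        f_p=f_p, n=n, sigma2=sigma2,
    )


def _greenspace_series(
    exposure: pd.DataFrame, scheme: str, metric: str, buffer_m: float
) -> pd.Series:
    sub = exposure[
        (exposure["scheme"] == scheme)
        & (exposure["metric"] == metric)
        & (exposure["buffer_m"] == buffer_m)
    ]
    if sub.empty:
        raise KeyError(
            f"exposure table lacks scheme={scheme!r} metric={metric!r} "
            f"buffer={buffer_m}"
        )
    return sub.set_index("county_id")["value"]


def boundary_grid(table: pd.DataFrame, exposure: pd.DataFrame) -> pd.DataFrame:
    """Zoning-effect grid: exercise on greenness per scheme x metric x model.

    24 models: 6 schemes x {MXN, TIN} x {null, adjusted}. Counties with
    a missing exposure under a scheme are dropped for that scheme only.
    Returns one row per model with the greenspace coefficient and fit.
    """
    t = table.set_index("county_id")
    rows = []
    for scheme in SCHEMES:
        for metric in METRICS:
            gs = _greenspace_series(exposure, scheme, metric, 0)
            data = t.copy()
            data["greenspace"] = gs
            for model in ("null", "adjusted"):
                preds = ["greenspace"] + (
                    ADJUSTMENT_COVARIATES if model == "adjusted" else []
                )
                fit = ols(data["exercise"], data[preds])
                g = fit.coefficients.set_index("predictor").loc["greenspace"]
                rows.append(
                    {
                        "scheme": scheme,
                        "metric": metric,
                        "model": model,
                        "n": fit.n,
                        "B": g["B"],
                        "SE": g["SE"],
                        "beta": g["beta"],
                        "p": g["p"],
                        "stars": stars(g["p"]),
                        "r2": fit.r2,
                        "adj_r2": fit.adj_r2,
                    }
                )
    return pd.DataFrame(rows)


def buffer_grid(
    table: pd.DataFrame,
    exposure: pd.DataFrame,
    scheme: str = "combined",
    metric: str = "TIN",
    buffers: list[float] = BUFFERS_M,
) -> dict[str, pd.DataFrame]:
    """Scaling-effect grid: adjusted exercise model per buffer distance.

    Returns ``coefficients`` (11 predictors x len(buffers)) and ``model``
    (per-buffer F, p, R^2, adjusted R^2, n).
    """
    t = table.set_index("county_id")
    coef_rows, model_rows = [], []
    for buf in buffers:
        data = t.copy()
        data["greenspace"] = _greenspace_series(exposure, scheme, metric, buf)
        fit = ols(data["exercise"], data[["greenspace", *ADJUSTMENT_COVARIATES]])
        c = fit.coefficients[fit.coefficients["predictor"] != "intercept"].copy()
        c.insert(0, "buffer_m", buf)
        c["stars"] = c["p"].map(stars)
        coef_rows.append(c)
        model_rows.append(
            {
                "buffer_m": buf,
                "n": fit.n,
                "f": fit.f_stat,
                "f_p": fit.f_p,
                "r2": fit.r2,
                "adj_r2": fit.adj_r2,
            }
        )
    return {
        "coefficients": pd.concat(coef_rows, ignore_index=True),
        "model": pd.DataFrame(model_rows),
    }


def health_models(
    table: pd.DataFrame,
    exposure: pd.DataFrame,
    scheme: str = "combined",
    metric: str = "TIN",
) -> dict[str, pd.DataFrame]:
    """Adjusted models for the three outcomes.

    Exercise is regressed on greenspace + 10 covariates (identical to
    the no-buffer column of :func:`buffer_grid`); the two health
    outcomes additionally adjust for exercise (12 predictors).
    """
    t = table.set_index("county_id")
    t = t.copy()
    t["greenspace"] = _greenspace_series(exposure, scheme, metric, 0)

    specs = {
        "exercise": ["greenspace", *ADJUSTMENT_COVARIATES],
        "physical_health": ["greenspace", *ADJUSTMENT_COVARIATES, "exercise"],
        "mental_health": ["greenspace", *ADJUSTMENT_COVARIATES, "exercise"],
    }
    coef_rows, model_rows = [], []
    for outcome, preds in specs.items():
        fit = ols(t[outcome], t[preds])
        c = fit.coefficients[fit.coefficients["predictor"] != "intercept"].copy()
        c.insert(0, "outcome", outcome)
        c["stars"] = c["p"].map(stars)
        coef_rows.append(c)
        model_rows.append(
            {
                "outcome": outcome,
                "n": fit.n,
                "f": fit.f_stat,
                "f_p": fit.f_p,
                "r2": fit.r2,
                "adj_r2": fit.adj_r2,
            }
        )
    return {
        "coefficients": pd.concat(coef_rows, ignore_index=True),
        "model": pd.DataFrame(model_rows),
    }
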