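"""Method-agreement and modality-comparison statistics on a study table.

Bland-Altman, Pearson/Spearman correlation and ordinary least squares are
implemented from their closed forms; the repeated-measures ANOVA F test
and Tukey's honestly-significant-difference comparisons use the standard
sum-of-squares decomposition with the within-subject error term, with
p-values from scipy's F and studentized-range distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of paired differences (a - b)."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_pairs: int


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    method: str
    n: int
    ci95: tuple[float, float] | None = None


@dataclass
class LinearFitResult:
    """OLS fit with the pointwise 95% confidence band of the mean response."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise CI of the mean response at the given x values."""
        x = np.asarray(x, dtype=float)
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        se = self.residual_sd * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        yhat = self.predict(x)
        return yhat - tcrit * se, yhat + tcrit * se


@dataclass
class PairedComparisonResult:
    """Repeated-measures one-way ANOVA plus Tukey pairwise comparisons."""

    group_means: dict[str, float]
    group_sds: dict[str, float]
    f_statistic: float
    p_value: float
    df_effect: int
    df_error: int
    tukey_p: dict[tuple[str, str], float]
    shapiro_p: float
    n_units: int


# ---------------------------------------------------------------------------
# closed-form statistics
# ---------------------------------------------------------------------------

def bland_altman(pairs: np.ndarray | list[tuple[float, float]]) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    differences d = a - b; bias = mean(d); limits of agreement
    bias +/- 1.96 * SD(d), with the sample SD (n-1 denominator).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    if len(arr) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n_pairs=len(d),
    )


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    return float((xc * yc).sum() / denom)


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided t-test p-value.

    Spearman is Pearson on average ranks.  The two-sided p-value uses
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; the Pearson 95%
    CI is the Fisher z-transform interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    r = _pearson_r(x, y)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    ci = None
    if method == "pearson" and n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        zse = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959963984540054 * zse)),
              float(np.tanh(z + 1.959963984540054 * zse)))
    return CorrelationResult(r=r, p_value=p, method=method, n=n, ci95=ci)


def linear_fit(x: np.ndarray, y: np.ndarray) -> LinearFitResult:
    """Ordinary least squares y = a + b*x with the closed-form solution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("linear_fit needs n >= 3")
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero variance in x")
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = (resid**2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    s = np.sqrt(ss_res / (n - 2))
    return LinearFitResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        n=n,
        residual_sd=float(s),
        x_mean=float(xm),
        sxx=float(sxx),
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_f(data: np.ndarray) -> tuple[float, int, int]:
    """One-way repeated-measures ANOVA F statistic.

    ``data`` is an (n_units, k_conditions) matrix of complete blocks.
    Returns (F, df_effect, df_error) from the standard decomposition
    SS_total = SS_units + SS_conditions + SS_error.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 units and 2 conditions")
    gm = data.mean()
    ss_units = k * ((data.mean(axis=1) - gm) ** 2).sum()
    ss_cond = n * ((data.mean(axis=0) - gm) ** 2).sum()
    ss_total = ((data - gm) ** 2).sum()
    ss_err = ss_total - ss_units - ss_cond
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    if ms_err > 0:
        f = ms_cond / ms_err
    else:  # no residual variation: no evidence of an effect unless means differ
        f = 0.0 if ms_cond <= 1e-300 else np.inf
    return float(f), df_effect, df_error


def paired_modalities_test(
    table: pd.DataFrame, method: str = "area", value_col: str = "enhancement_pct"
) -> PairedComparisonResult:
    """Compare modality means with repeated-measures ANOVA and Tukey HSD.

    The repeated unit is the individual slice (subject, slice); rows of the
    long-format study table are filtered to the requested measurement
    ``method``, pivoted to complete blocks (incomplete blocks are dropped
    listwise with a warning), and tested with the within-subject error term.
    A Shapiro-Wilk normality p-value on the ANOVA residuals is reported
    alongside.
    """
    df = table[table["method"] == method] if "method" in table.columns else table
    wide = df.pivot_table(
        index=["subject", "slice"], columns="modality", values=value_col, aggfunc="first"
    )
    n_before = len(wide)
    wide = wide.dropna()
    if len(wide) < n_before:
        warnings.warn(
            f"dropped {n_before - len(wide)} incomplete blocks (missing modalities)",
            stacklevel=2,
        )
    if len(wide) < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 complete blocks and >= 2 modalities")

    modalities = list(wide.columns)
    data = wide.to_numpy()
    n, k = data.shape
    f, df_eff, df_err = rm_anova_f(data)
    p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0

    # Tukey HSD on modality means with the within-subject mean-square error
    gm = data.mean()
    ss_units = k * ((data.mean(axis=1) - gm) ** 2).sum()
    ss_cond = n * ((data.mean(axis=0) - gm) ** 2).sum()
    ss_err = ((data - gm) ** 2).sum() - ss_units - ss_cond
    ms_err = ss_err / df_err
    means = data.mean(axis=0)
    tukey_p: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            if ms_err > 0:
                q = abs(means[i] - means[j]) / np.sqrt(ms_err / n)
                pq = float(sps.studentized_range.sf(q, k, df_err))
            else:
                pq = 1.0 if means[i] == means[j] else 0.0
            tukey_p[(modalities[i], modalities[j])] = pq

    # residuals after removing unit and condition effects
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0, keepdims=True) + gm
    flat = resid.ravel()
    shapiro_p = float(sps.shapiro(flat).pvalue) if np.ptp(flat) > 0 and len(flat) >= 3 else 1.0

    return PairedComparisonResult(
        group_means={m: float(v) for m, v in zip(modalities, means)},
        group_sds={m: float(data[:, i].std(ddof=1)) for i, m in enumerate(modalities)},
        f_statistic=f,
        p_value=p,
        df_effect=df_eff,
        df_error=df_err,
        tukey_p=tukey_p,
        shapiro_p=shapiro_p,
        n_units=n,
    )
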