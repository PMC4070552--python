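"""GC-dependent coverage bias: regressions, model comparison, and ANCOVA.

Library-preparation PCR under-amplifies GC-rich template, so window-mean
coverage falls with GC fraction over most of the observed range; a quadratic
term captures the mild non-linearity whose peak sits near the lower end of
the GC range. Model choice is by Gaussian AIC. At single-site resolution,
base identity and gene type are tested jointly with local GC in an ANCOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass
class RegressionFit:
    """OLS fit of window-mean coverage on GC (degree 1) or GC + GC^2 (degree 2).

    ``aic`` is the Gaussian profile form n*ln(RSS/n) + 2*(degree+2), counting
    the variance parameter; an RSS floor of eps*n*var(y) keeps noiseless
    fixtures finite. ``vertex_gc`` (degree 2 only) is the GC fraction at the
    parabola's extremum, -b1/(2*b2).
    """

    degree: int
    coefficients: np.ndarray
    F: float
    R2: float
    df: int
    p: float
    aic: float
    n: int
    rss: float

    @property
    def vertex_gc(self) -> float | None:
        if self.degree == 2 and self.coefficients[2] != 0:
            return float(-self.coefficients[1] / (2 * self.coefficients[2]))
        return None


def _gaussian_aic(rss: float, n: int, degree: int, y: np.ndarray) -> float:
    floor = np.finfo(float).eps * n * float(np.var(y))
    rss = max(rss, floor, np.finfo(float).tiny)
    return n * np.log(rss / n) + 2 * (degree + 2)


def fit_gc_regression(table: pd.DataFrame, degree: int) -> RegressionFit:
    """Fit window-mean coverage against GC fraction by OLS.

    ``table`` needs columns ``gc`` and ``mean_cov`` (NaN-GC windows are
    dropped). Residual df is n - (degree+1).
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    data = table[["gc", "mean_cov"]].dropna()
    gc = data["gc"].to_numpy(dtype=float)
    y = data["mean_cov"].to_numpy(dtype=float)
    n = len(y)
    if n <= degree + 1:
        raise ValueError(f"need more than {degree + 1} windows, got {n}")
    if np.ptp(gc) == 0:
        raise ValueError("gc is constant; regression undefined")
    X = np.column_stack([gc**d for d in range(degree + 1)])
    fit = sm.OLS(y, X).fit()
    rss = float(fit.ssr)
    return RegressionFit(
        degree=degree,
        coefficients=np.asarray(fit.params, dtype=float),
        F=float(fit.fvalue),
        R2=float(fit.rsquared),
        df=int(fit.df_resid),
        p=float(fit.f_pvalue),
        aic=_gaussian_aic(rss, n, degree, y),
        n=n,
        rss=rss,
    )


def compare_models_aic(fit_lin: RegressionFit, fit_quad: RegressionFit) -> float:
    """AIC(quadratic) - AIC(linear); negative favours the quadratic model."""
    if fit_lin.n != fit_quad.n:
        raise ValueError("fits are on different numbers of windows")
    return fit_quad.aic - fit_lin.aic


def at_gc_coverage_ttest(
    coverage: np.ndarray, sequence: str
) -> tuple[float, float, float, float, float]:
    """Welch two-sample t-test of per-site coverage, A/T sites vs G/C sites.

    Returns (t, df, p, mean_AT, mean_GC) with t > 0 when mean_AT > mean_GC
    and Welch-Satterthwaite df. N sites belong to neither group. A tiny
    variance floor keeps degenerate equal-value fixtures finite.
    """
    coverage = np.asarray(coverage, dtype=float)
    if len(coverage) != len(sequence):
        raise ValueError("coverage and sequence lengths differ")
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    at = coverage[(seq == b"A") | (seq == b"T")]
    gc = coverage[(seq == b"G") | (seq == b"C")]
    if len(at) < 2 or len(gc) < 2:
        raise ValueError("both base groups need at least 2 sites")
    m1, m2 = at.mean(), gc.mean()
    floor = np.finfo(float).eps * max(1.0, abs(m1), abs(m2)) ** 2
    v1 = max(at.var(ddof=1), floor)
    v2 = max(gc.var(ddof=1), floor)
    se2 = v1 / len(at) + v2 / len(gc)
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (
        (v1 / len(at)) ** 2 / (len(at) - 1) + (v2 / len(gc)) ** 2 / (len(gc) - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), float(m1), float(m2)


def site_gc50(sequence: str, window: int = 50) -> np.ndarray:
    """Per-site GC fraction of a ``window``-bp window centered on the site.

    Windows are truncated at the region edges; N bases are excluded from
    numerator and denominator.
    """
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    is_gc = ((seq == b"G") | (seq == b"C")).astype(float)
    not_n = (seq != b"N").astype(float)
    half_lo = window // 2
    half_hi = window - half_lo  # window covers [i - half_lo, i + half_hi)
    cum_gc = np.concatenate([[0.0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0.0], np.cumsum(not_n)])
    idx = np.arange(len(seq))
    lo = np.clip(idx - half_lo, 0, len(seq))
    hi = np.clip(idx + half_hi, 0, len(seq))
    num = cum_gc[hi] - cum_gc[lo]
    den = cum_n[hi] - cum_n[lo]
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def site_ancova(
    coverage: np.ndarray,
    base_per_site: np.ndarray,
    gene_type_per_site: np.ndarray,
    gc50: np.ndarray,
) -> dict:
    """Per-site ANCOVA of coverage on base identity, gene type and local GC.

    Treatment-coded categoricals (reference level = alphabetically first),
    continuous gc50, per-term F from Type II sums of squares. Returns a dict
    with the ANOVA table, the coefficient table and the reference levels.
    """
    data = pd.DataFrame(
        {
            "coverage": np.asarray(coverage, dtype=float),
            "base": np.asarray(base_per_site, dtype=object),
            "gene_type": np.asarray(gene_type_per_site, dtype=object),
            "gc50": np.asarray(gc50, dtype=float),
        }
    ).dropna()
    for term in ("base", "gene_type"):
        levels = data[term].nunique()
        if levels < 2:
            raise ValueError(f"categorical term {term!r} has {levels} level(s)")
    if data["gc50"].nunique() < 2:
        raise ValueError("gc50 is constant")
    model = smf.ols("coverage ~ C(base) + C(gene_type) + gc50", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return {
        "anova": anova,
        "coefficients": model.params,
        "model": model,
        "reference_levels": {
            "base": sorted(data["base"].unique())[0],
            "gene_type": sorted(data["gene_type"].unique())[0],
        },
        "n": int(model.nobs),
    }
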