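"""Group-level statistics: rank transform, MANOVA/MANCOVA, summary t and F,
bootstrap Spearman correlations, and slope comparison.

Conventions mirror the source study's analysis style: extracted ROI parameter
estimates are Shapiro-Wilk gated and mid-rank transformed over the pooled
sample when non-normal; the multivariate group test is Wilks lambda with
Rao's F approximation and partial eta-squared (for two groups,
eta_p^2 = 1 - lambda); univariate follow-ups are pooled-variance one-way
ANOVAs with Bonferroni adjustment over the 18 ROIs; demographic contrasts
are Welch t with the control-minus-AN sign convention; correlations are
Spearman with 1000-sample percentile bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class SummaryStat:
    """Group summary: sample size, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class ManovaResult:
    """Wilks-lambda multivariate test with univariate follow-ups."""

    wilks_lambda: float
    f_approx: float
    df_h: float
    df_e: float
    p_value: float
    partial_eta2: float
    univariate: pd.DataFrame  # index ROI; columns F, p_raw, p_bonferroni, partial_eta2


@dataclass(frozen=True)
class BootstrapCorrelation:
    """Spearman rho with a percentile bootstrap confidence interval."""

    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int


def welch_t_from_summary(control: SummaryStat, an: SummaryStat) -> tuple[float, float]:
    """Welch two-sample t from group summaries, contrast control - AN.

    Returns (t, Welch-Satterthwaite df).
    """
    va, vc = an.sd ** 2 / an.n, control.sd ** 2 / control.n
    if va + vc == 0:
        raise ValueError("zero variance in both groups")
    t = (control.mean - an.mean) / np.sqrt(va + vc)
    df = (va + vc) ** 2 / (va ** 2 / (an.n - 1) + vc ** 2 / (control.n - 1))
    return float(t), float(df)


def pooled_anova_f_from_summary(an: SummaryStat, control: SummaryStat) -> tuple[float, float]:
    """Pooled-variance one-way ANOVA F (= pooled t^2) from group summaries.

    Returns (F, partial eta-squared) with eta_p^2 = F / (F + n_a + n_c - 2).
    """
    n_a, n_c = an.n, control.n
    sp2 = ((n_a - 1) * an.sd ** 2 + (n_c - 1) * control.sd ** 2) / (n_a + n_c - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (an.mean - control.mean) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_c))
    f = float(t ** 2)
    return f, f / (f + n_a + n_c - 2)


def rank_transform_panel(
    panel: pd.DataFrame,
    alpha_normality: float = 0.05,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Shapiro-Wilk gated mid-rank transform, per column over the pooled sample.

    Columns whose pooled Shapiro-Wilk p-value falls below ``alpha_normality``
    are replaced by mid-ranks (ties averaged); normal-looking columns pass
    through unchanged. Constant columns are skipped with a warning. Non-listed
    (metadata) columns are untouched.
    """
    out = panel.copy()
    cols = columns if columns is not None else [
        c for c in panel.columns if pd.api.types.is_numeric_dtype(panel[c])]
    for c in cols:
        x = panel[c].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"column {c!r} has fewer than 3 observations")
        if np.allclose(x, x[0]):
            warnings.warn(f"constant column {c!r} skipped by rank transform",
                          stacklevel=2)
            continue
        if sps.shapiro(x).pvalue < alpha_normality:
            out[c] = sps.rankdata(x)
    return out


def _wilks_from_matrices(E: np.ndarray, H: np.ndarray) -> float:
    det_e = np.linalg.det(E)
    det_eh = np.linalg.det(E + H)
    if det_e <= 0 or det_eh <= 0:
        raise np.linalg.LinAlgError("singular error matrix")
    return float(det_e / det_eh)


def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residualize columns of Y on covariates C (with intercept)."""
    X = np.column_stack([np.ones(len(Y)), C])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def manova(
    panel: pd.DataFrame,
    group: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    roi_columns: list[str] | None = None,
    n_comparisons: int | None = None,
) -> ManovaResult:
    """Wilks-lambda MANOVA (or MANCOVA via covariate residualization).

    The hypothesis and error cross-product matrices are formed from the
    group-mean model after residualizing both responses and design on the
    covariates; lambda = |E| / |E + H|, with Rao's F approximation. Partial
    eta-squared is 1 - lambda^(1/s). Univariate pooled-variance F tests per
    column carry Bonferroni-adjusted p-values (default: number of columns).
    """
    cols = roi_columns if roi_columns is not None else [
        c for c in panel.columns if pd.api.types.is_numeric_dtype(panel[c])]
    Y = panel[cols].to_numpy(dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    k = len(levels)
    n, p = Y.shape
    n_cov = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = C.reshape(n, -1)
        keep = [j for j in range(C.shape[1]) if not np.allclose(C[:, j], C[0, j])]
        C = C[:, keep]
        n_cov = C.shape[1]
        if n_cov:
            Y = _residualize(Y, C)
    if n <= p + n_cov + 1:
        raise ValueError("too few observations for the multivariate test")

    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lv in levels:
        Yg = Y[g == lv]
        m = Yg.mean(axis=0)
        d = (m - grand)[:, None]
        H += len(Yg) * (d @ d.T)
        R = Yg - m
        E += R.T @ R
    try:
        lam = _wilks_from_matrices(E, H)
    except np.linalg.LinAlgError:
        bad = [cols[j] for j in range(p) if E[j, j] <= 1e-12]
        raise np.linalg.LinAlgError(
            f"singular error matrix; offending columns: {bad or cols}")

    # Rao's F approximation
    df_h = float(k - 1)
    df_err = n - k - n_cov
    t_ = np.sqrt((p ** 2 * df_h ** 2 - 4) / (p ** 2 + df_h ** 2 - 5)) \
        if (p ** 2 + df_h ** 2 - 5) > 0 else 1.0
    w = df_err + df_h - (p + df_h + 1) / 2.0
    df1 = p * df_h
    df2 = w * t_ - (p * df_h - 2) / 2.0
    lam_t = lam ** (1.0 / t_)
    f_approx = (1 - lam_t) / lam_t * df2 / df1
    p_value = float(sps.f.sf(f_approx, df1, df2))
    s = min(p, k - 1)
    partial_eta2 = float(1.0 - lam ** (1.0 / s))

    n_cmp = n_comparisons if n_comparisons is not None else p
    rows = []
    for j, c in enumerate(cols):
        f_u = (H[j, j] / df_h) / (E[j, j] / df_err)
        p_raw = float(sps.f.sf(f_u, df_h, df_err))
        rows.append({
            "F": float(f_u),
            "p_raw": p_raw,
            "p_bonferroni": min(1.0, p_raw * n_cmp),
            "partial_eta2": float(f_u * df_h / (f_u * df_h + df_err)),
        })
    uni = pd.DataFrame(rows, index=cols)

    return ManovaResult(wilks_lambda=lam, f_approx=float(f_approx),
                        df_h=df1, df_e=float(df2), p_value=p_value,
                        partial_eta2=partial_eta2, univariate=uni)


def spearman_bootstrap(
    x, y, n_boot: int = 1000, seed: int = 0, ci: float = 0.95,
) -> BootstrapCorrelation:
    """Spearman rho with a seeded percentile bootstrap confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input: Spearman rho undefined")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.allclose(xb, xb[0]) or np.allclose(yb, yb[0]):
            boots[b] = np.nan
            continue
        boots[b] = sps.spearmanr(xb, yb).statistic
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    # a degenerate (perfectly monotone) relation bootstraps to itself
    lo, hi = min(lo, rho), max(hi, rho)
    return BootstrapCorrelation(rho=rho, ci_low=float(lo), ci_high=float(hi),
                                p_value=float(res.pvalue), n_boot=n_boot,
                                seed=seed)


def fisher_z_compare(rho1: float, n1: int, rho2: float, n2: int) -> float:
    """Fisher z test for the difference of two independent correlations."""
    for rho in (rho1, rho2):
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both samples")
    return float((np.arctanh(rho1) - np.arctanh(rho2))
                 / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3)))


def bmi_change_rate(delta_percentile: float, days: float) -> float:
    """Age-adjusted BMI percentile change per treatment day."""
    if days <= 0:
        raise ValueError("days must be positive")
    return delta_percentile / days
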