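"""Salivary cortisol: trapezoid area under the curve and its comparisons.

Saliva is sampled three times on the scan morning (before breakfast, after
breakfast, right before imaging); total cortisol output is summarized as the
area under the curve with respect to ground (AUCg) by the trapezoid rule,
compared between groups with Welch t, and correlated with ROI prediction-error
estimates by bootstrap Spearman.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from tastepe.stats import BootstrapCorrelation, spearman_bootstrap

#: default sampling schedule, minutes from the first sample: 30 min before
#: breakfast, 30 min after breakfast, right before imaging.
DEFAULT_SCHEDULE_MIN = (0.0, 60.0, 90.0)


@dataclass(frozen=True)
class CortisolSeries:
    """Three timestamped salivary cortisol concentrations (ug/dL)."""

    times_min: tuple[float, float, float]
    concentrations: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.times_min) != 3 or len(self.concentrations) != 3:
            raise ValueError("cortisol series requires exactly 3 samples")
        if not (self.times_min[0] < self.times_min[1] < self.times_min[2]):
            raise ValueError("timestamps must be strictly increasing")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class AUCResult:
    """Area under the cortisol curve with respect to ground (ug/dL * min)."""

    auc: float
    subject_id: str = ""
    group: str = ""


def auc_trapezoid(series: CortisolSeries, subject_id: str = "",
                  group: str = "") -> AUCResult:
    """AUC with respect to ground by the trapezoid rule over the 3 samples."""
    t = np.asarray(series.times_min, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    return AUCResult(auc=float(np.trapezoid(c, t)), subject_id=subject_id,
                     group=group)


def cortisol_group_compare(auc_an, auc_control) -> tuple[float, float]:
    """Welch t for AUC between groups, contrast control - AN.

    Returns (t, Satterthwaite fractional df); a negative t means cortisol
    output is elevated in the AN group.
    """
    a = np.asarray(auc_an, dtype=float)
    c = np.asarray(auc_control, dtype=float)
    if len(a) < 2 or len(c) < 2:
        raise ValueError("each group needs at least 2 subjects")
    res = sps.ttest_ind(c, a, equal_var=False)
    return float(res.statistic), float(res.df)


def auc_pe_correlation(auc, pe_panel_column, n_boot: int = 1000,
                       seed: int = 0) -> BootstrapCorrelation:
    """Bootstrap Spearman correlation of cortisol AUC with an ROI PE column."""
    auc = np.asarray(auc, dtype=float)
    pe = np.asarray(pe_panel_column, dtype=float)
    if auc.shape != pe.shape:
        raise ValueError("AUC and PE vectors must be paired")
    return spearman_bootstrap(auc, pe, n_boot=n_boot, seed=seed)
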