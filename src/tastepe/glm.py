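"""First-level GLM: canonical HRF, design matrices, OLS fits, ROI panels.

The design follows the convention of event-related model-based fMRI: each CS
condition contributes a boxcar regressor, the absolute prediction error enters
as a mean-centered parametric modulator at taste (US) delivery, every
task regressor carries temporal and dispersion derivatives, slow drifts are
absorbed by a discrete-cosine basis with all periods above a 128-second
cutoff, and the fit is ordinary least squares per ROI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from tastepe.reward_task import CS_TYPES, PETrace, TrialSequence

log = logging.getLogger(__name__)

HRF_TRUNCATE_S = 32.0


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response parameters.

    The kernel is the difference of two gamma densities (peak minus
    undershoot scaled by 1/peak_undershoot_ratio), sampled on a microtime
    grid, truncated at 32 s and normalized to unit peak.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    microtime_dt_s: float = 0.1

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s", "peak_dispersion",
                     "undershoot_dispersion", "peak_undershoot_ratio",
                     "microtime_dt_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DesignMatrix:
    """Named design matrix on the scan grid."""

    matrix: np.ndarray          # n_scans x n_columns
    names: list[str]
    tr_s: float
    n_scans: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class GLMFit:
    """OLS fit for one ROI time series."""

    beta: pd.Series
    sigma2: float
    df_resid: int
    names: list[str]


def _gamma_diff(t: np.ndarray, spec: HRFSpec, dispersion_scale: float = 1.0) -> np.ndarray:
    """Raw (unnormalized) double-gamma evaluated at times t (seconds)."""
    pd_ = spec.peak_dispersion * dispersion_scale
    ud = spec.undershoot_dispersion * dispersion_scale
    # shape/scale parameterization: shape = delay/dispersion, scale = dispersion
    peak = gamma_dist.pdf(t, spec.peak_delay_s / pd_, scale=pd_)
    under = gamma_dist.pdf(t, spec.undershoot_delay_s / ud, scale=ud)
    return peak - under / spec.peak_undershoot_ratio


def canonical_hrf(spec: HRFSpec | None = None,
                  dispersion_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample the canonical HRF on the microtime grid.

    Returns (t, kernel) with the kernel truncated at 32 s and normalized so
    its peak is 1. ``dispersion_scale`` rescales both dispersions and is used
    internally for the dispersion-derivative finite difference.
    """
    if spec is None:
        spec = HRFSpec()
    t = np.arange(0.0, HRF_TRUNCATE_S + spec.microtime_dt_s / 2, spec.microtime_dt_s)
    h = _gamma_diff(t, spec, dispersion_scale)
    peak = np.max(np.abs(h))
    if peak > 0:
        h = h / peak
    return t, h


def _dct_drift_basis(n_scans: int, tr_s: float, hp_cutoff_s: float) -> tuple[np.ndarray, list[str]]:
    """Discrete-cosine drift regressors with all periods > hp_cutoff_s.

    The k-th basis function cos(pi*k*(i+1/2)/N) has period 2*N*TR/k, so k runs
    from 1 to floor(2*N*TR / cutoff).
    """
    total_s = n_scans * tr_s
    n_basis = int(np.floor(2.0 * total_s / hp_cutoff_s))
    i = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (i + 0.5) / n_scans) for k in range(1, n_basis + 1)]
    basis = np.column_stack(cols) if cols else np.empty((n_scans, 0))
    return basis, [f"drift_{k:02d}" for k in range(1, n_basis + 1)]


def _microtime_stick(onsets: np.ndarray, durations: np.ndarray,
                     amplitudes: np.ndarray, n_micro: int, dt: float) -> np.ndarray:
    """Amplitude-weighted boxcar signal on the microtime grid."""
    x = np.zeros(n_micro)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        x[i0:min(i1, n_micro)] += amp
    return x


def build_design_matrix(
    seq: TrialSequence,
    trace: PETrace | None,
    tr_s: float,
    n_scans: int,
    hp_cutoff_s: float = 128.0,
    nuisance: np.ndarray | None = None,
    hrf_spec: HRFSpec | None = None,
) -> DesignMatrix:
    """Build the first-level design matrix on the scan grid.

    Condition boxcars (one per CS type present) and the mean-centered |delta|
    modulator are convolved with the canonical HRF at microtime resolution and
    downsampled to scan onsets. Each convolved task regressor carries a
    temporal derivative (finite difference of the kernel in time) and a
    dispersion derivative (symmetric finite difference in the dispersion
    parameter, +-5%). A DCT drift basis with periods above ``hp_cutoff_s``,
    optional nuisance columns, and an intercept complete the matrix.

    An empty sequence yields drift + intercept (+ nuisance) only. A constant
    |delta| modulator mean-centers to zero and is dropped with a warning.
    """
    if hrf_spec is None:
        hrf_spec = HRFSpec()
    dt = hrf_spec.microtime_dt_s
    total_s = n_scans * tr_s

    trials = list(seq) if len(seq) else []
    if trials:
        last_end = max(t.onset_s + t.duration_s for t in trials)
        if last_end >= total_s:
            raise ValueError(
                f"events extend to {last_end:.1f}s beyond the scan window {total_s:.1f}s")
    if trace is not None and trials and len(trace) != len(trials):
        raise ValueError("trace length does not match sequence length")

    n_micro = int(np.ceil(total_s / dt))
    _, h0 = canonical_hrf(hrf_spec)
    # temporal derivative: backward difference of the kernel, one microtime step
    h_t = np.diff(h0, prepend=0.0) / dt
    # dispersion derivative: symmetric finite difference, +-5% in dispersion
    _, h_plus = canonical_hrf(hrf_spec, dispersion_scale=1.05)
    _, h_minus = canonical_hrf(hrf_spec, dispersion_scale=0.95)
    h_d = (h_plus - h_minus) / 0.1

    scan_idx = np.round(np.arange(n_scans) * tr_s / dt).astype(int)

    cols: list[np.ndarray] = []
    names: list[str] = []

    def add_task_regressor(name: str, signal: np.ndarray) -> None:
        for suffix, kernel in (("", h0), ("_tderiv", h_t), ("_dderiv", h_d)):
            conv = np.convolve(signal, kernel)[:n_micro] * dt
            cols.append(conv[scan_idx])
            names.append(name + suffix)

    if trials:
        onsets = np.array([t.onset_s for t in trials])
        durs = np.array([t.duration_s for t in trials])
        for cs in CS_TYPES:
            mask = np.array([t.cs_type == cs for t in trials])
            if not mask.any():
                continue
            sig = _microtime_stick(onsets[mask], durs[mask],
                                   np.ones(mask.sum()), n_micro, dt)
            add_task_regressor(f"cs_{cs}", sig)
        if trace is not None:
            mod = trace.abs_delta - trace.abs_delta.mean()
            if np.allclose(mod, 0.0):
                warnings.warn("constant |delta| modulator is all zeros after "
                              "mean-centering; dropped", stacklevel=2)
            else:
                sig = _microtime_stick(onsets, durs, mod, n_micro, dt)
                add_task_regressor("pe_mod", sig)

    drift, drift_names = _dct_drift_basis(n_scans, tr_s, hp_cutoff_s)
    for j, nm in enumerate(drift_names):
        cols.append(drift[:, j])
        names.append(nm)

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance matrix must have n_scans rows")
        for j in range(nuisance.shape[1]):
            col = nuisance[:, j]
            if np.allclose(col, col[0]):
                continue  # constant nuisance is the intercept's job
            cols.append(col)
            names.append(f"nuisance_{j:02d}")

    cols.append(np.ones(n_scans))
    names.append("intercept")

    X = np.column_stack(cols)
    return DesignMatrix(matrix=X, names=names, tr_s=tr_s, n_scans=n_scans)


def fit_glm(Y: np.ndarray | pd.DataFrame, X: DesignMatrix) -> list[GLMFit]:
    """Ordinary least squares of each column of Y on the design matrix.

    Returns one GLMFit per ROI column. A rank-deficient design falls back to
    the pseudo-inverse with a logged warning.
    """
    if isinstance(Y, pd.DataFrame):
        roi_names = list(Y.columns)
        Ymat = Y.to_numpy(dtype=float)
    else:
        Ymat = np.atleast_2d(np.asarray(Y, dtype=float))
        if Ymat.shape[0] == 1:
            Ymat = Ymat.T
        roi_names = [f"roi_{j}" for j in range(Ymat.shape[1])]
    if Ymat.shape[0] != X.n_scans:
        raise ValueError("Y row count does not match design n_scans")

    Xm = X.matrix
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        log.warning("design matrix is rank deficient (rank %d < %d columns); "
                    "using pseudo-inverse", rank, Xm.shape[1])
    df_resid = X.n_scans - rank
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    beta, *_ = np.linalg.lstsq(Xm, Ymat, rcond=None)
    resid = Ymat - Xm @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df_resid

    fits = []
    for j, roi in enumerate(roi_names):
        fits.append(GLMFit(beta=pd.Series(beta[:, j], index=X.names, name=roi),
                           sigma2=float(sigma2[j]), df_resid=int(df_resid),
                           names=X.names))
    return fits


def extract_roi_panel(
    subject_fits: dict[str, list[GLMFit]],
    metadata: pd.DataFrame | None = None,
    coef: str = "pe_mod",
    roi_names: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the subjects x ROIs panel of PE parameter estimates.

    ``subject_fits`` maps subject id to the per-ROI fit list; when several
    fits share an ROI label (voxel-level input) their betas are averaged.
    Metadata columns (group, covariates) are joined on subject id.
    """
    rows = {}
    for sid, fits in subject_fits.items():
        by_roi: dict[str, list[float]] = {}
        for fit in fits:
            if coef not in fit.names:
                raise ValueError(f"fit for {fit.beta.name!r} lacks column {coef!r}")
            by_roi.setdefault(str(fit.beta.name), []).append(fit.beta[coef])
        rows[sid] = {roi: float(np.mean(v)) for roi, v in by_roi.items()}
    panel = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    expected = roi_names if roi_names is not None else list(panel.columns)
    absent = set(expected) - set(panel.columns)
    if absent:
        raise ValueError(f"missing ROI estimates: {sorted(absent)}")
    panel = panel[expected]
    if panel.isna().any().any():
        bad = sorted(panel.columns[panel.isna().any()])
        raise ValueError(f"missing ROI estimates: {bad}")

    if metadata is not None:
        panel = panel.join(metadata, how="left")
    panel.index.name = "subject_id"
    return panel
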