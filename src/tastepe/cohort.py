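"""Synthetic cohort generator with known ground truth for every pipeline stage.

Emulates the study cohort the analysis assumes: 56 adolescents with anorexia
nervosa (AN) and 52 matched controls, each with (i) a probabilistic taste
conditioning sequence and its Rescorla-Wagner prediction-error trace, (ii)
ROI BOLD time series at TR 2.1 s built from the convolved design with a
group-specific PE amplitude, AR(1) noise, and slow drift, (iii) trial-wise
activation samples for the 80 expected-sucrose-receipt trials drawn from a
linear non-gaussian structural model whose ventral-striatum/hypothalamus
direction differs by group, (iv) behavioral scales matching the reference
cohort means/SDs and rank-coupled to orbitofrontal PE amplitude, (v)
three-point salivary cortisol with an elevated AN level, and (vi) a
BMI-restoration trajectory for the AN group.

Ground truth (amplitudes, coupling directions, correlation targets) is
recorded so downstream stages can be benchmarked against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from tastepe import datasets
from tastepe.cortisol import DEFAULT_SCHEDULE_MIN, CortisolSeries
from tastepe.glm import HRFSpec, build_design_matrix
from tastepe.reward_task import (RWModel, TrialSequence, compute_pe_trace,
                                 generate_trial_sequence)

#: the 18 reward-circuit ROIs whose PE estimates enter the group analysis
DEFAULT_ROI_NAMES = tuple(datasets.TABLE2.keys())

#: subnetwork entering the effective-connectivity search: bilateral ventral
#: striatum, hypothalamus, inferior/middle OFC, dorsal anterior insula
CONNECTIVITY_ROIS = (
    "ventral_striatum_R", "ventral_striatum_L",
    "hypothalamus_R", "hypothalamus_L",
    "inferior_ofc_R", "inferior_ofc_L",
    "middle_ofc_R", "middle_ofc_L",
    "dorsal_anterior_insula_R", "dorsal_anterior_insula_L",
)

N_EXPECTED_RECEIPT_TRIALS = 80

#: default group-mean PE amplitudes (signal units per unit |delta|, noise_sd
#: = 1). AN amplitudes are elevated most strongly in caudate and accumbens,
#: moderately in ventral striatum and insula, weakly in OFC, matching the
#: reference cohort's effect-size ordering.
_CONTROL_AMP = 0.5
_AN_AMP = {
    "caudate_head_R": 1.00, "caudate_head_L": 1.00,
    "nucleus_accumbens_R": 0.95, "nucleus_accumbens_L": 0.95,
    "ventral_striatum_R": 0.80, "ventral_striatum_L": 0.80,
    "ventral_anterior_insula_R": 0.85, "ventral_anterior_insula_L": 0.60,
    "dorsal_anterior_insula_R": 0.72, "dorsal_anterior_insula_L": 0.65,
    "inferior_ofc_R": 0.72, "inferior_ofc_L": 0.62,
    "medial_ofc_R": 0.68, "medial_ofc_L": 0.65,
    "middle_ofc_R": 0.62, "middle_ofc_L": 0.60,
    "gyrus_rectus_R": 0.70, "gyrus_rectus_L": 0.60,
}


def default_pe_amplitude() -> dict[tuple[str, str], float]:
    amp = {}
    for roi in DEFAULT_ROI_NAMES:
        amp[("control", roi)] = _CONTROL_AMP
        amp[("AN", roi)] = _AN_AMP[roi]
    return amp


def default_behavior_targets() -> dict[str, dict[str, tuple[float, float]]]:
    """Behavioral scale (mean, sd) per group from the reference cohort table."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for scale, (an, ctl, _t) in datasets.TABLE1.items():
        out[scale] = {"AN": (an.mean, an.sd), "control": (ctl.mean, ctl.sd)}
    return out


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic cohort."""

    n_an: int = 56
    n_control: int = 52
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    connectivity_rois: tuple[str, ...] = CONNECTIVITY_ROIS
    pe_amplitude: dict = field(default_factory=default_pe_amplitude)
    amplitude_subject_sd: float = 0.45
    cond_amplitude: float = 1.0
    coupling_direction: dict = field(default_factory=lambda: {
        "AN": "vs_to_hyp", "control": "hyp_to_vs"})
    coupling_strength: float = 0.8
    innovation_dist: str = "uniform"
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    behavior_targets: dict = field(default_factory=default_behavior_targets)
    behavior_pe_rho: float = 0.33
    bmi_pe_rho: float = -0.35
    cortisol_an_shift: float = 0.07
    tr_s: float = 2.1
    n_scans: int = 300
    n_trials_per_cs: int = 16
    p_violation: float = 0.2
    alpha: float = 0.7
    v0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_an < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in [0, 1)")
        if not np.isfinite(self.coupling_strength):
            raise ValueError("coupling_strength must be finite")
        known = set(self.roi_names)
        for key in self.pe_amplitude:
            if key[1] not in known:
                raise ValueError(f"unknown ROI in pe_amplitude: {key[1]!r}")


@dataclass
class SubjectRecord:
    """One simulated subject with ground-truth annotations."""

    subject_id: str
    group: str
    trial_sequence: TrialSequence
    roi_timeseries: pd.DataFrame          # scans x ROIs
    trial_samples: pd.DataFrame           # expected-receipt trials x connectivity ROIs
    behavior: dict[str, float]
    cortisol: CortisolSeries
    bmi_percentile_change: float
    treatment_days: float
    true_amplitude: dict[str, float]      # ground-truth PE amplitude per ROI
    seed: int


def _innovations(rng: np.random.Generator, dist: str, size) -> np.ndarray:
    """Unit-variance innovations of the requested family."""
    if dist == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=size)
    if dist == "laplace":
        return rng.laplace(scale=1.0 / np.sqrt(2.0), size=size)
    if dist == "gaussian":
        return rng.standard_normal(size=size)
    raise ValueError(f"unknown innovation distribution {dist!r}")


def simulate_trial_samples(
    direction: str,
    strength: float,
    n_trials: int = N_EXPECTED_RECEIPT_TRIALS,
    innovation_dist: str = "uniform",
    seed: int = 0,
) -> np.ndarray:
    """Two-variable linear structural model: columns (ventral striatum, hypothalamus).

    The child equals ``strength`` times the parent plus an independent
    unit-variance innovation; the parent is exogenous. With gaussian
    innovations the direction is not identifiable and a warning is raised.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    if direction not in ("vs_to_hyp", "hyp_to_vs"):
        raise ValueError(f"unknown direction {direction!r}")
    if innovation_dist == "gaussian":
        warnings.warn("gaussian innovations make the orientation "
                      "unidentifiable", stacklevel=2)
    rng = np.random.default_rng(seed)
    e = _innovations(rng, innovation_dist, (n_trials, 2))
    parent = e[:, 0]
    child = strength * parent + e[:, 1]
    if direction == "vs_to_hyp":
        return np.column_stack([parent, child])
    return np.column_stack([child, parent])


def simulate_cortisol(
    group: str,
    seed: int = 0,
    schedule_min: tuple[float, float, float] = DEFAULT_SCHEDULE_MIN,
    base_profile: tuple[float, float, float] = (0.35, 0.30, 0.25),
    an_shift: float = 0.07,
    level_sd: float = 0.08,
    point_sd: float = 0.05,
) -> CortisolSeries:
    """Three-point morning salivary cortisol (ug/dL) for one subject.

    The profile declines across the morning; a subject-level random effect
    (``level_sd``) dominates point-to-point assay noise (``point_sd``), and
    the AN group is shifted upward by ``an_shift``.
    """
    rng = np.random.default_rng(seed)
    level = rng.normal(0.0, level_sd) + (an_shift if group == "AN" else 0.0)
    conc = np.asarray(base_profile) + level + rng.normal(0.0, point_sd, size=3)
    conc = np.clip(conc, 0.005, None)
    return CortisolSeries(times_min=tuple(schedule_min),
                          concentrations=tuple(float(c) for c in conc))


def _ar1_noise(rng: np.random.Generator, phi: float, sd: float,
               shape: tuple[int, int]) -> np.ndarray:
    """AR(1) noise with stationary marginal standard deviation ``sd``."""
    w = rng.standard_normal(shape) * sd * np.sqrt(1.0 - phi ** 2)
    return lfilter([1.0], [1.0, -phi], w, axis=0)


def _simulate_subject(
    sid: str, group: str, spec: CohortSpec, rng: np.random.Generator,
    seed: int, z_common: float, z_roi: dict[str, float],
) -> SubjectRecord:
    seq = generate_trial_sequence(
        spec.n_trials_per_cs, spec.n_trials_per_cs, spec.n_trials_per_cs,
        p_violation=spec.p_violation, seed=int(rng.integers(2 ** 31)))
    trace = compute_pe_trace(seq, RWModel(alpha=spec.alpha, v0=spec.v0))
    X = build_design_matrix(seq, trace, tr_s=spec.tr_s, n_scans=spec.n_scans)
    pe_col = X.column("pe_mod")
    cond_cols = sum(X.column(f"cs_{c}") for c in ("sucrose", "no_solution", "saliva"))

    # per-ROI true amplitude: group mean + subject deviation (shared factor
    # plus ROI-specific part), shared factor carries the behavior couplings
    amp = {}
    w = 0.5
    for roi in spec.roi_names:
        mean = spec.pe_amplitude[(group, roi)]
        dev = spec.amplitude_subject_sd * (
            np.sqrt(w) * z_common + np.sqrt(1 - w) * z_roi[roi])
        amp[roi] = mean + dev

    noise = _ar1_noise(rng, spec.ar1_phi, spec.noise_sd,
                       (spec.n_scans, len(spec.roi_names)))
    t = np.arange(spec.n_scans) / spec.n_scans
    drift = np.outer(np.cos(np.pi * t * rng.uniform(0.5, 1.5)),
                     rng.normal(0.0, spec.drift_amplitude, len(spec.roi_names)))
    signal = np.column_stack([
        amp[roi] * pe_col + spec.cond_amplitude * cond_cols
        for roi in spec.roi_names])
    ts = pd.DataFrame(signal + noise + drift, columns=list(spec.roi_names))

    # trial samples for the 80 expected sucrose receipts: SEM over the
    # connectivity subnetwork, VS->HYP (or reverse) per hemisphere
    n_tr = N_EXPECTED_RECEIPT_TRIALS
    direction = spec.coupling_direction[group]
    samples = {}
    for hemi in ("R", "L"):
        mat = simulate_trial_samples(direction, spec.coupling_strength, n_tr,
                                     spec.innovation_dist,
                                     seed=int(rng.integers(2 ** 31)))
        samples[f"ventral_striatum_{hemi}"] = mat[:, 0]
        samples[f"hypothalamus_{hemi}"] = mat[:, 1]
    for roi in spec.connectivity_rois:
        if roi not in samples:
            samples[roi] = _innovations(rng, spec.innovation_dist, n_tr)
    trial_samples = pd.DataFrame(
        {roi: samples[roi] for roi in spec.connectivity_rois})

    # behavior: target marginals per group; harm avoidance rank-coupled to
    # the gyrus-rectus amplitude deviation via a gaussian copula
    z_rectus = (amp["gyrus_rectus_R"] - spec.pe_amplitude[(group, "gyrus_rectus_R")]) \
        / spec.amplitude_subject_sd
    behavior = {}
    for scale, targets in spec.behavior_targets.items():
        mean, sd = targets[group]
        if scale == "harm_avoidance":
            r = spec.behavior_pe_rho
            z = r * z_rectus + np.sqrt(1 - r ** 2) * rng.standard_normal()
        else:
            z = rng.standard_normal()
        behavior[scale] = mean + sd * z

    cort = simulate_cortisol(group, seed=int(rng.integers(2 ** 31)),
                             an_shift=spec.cortisol_an_shift)

    if group == "AN":
        r = spec.bmi_pe_rho
        z = r * z_common + np.sqrt(1 - r ** 2) * rng.standard_normal()
        bmi_change = datasets.BMI_PERCENTILE_CHANGE.mean \
            + datasets.BMI_PERCENTILE_CHANGE.sd * z
        days = max(7.0, datasets.TREATMENT_DAYS.mean
                   + datasets.TREATMENT_DAYS.sd * rng.standard_normal())
    else:
        bmi_change, days = float("nan"), float("nan")

    return SubjectRecord(
        subject_id=sid, group=group, trial_sequence=seq, roi_timeseries=ts,
        trial_samples=trial_samples, behavior=behavior, cortisol=cort,
        bmi_percentile_change=float(bmi_change), treatment_days=float(days),
        true_amplitude=amp, seed=seed)


def simulate_cohort(spec: CohortSpec | None = None) -> list[SubjectRecord]:
    """Simulate the full two-group cohort; reproducible from (spec, seed)."""
    if spec is None:
        spec = CohortSpec()
    master = np.random.SeedSequence(spec.seed)
    groups = ["AN"] * spec.n_an + ["control"] * spec.n_control
    children = master.spawn(len(groups))
    records = []
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        z_common = rng.standard_normal()
        z_roi = {roi: rng.standard_normal() for roi in spec.roi_names}
        sid = f"{'an' if group == 'AN' else 'hc'}{i:03d}"
        records.append(_simulate_subject(sid, group, spec, rng,
                                         seed=spec.seed, z_common=z_common,
                                         z_roi=z_roi))
    return records


def cohort_manifest(spec: CohortSpec, records: list[SubjectRecord]) -> dict:
    """JSON-serializable manifest: spec echo, group labels, conventions."""
    spec_dict = asdict(spec)
    spec_dict["pe_amplitude"] = {f"{g}:{r}": v
                                 for (g, r), v in spec.pe_amplitude.items()}
    return {
        "spec": spec_dict,
        "subjects": [{"subject_id": r.subject_id, "group": r.group}
                     for r in records],
        "trial_sample_convention": "direct-sem",  # samples drawn from the
        # structural model directly, not re-extracted from the BOLD series
        "n_expected_receipt_trials": N_EXPECTED_RECEIPT_TRIALS,
    }


def write_cohort(records: list[SubjectRecord], spec: CohortSpec,
                 out_dir: str | Path) -> Path:
    """Write per-subject ROI time-series CSVs and the cohort manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        rec.roi_timeseries.to_csv(out / f"{rec.subject_id}_timeseries.csv",
                                  index=False)
    manifest = cohort_manifest(spec, records)
    with open(out / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
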