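"""End-to-end pipeline: simulate -> PE model -> GLM -> panel -> group stats ->
connectivity -> cortisol, as one seeded, configured, logged run.

Every output is re-derivable from (config, seed): the single run seed fans
out to per-stage child seeds through ``numpy.random.SeedSequence`` spawning,
and the run manifest records the configuration echo, stage seeds, and the
headline metrics (caudate group F, ventral-striatum/hypothalamus direction
per group, cortisol t).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tastepe import datasets
from tastepe.cohort import (CONNECTIVITY_ROIS, CohortSpec, SubjectRecord,
                            cohort_manifest, simulate_cohort)
from tastepe.connectivity import (ROISampleSet, estimate_edge_coefficients,
                                  images_search, orient_fixed_structure)
from tastepe.cortisol import auc_trapezoid, cortisol_group_compare
from tastepe.glm import build_design_matrix, extract_roi_panel, fit_glm
from tastepe.reward_task import RWModel, compute_pe_trace, write_events_tsv
from tastepe.stats import (bmi_change_rate, manova, rank_transform_panel,
                           spearman_bootstrap, welch_t_from_summary)

log = logging.getLogger(__name__)

_pkg_version = "0.1.0"


@dataclass
class PipelineConfig:
    """Run configuration: cohort spec plus analysis knobs."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    hp_cutoff_s: float = 128.0
    penalty_discount: float = 1.0
    orientation_rule: str = "entropy_lr"
    connectivity_rois: tuple[str, ...] = CONNECTIVITY_ROIS
    alpha_normality: float = 0.05
    n_boot: int = 1000
    output_dir: str = "tastepe_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hp_cutoff_s <= 0:
            raise ValueError("invalid config field hp_cutoff_s: must be > 0")
        if self.penalty_discount <= 0:
            raise ValueError("invalid config field penalty_discount: must be > 0")
        if self.orientation_rule not in ("entropy_lr", "skew"):
            raise ValueError("invalid config field orientation_rule")
        if self.n_boot < 1:
            raise ValueError("invalid config field n_boot: must be >= 1")
        self.cohort.seed = self.seed

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None,
                  output_dir: str | None = None) -> "PipelineConfig":
        """Load a YAML or JSON config; CLI overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_kwargs = raw.pop("cohort", {})
        if "pe_amplitude" in cohort_kwargs:
            cohort_kwargs["pe_amplitude"] = {
                tuple(k.split(":")): v
                for k, v in cohort_kwargs["pe_amplitude"].items()}
        for tup_field in ("roi_names", "connectivity_rois"):
            if tup_field in cohort_kwargs:
                cohort_kwargs[tup_field] = tuple(cohort_kwargs[tup_field])
        if "connectivity_rois" in raw:
            raw["connectivity_rois"] = tuple(raw["connectivity_rois"])
        if seed is not None:
            raw["seed"] = seed
        if output_dir is not None:
            raw["output_dir"] = output_dir
        try:
            cohort = CohortSpec(**cohort_kwargs)
            return cls(cohort=cohort, **raw)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc


def fit_cohort_panel(records: list[SubjectRecord], spec: CohortSpec,
                     hp_cutoff_s: float = 128.0) -> pd.DataFrame:
    """First-level GLM for every subject; returns the subjects x ROIs panel.

    Rebuilds each subject's design from their trial sequence and
    Rescorla-Wagner trace, fits OLS to the ROI time series, and extracts the
    |delta| parametric-modulator betas with group metadata attached.
    """
    fits = {}
    meta = {}
    for rec in records:
        trace = compute_pe_trace(rec.trial_sequence,
                                 RWModel(alpha=spec.alpha, v0=spec.v0))
        X = build_design_matrix(rec.trial_sequence, trace, tr_s=spec.tr_s,
                                n_scans=spec.n_scans, hp_cutoff_s=hp_cutoff_s)
        fits[rec.subject_id] = fit_glm(rec.roi_timeseries, X)
        meta[rec.subject_id] = {"group": rec.group}
    metadata = pd.DataFrame.from_dict(meta, orient="index")
    return extract_roi_panel(fits, metadata=metadata,
                             roi_names=list(spec.roi_names))


def group_connectivity(records: list[SubjectRecord], group: str,
                       rois=CONNECTIVITY_ROIS, penalty_discount: float = 1.0,
                       rule: str = "entropy_lr"):
    """Search + orient + coefficients for one group's trial samples."""
    members = [r for r in records if r.group == group]
    samples = ROISampleSet.from_records(members, rois=list(rois))
    cpdag = images_search(samples, penalty_discount=penalty_discount)
    directed = orient_fixed_structure(samples, cpdag, rule=rule)
    coefs = estimate_edge_coefficients(samples, directed)
    return samples, directed, coefs


def vs_hyp_direction(graph, hemi: str = "R") -> str:
    """'vs_to_hyp', 'hyp_to_vs', 'undirected', or 'absent'."""
    vs, hyp = f"ventral_striatum_{hemi}", f"hypothalamus_{hemi}"
    state = graph.edge_orientation(vs, hyp)
    if state is None:
        return "absent"
    if state == "undirected":
        return "undirected"
    return "vs_to_hyp" if state == f"{vs}->{hyp}" else "hyp_to_vs"


def _table1_report(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    scales = records[0].behavior.keys()
    for scale in scales:
        an = np.array([r.behavior[scale] for r in records if r.group == "AN"])
        ctl = np.array([r.behavior[scale] for r in records if r.group == "control"])
        from tastepe.stats import SummaryStat
        s_an = SummaryStat(len(an), float(an.mean()), float(an.std(ddof=1)))
        s_ctl = SummaryStat(len(ctl), float(ctl.mean()), float(ctl.std(ddof=1)))
        t, df = welch_t_from_summary(s_ctl, s_an)
        rows.append({"scale": scale, "an_mean": s_an.mean, "an_sd": s_an.sd,
                     "control_mean": s_ctl.mean, "control_sd": s_ctl.sd,
                     "t": t, "df": df})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | None = None,
                 stages: tuple[str, ...] = ("simulate", "fit", "stats",
                                            "connect", "cortisol", "report"),
                 ) -> dict:
    """Execute the pipeline and write report tables; returns the run manifest."""
    if config is None:
        config = PipelineConfig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(("bootstrap", "cortisol_boot"),
                                      seed_seq.spawn(2))}
    manifest: dict = {
        "version": _pkg_version,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "outputs": {},
        "headline": {},
        "completed_stages": [],
    }

    def record_output(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    log.info("simulating cohort (seed %d)", config.seed)
    records = simulate_cohort(config.cohort)

    if "simulate" in stages:
        cm = cohort_manifest(config.cohort, records)
        with open(out / "cohort_manifest.json", "w") as fh:
            json.dump(cm, fh, indent=2, default=str)
        record_output("cohort_manifest", out / "cohort_manifest.json")
        rec0 = records[0]
        trace0 = compute_pe_trace(rec0.trial_sequence,
                                  RWModel(alpha=config.cohort.alpha,
                                          v0=config.cohort.v0))
        write_events_tsv(out / f"{rec0.subject_id}_events.tsv",
                         rec0.trial_sequence, trace0)
        record_output("example_events", out / f"{rec0.subject_id}_events.tsv")
        manifest["completed_stages"].append("simulate")

    panel = None
    if {"fit", "stats", "cortisol"} & set(stages):
        log.info("fitting first-level GLMs for %d subjects", len(records))
        panel = fit_cohort_panel(records, config.cohort,
                                 hp_cutoff_s=config.hp_cutoff_s)
        if "fit" in stages:
            panel.to_csv(out / "roi_panel.csv")
            with open(out / "roi_panel.json", "w") as fh:
                json.dump({"coefficient": "pe_mod",
                           "rois": list(config.cohort.roi_names),
                           "groups": {"AN": config.cohort.n_an,
                                      "control": config.cohort.n_control}},
                          fh, indent=2)
            record_output("roi_panel", out / "roi_panel.csv")
            manifest["completed_stages"].append("fit")

    if "stats" in stages and panel is not None:
        log.info("group statistics")
        roi_cols = list(config.cohort.roi_names)
        ranked = rank_transform_panel(panel, config.alpha_normality,
                                      columns=roi_cols)
        res = manova(ranked, ranked["group"], roi_columns=roi_cols)
        t2 = res.univariate.copy()
        for grp, prefix in (("AN", "an"), ("control", "control")):
            sub = ranked.loc[ranked["group"] == grp, roi_cols]
            t2[f"{prefix}_mean"] = sub.mean()
            t2[f"{prefix}_sd"] = sub.std(ddof=1)
        t2.index.name = "roi"
        t2.to_csv(out / "table2_report.csv")
        record_output("table2_report", out / "table2_report.csv")

        t1 = _table1_report(records)
        t1.to_csv(out / "table1_report.csv", index=False)
        record_output("table1_report", out / "table1_report.csv")

        # correlation analyses on the AN group
        an = panel[panel["group"] == "AN"]
        an_records = [r for r in records if r.group == "AN"]
        ha = [r.behavior["harm_avoidance"] for r in an_records]
        rate = [bmi_change_rate(r.bmi_percentile_change, r.treatment_days)
                for r in an_records]
        corr_rows = []
        boot_seed = stage_seeds["bootstrap"]
        for name, x, y in (
            ("harm_avoidance~gyrus_rectus_R", ha, an["gyrus_rectus_R"]),
            ("bmi_rate~inferior_ofc_R", rate, an["inferior_ofc_R"]),
            ("bmi_rate~dorsal_anterior_insula_R", rate,
             an["dorsal_anterior_insula_R"]),
        ):
            bc = spearman_bootstrap(np.asarray(x), np.asarray(y),
                                    n_boot=config.n_boot, seed=boot_seed)
            corr_rows.append({"pair": name, "rho": bc.rho, "ci_low": bc.ci_low,
                              "ci_high": bc.ci_high, "n_boot": bc.n_boot,
                              "seed": bc.seed})
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)
        record_output("correlations", out / "correlations.csv")

        manifest["headline"].update({
            "wilks_lambda": res.wilks_lambda,
            "partial_eta2": res.partial_eta2,
            "caudate_R_F": float(res.univariate.loc["caudate_head_R", "F"]),
            "caudate_R_p_bonferroni": float(
                res.univariate.loc["caudate_head_R", "p_bonferroni"]),
        })
        manifest["completed_stages"].append("stats")

    if "connect" in stages:
        log.info("effective connectivity search per group")
        edge_tables = []
        coef_tables = []
        for group in ("AN", "control"):
            _, graph, coefs = group_connectivity(
                records, group, rois=config.connectivity_rois,
                penalty_discount=config.penalty_discount,
                rule=config.orientation_rule)
            tab = graph.to_edge_table()
            tab.insert(0, "group", group)
            tab["pooled_score"] = graph.score
            edge_tables.append(tab)
            coefs = coefs.copy()
            coefs.insert(0, "search_group", group)
            coef_tables.append(coefs)
            manifest["headline"][f"vs_hyp_direction_{group}_R"] = \
                vs_hyp_direction(graph, "R")
            manifest["headline"][f"vs_hyp_direction_{group}_L"] = \
                vs_hyp_direction(graph, "L")
        pd.concat(edge_tables).to_csv(out / "connectivity_edges.tsv",
                                      sep="\t", index=False)
        record_output("connectivity_edges", out / "connectivity_edges.tsv")
        pd.concat(coef_tables).to_csv(out / "edge_coefficients.csv")
        record_output("edge_coefficients", out / "edge_coefficients.csv")
        manifest["completed_stages"].append("connect")

    if "cortisol" in stages and panel is not None:
        log.info("cortisol AUC analysis")
        an_records = [r for r in records if r.group == "AN"]
        ctl_records = [r for r in records if r.group == "control"]
        sub_an = an_records[:datasets.N_CORTISOL_AN]
        sub_ctl = ctl_records[:datasets.N_CORTISOL_CONTROL]
        rows = []
        for r in sub_an + sub_ctl:
            rows.append({"subject_id": r.subject_id, "group": r.group,
                         "auc": auc_trapezoid(r.cortisol, r.subject_id,
                                              r.group).auc})
        cort = pd.DataFrame(rows)
        t, df = cortisol_group_compare(
            cort.loc[cort["group"] == "AN", "auc"],
            cort.loc[cort["group"] == "control", "auc"])
        cort.to_csv(out / "cortisol.csv", index=False)
        record_output("cortisol", out / "cortisol.csv")
        bc = spearman_bootstrap(
            cort.loc[cort["group"] == "AN", "auc"].to_numpy(),
            panel.loc[[r.subject_id for r in sub_an], "caudate_head_R"].to_numpy(),
            n_boot=config.n_boot, seed=stage_seeds["cortisol_boot"])
        manifest["headline"].update({
            "cortisol_t": t, "cortisol_df": df,
            "cortisol_caudate_rho": bc.rho,
        })
        manifest["completed_stages"].append("cortisol")

    if "report" in stages:
        cfg = asdict(config)
        cfg["cohort"]["pe_amplitude"] = {
            f"{g}:{r}": v for (g, r), v in config.cohort.pe_amplitude.items()}
        manifest["config"] = cfg
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        record_output("run_manifest", out / "run_manifest.json")
        manifest["completed_stages"].append("report")

    return manifest
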