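"""End-to-end orchestration: cohort -> kinetics -> risk score -> response ->
survival models -> risk tree -> report bundle.

Two run modes mirror the two cohort designs:

* ``historical`` — untreated reference cohort (two scans per patient).  Only
  the pre-treatment kinetics window exists; the stage list is kinetics ->
  lethal-threshold calibration -> Cox on the risk score.  Treatment-dependent
  stages (initial-response window, response classification, multistate
  models) are skipped.
* ``braf`` — treated cohort with delayed entry at the first on-treatment
  evaluation; all stages run, using a lethal threshold supplied in the
  config (typically the one calibrated on a historical run).

Every artifact is a pure function of (inputs, config, seed); the resolved
configuration is serialized into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io
from . import kinetics as kin
from . import lethal_burden as lb_mod
from . import response as resp_mod
from . import survival as surv
from . import tree as tree_mod
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    mode: str = "braf"  # "braf" or "historical"
    outdir: str = "metkin_run"
    seed: int = 0
    #: either a simulation block ...
    simulation: SimulationConfig | None = None
    #: ... or input CSV paths
    measurements_path: str | None = None
    metadata_path: str | None = None
    dialect_path: str | None = None
    #: analysis parameters
    v_lethal: float = 1200.0            # used in braf mode
    calibration_grid: tuple = (100.0, 10_000.0, 60)  # historical mode: lo, hi, n
    stable_band: float = 0.05
    missing_policy: str = "floor"
    tree_control: tree_mod.TreeControl = field(default_factory=tree_mod.TreeControl)
    log_level: str = "INFO"

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("load")
def _load(cfg: RunConfig):
    if cfg.simulation is not None:
        sim = simulate_cohort(cfg.simulation)
        return sim.measurements, sim.metadata
    if cfg.measurements_path is None:
        raise ValueError("config needs either a simulation block or input paths")
    dialect = cohort_io.Dialect.from_yaml(cfg.dialect_path) if cfg.dialect_path else None
    df, _ = cohort_io.read_cohort(cfg.measurements_path, None, dialect,
                                  historical=cfg.mode == "historical")
    meta = pd.read_csv(cfg.metadata_path) if cfg.metadata_path else None
    return df, meta


def _patient_frame(profiles: pd.DataFrame, timelines, assessments: pd.DataFrame | None,
                   v_lethal: float) -> pd.DataFrame:
    """One row per patient: outcome, entry, risk score and candidate covariates."""
    bl = profiles[profiles["window"] == "BL"].set_index("patient_id")
    ir = profiles[profiles["window"] == "IR"].set_index("patient_id") if "IR" in set(profiles["window"]) else None
    rows = []
    for pid, tl in timelines.items():
        if pid not in bl.index or tl.event_time is None:
            continue
        b = bl.loc[pid]
        row = {
            "patient_id": pid, "time": tl.event_time, "event": tl.event or 0,
            "entry": tl.ir if tl.ir is not None else (tl.bl or 0.0),
            "v_bl": b["v2_global"], "aexp_global": b["aexp_global"],
            "lb": lb_mod.lb_score(b["v2_global"], b["aexp_global"], v_lethal),
            "rvc_range_bl": b["rvc_range"],
        }
        if ir is not None and pid in ir.index:
            row["rvc_range_ir"] = ir.loc[pid, "rvc_range"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if assessments is not None and len(assessments):
        a = assessments.set_index("patient_id")
        df["recist_pd"] = df["patient_id"].map(
            (a["recist_category"] == "PD").astype(int)).fillna(0).astype(int)
        df["new_lesions"] = df["patient_id"].map(
            (a["new_lesions"].astype(str).str.len() > 0).astype(int)).fillna(0).astype(int)
        df["mixed_response"] = df["patient_id"].map(
            a["mixed_response"].astype(int)).fillna(0).astype(int)
    return df


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages for one cohort; returns a dict of artifact paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    cfg.to_yaml(outdir / "run_config.yaml")
    artifacts = {"config": outdir / "run_config.yaml"}
    report = [f"# Kinetics analysis report ({cfg.mode} mode)", ""]

    measurements, metadata = _load(cfg)
    historical = cfg.mode == "historical"
    timelines = cohort_io.build_timelines(measurements, metadata, historical=historical)
    report += [f"Patients with anchored timelines: {len(timelines)}",
               f"Lesion-scan rows: {len(measurements)}", ""]

    # --- kinetics -----------------------------------------------------------
    try:
        windows = ("BL",) if historical else ("BL", "IR")
        profiles = kin.cohort_kinetics(measurements, timelines, windows, cfg.missing_policy)
    except Exception as exc:
        raise PipelineError("kinetics", exc) from exc
    artifacts["kinetics"] = outdir / "kinetics.csv"
    profiles.to_csv(artifacts["kinetics"], index=False)
    report += [f"Kinetics profiles: {len(profiles)} (windows: {', '.join(windows)})", ""]

    assessments = None
    if not historical:
        try:
            assessments = resp_mod.cohort_response(measurements, timelines)
        except Exception as exc:
            raise PipelineError("response", exc) from exc
        artifacts["response"] = outdir / "response.csv"
        assessments.to_csv(artifacts["response"], index=False)
        if len(assessments):
            n_pd = int((assessments["recist_category"] == "PD").sum())
            report += [f"First-assessment PD: {n_pd}/{len(assessments)}", ""]

    # --- lethal burden ------------------------------------------------------
    try:
        patients = _patient_frame(profiles, timelines, assessments, cfg.v_lethal)
        if historical:
            lo, hi, n = cfg.calibration_grid
            model = lb_mod.calibrate_vlethal(patients.dropna(subset=["aexp_global"]),
                                             grid=lb_mod.default_grid(lo, hi, int(n)))
            patients["lb"] = model.scores(patients["v_bl"], patients["aexp_global"])
            artifacts["lethal_burden"] = outdir / "lethal_burden.json"
            model.to_json(artifacts["lethal_burden"])
            artifacts["calibration_trace"] = outdir / "calibration_trace.csv"
            model.trace.to_csv(artifacts["calibration_trace"], index=False)
            report += [f"Calibrated V_lethal: {model.v_lethal:.0f} cm^3 "
                       f"({model.criterion})", ""]
    except Exception as exc:
        raise PipelineError("lethal_burden", exc) from exc
    artifacts["patients"] = outdir / "patients.csv"
    patients.to_csv(artifacts["patients"], index=False)

    # --- Cox screen ---------------------------------------------------------
    try:
        if historical:
            covs = ["lb"]
            anchor = None
        else:
            covs = [c for c in ("lb", "rvc_range_bl", "rvc_range_ir",
                                "new_lesions", "mixed_response") if c in patients.columns]
            anchor = "recist_pd" if "recist_pd" in patients.columns else None
        screen_df = patients.dropna(subset=[c for c in covs])
        screen = surv.covariate_screen(screen_df, covs, entry_col="entry", anchor=anchor)
        artifacts["cox_screen"] = outdir / "cox_screen.csv"
        screen["table"].to_csv(artifacts["cox_screen"], index=False)
        artifacts["cox_joint"] = outdir / "cox_joint.csv"
        screen["joint"].summary().to_csv(artifacts["cox_joint"])
        report += ["## Cox screen", screen["table"].to_string(index=False), "",
                   f"Selected after de-duplication: {screen['selected']}", ""]
    except Exception as exc:
        raise PipelineError("cox", exc) from exc

    # --- multistate + tree + post-treatment (braf only) ---------------------
    if not historical:
        try:
            brain_onset = {}
            for pid, tl in timelines.items():
                sub = measurements[(measurements["patient_id"] == pid)
                                   & (measurements["organ"] == "brain")]
                if len(sub):
                    brain_onset[pid] = float(sub["time"].min())
            ms = patients.copy()
            ms["brain_time"] = ms["patient_id"].map(brain_onset)
            if assessments is not None and len(assessments):
                pd_time = assessments[assessments["recist_category"] == "PD"] \
                    .set_index("patient_id")["assessment_time"]
                ms["pd_time"] = ms["patient_id"].map(pd_time)
            else:
                ms["pd_time"] = np.nan
            for name in ("brain", "recist"):
                # the PD flag defines the recist model's intermediate state,
                # so it enters only the brain model
                allowed = ("rvc_range_ir", "recist_pd") if name == "brain" else ("rvc_range_ir",)
                covs_ms = [c for c in allowed if c in ms.columns]
                tdf = surv.build_transition_dataset(ms.dropna(subset=covs_ms),
                                                    model=name, covariates=covs_ms)
                if len(tdf) and tdf["status"].sum() >= 3:
                    # small cohorts: effects only on transitions with enough
                    # events, light ridge to stabilise near-separation
                    fitres = surv.fit_multistate(tdf, min_events=5, penalizer=0.05)
                    artifacts[f"multistate_{name}"] = outdir / f"multistate_{name}.csv"
                    fitres["effects"].to_csv(artifacts[f"multistate_{name}"], index=False)
                    report += [f"## Multistate ({name})",
                               fitres["effects"].to_string(index=False), ""]
                else:
                    logger.warning("multistate %s skipped: too few events", name)
        except Exception as exc:
            raise PipelineError("multistate", exc) from exc

        try:
            tree_covs = [c for c in ("lb", "rvc_range_bl", "rvc_range_ir", "recist_pd")
                         if c in patients.columns]
            tdata = patients.dropna(subset=tree_covs)
            if len(tdata) >= cfg.tree_control.min_split and tdata["event"].sum() > 0:
                rtree = tree_mod.fit_risk_tree(tdata, tree_covs, cfg.tree_control,
                                               seed=cfg.seed, entry_col="entry")
                artifacts["tree"] = outdir / "risk_tree.json"
                rtree.to_json(artifacts["tree"])
                report += ["## Relative-risk tree", "```", rtree.render(), "```", ""]
            else:
                logger.warning("risk tree skipped: cohort too small")
        except Exception as exc:
            raise PipelineError("tree", exc) from exc

        try:
            comp = kin.post_treatment_comparison(measurements, timelines, cfg.stable_band)
            artifacts["post_treatment"] = outdir / "post_treatment_comparison.csv"
            comp.to_csv(artifacts["post_treatment"], index=False)
            if len(comp):
                for col in ("global_rate", "mean_rate", "range_rate"):
                    counts = comp[col].value_counts().to_dict()
                    report.append(f"Post-discontinuation {col}: {counts}")
                report.append("")
        except Exception as exc:
            raise PipelineError("post_treatment", exc) from exc

    artifacts["report"] = outdir / "report.md"
    Path(artifacts["report"]).write_text("\n".join(report))
    return artifacts
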