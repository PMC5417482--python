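"""Synthetic cohort generator for metastatic growth-kinetics analyses.

The generative model mirrors the structure the analysis assumes:

* each patient carries several metastases with lesion-specific exponential
  growth rates drawn around a patient-level mean (inter-lesion heterogeneity);
* a targeted therapy multiplies each lesion's rate by a lesion-specific
  effect at treatment start (a negative product = response; the spread of the
  effect encodes heterogeneous resistance);
* responding lesions may revert to regrowth after an exponentially
  distributed resistance delay, and all lesions rebound after treatment
  discontinuation with lesion-specific rebound factors;
* a patient dies when the summed lesion volume first crosses a lethal burden
  threshold (evaluated on a fine time grid); survivors are administratively
  censored;
* CT scans follow a fixed schedule (one before-baseline scan, one baseline
  scan, several on-treatment scans); a lesion is recorded at a scan only if
  at least one of its measured diameters reaches the detection limit, so
  lesions can appear and disappear from the table;
* diameters carry multiplicative log-normal measurement noise.

Time is measured in months; the treatment start is time zero in treated mode,
the first scan is time zero in historical (untreated) mode.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "write_cohort"]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model, with cohort-realistic defaults.

    Defaults describe a metastatic-melanoma cohort under targeted therapy:
    a handful of lesions per patient, baseline lesion volumes around 1 cm^3
    (log-normal), pre-treatment doubling times of one to a few months, a
    treatment effect that typically flips growth to shrinkage but varies
    across lesions, and a lethal total burden of 1200 cm^3.
    """

    n_patients: int = 40
    #: lesions per patient: 1 + Poisson(mets_mean - 1), truncated at mets_max
    mets_mean: float = 5.0
    mets_max: int = 20
    organs: tuple = ("lung", "liver", "lymph_node", "soft_tissue", "brain")
    organ_weights: tuple = (0.3, 0.25, 0.2, 0.1, 0.15)
    #: log-normal baseline (treatment-start) lesion volume, cm^3
    baseline_volume_median: float = 1.5
    baseline_volume_sigma: float = 1.1
    #: exponential growth rate hierarchy, 1/month
    rate_mean: float = 0.35
    rate_patient_sd: float = 0.25
    rate_lesion_sd: float = 0.15
    #: per-lesion multiplicative treatment effect on the rate (sign flip = response)
    treatment: bool = True
    effect_mean: float = -1.0
    effect_sd: float = 0.8
    #: per-lesion hazard (1/month) of reverting to pre-treatment growth while on therapy
    resistance_hazard: float = 0.08
    #: fraction of patients who discontinue, window of stop times (months)
    stop_prob: float = 0.35
    stop_window: tuple = (4.0, 10.0)
    #: lesion-specific rebound factor applied to the pre-treatment rate after
    #: reversion or discontinuation (heterogeneous escape)
    rebound_sd: float = 0.4
    v_lethal_true: float = 1200.0
    #: death is attributed to brain disease when brain lesions alone exceed
    #: this fraction of total burden at death
    brain_death_fraction: float = 0.5
    #: scan schedule, months relative to treatment start (treated mode)
    bbl_offset: float = -3.0
    bl_offset: float = -0.5
    post_offsets: tuple = (2.0, 4.0, 7.0, 10.0, 14.0, 18.0, 22.0)
    #: historical mode: two scans at these absolute times
    historical_offsets: tuple = (0.0, 3.0)
    detection_limit: float = 1.0  # cm, minimal measurable diameter
    measurement_cv: float = 0.05  # log-normal diameter noise
    censor_time: float = 24.0  # months
    grid_step: float = 0.01  # months, death-time resolution
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0 or self.mets_mean < 1 or self.mets_max < 1:
            raise ConfigurationError("cohort sizes must be positive (mets_mean >= 1)")
        for name in ("baseline_volume_median", "v_lethal_true", "detection_limit",
                     "censor_time", "grid_step"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("baseline_volume_sigma", "rate_patient_sd", "rate_lesion_sd",
                     "effect_sd", "resistance_hazard", "rebound_sd", "measurement_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if len(self.organs) != len(self.organ_weights):
            raise ConfigurationError("organs and organ_weights must align")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("organs", "organ_weights", "post_offsets", "historical_offsets", "stop_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth that produced it."""

    measurements: pd.DataFrame
    metadata: pd.DataFrame
    truth_lesions: pd.DataFrame
    truth_patients: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _log_volume(t, log_v0, r_pre, r_post, t_change, r_rebound):
    """Piecewise-linear log-volume: r_pre before 0, r_post on [0, t_change), rebound after."""
    t = np.asarray(t, float)
    tc = min(t_change, 1e12)  # guard inf*0 in the unused branch
    lv = np.where(
        t < 0,
        log_v0 + r_pre * t,
        np.where(
            t < tc,
            log_v0 + r_post * t,
            log_v0 + r_post * tc + r_rebound * (t - tc),
        ),
    )
    return lv


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort from the generative model.

    Returns the long-format measurement table, patient metadata (treatment
    and outcome), and the lesion- and patient-level ground truth needed for
    parameter-recovery tests.  A fixed seed yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config
    organs = np.array(cfg.organs)
    organ_p = np.array(cfg.organ_weights, float)
    organ_p = organ_p / organ_p.sum()

    if cfg.treatment:
        scan_times = np.array([cfg.bbl_offset, cfg.bl_offset, *cfg.post_offsets], float)
        t0 = cfg.bbl_offset
    else:
        scan_times = np.array(cfg.historical_offsets, float)
        t0 = float(scan_times.min())
    grid = np.arange(t0, cfg.censor_time + cfg.grid_step, cfg.grid_step)

    meas_rows, meta_rows, les_rows, pat_rows = [], [], [], []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:03d}"
        n = 1 + rng.poisson(cfg.mets_mean - 1.0)
        n = int(min(n, cfg.mets_max))
        organ = rng.choice(organs, size=n, p=organ_p)
        log_v0 = np.log(cfg.baseline_volume_median) + cfg.baseline_volume_sigma * rng.standard_normal(n)
        mu_p = cfg.rate_mean + cfg.rate_patient_sd * rng.standard_normal()
        r_pre = mu_p + cfg.rate_lesion_sd * rng.standard_normal(n)

        if cfg.treatment:
            effect = cfg.effect_mean + cfg.effect_sd * rng.standard_normal(n)
            r_post = effect * r_pre
            # responding lesions can escape after an exponential resistance delay
            if cfg.resistance_hazard > 0:
                t_rev = rng.exponential(1.0 / cfg.resistance_hazard, size=n)
            else:
                t_rev = np.full(n, np.inf)
            t_rev = np.where(r_post < r_pre, t_rev, np.inf)
            stopped = rng.random() < cfg.stop_prob
            t_stop = rng.uniform(*cfg.stop_window) if stopped else np.inf
            t_change = np.minimum(t_rev, t_stop)
            rebound = 1.0 + cfg.rebound_sd * rng.standard_normal(n)
            r_rebound = r_pre * np.clip(rebound, 0.05, None)
        else:
            r_post = r_pre.copy()
            t_change = np.full(n, np.inf)
            r_rebound = r_pre.copy()
            t_stop = np.inf

        # lesion shape: d1 >= d2 >= d3 with (pi/6) d1 d2 d3 = V
        s2 = rng.uniform(0.6, 1.0, size=n)
        s3 = rng.uniform(0.5, 1.0, size=n) * s2

        lv = np.stack([
            _log_volume(grid, log_v0[j], r_pre[j], r_post[j], t_change[j], r_rebound[j])
            for j in range(n)
        ])
        total = np.exp(lv).sum(axis=0)
        crossing = np.nonzero(total >= cfg.v_lethal_true)[0]
        death_time = float(grid[crossing[0]]) if len(crossing) else np.inf

        if death_time <= cfg.censor_time:
            event, event_time = 1, death_time
            idx = crossing[0]
            brain_frac = np.exp(lv[organ == "brain", idx]).sum() / total[idx] if (organ == "brain").any() else 0.0
            cause = "brain" if brain_frac > cfg.brain_death_fraction else "other"
        else:
            event, event_time = 0, cfg.censor_time
            cause = ""

        for st in scan_times:
            if st >= death_time or st > cfg.censor_time:
                continue
            for j in range(n):
                v = math.exp(_log_volume(st, log_v0[j], r_pre[j], r_post[j], t_change[j], r_rebound[j]))
                d1 = (6.0 * v / (math.pi * s2[j] * s3[j])) ** (1.0 / 3.0)
                d = np.array([d1, s2[j] * d1, s3[j] * d1])
                if cfg.measurement_cv > 0:
                    d = d * np.exp(cfg.measurement_cv * rng.standard_normal(3))
                if d.max() < cfg.detection_limit:
                    continue  # below detection: unmeasured at this scan
                meas_rows.append({
                    "patient_id": pid, "lesion_id": f"L{j + 1:02d}", "organ": organ[j],
                    "time": float(st),
                    "d1": round(float(d[0]), 6), "d2": round(float(d[1]), 6),
                    "d3": round(float(d[2]), 6),
                    "volume": round(float(math.pi / 6 * d[0] * d[1] * d[2]), 6),
                })

        meta_rows.append({
            "patient_id": pid,
            "treatment_start": 0.0 if cfg.treatment else np.nan,
            "treatment_stop": (float(t_stop) if np.isfinite(t_stop) and t_stop < event_time else np.nan),
            "event_time": float(event_time), "event": event, "death_cause": cause,
        })
        for j in range(n):
            les_rows.append({
                "patient_id": pid, "lesion_id": f"L{j + 1:02d}", "organ": organ[j],
                "v0": math.exp(log_v0[j]), "r_pre": r_pre[j], "r_post": r_post[j],
                "t_change": t_change[j] if np.isfinite(t_change[j]) else np.nan,
                "r_rebound": r_rebound[j],
            })
        pat_rows.append({
            "patient_id": pid, "true_death_time": death_time if np.isfinite(death_time) else np.nan,
            "event_time": float(event_time), "event": event, "death_cause": cause,
            "v_lethal_true": cfg.v_lethal_true,
        })

    measurements = pd.DataFrame(meas_rows, columns=list(cohort_io.MEASUREMENT_COLUMNS))
    metadata = pd.DataFrame(meta_rows, columns=list(cohort_io.METADATA_COLUMNS))
    return SimulatedCohort(
        measurements=measurements, metadata=metadata,
        truth_lesions=pd.DataFrame(les_rows), truth_patients=pd.DataFrame(pat_rows),
        config=cfg,
    )


def write_cohort(sim: SimulatedCohort, outdir) -> dict:
    """Persist a simulated cohort: canonical CSVs, truth sidecars, config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = cohort_io.write_cohort(sim.measurements, sim.metadata, outdir)
    paths["truth_lesions"] = outdir / "truth_lesions.csv"
    paths["truth_patients"] = outdir / "truth_patients.csv"
    sim.truth_lesions.to_csv(paths["truth_lesions"], index=False)
    sim.truth_patients.to_csv(paths["truth_patients"], index=False)
    if sim.config is not None:
        paths["config"] = outdir / "config.yaml"
        sim.config.to_yaml(paths["config"])
    return paths
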