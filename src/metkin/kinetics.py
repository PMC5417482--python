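"""Growth-kinetics indices from serial CT volumetry.

Every index derives from two volume measurements ``V1`` (earlier scan) and
``V2`` (later scan) taken ``dt`` months apart:

* exponential growth rate  ``aExp = (ln V2 - ln V1) / dt``  [1/month]
* linear slope             ``aLin = (V2 - V1) / dt``        [cm^3/month]
* relative volume change   ``RVC  = (V2 - V1) / V1``        [unitless]

Each index is computed *globally* (on the summed volume of all measurable
metastases) and as a *mean* over the per-lesion values; the spread (sample
standard deviation and range) of the per-lesion values quantifies
inter-metastasis heterogeneity of kinetics — the construct of interest for
prognosis.  Two analysis windows are supported: the pre-treatment window
(before-baseline scan -> baseline scan) and the initial-response window
(baseline -> first on-treatment scan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import PatientTimeline

__all__ = [
    "ellipsoid_volume",
    "exp_growth_rate",
    "linear_slope",
    "relative_volume_change",
    "DETECTION_FLOOR_VOLUME",
    "KineticsProfile",
    "patient_kinetics",
    "cohort_kinetics",
    "change_in_kinetics",
    "post_treatment_comparison",
]

#: Volume (cm^3) of a sphere at the 0.5 cm measurability midpoint; used as the
#: bounded stand-in volume for a lesion below the detection limit when the
#: "floor" missing-lesion policy is active.
DETECTION_FLOOR_VOLUME = math.pi / 6 * 0.5**3


def ellipsoid_volume(d1, d2, d3):
    """Ellipsoid volume (cm^3) from three orthogonal diameters (cm).

    ``V = (pi/6) d1 d2 d3`` — two native axial diameters plus one from a
    coronal reconstruction.  Accepts scalars or arrays; all diameters must be
    strictly positive.
    """
    d1, d2, d3 = np.asarray(d1, float), np.asarray(d2, float), np.asarray(d3, float)
    if np.any(d1 <= 0) or np.any(d2 <= 0) or np.any(d3 <= 0):
        raise ValueError("diameters must be strictly positive")
    out = math.pi / 6.0 * d1 * d2 * d3
    return float(out) if out.ndim == 0 else out


def exp_growth_rate(v1, v2, dt):
    """Exponential growth rate (1/month), natural log: ``(ln V2 - ln V1)/dt``."""
    v1, v2, dt = np.asarray(v1, float), np.asarray(v2, float), np.asarray(dt, float)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise ValueError("volumes must be strictly positive (apply a floor policy first)")
    if np.any(dt <= 0):
        raise ValueError("time interval must be strictly positive")
    out = (np.log(v2) - np.log(v1)) / dt
    return float(out) if out.ndim == 0 else out


def linear_slope(v1, v2, dt):
    """Linear slope (cm^3/month): ``(V2 - V1)/dt``."""
    v1, v2, dt = np.asarray(v1, float), np.asarray(v2, float), np.asarray(dt, float)
    if np.any(dt <= 0):
        raise ValueError("time interval must be strictly positive")
    out = (v2 - v1) / dt
    return float(out) if out.ndim == 0 else out


def relative_volume_change(v1, v2):
    """Relative volume change (unitless): ``(V2 - V1)/V1``; > -1 whenever V2 > 0."""
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    if np.any(v1 <= 0):
        raise ValueError("V1 must be strictly positive")
    out = (v2 - v1) / v1
    return float(out) if out.ndim == 0 else out


@dataclass
class KineticsProfile:
    """The full index set for one patient over one analysis window.

    Spread fields are ``None`` when fewer than two lesions are usable —
    "unmeasurable heterogeneity" is deliberately distinct from zero spread.
    """

    patient_id: object
    window: str  # "BL" (before-baseline -> baseline) or "IR" (baseline -> initial response)
    t1: float
    t2: float
    dt: float
    v1_global: float
    v2_global: float
    aexp_global: float | None = None
    alin_global: float | None = None
    rvc_global: float | None = None
    aexp_mean: float | None = None
    alin_mean: float | None = None
    rvc_mean: float | None = None
    aexp_sd: float | None = None
    aexp_range: float | None = None
    alin_sd: float | None = None
    alin_range: float | None = None
    rvc_sd: float | None = None
    rvc_range: float | None = None
    n_lesions_used: int = 0
    n_mets_baseline: int = 0
    v_bbl: float | None = None
    v_bl: float | None = None
    v_ir: float | None = None
    per_lesion: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("per_lesion")
        return d


def _spread(values: np.ndarray) -> tuple[float | None, float | None]:
    if len(values) < 2:
        return None, None
    return float(np.std(values, ddof=1)), float(np.ptp(values))


def _lesion_volumes_at(measurements: pd.DataFrame, time: float) -> pd.Series:
    sub = measurements[np.isclose(measurements["time"].to_numpy(float), time)]
    return sub.set_index("lesion_id")["volume"].astype(float)


def patient_kinetics(
    measurements: pd.DataFrame,
    timeline: PatientTimeline,
    window: str = "BL",
    missing_policy: str = "floor",
    floor_volume: float = DETECTION_FLOOR_VOLUME,
) -> KineticsProfile:
    """Compute the kinetics index set for one patient over one window.

    Parameters
    ----------
    measurements
        Long-format lesion table for this patient (columns ``lesion_id``,
        ``time`` in months, ``volume`` in cm^3).
    timeline
        Anchored patient timeline supplying the window endpoints.
    window
        ``"BL"`` uses (before-baseline, baseline); ``"IR"`` uses (baseline,
        initial-response).
    missing_policy
        How lesions measurable at only one endpoint enter the per-lesion
        indices.  ``"floor"`` (default): the missing endpoint is imputed at
        `floor_volume` for RVC and the linear slope (both bounded), while the
        exponential rate still requires both endpoints; ``"exclude"``: such
        lesions are dropped from all per-lesion indices.  Global indices
        always use the summed volume of the lesions measured at each endpoint.

    Notes
    -----
    The global exponential rate is exactly ``ln(V2/V1)/dt`` on total volume,
    so it is *not* the mean of the per-lesion rates in general — the gap
    between the two is itself a heterogeneity signal.
    """
    if window == "BL":
        t1, t2 = timeline.bbl, timeline.bl
    elif window == "IR":
        t1, t2 = timeline.bl, timeline.ir
    else:
        raise ValueError(f"unknown window {window!r}; expected 'BL' or 'IR'")
    if t1 is None or t2 is None:
        raise ValueError(f"window {window!r} endpoints missing for patient {timeline.patient_id!r}")
    if missing_policy not in ("floor", "exclude"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    dt = t2 - t1
    vols1 = _lesion_volumes_at(measurements, t1)
    vols2 = _lesion_volumes_at(measurements, t2)
    v1g, v2g = float(vols1.sum()), float(vols2.sum())

    bl_time = timeline.bl
    n_mets_baseline = int(len(_lesion_volumes_at(measurements, bl_time))) if bl_time is not None else 0

    prof = KineticsProfile(
        patient_id=timeline.patient_id, window=window, t1=float(t1), t2=float(t2),
        dt=float(dt), v1_global=v1g, v2_global=v2g, n_mets_baseline=n_mets_baseline,
        v_bbl=float(_lesion_volumes_at(measurements, timeline.bbl).sum()) if timeline.bbl is not None else None,
        v_bl=float(_lesion_volumes_at(measurements, bl_time).sum()) if bl_time is not None else None,
        v_ir=float(_lesion_volumes_at(measurements, timeline.ir).sum()) if timeline.ir is not None else None,
    )

    if v1g > 0 and v2g > 0:
        prof.aexp_global = exp_growth_rate(v1g, v2g, dt)
        prof.alin_global = linear_slope(v1g, v2g, dt)
        prof.rvc_global = relative_volume_change(v1g, v2g)

    both = sorted(set(vols1.index) & set(vols2.index))
    one_sided = sorted(set(vols1.index) ^ set(vols2.index))

    aexp, alin, rvc = {}, {}, {}
    for lid in both:
        aexp[lid] = exp_growth_rate(vols1[lid], vols2[lid], dt)
        alin[lid] = linear_slope(vols1[lid], vols2[lid], dt)
        rvc[lid] = relative_volume_change(vols1[lid], vols2[lid])
    if missing_policy == "floor":
        for lid in one_sided:
            w1 = float(vols1.get(lid, floor_volume))
            w2 = float(vols2.get(lid, floor_volume))
            alin[lid] = linear_slope(w1, w2, dt)
            rvc[lid] = relative_volume_change(w1, w2)

    if aexp:
        vals = np.array(list(aexp.values()))
        prof.aexp_mean = float(vals.mean())
        prof.aexp_sd, prof.aexp_range = _spread(vals)
    if alin:
        vals = np.array(list(alin.values()))
        prof.alin_mean = float(vals.mean())
        prof.alin_sd, prof.alin_range = _spread(vals)
    if rvc:
        vals = np.array(list(rvc.values()))
        prof.rvc_mean = float(vals.mean())
        prof.rvc_sd, prof.rvc_range = _spread(vals)

    prof.n_lesions_used = len(rvc) if missing_policy == "floor" else len(both)
    prof.per_lesion = {"aexp": aexp, "alin": alin, "rvc": rvc}
    return prof


def change_in_kinetics(bl: KineticsProfile, ir: KineticsProfile) -> dict:
    """Change-in-kinetics indices: IR-window minus BL-window rates and slopes."""
    def _delta(a, b):
        return None if (a is None or b is None) else b - a

    return {
        "d_aexp_global": _delta(bl.aexp_global, ir.aexp_global),
        "d_aexp_mean": _delta(bl.aexp_mean, ir.aexp_mean),
        "d_alin_global": _delta(bl.alin_global, ir.alin_global),
        "d_alin_mean": _delta(bl.alin_mean, ir.alin_mean),
    }


def cohort_kinetics(
    measurements: pd.DataFrame,
    timelines: Mapping[object, PatientTimeline],
    windows: Iterable[str] = ("BL", "IR"),
    missing_policy: str = "floor",
) -> pd.DataFrame:
    """Tidy table of kinetics profiles: one row per patient x available window."""
    rows = []
    for pid, tl in timelines.items():
        sub = measurements[measurements["patient_id"] == pid]
        for window in windows:
            if window == "IR" and tl.ir is None:
                continue
            if window == "BL" and (tl.bbl is None or tl.bl is None):
                continue
            rows.append(patient_kinetics(sub, tl, window, missing_policy).to_dict())
    return pd.DataFrame(rows)


def _ternary(pre: float, post: float, stable_band: float) -> str:
    band = stable_band * abs(pre)
    if post < pre - band:
        return "decreased"
    if post > pre + band:
        return "increased"
    return "stable"


def post_treatment_comparison(
    measurements: pd.DataFrame,
    timelines: Mapping[object, PatientTimeline],
    stable_band: float = 0.05,
) -> pd.DataFrame:
    """Compare post-discontinuation growth with pre-treatment growth.

    For every patient with at least two scans after treatment stop, the
    exponential rates from the two scans bracketing treatment start (the
    pre-treatment window) are compared with those from the first two scans
    after discontinuation.  Three summaries are classified as
    decreased/stable/increased: the global-burden rate, the mean per-lesion
    rate, and the range of per-lesion rates (heterogeneity).  ``stable``
    means the post value lies within ``stable_band * |pre|`` of the pre value.
    """
    rows = []
    for pid, tl in timelines.items():
        if tl.treatment_stop is None:
            continue
        sub = measurements[measurements["patient_id"] == pid]
        post_scans = sorted(t for t in sub["time"].unique() if t > tl.treatment_stop)
        if len(post_scans) < 2 or tl.bbl is None or tl.bl is None:
            continue
        pre = patient_kinetics(sub, tl, "BL")
        post_tl = PatientTimeline(
            patient_id=pid, scan_times=tuple(post_scans),
            bbl=post_scans[0], bl=post_scans[1], ir=None,
        )
        post = patient_kinetics(sub, post_tl, "BL")
        row = {"patient_id": pid}
        for name, a, b in [
            ("global_rate", pre.aexp_global, post.aexp_global),
            ("mean_rate", pre.aexp_mean, post.aexp_mean),
            ("range_rate", pre.aexp_range, post.aexp_range),
        ]:
            row[name] = None if (a is None or b is None) else _ternary(a, b, stable_band)
            row[f"{name}_pre"] = a
            row[f"{name}_post"] = b
        rows.append(row)
    return pd.DataFrame(rows)
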