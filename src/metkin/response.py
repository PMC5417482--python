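"""RECIST-1.1-proxy response classification from volumetric lesion tables.

When a formal RECIST read is unavailable, the baseline lesions with the
largest volumes stand in as target lesions — at most five in total and two
per organ.  Progression (PD) is called when any of three rules fires:

* the sum of target longest diameters grows >= 20% from its nadir (the
  smallest sum at or after baseline) with >= 0.5 cm absolute increase;
* a new lesion appears (first becomes measurable after baseline);
* any non-target lesion at least doubles its baseline volume (treated as
  unequivocal progression).

A *mixed response* labels assessments where some lesions clearly shrink
while others clearly grow (or new lesions appear) — per-lesion relative
volume change <= -30% alongside >= +20%, mirroring the per-lesion PR/PD
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "select_targets",
    "classify_response",
    "detect_new_lesions",
    "classify_mixed_response",
    "ResponseAssessment",
]

MAX_TARGETS = 5
MAX_TARGETS_PER_ORGAN = 2
PD_RELATIVE_INCREASE = 0.20
PD_ABSOLUTE_INCREASE_CM = 0.5
NONTARGET_DOUBLING = 2.0
MIXED_SHRINK_THRESHOLD = -0.30
MIXED_GROW_THRESHOLD = 0.20


@dataclass
class ResponseAssessment:
    patient_id: object
    assessment_time: float
    target_ids: list
    target_diameter_sum_bl: float
    target_diameter_sum: float
    target_diameter_nadir: float
    recist_category: str  # "PD" or "non-PD"
    new_lesions: list = field(default_factory=list)
    non_target_doubling: bool = False
    target_progression: bool = False
    mixed_response: bool | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["target_ids"] = ";".join(map(str, self.target_ids))
        d["new_lesions"] = ";".join(map(str, self.new_lesions))
        return d


def _longest_diameter(df: pd.DataFrame) -> pd.Series:
    return df[["d1", "d2", "d3"]].astype(float).max(axis=1)


def select_targets(baseline: pd.DataFrame) -> list:
    """Pick theoretical RECIST target lesions at baseline.

    Lesions sorted by baseline volume (descending, ties broken by lesion id)
    are accepted greedily while the total stays below five and the per-organ
    count below two.
    """
    if baseline.empty:
        raise ValueError("no baseline lesions to select targets from")
    ordered = baseline.sort_values(["volume", "lesion_id"], ascending=[False, True],
                                   kind="mergesort")
    targets, per_organ = [], {}
    for _, row in ordered.iterrows():
        if len(targets) >= MAX_TARGETS:
            break
        organ = row["organ"]
        if per_organ.get(organ, 0) >= MAX_TARGETS_PER_ORGAN:
            continue
        targets.append(row["lesion_id"])
        per_organ[organ] = per_organ.get(organ, 0) + 1
    return targets


def detect_new_lesions(measurements: pd.DataFrame, bl_time: float) -> dict:
    """Map each post-baseline scan time to lesion ids first measurable there."""
    first_seen = measurements.groupby("lesion_id")["time"].min()
    new = first_seen[first_seen > bl_time]
    out: dict = {}
    for lid, t in new.items():
        out.setdefault(float(t), []).append(lid)
    return {t: sorted(ids) for t, ids in sorted(out.items())}


def classify_response(
    measurements: pd.DataFrame,
    bl_time: float,
    assessment_time: float,
    targets: list | None = None,
    use_volume_sum: bool = False,
) -> ResponseAssessment:
    """Call PD / non-PD at one assessment scan for one patient.

    `measurements` is the patient's long-format lesion table.  The nadir is
    the smallest target diameter sum over scans in [baseline, assessment].
    With ``use_volume_sum`` the target sum is of volumes instead of longest
    diameters (the 20%-diameter rule then applies to the cube root of the
    volume ratio, keeping the threshold equivalent for self-similar growth).
    """
    baseline = measurements[np.isclose(measurements["time"], bl_time)]
    if targets is None:
        targets = select_targets(baseline)
    tset = set(targets)

    def target_sum(at: float) -> float:
        scan = measurements[np.isclose(measurements["time"], at)]
        scan_t = scan[scan["lesion_id"].isin(tset)]
        if use_volume_sum:
            return float(np.cbrt(scan_t["volume"].astype(float)).sum())
        return float(_longest_diameter(scan_t).sum()) if len(scan_t) else 0.0

    scan_times = sorted(t for t in measurements["time"].unique()
                        if bl_time <= t <= assessment_time)
    sums = {t: target_sum(t) for t in scan_times}
    s_bl = sums[scan_times[0]]
    s_now = sums[scan_times[-1]]
    nadir = min(sums[t] for t in scan_times[:-1]) if len(scan_times) > 1 else s_bl

    target_pd = (
        nadir > 0
        and s_now >= (1.0 + PD_RELATIVE_INCREASE) * nadir
        and s_now - nadir >= PD_ABSOLUTE_INCREASE_CM
    )

    new_by_scan = detect_new_lesions(measurements, bl_time)
    new_here = sorted({lid for t, ids in new_by_scan.items() if t <= assessment_time for lid in ids})

    assess = measurements[np.isclose(measurements["time"], assessment_time)]
    nt_bl = baseline[~baseline["lesion_id"].isin(tset)].set_index("lesion_id")["volume"]
    nt_now = assess[assess["lesion_id"].isin(nt_bl.index)].set_index("lesion_id")["volume"]
    common = nt_now.index.intersection(nt_bl.index)
    doubling = bool((nt_now[common].to_numpy(float)
                     >= NONTARGET_DOUBLING * nt_bl[common].to_numpy(float)).any())

    pd_flag = target_pd or bool(new_here) or doubling
    return ResponseAssessment(
        patient_id=measurements["patient_id"].iloc[0] if len(measurements) else None,
        assessment_time=float(assessment_time),
        target_ids=list(targets),
        target_diameter_sum_bl=s_bl,
        target_diameter_sum=s_now,
        target_diameter_nadir=nadir,
        recist_category="PD" if pd_flag else "non-PD",
        new_lesions=new_here,
        non_target_doubling=doubling,
        target_progression=bool(target_pd),
    )


def classify_mixed_response(
    per_lesion_rvc,
    new_lesions=(),
    shrink_threshold: float = MIXED_SHRINK_THRESHOLD,
    grow_threshold: float = MIXED_GROW_THRESHOLD,
) -> str:
    """Label an initial response "mixed" or "uniform".

    Mixed: at least one lesion shrinks past `shrink_threshold` while another
    grows past `grow_threshold`, or a clearly shrinking lesion coexists with
    a new lesion.  A single lesion with no new lesions is uniform by
    convention.
    """
    rvc = np.asarray(list(per_lesion_rvc), float)
    shrinks = bool((rvc <= shrink_threshold).any())
    grows = bool((rvc >= grow_threshold).any())
    if (shrinks and grows) or (shrinks and len(tuple(new_lesions)) > 0):
        return "mixed"
    return "uniform"


def cohort_response(measurements: pd.DataFrame, timelines, use_volume_sum: bool = False) -> pd.DataFrame:
    """First-assessment (initial-response scan) classification for every patient."""
    from .kinetics import patient_kinetics

    rows = []
    for pid, tl in timelines.items():
        if tl.ir is None or tl.bl is None:
            continue
        sub = measurements[measurements["patient_id"] == pid]
        assess = classify_response(sub, tl.bl, tl.ir, use_volume_sum=use_volume_sum)
        prof = patient_kinetics(sub, tl, "IR")
        assess.mixed_response = classify_mixed_response(
            prof.per_lesion["rvc"].values(), assess.new_lesions
        ) == "mixed"
        rows.append(assess.to_dict())
    return pd.DataFrame(rows)
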