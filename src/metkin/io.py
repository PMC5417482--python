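"""Reading, validation and timeline anchoring of per-lesion CT measurement tables.

The canonical measurement table is long-format, one row per lesion per scan:

======================  =====================================================
column                  meaning
======================  =====================================================
``patient_id``          opaque patient label
``lesion_id``           opaque lesion label, unique within a patient
``organ``               organ label; ``"brain"`` is special-cased downstream
``time``                study time of the scan in months (float)
``d1``, ``d2``, ``d3``  diameters in cm (two axial, one coronal); optional if
                        ``volume`` is given
``volume``              lesion volume in cm^3 (computed from diameters when
                        absent, assuming an ellipsoid)
======================  =====================================================

Patient metadata is one row per patient: ``patient_id``, ``treatment_start``,
``treatment_stop`` (months, may be empty), ``event_time`` (death or censoring,
months), ``event`` (1 = death, 0 = censored), ``death_cause`` (``brain`` /
``other`` / empty).

Input files whose column names differ are mapped onto this schema through a
:class:`Dialect` (optionally loaded from YAML).  Dates, when given instead of
study times, are converted at 30.44 days per month.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44

MEASUREMENT_COLUMNS = ("patient_id", "lesion_id", "organ", "time", "d1", "d2", "d3", "volume")
METADATA_COLUMNS = ("patient_id", "treatment_start", "treatment_stop", "event_time", "event", "death_cause")


class SchemaError(ValueError):
    """Mandatory columns missing or unmappable."""


class ValidationError(ValueError):
    """Rows violating table invariants (reported with row numbers)."""


class EligibilityError(ValueError):
    """Patient does not meet the minimum-scans eligibility rule."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping from an input CSV onto the canonical schema.

    ``measurement_columns`` / ``metadata_columns`` map canonical names to the
    file's column names.  ``time_unit`` is ``"months"`` or ``"days"``.
    """

    measurement_columns: Mapping[str, str] = dataclasses.field(default_factory=dict)
    metadata_columns: Mapping[str, str] = dataclasses.field(default_factory=dict)
    time_unit: str = "months"

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            measurement_columns=raw.get("measurement_columns", {}),
            metadata_columns=raw.get("metadata_columns", {}),
            time_unit=raw.get("time_unit", "months"),
        )


@dataclass
class PatientTimeline:
    """Ordered scans with anchors and outcome for one patient.

    Anchors (all in study months): ``bbl`` the scan before baseline, ``bl``
    the last scan before treatment start, ``ir`` the first scan after
    treatment start (``None`` if no on-treatment scan exists).  In
    historical-cohort mode (no treatment) the first two scans play the roles
    of ``bbl`` and ``bl``.
    """

    patient_id: object
    scan_times: Sequence[float]
    bbl: float | None = None
    bl: float | None = None
    ir: float | None = None
    treatment_start: float | None = None
    treatment_stop: float | None = None
    event_time: float | None = None
    event: int | None = None
    death_cause: str | None = None

    def __post_init__(self):
        self.scan_times = tuple(sorted(float(t) for t in self.scan_times))
        if self.bbl is not None and self.bl is not None and not self.bbl < self.bl:
            raise ValidationError(f"patient {self.patient_id!r}: BBL must precede BL")
        if self.ir is not None and self.treatment_start is not None and self.ir < self.treatment_start:
            raise ValidationError(f"patient {self.patient_id!r}: IR precedes treatment start")


def anchor_timeline(scan_times: Sequence[float], treatment_start: float | None):
    """Assign (bbl, bl, ir) anchors to an ordered scan list.

    With a treatment start: ``bl`` is the latest scan at or before treatment
    start, ``bbl`` the latest earlier scan, ``ir`` the earliest strictly later
    scan than treatment start (or ``None``).  Patients with fewer than two
    pre-treatment scans are ineligible.  Without treatment (historical
    cohort), the first two scans become ``bbl`` and ``bl``.
    """
    times = sorted(float(t) for t in scan_times)
    if treatment_start is None:
        if len(times) < 2:
            raise EligibilityError("historical mode requires at least 2 scans")
        return times[0], times[1], None
    pre = [t for t in times if t <= treatment_start]
    post = [t for t in times if t > treatment_start]
    if len(pre) < 2:
        raise EligibilityError(
            f"eligibility requires >=2 pre-treatment scans, found {len(pre)}"
        )
    return pre[-2], pre[-1], (post[0] if post else None)


def build_timelines(
    measurements: pd.DataFrame,
    metadata: pd.DataFrame | None,
    historical: bool = False,
) -> dict:
    """Anchor a timeline for every patient; ineligible patients are logged and dropped."""
    meta = {}
    if metadata is not None:
        meta = metadata.set_index("patient_id").to_dict("index")
    timelines = {}
    for pid, sub in measurements.groupby("patient_id", sort=True):
        scans = sorted(sub["time"].unique())
        m = meta.get(pid, {})
        tstart = m.get("treatment_start")
        tstart = None if (historical or tstart is None or (isinstance(tstart, float) and math.isnan(tstart))) else float(tstart)
        try:
            bbl, bl, ir = anchor_timeline(scans, tstart)
        except EligibilityError as exc:
            logger.warning("excluding patient %r: %s", pid, exc)
            continue
        def _f(key):
            v = m.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v
        timelines[pid] = PatientTimeline(
            patient_id=pid, scan_times=scans, bbl=bbl, bl=bl, ir=ir,
            treatment_start=tstart, treatment_stop=_f("treatment_stop"),
            event_time=_f("event_time"),
            event=None if _f("event") is None else int(m["event"]),
            death_cause=_f("death_cause") or None,
        )
    return timelines


def _apply_dialect(df: pd.DataFrame, colmap: Mapping[str, str]) -> pd.DataFrame:
    if colmap:
        inverse = {src: dst for dst, src in colmap.items()}
        df = df.rename(columns=inverse)
    return df


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the canonical measurement table; raise with offending row numbers."""
    missing = {"patient_id", "lesion_id", "time"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
    df = df.copy()
    if "organ" not in df.columns:
        df["organ"] = "unspecified"
    have_d = all(c in df.columns for c in ("d1", "d2", "d3"))
    if "volume" not in df.columns:
        if not have_d:
            raise SchemaError("need either volume or all of d1,d2,d3")
        df["volume"] = np.nan
    if have_d:
        from .kinetics import ellipsoid_volume  # local import: avoid cycle at import time

        diam = df[["d1", "d2", "d3"]].to_numpy(float)
        bad = np.where(np.nan_to_num(diam, nan=1.0) <= 0)[0]
        if len(bad):
            raise ValidationError(f"non-positive diameters at rows {sorted(set(bad.tolist()))[:20]}")
        need = df["volume"].isna() & ~np.isnan(diam).any(axis=1)
        if need.any():
            d = df.loc[need, ["d1", "d2", "d3"]].to_numpy(float)
            df.loc[need, "volume"] = ellipsoid_volume(d[:, 0], d[:, 1], d[:, 2])
    bad = np.where(df["volume"].to_numpy(float) <= 0)[0]
    if len(bad):
        raise ValidationError(f"non-positive volumes at rows {bad.tolist()[:20]}")
    dup = df.duplicated(subset=["patient_id", "lesion_id", "time"])
    if dup.any():
        raise ValidationError(
            f"duplicate (patient, lesion, scan) keys at rows {np.where(dup)[0].tolist()[:20]}"
        )
    df["time"] = df["time"].astype(float)
    return df


def read_cohort(
    measurements_path,
    metadata_path=None,
    dialect: Dialect | None = None,
    historical: bool = False,
):
    """Read a cohort from CSV files.

    Returns ``(measurements, timelines)`` where ``measurements`` is the
    validated canonical table and ``timelines`` maps patient id to an
    anchored :class:`PatientTimeline`.  Patients failing the eligibility rule
    (fewer than two pre-treatment scans) are excluded with a logged warning.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(measurements_path)
    df = _apply_dialect(df, dialect.measurement_columns)
    if dialect.time_unit == "days":
        df["time"] = df["time"].astype(float) / DAYS_PER_MONTH
    df = validate_measurements(df)

    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path)
        metadata = _apply_dialect(metadata, dialect.metadata_columns)
        if "patient_id" not in metadata.columns:
            raise SchemaError("metadata missing patient_id")
        if dialect.time_unit == "days":
            for c in ("treatment_start", "treatment_stop", "event_time"):
                if c in metadata.columns:
                    metadata[c] = metadata[c].astype(float) / DAYS_PER_MONTH
    timelines = build_timelines(df, metadata, historical=historical)
    return df, timelines


def write_cohort(measurements: pd.DataFrame, metadata: pd.DataFrame, outdir) -> dict:
    """Write the canonical tables as CSV; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": outdir / "measurements.csv",
        "metadata": outdir / "metadata.csv",
    }
    cols = [c for c in MEASUREMENT_COLUMNS if c in measurements.columns]
    measurements[cols].to_csv(paths["measurements"], index=False)
    mcols = [c for c in METADATA_COLUMNS if c in metadata.columns]
    metadata[mcols].to_csv(paths["metadata"], index=False)
    return paths
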