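import numpy as np
import pandas as pd
import pytest

import metkin as mk


@pytest.fixture
def two_lesion_patient():
    """Two lesions measured at scans -3, -1 (pre) and +2 (post), treatment at 0."""
    rows = []
    vols = {"L1": {-3.0: 10.0, -1.0: 20.0, 2.0: 10.0},
            "L2": {-3.0: 5.0, -1.0: 10.0, 2.0: 20.0}}
    for lid, series in vols.items():
        for t, v in series.items():
            d = (6 * v / np.pi) ** (1 / 3)
            rows.append({"patient_id": "P1", "lesion_id": lid, "organ": "lung",
                         "time": t, "d1": d, "d2": d, "d3": d, "volume": v})
    df = pd.DataFrame(rows)
    tl = mk.PatientTimeline(patient_id="P1", scan_times=[-3.0, -1.0, 2.0],
                            bbl=-3.0, bl=-1.0, ir=2.0, treatment_start=0.0)
    return df, tl


@pytest.fixture(scope="session")
def sim_braf():
    return mk.simulate_cohort(mk.SimulationConfig(n_patients=40, seed=11))


@pytest.fixture(scope="session")
def sim_hist_clean():
    """Untreated cohort without noise or detection censoring: death exactly at
    the lethal crossing of the observed exponential trajectory."""
    cfg = mk.SimulationConfig(
        n_patients=80, treatment=False, seed=5, measurement_cv=0.0,
        rate_lesion_sd=0.0, detection_limit=1e-3, v_lethal_true=800.0,
        censor_time=40.0,
    )
    return mk.simulate_cohort(cfg)


def historical_survival_frame(sim):
    """Per-patient calibration frame (v_bl, aexp_global, time, event) from an
    untreated simulated cohort."""
    tls = mk.build_timelines(sim.measurements, sim.metadata, historical=True)
    prof = mk.cohort_kinetics(sim.measurements, tls, windows=("BL",))
    df = prof[["patient_id", "v2_global", "aexp_global"]].rename(
        columns={"v2_global": "v_bl"})
    meta = sim.metadata.set_index("patient_id")
    df["time"] = df["patient_id"].map(meta["event_time"])
    df["event"] = df["patient_id"].map(meta["event"])
    return df.dropna(subset=["aexp_global"])
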