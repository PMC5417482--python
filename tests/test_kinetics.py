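import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metkin as mk
from metkin.kinetics import _ternary

pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)
dt_st = st.floats(min_value=1e-2, max_value=60.0, allow_nan=False)


@pytest.mark.parametrize("d, expected", [
    ((2, 2, 2), 4 * math.pi / 3),
    ((1, 1, 1), math.pi / 6),
    ((3, 2, 1), math.pi),
])
def test_ellipsoid_volume_closed_form(d, expected):
    assert mk.ellipsoid_volume(*d) == pytest.approx(expected, rel=1e-12)


def test_ellipsoid_volume_rejects_nonpositive():
    with pytest.raises(ValueError):
        mk.ellipsoid_volume(1.0, 0.0, 2.0)


@pytest.mark.parametrize("v1, v2, dt, expected", [
    (7.0, 7.0, 2.0, 0.0),
    (10.0, 20.0, 1.0, math.log(2)),
    (8.0, 1.0, 3.0, -math.log(8) / 3),
])
def test_exp_growth_rate_closed_form(v1, v2, dt, expected):
    assert mk.exp_growth_rate(v1, v2, dt) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("v1, v2, dt, expected", [
    (7.0, 7.0, 2.0, 0.0),
    (10.0, 25.0, 3.0, 5.0),
    (25.0, 10.0, 3.0, -5.0),
])
def test_linear_slope_closed_form(v1, v2, dt, expected):
    assert mk.linear_slope(v1, v2, dt) == pytest.approx(expected, rel=1e-12)


def test_rvc_closed_form_and_disappearance_bound():
    assert mk.relative_volume_change(10.0, 10.0) == 0.0
    assert mk.relative_volume_change(10.0, 15.0) == pytest.approx(0.5)
    # lesion shrinking to the detection floor approaches but never reaches -1
    floored = mk.relative_volume_change(10.0, mk.DETECTION_FLOOR_VOLUME)
    assert -1.0 < floored < -0.99


@given(v1=pos, v2=pos, dt=dt_st)
@settings(max_examples=200, deadline=None)
def test_rate_identities(v1, v2, dt):
    """aExp antisymmetry under V1<->V2; aExp and aLin share sign; RVC > -1."""
    a = mk.exp_growth_rate(v1, v2, dt)
    assert a == pytest.approx(-mk.exp_growth_rate(v2, v1, dt), abs=1e-10)
    assert np.sign(a) == np.sign(mk.linear_slope(v1, v2, dt))
    assert mk.relative_volume_change(v1, v2) > -1.0


@given(v1=pos, v2=pos, dt=dt_st, scale=st.floats(min_value=1e-2, max_value=1e2))
@settings(max_examples=200, deadline=None)
def test_scaling_invariance(v1, v2, dt, scale):
    """Volume rescaling leaves aExp and RVC unchanged and scales aLin."""
    assert mk.exp_growth_rate(scale * v1, scale * v2, dt) == pytest.approx(
        mk.exp_growth_rate(v1, v2, dt), rel=1e-9, abs=1e-12)
    assert mk.relative_volume_change(scale * v1, scale * v2) == pytest.approx(
        mk.relative_volume_change(v1, v2), rel=1e-9, abs=1e-12)
    assert mk.linear_slope(scale * v1, scale * v2, dt) == pytest.approx(
        scale * mk.linear_slope(v1, v2, dt), rel=1e-9, abs=1e-12)


def test_patient_kinetics_equal_rates(two_lesion_patient):
    df, tl = two_lesion_patient
    prof = mk.patient_kinetics(df, tl, "BL")
    # both lesions double over 2 months
    assert prof.aexp_mean == pytest.approx(math.log(2) / 2)
    assert prof.aexp_range == pytest.approx(0.0, abs=1e-12)
    assert prof.aexp_global == pytest.approx(math.log(30 / 15) / 2)
    assert prof.n_mets_baseline == 2


def test_patient_kinetics_opposite_rates():
    rows = []
    for lid, (v1, v2) in {"L1": (10.0, 20.0), "L2": (10.0, 5.0)}.items():
        for t, v in [(-1.0, v1), (0.0, v2)]:
            rows.append({"patient_id": "P", "lesion_id": lid, "organ": "lung",
                         "time": t, "volume": v})
    tl = mk.PatientTimeline("P", [-1.0, 0.0], bbl=-1.0, bl=0.0)
    prof = mk.patient_kinetics(pd.DataFrame(rows), tl, "BL")
    assert prof.aexp_range == pytest.approx(2 * math.log(2))
    assert prof.aexp_mean == pytest.approx(0.0, abs=1e-12)


def test_single_lesion_spread_absent_and_global_matches_lesion():
    rows = [{"patient_id": "P", "lesion_id": "L1", "organ": "lung", "time": t, "volume": v}
            for t, v in [(0.0, 4.0), (2.0, 9.0)]]
    tl = mk.PatientTimeline("P", [0.0, 2.0], bbl=0.0, bl=2.0)
    prof = mk.patient_kinetics(pd.DataFrame(rows), tl, "BL")
    assert prof.aexp_sd is None and prof.aexp_range is None
    assert prof.aexp_global == pytest.approx(prof.per_lesion["aexp"]["L1"])


def test_mean_alin_times_n_equals_global(two_lesion_patient):
    df, tl = two_lesion_patient
    prof = mk.patient_kinetics(df, tl, "BL")
    assert prof.alin_mean * prof.n_lesions_used == pytest.approx(prof.alin_global)


def test_missing_lesion_policies():
    """A lesion absent at one endpoint: excluded from aExp, floored into RVC."""
    rows = [
        {"patient_id": "P", "lesion_id": "L1", "organ": "lung", "time": 0.0, "volume": 10.0},
        {"patient_id": "P", "lesion_id": "L1", "organ": "lung", "time": 2.0, "volume": 20.0},
        {"patient_id": "P", "lesion_id": "L2", "organ": "lung", "time": 2.0, "volume": 3.0},
    ]
    tl = mk.PatientTimeline("P", [0.0, 2.0], bbl=0.0, bl=2.0)
    floor = mk.patient_kinetics(pd.DataFrame(rows), tl, "BL", missing_policy="floor")
    assert set(floor.per_lesion["aexp"]) == {"L1"}
    assert set(floor.per_lesion["rvc"]) == {"L1", "L2"}
    assert floor.per_lesion["rvc"]["L2"] == pytest.approx(
        (3.0 - mk.DETECTION_FLOOR_VOLUME) / mk.DETECTION_FLOOR_VOLUME)
    strict = mk.patient_kinetics(pd.DataFrame(rows), tl, "BL", missing_policy="exclude")
    assert set(strict.per_lesion["rvc"]) == {"L1"}


def test_change_in_kinetics(two_lesion_patient):
    df, tl = two_lesion_patient
    bl = mk.patient_kinetics(df, tl, "BL")
    ir = mk.patient_kinetics(df, tl, "IR")
    delta = mk.change_in_kinetics(bl, ir)
    assert delta["d_aexp_global"] == pytest.approx(ir.aexp_global - bl.aexp_global)


def test_ternary_stable_band():
    assert _ternary(1.0, 1.04, 0.05) == "stable"
    assert _ternary(1.0, 0.90, 0.05) == "decreased"
    assert _ternary(-0.5, -0.4, 0.05) == "increased"


def test_post_treatment_comparison_halved_rates():
    """All post-discontinuation rates at half the pre-treatment rates ->
    'decreased' for the global rate, the mean rate and the range."""
    rows = []
    rates = {"L1": 0.8, "L2": 0.4}
    for lid, r in rates.items():
        v0 = 10.0
        for t in [-3.0, -1.0, 6.0, 8.0]:
            rate = r if t < 0 else r / 2
            ref = -1.0 if t < 0 else 6.0
            base = v0 if t < 0 else 30.0
            v = base * math.exp(rate * (t - ref))
            rows.append({"patient_id": "P", "lesion_id": lid, "organ": "lung",
                         "time": t, "volume": v})
    tl = mk.PatientTimeline("P", [-3.0, -1.0, 6.0, 8.0], bbl=-3.0, bl=-1.0,
                            treatment_start=0.0, treatment_stop=5.0)
    out = mk.post_treatment_comparison(pd.DataFrame(rows), {"P": tl})
    row = out.iloc[0]
    assert row["global_rate"] == "decreased"
    assert row["mean_rate"] == "decreased"
    assert row["range_rate"] == "decreased"
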