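import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import metkin as mk
from metkin import survival as surv


# ---------------------------------------------------------------------------
# brute-force Efron partial likelihood (independent oracle)
# ---------------------------------------------------------------------------

def efron_partial_loglik(beta, time, event, x, entry=None):
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    entry = np.zeros_like(time) if entry is None else np.asarray(entry, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = (entry < t) & (time >= t)
        d = D.sum()
        theta_R = np.exp(beta * x[R]).sum()
        theta_D = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum()
        for j in range(d):
            ll -= np.log(theta_R - (j / d) * theta_D)
    return ll


@pytest.mark.parametrize("entry", [None, [0.0, 0.0, 1.5, 0.0, 2.0, 0.0]])
def test_cox_matches_brute_force_oracle(entry):
    """On a tiny dataset (with ties and optional delayed entry), the fitted
    coefficient equals the brute-force maximiser of the explicit Efron
    partial likelihood."""
    time = [5.0, 5.0, 8.0, 3.0, 9.0, 11.0]
    event = [1, 1, 1, 0, 1, 0]
    x = [1.0, 0.0, 1.0, 0.0, 0.0, 1.0]
    df = pd.DataFrame({"time": time, "event": event, "x": x})
    kwargs = {}
    if entry is not None:
        df["entry"] = entry
        kwargs["entry_col"] = "entry"
    fit = surv.fit_cox(df, covariates=["x"], **kwargs)
    res = minimize_scalar(
        lambda b: -efron_partial_loglik(b, time, event, x, entry),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    )
    assert fit.coefficients.iloc[0] == pytest.approx(res.x, abs=1e-6)
    assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-8)


def test_left_truncation_excludes_pre_entry_subjects():
    """A subject entering after every event time contributes to no risk set:
    the fit is identical with or without them."""
    base = pd.DataFrame({
        "time": [3.0, 5.0, 7.0, 9.0], "event": [1, 1, 1, 0],
        "x": [1.0, 0.0, 1.0, 0.0], "entry": [0.0, 0.0, 0.0, 0.0],
    })
    extra = pd.concat([base, pd.DataFrame(
        {"time": [12.0], "event": [0], "x": [1.0], "entry": [8.0]})],
        ignore_index=True)
    f1 = surv.fit_cox(base, covariates=["x"], entry_col="entry")
    f2 = surv.fit_cox(extra, covariates=["x"], entry_col="entry")
    assert f1.coefficients.iloc[0] == pytest.approx(f2.coefficients.iloc[0], abs=1e-8)


def test_zero_covariate_gives_null_fit():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"time": rng.exponential(5.0, 30),
                       "event": rng.integers(0, 2, 30), "x": 0.0})
    fit = surv.fit_cox(df, covariates=["x"], penalizer=1e-8)
    assert fit.coefficients.iloc[0] == pytest.approx(0.0, abs=1e-8)
    assert fit.hazard_ratios.iloc[0] == pytest.approx(1.0, abs=1e-8)


def _dummy_fit(ll, k):
    s = pd.Series(np.zeros(k), index=[f"b{i}" for i in range(k)])
    return surv.CoxFit(coefficients=s, hazard_ratios=s, ci_lower=s, ci_upper=s,
                       standard_errors=s, p_values=s, log_likelihood=ll,
                       n=10, n_events=5, concordance=None)


def test_lr_test_identical_models_p_one_and_df_mismatch_error():
    assert surv.lr_test(_dummy_fit(-20.0, 2), _dummy_fit(-20.0, 1))[2] == 1.0
    with pytest.raises(ValueError):
        surv.lr_test(_dummy_fit(-20.0, 1), _dummy_fit(-21.0, 1))


def test_lr_test_detects_strong_covariate():
    rng = np.random.default_rng(2)
    n = 200
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.1 * np.exp(1.2 * x)))
    df = pd.DataFrame({"time": np.minimum(t, 20.0), "event": (t <= 20.0).astype(int),
                       "x": x, "z": rng.normal(size=n)})
    full = surv.fit_cox(df, covariates=["x", "z"])
    reduced = surv.fit_cox(df, covariates=["z"])
    stat, dof, p = surv.lr_test(full, reduced)
    assert dof == 1 and p < 0.05


def test_wald_ci_brackets_hazard_ratio(sim_braf):
    tls = mk.build_timelines(sim_braf.measurements, sim_braf.metadata)
    rng = np.random.default_rng(3)
    n = 120
    x = rng.normal(size=n)
    t = rng.exponential(1 / (0.2 * np.exp(0.5 * x)))
    df = pd.DataFrame({"time": t, "event": 1, "x": x})
    fit = surv.fit_cox(df, covariates=["x"])
    assert fit.ci_lower.iloc[0] < fit.hazard_ratios.iloc[0] < fit.ci_upper.iloc[0]


# ---------------------------------------------------------------------------
# martingale diagnostics
# ---------------------------------------------------------------------------

def _exp_cohort(n, beta, transform, seed):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0.0, 0.8, n)
    lam = 0.1 * np.exp(beta * transform(x))
    t = rng.exponential(1 / lam)
    c = np.full(n, 30.0)
    return pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int),
                         "x": x})


def test_martingale_residuals_sum_to_zero_and_flat_under_null():
    df = _exp_cohort(150, 0.0, np.log, seed=5)
    fit = surv.fit_cox(df, covariates=["x"])
    table = surv.martingale_diagnostic(fit, df, "x")
    assert table["martingale_residual"].sum() == pytest.approx(0.0, abs=1e-6)
    # flat over the well-populated covariate range (the sparse tail wiggles)
    lo, hi = table["covariate"].quantile([0.05, 0.95])
    central = table[(table["covariate"] >= lo) & (table["covariate"] <= hi)]
    assert np.abs(central["lowess"]).max() < 0.35
    # plotting path draws the scatter + smooth on a provided axis
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots()
    surv.martingale_diagnostic(fit, df, "x", ax=ax)
    assert len(ax.lines) >= 2
    plt.close(fig)


def test_martingale_curvature_for_misspecified_functional_form():
    """A log-linear effect entered raw shows more curvature than entered
    on the log scale."""
    df = _exp_cohort(250, 1.2, np.log, seed=6)
    raw = surv.martingale_diagnostic(surv.fit_cox(df, covariates=["x"]), df, "x")
    dfl = df.assign(x=np.log(df["x"]))
    logged = surv.martingale_diagnostic(surv.fit_cox(dfl, covariates=["x"]), dfl, "x")
    assert np.ptp(raw["lowess"]) > 1.5 * np.ptp(logged["lowess"])


def test_maybe_log_transform_rule():
    wide = pd.Series(np.geomspace(0.01, 10.0, 20))
    out, did = surv.maybe_log_transform(wide)
    assert did and np.allclose(out, np.log(wide))
    narrow = pd.Series(np.linspace(1.0, 3.0, 20))
    _, did = surv.maybe_log_transform(narrow)
    assert not did
    signed = pd.Series(np.linspace(-5.0, 5.0, 20))
    _, did = surv.maybe_log_transform(signed)
    assert not did  # scores with non-positive values are exempt


# ---------------------------------------------------------------------------
# multistate
# ---------------------------------------------------------------------------

def test_transition_rows_for_brain_death_patient():
    p = pd.DataFrame([{"patient_id": "A", "entry": 1.0, "time": 10.0, "event": 1,
                       "death_cause": "brain", "brain_time": 4.0}])
    tdf = surv.build_transition_dataset(p, model="brain")
    rows = tdf.set_index("transition")
    assert rows.loc["onstudy->brain", "status"] == 1
    assert rows.loc["onstudy->brain", "exit"] == 4.0
    assert rows.loc["onstudy->death_other", "status"] == 0
    assert rows.loc["brain->death_brain", "status"] == 1
    assert rows.loc["brain->death_other", "status"] == 0


def test_transition_rows_for_censored_patient():
    p = pd.DataFrame([{"patient_id": "B", "entry": 1.0, "time": 12.0, "event": 0,
                       "death_cause": "", "brain_time": np.nan}])
    tdf = surv.build_transition_dataset(p, model="brain")
    assert (tdf["status"] == 0).all()
    assert (tdf["exit"] == 12.0).all()


def _markov_cohort(n, seed, h12=0.10, h13=0.05, h23=0.25, censor=15.0, beta13=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        x = float(rng.integers(0, 2))
        t12 = rng.exponential(1 / h12)
        t13 = rng.exponential(1 / (h13 * np.exp(beta13 * x)))
        if t13 <= t12:  # death straight from the initial state
            t_end, ev, pd_t = t13, 1, np.nan
        else:
            t_death = t12 + rng.exponential(1 / h23)
            t_end, ev, pd_t = t_death, 1, t12
        if t_end > censor:
            ev = 0
            t_end = censor
            if not np.isnan(pd_t) and pd_t >= censor:
                pd_t = np.nan
        rows.append({"patient_id": i, "entry": 0.0, "time": t_end, "event": ev,
                     "pd_time": pd_t, "x": x})
    return pd.DataFrame(rows)


def test_multistate_event_count_conservation():
    pats = _markov_cohort(200, seed=8)
    tdf = surv.build_transition_dataset(pats, model="recist", covariates=["x"])
    deaths = int(pats["event"].sum())
    terminal = tdf[tdf["to_state"] == "death"]["status"].sum()
    assert terminal == deaths
    inter = tdf[tdf["transition"] == "onstudy->pd"]["status"].sum()
    assert inter == pats["pd_time"].notna().sum()


def test_markov_hazards_recovered_from_counting_process():
    """Nelson-Aalen on each transition's stacked rows recovers the constant
    true hazards (cumulative hazard ~ h*t)."""
    from lifelines import NelsonAalenFitter

    h = {"onstudy->pd": 0.10, "onstudy->death": 0.05, "pd->death": 0.25}
    pats = _markov_cohort(500, seed=9)
    tdf = surv.build_transition_dataset(pats, model="recist")
    for tr, h_true in h.items():
        sub = tdf[tdf["transition"] == tr]
        naf = NelsonAalenFitter().fit(sub["exit"], sub["status"], entry=sub["entry"])
        t_eval = 6.0
        est = float(naf.cumulative_hazard_at_times(t_eval).iloc[0])
        assert est == pytest.approx(h_true * t_eval, rel=0.25)


def test_covariate_effect_isolated_to_its_transition():
    """A covariate acting only on death-from-initial-state shows its effect
    there and near-zero effects elsewhere."""
    pats = _markov_cohort(600, seed=10, beta13=1.0)
    tdf = surv.build_transition_dataset(pats, model="recist", covariates=["x"])
    res = surv.fit_multistate(tdf)
    eff = res["effects"].set_index("term")
    assert eff.loc["x@onstudy->death", "coef"] == pytest.approx(1.0, abs=0.35)
    assert abs(eff.loc["x@onstudy->pd", "coef"]) < 0.3
    assert abs(eff.loc["x@pd->death", "coef"]) < 0.3


def test_nonproportional_baselines_rejected():
    """Two transitions with wildly different baseline hazard shapes fail the
    shared-baseline (proportionality) test."""
    rng = np.random.default_rng(11)
    n = 300
    early = rng.weibull(0.5, n) * 2.0   # events pile up immediately
    late = 8.0 + rng.weibull(5.0, n)    # events cluster late
    rows = []
    for i in range(n):
        rows.append({"patient_id": f"a{i}", "transition": "t1", "entry": 0.0,
                     "exit": min(early[i], 12.0), "status": int(early[i] <= 12.0)})
        rows.append({"patient_id": f"b{i}", "transition": "t2", "entry": 0.0,
                     "exit": min(late[i], 12.0), "status": int(late[i] <= 12.0)})
    p = surv.proportional_baselines_test(pd.DataFrame(rows))
    assert p < 0.05


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

def test_covariate_screen_dedup_and_joint_fit():
    rng = np.random.default_rng(12)
    n = 150
    x1 = rng.normal(size=n)
    x2 = x1 + rng.normal(scale=0.1, size=n)  # near-duplicate of x1
    x3 = rng.normal(size=n)                  # pure noise
    t = rng.exponential(1 / (0.1 * np.exp(0.9 * x1)))
    df = pd.DataFrame({"time": np.minimum(t, 25.0), "event": (t <= 25.0).astype(int),
                       "x1": x1, "x2": x2, "x3": x3})
    out = surv.covariate_screen(df, ["x1", "x2", "x3"])
    assert "x1" in out["selected"]
    assert "x2" in out["dropped"]  # correlated pair keeps the more significant
    joint = out["joint"]
    assert joint.p_values["x1"] < 0.01


def test_covariate_screen_empty_set_errors():
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0]})
    with pytest.raises(ValueError):
        surv.covariate_screen(df, [])
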