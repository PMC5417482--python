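"""Survival inference: left-truncated Cox regression, likelihood-ratio model
selection, martingale-residual diagnostics, covariate screening, and
multistate models on counting-process data.

Overall survival is measured from treatment start, with delayed entry at the
first post-treatment evaluation (patients only join the risk set once the
eligibility criteria are met).  Fits use the Cox proportional-hazards partial
likelihood with Efron tie handling.

Two multistate structures are supported, both fitted as a single stratified
Cox model on stacked counting-process rows (clock-forward, Markov):

* ``brain``:  on-study -> brain-mets; on-study -> death-other;
  brain-mets -> death-brain; brain-mets -> death-other
* ``recist``: on-study -> recist-pd; on-study -> death; recist-pd -> death

Each transition is a stratum with its own baseline hazard; covariates act
transition-specifically through covariate-by-transition interaction columns,
so an effect can be modelled on any configurable subset of transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "fit_cox",
    "lr_test",
    "martingale_diagnostic",
    "maybe_log_transform",
    "MULTISTATE_MODELS",
    "build_transition_dataset",
    "fit_multistate",
    "proportional_baselines_test",
    "covariate_screen",
]


@dataclass
class CoxFit:
    """A fitted Cox model: coefficients, hazard ratios with Wald 95% CIs."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    concordance: float | None
    model: CoxPHFitter = field(repr=False, default=None)

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients, "HR": self.hazard_ratios,
            "HR_lower95": self.ci_lower, "HR_upper95": self.ci_upper,
            "se": self.standard_errors, "p": self.p_values,
        })


def _wrap_fit(cph: CoxPHFitter, df: pd.DataFrame, event_col: str) -> CoxFit:
    s = cph.summary
    try:
        conc = float(cph.concordance_index_)
    except Exception:
        conc = None
    return CoxFit(
        coefficients=s["coef"].copy(),
        hazard_ratios=np.exp(s["coef"]),
        ci_lower=np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
        ci_upper=np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
        standard_errors=s["se(coef)"].copy(),
        p_values=s["p"].copy(),
        log_likelihood=float(cph.log_likelihood_),
        n=len(df), n_events=int(df[event_col].sum()),
        concordance=conc, model=cph,
    )


def fit_cox(
    df: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    entry_col: str | None = None,
    covariates: list | None = None,
    strata: list | str | None = None,
    robust: bool = False,
    penalizer: float = 0.0,
) -> CoxFit:
    """Fit a Cox PH model, optionally left-truncated (delayed entry).

    `covariates` restricts the design matrix; by default every column other
    than the time/event/entry/strata bookkeeping enters.  Ties are handled by
    the Efron approximation.  Raises on non-finite covariates, no events, or
    entry >= exit rows.
    """
    if df[event_col].sum() == 0:
        raise ValueError("no events in the data")
    if entry_col is not None:
        bad = df[df[entry_col] >= df[duration_col]]
        if len(bad):
            raise ValueError(f"entry >= exit for {len(bad)} rows")
    keep = [duration_col, event_col]
    if entry_col:
        keep.append(entry_col)
    strata_cols = [strata] if isinstance(strata, str) else list(strata or [])
    keep += strata_cols
    if covariates is None:
        covariates = [c for c in df.columns if c not in keep and c != "patient_id"]
    X = df[keep + list(covariates)].copy()
    if not np.isfinite(X[covariates].to_numpy(float)).all():
        raise ValueError("non-finite covariate values")
    const = [c for c in covariates if X[c].nunique() <= 1]
    if const:
        # a constant covariate carries no information: coefficient 0, HR 1
        logger.warning("constant covariates %s: coefficients fixed at 0", const)
        varying = [c for c in covariates if c not in const]
        if varying:
            fit = fit_cox(df, duration_col, event_col, entry_col, varying,
                          strata, robust, penalizer)
        else:
            fit = _null_coxfit(X, duration_col, event_col, entry_col)
        zeros = pd.Series(0.0, index=const)
        nans = pd.Series(np.nan, index=const)
        fit.coefficients = pd.concat([fit.coefficients, zeros])
        fit.hazard_ratios = pd.concat([fit.hazard_ratios, zeros + 1.0])
        fit.ci_lower = pd.concat([fit.ci_lower, nans])
        fit.ci_upper = pd.concat([fit.ci_upper, nans])
        fit.standard_errors = pd.concat([fit.standard_errors, nans])
        fit.p_values = pd.concat([fit.p_values, nans])
        return fit
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(
            X, duration_col=duration_col, event_col=event_col,
            entry_col=entry_col, strata=strata_cols or None, robust=robust,
        )
    except Exception as exc:  # convergence/separation diagnostics surfaced
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    return _wrap_fit(cph, X, event_col)


def _efron_null_loglik(time, event, entry) -> float:
    """Efron partial log-likelihood at beta = 0 (risk-set counting only)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d = int(((time == t) & (event == 1)).sum())
        n_risk = int(((entry < t) & (time >= t)).sum())
        # at beta=0 the Efron denominator collapses to n_risk - j
        ll -= sum(np.log(n_risk - j) for j in range(d))
    return ll


def _null_coxfit(X, duration_col, event_col, entry_col) -> CoxFit:
    time = X[duration_col].to_numpy(float)
    event = X[event_col].to_numpy(int)
    entry = X[entry_col].to_numpy(float) if entry_col else np.zeros_like(time)
    empty = pd.Series(dtype=float)
    return CoxFit(coefficients=empty.copy(), hazard_ratios=empty.copy(),
                  ci_lower=empty.copy(), ci_upper=empty.copy(),
                  standard_errors=empty.copy(), p_values=empty.copy(),
                  log_likelihood=_efron_null_loglik(time, event, entry),
                  n=len(X), n_events=int(event.sum()), concordance=None)


def lr_test(full: CoxFit, reduced: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Cox fits: (statistic, df, p-value)."""
    df_diff = full.n_parameters - reduced.n_parameters
    if df_diff <= 0:
        raise ValueError("'full' must have strictly more parameters than 'reduced'")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df_diff))
    return float(stat), df_diff, p


def null_log_likelihood(fit: CoxFit) -> float:
    """Partial log-likelihood of the covariate-free model nested in `fit`."""
    lrt = fit.model.log_likelihood_ratio_test()
    return fit.log_likelihood - float(lrt.test_statistic) / 2.0


def martingale_diagnostic(
    fit: CoxFit, df: pd.DataFrame, covariate: str, lowess_frac: float = 0.6,
    ax=None,
):
    """Martingale residuals against one covariate, with a lowess smooth.

    Used graphically to judge the functional form of a continuous covariate:
    a flat smooth supports the fitted (log-linear) form; curvature suggests a
    transformation.  Returns a tidy table (covariate value, residual,
    smooth); pass a matplotlib ``ax`` to also draw the diagnostic plot.
    """
    import statsmodels.api as sm

    resid = fit.model.compute_residuals(training_dataframe=df, kind="martingale")
    out = pd.DataFrame({
        "covariate": df.loc[resid.index, covariate].to_numpy(float),
        "martingale_residual": resid["martingale"].to_numpy(float),
    }).sort_values("covariate", ignore_index=True)
    smooth = sm.nonparametric.lowess(
        out["martingale_residual"], out["covariate"], frac=lowess_frac, return_sorted=False,
    )
    out["lowess"] = smooth
    if ax is not None:
        ax.scatter(out["covariate"], out["martingale_residual"], s=12, alpha=0.5)
        ax.plot(out["covariate"], out["lowess"], color="C1", lw=2)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(covariate)
        ax.set_ylabel("martingale residual")
    return out


def maybe_log_transform(series: pd.Series, span_orders: float = 2.0) -> tuple[pd.Series, bool]:
    """Log-transform a positive covariate spanning >= `span_orders` orders of magnitude.

    Covariates with non-positive values (e.g. a risk score that can be
    negative for shrinking disease) are exempt and returned unchanged.
    """
    x = series.astype(float)
    if (x <= 0).any():
        return x, False
    if np.log10(x.max() / x.min()) >= span_orders:
        return np.log(x), True
    return x, False


# ---------------------------------------------------------------------------
# multistate models
# ---------------------------------------------------------------------------

#: state graphs: transition id -> (from-state, to-state)
MULTISTATE_MODELS = {
    "brain": {
        "onstudy->brain": ("onstudy", "brain"),
        "onstudy->death_other": ("onstudy", "death_other"),
        "brain->death_brain": ("brain", "death_brain"),
        "brain->death_other": ("brain", "death_other"),
    },
    "recist": {
        "onstudy->pd": ("onstudy", "pd"),
        "onstudy->death": ("onstudy", "death"),
        "pd->death": ("pd", "death"),
    },
}


def build_transition_dataset(
    patients: pd.DataFrame,
    model: str = "brain",
    transitions: dict | None = None,
    covariates: list | None = None,
) -> pd.DataFrame:
    """Stack counting-process rows for a multistate model.

    `patients` has one row per patient with ``entry`` (delayed-entry time,
    0 if none), ``time`` (death/censoring), ``event``, plus the
    intermediate-state onset time: ``brain_time`` (first scan showing brain
    metastases; NaN if never) and ``death_cause`` (``brain``/``other``) for
    the brain model, or ``pd_time`` for the RECIST model.  Covariate columns
    listed in `covariates` are carried onto every row.

    Each patient contributes, for every transition reachable from the states
    they occupy, one row (entry, exit, status); at most one terminal event
    per patient.  Clock-forward time scale (time since treatment start).
    """
    trans = transitions or MULTISTATE_MODELS[model]
    covariates = covariates or []
    inter_col = "brain_time" if model == "brain" else "pd_time"
    rows = []
    for _, p in patients.iterrows():
        entry = float(p.get("entry", 0.0) or 0.0)
        t_end = float(p["time"])
        died = int(p["event"]) == 1
        t_inter = p.get(inter_col, np.nan)
        t_inter = None if pd.isna(t_inter) else float(t_inter)
        if t_inter is not None and t_inter >= t_end:
            t_inter = None  # onset at/after end of follow-up: never occupies the state

        covs = {c: p[c] for c in covariates}

        def emit(tr, start, stop, status):
            if stop > start:
                rows.append({"patient_id": p["patient_id"], "transition": tr,
                             "from_state": trans[tr][0], "to_state": trans[tr][1],
                             "entry": start, "exit": stop, "status": int(status), **covs})

        # a patient already in the intermediate state at entry contributes no
        # on-study rows; their downstream rows start at entry
        if model == "brain":
            cause = str(p.get("death_cause") or "")
            stop1 = t_inter if t_inter is not None else t_end
            emit("onstudy->brain", entry, stop1, t_inter is not None)
            emit("onstudy->death_other", entry, stop1,
                 t_inter is None and died and cause != "brain")
            if t_inter is not None:
                start2 = max(t_inter, entry)
                emit("brain->death_brain", start2, t_end, died and cause == "brain")
                emit("brain->death_other", start2, t_end, died and cause != "brain")
        else:
            stop1 = t_inter if t_inter is not None else t_end
            emit("onstudy->pd", entry, stop1, t_inter is not None)
            emit("onstudy->death", entry, stop1, t_inter is None and died)
            if t_inter is not None:
                emit("pd->death", max(t_inter, entry), t_end, died)
    out = pd.DataFrame(rows)
    if len(out):
        n_term = out[out["to_state"].str.contains("death")].groupby("patient_id")["status"].sum()
        if (n_term > 1).any():
            raise AssertionError("more than one terminal event for a patient")
    return out


def fit_multistate(
    tdata: pd.DataFrame,
    covariate_map: dict | None = None,
    shared_baseline: bool = False,
    min_events: int = 1,
    penalizer: float = 0.0,
) -> dict:
    """Fit transition-specific Cox models on stacked counting-process data.

    One stratified Cox fit (stratum = transition, so each transition keeps
    its own baseline hazard) with covariate-by-transition interaction columns:
    `covariate_map` maps a covariate name to the list of transitions it acts
    on (default: all transitions with at least one event).  Transitions
    without events are skipped for covariate effects, with a logged notice.

    Returns ``{"fit": CoxFit, "effects": tidy DataFrame, "events": per-
    transition event counts}``.  With ``shared_baseline=True`` the transition
    enters as dummy covariates instead of strata (proportional baselines).
    """
    events = tdata.groupby("transition")["status"].sum()
    live = [t for t in events.index if events[t] >= max(min_events, 1)]
    for t in events.index:
        if t not in live:
            logger.warning("transition %s has %d events (< %d); covariate effects skipped",
                           t, events[t], max(min_events, 1))
    if covariate_map is None:
        base = [c for c in tdata.columns
                if c not in ("patient_id", "transition", "from_state", "to_state",
                             "entry", "exit", "status")]
        covariate_map = {c: live for c in base}

    df = tdata.copy()
    design = []
    for cov, trs in covariate_map.items():
        for tr in trs:
            if tr not in live:
                continue
            col = f"{cov}@{tr}"
            df[col] = df[cov].astype(float) * (df["transition"] == tr).astype(float)
            design.append(col)
    if shared_baseline:
        trans_levels = sorted(df["transition"].unique())
        for tr in trans_levels[1:]:
            col = f"baseline[{tr}]"
            df[col] = (df["transition"] == tr).astype(float)
            design.append(col)
        strata = None
    else:
        strata = "transition"

    fit = fit_cox(df, duration_col="exit", event_col="status", entry_col="entry",
                  covariates=design, strata=strata, penalizer=penalizer)
    eff = fit.summary().reset_index(names="term")
    eff[["covariate", "transition"]] = eff["term"].str.extract(r"^(.*?)(?:@(.*))?$")
    return {"fit": fit, "effects": eff, "events": events}


def proportional_baselines_test(tdata: pd.DataFrame) -> float:
    """Test proportionality of baseline hazards across transitions.

    Fits the shared-baseline model (transition as dummy covariates) and runs
    a Schoenfeld-residual proportional-hazards test on the transition
    dummies: strongly non-proportional transition-specific baselines show up
    as time-varying dummy effects.  Returns the smallest dummy p-value.
    """
    from lifelines.statistics import proportional_hazard_test

    df = tdata.copy()
    trans_levels = sorted(df["transition"].unique())
    design = []
    for tr in trans_levels[1:]:
        col = f"baseline[{tr}]"
        df[col] = (df["transition"] == tr).astype(float)
        design.append(col)
    # lifelines' Schoenfeld machinery does not support delayed entry, so the
    # proportionality test is run on the fit without the entry column; entry
    # times still shape the effect estimates in fit_multistate itself
    X = df[["exit", "status"] + design]
    fit = fit_cox(X, duration_col="exit", event_col="status", covariates=design)
    res = proportional_hazard_test(fit.model, X, time_transform="rank")
    return float(res.summary["p"].min())


def covariate_screen(
    data: pd.DataFrame,
    covariates: list,
    duration_col: str = "time",
    event_col: str = "event",
    entry_col: str | None = None,
    anchor: str | None = None,
    corr_threshold: float = 0.8,
) -> dict:
    """Single-covariate Cox screen, correlation de-duplication, and joint fit.

    Each covariate is first fitted alone (after the automatic log-transform
    rule for positive covariates spanning orders of magnitude) and scored by
    the likelihood-ratio p-value against the null model.  Pairs of retained
    covariates with \\|Spearman rho\\| above `corr_threshold` are de-duplicated,
    keeping the more significant.  The survivors (plus `anchor`, e.g. the
    RECIST PD flag, which always enters) go into one joint model.

    Returns ``{"table": per-covariate results, "selected": names,
    "joint": CoxFit}``.
    """
    if not covariates:
        raise ValueError("empty covariate set")
    work = data.copy()
    transformed = {}
    for c in covariates:
        work[c], transformed[c] = maybe_log_transform(work[c])

    rows = []
    for c in covariates:
        fit = fit_cox(work, duration_col, event_col, entry_col, covariates=[c])
        p = float(fit.model.log_likelihood_ratio_test().p_value)
        rows.append({"covariate": c, "log_transformed": transformed[c],
                     "coef": fit.coefficients.iloc[0], "HR": fit.hazard_ratios.iloc[0],
                     "HR_lower95": fit.ci_lower.iloc[0], "HR_upper95": fit.ci_upper.iloc[0],
                     "p_lr": p})
    table = pd.DataFrame(rows).sort_values("p_lr", ignore_index=True)

    selected = list(table["covariate"])
    dropped = set()
    for i, ci in enumerate(selected):
        if ci in dropped:
            continue
        for cj in selected[i + 1:]:
            if cj in dropped:
                continue
            rho = stats.spearmanr(work[ci], work[cj]).statistic
            if np.isfinite(rho) and abs(rho) > corr_threshold:
                dropped.add(cj)  # table is sorted by significance; keep the better
    selected = [c for c in selected if c not in dropped]

    joint_covs = list(dict.fromkeys(selected + ([anchor] if anchor else [])))
    if anchor and anchor not in work.columns:
        raise ValueError(f"anchor covariate {anchor!r} not in data")
    joint = fit_cox(work, duration_col, event_col, entry_col, covariates=joint_covs)
    return {"table": table, "selected": selected, "dropped": sorted(dropped), "joint": joint}
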