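"""Phenotypic-association stage on registry data.

Survival analysis runs on the age timescale with delayed entry (subjects
enter risk sets at their entry age, not birth) and a time-varying
diagnosis exposure handled through counting-process rows:

* ``build_counting_process`` splits each person's follow-up at the
  diagnosis age into exposure-constant (start, stop] intervals;
* ``cox_fit`` wraps a time-varying Cox partial-likelihood fit (Efron tie
  handling);
* ``km_cumulative_incidence`` gives 1 - Kaplan-Meier survival per group
  with log(-log) Greenwood confidence bands, assuming no competing risks;
* ``ols_cluster_robust`` is the standardized linear-regression stage with
  cluster-sandwich standard errors for paired (e.g. twin) observations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxTimeVaryingFitter, KaplanMeierFitter

__all__ = [
    "build_counting_process",
    "cox_fit",
    "SurvivalCurve",
    "km_cumulative_incidence",
    "ols_cluster_robust",
]


def build_counting_process(registry: pd.DataFrame, outcome: str,
                           by_ref: float | None = None) -> pd.DataFrame:
    """Counting-process rows for one outcome category.

    A person diagnosed at age d inside (entry, stop) contributes an
    unexposed row (entry, d] and an exposed row (d, stop]; diagnosis before
    entry gives a single exposed row, diagnosis after stop (or none) a
    single unexposed row.  ``stop`` is the event age when the outcome
    occurred, otherwise the censoring age.  The event flag sits on the
    final row only.
    """
    col = f"{outcome}_age"
    if col not in registry.columns:
        raise KeyError(f"outcome column {col!r} not in registry")
    if by_ref is None:
        by_ref = float(registry["birth_year"].mean())
    entry = registry["entry_age"].to_numpy(dtype=float)
    event_age = registry[col].to_numpy(dtype=float)
    exit_age = registry["exit_age"].to_numpy(dtype=float)
    stop = np.where(np.isnan(event_age), exit_age, event_age)
    event = (~np.isnan(event_age)).astype(int)
    bad = stop <= entry
    if np.any(bad):
        pid = registry["person_id"].to_numpy()[bad][0]
        raise ValueError(f"event/censoring age <= entry age for person {pid}")
    dx = registry["ocd_dx_age"].to_numpy(dtype=float)
    byc = (registry["birth_year"].to_numpy(dtype=float) - by_ref) / 10.0
    sex = registry["sex"].to_numpy()
    pid = registry["person_id"].to_numpy()

    split = ~np.isnan(dx) & (dx > entry) & (dx < stop)
    pre_dx = np.isnan(dx) | (dx >= stop)

    def rows(mask, start_a, stop_a, exposed, ev):
        return pd.DataFrame({
            "person_id": pid[mask], "start_age": start_a[mask],
            "stop_age": stop_a[mask], "event": ev[mask].astype(int),
            "exposed": exposed, "sex": sex[mask], "byc": byc[mask],
        })

    zeros = np.zeros_like(event)
    out = pd.concat([
        rows(pre_dx, entry, stop, 0, event),                    # never exposed in window
        rows(~pre_dx & ~split, entry, stop, 1, event),          # exposed from entry
        rows(split, entry, np.where(split, dx, 0.0), 0, zeros),  # pre-diagnosis part
        rows(split, np.where(split, dx, 0.0), stop, 1, event),  # post-diagnosis part
    ], ignore_index=True)
    return out.sort_values(["person_id", "start_age"], ignore_index=True)


def cox_fit(rows: pd.DataFrame, covariates=("exposed", "sex", "byc")) -> dict:
    """Cox proportional hazards on (start, stop] rows, age as the timescale.

    Efron tie handling; delayed entry comes from the counting-process risk
    sets.  Returns hazard ratios with Wald 95% CIs and the partial
    log-likelihood.
    """
    covariates = list(covariates)
    if rows["event"].sum() < 1:
        raise ValueError("no events; Cox model not estimable")
    for c in covariates:
        if rows[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant; not identifiable")
    data = rows[["person_id", "start_age", "stop_age", "event"] + covariates]
    last_err = None
    for step in (0.95, 0.5, 0.25, 0.1):
        ctv = CoxTimeVaryingFitter()
        try:
            ctv.fit(data, id_col="person_id", start_col="start_age",
                    stop_col="stop_age", event_col="event",
                    fit_options={"step_size": step})
            last_err = None
            break
        except Exception as err:  # Newton overflow: retry with damped steps
            last_err = err
    if last_err is not None:
        raise RuntimeError(
            f"Cox partial-likelihood maximization did not converge "
            f"(possible separation): {last_err}") from last_err
    s = ctv.summary
    return {
        "coef": s["coef"].to_dict(),
        "se": s["se(coef)"].to_dict(),
        "hr": s["exp(coef)"].to_dict(),
        "hr_ci": {k: (float(s.loc[k, "exp(coef) lower 95%"]),
                      float(s.loc[k, "exp(coef) upper 95%"])) for k in s.index},
        "loglik": float(ctv.log_likelihood_),
        "n_events": int(rows["event"].sum()),
        "model": ctv,
    }


@dataclass
class SurvivalCurve:
    """A delayed-entry Kaplan-Meier curve for one group."""

    group: str
    ages: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    entry_min: float

    def cumulative_incidence_at(self, age: float) -> float:
        """1 - S(age); NaN (undefined) before the group's entry support."""
        if age < self.entry_min:
            return float("nan")
        i = np.searchsorted(self.ages, age, side="right") - 1
        return float(1.0 - (self.survival[i] if i >= 0 else 1.0))

    def ci_at(self, age: float) -> tuple:
        i = np.searchsorted(self.ages, age, side="right") - 1
        if age < self.entry_min or i < 0:
            return (float("nan"), float("nan"))
        return (float(1.0 - self.ci_upper[i]), float(1.0 - self.ci_lower[i]))


def km_cumulative_incidence(registry: pd.DataFrame, outcome: str,
                            group_col: str = "ocd") -> dict:
    """Kaplan-Meier cumulative incidence (no competing risks) per group.

    Product-limit estimator with delayed entry; pointwise 95% CIs on the
    log(-log) scale.  Groups must partition persons via ``group_col``.
    """
    col = f"{outcome}_age"
    entry = registry["entry_age"].to_numpy(dtype=float)
    event_age = registry[col].to_numpy(dtype=float)
    stop = np.where(np.isnan(event_age), registry["exit_age"].to_numpy(dtype=float),
                    event_age)
    event = ~np.isnan(event_age)
    curves = {}
    for g in np.unique(registry[group_col].to_numpy()):
        m = (registry[group_col] == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(durations=stop[m], event_observed=event[m], entry=entry[m],
                label=str(g))
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_survival_function_
        curves[g] = SurvivalCurve(
            group=str(g), ages=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(),
            ci_lower=ci.iloc[:, 0].to_numpy(), ci_upper=ci.iloc[:, 1].to_numpy(),
            n=int(m.sum()), entry_min=float(entry[m].min()))
    return curves


def ols_cluster_robust(df: pd.DataFrame, outcome: str, exposure: str,
                       covariates=("sex", "byc"), cluster: str = "pair_id") -> dict:
    """Standardized linear regression with cluster-robust (sandwich) SEs.

    Outcome and exposure are z-scored on the analysis sample; covariates
    enter untransformed.  The sandwich estimator uses the small-sample
    factor G/(G-1) * (N-1)/(N-k).
    """
    covariates = list(covariates)
    cols = [outcome, exposure, cluster] + covariates
    d = df[cols].dropna()
    groups = d[cluster]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 clusters for cluster-robust errors")
    y = (d[outcome] - d[outcome].mean()) / d[outcome].std(ddof=1)
    x = (d[exposure] - d[exposure].mean()) / d[exposure].std(ddof=1)
    X = sm.add_constant(pd.concat([x.rename(exposure), d[covariates]], axis=1))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y.to_numpy(), X).fit(cov_type="cluster",
                                      cov_kwds={"groups": groups.to_numpy()},
                                      use_t=True)
    ci = res.conf_int()
    return {
        "beta": res.params.to_dict(),
        "se": res.bse.to_dict(),
        "ci": {k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in res.params.index},
        "n": int(res.nobs),
        "n_clusters": int(groups.nunique()),
        "model": res,
    }
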