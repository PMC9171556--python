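"""Bivariate ACE model fitting for kinship pair data.

Two likelihoods share one parameterization:

* continuous traits — full-information maximum likelihood (FIML): each pair
  contributes the multivariate-normal log-density of its observed subset of
  the 4-vector (member1 trait1, member1 trait2, member2 trait1, member2
  trait2), with means from a linear sex/birth-year model and covariance
  implied by the pair type;
* binary traits — a liability-threshold likelihood: pairs are aggregated
  into 16-cell tables per pair type and covariate stratum, and each cell
  probability is a rectangle of the implied 4-dimensional liability normal
  with thresholds shifted per stratum.

The free parameters are the entries of the component matrices themselves
(direct-symmetric parameterization), so estimated variance contributions
may go negative; the total phenotypic covariance must stay positive
definite, enforced through a penalty.  For binary traits the liability
scale is identified by fixing the total variance to 1 per trait: the
nonshared-environmental diagonal is derived, not free.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import approx_fprime, minimize
from scipy.stats import chi2

from .liability import mvn_rectangles_batch, tetrachoric_mle, threshold_from_prevalence
from .types import (PAIR_TYPES, ComponentMatrices, DerivedEstimates,
                    FitResult, ModelComparison, PairType)

__all__ = [
    "AceModelSpec",
    "implied_pair_covariance",
    "continuous_pair_loglik",
    "binary_pair_loglik",
    "binary_cell_counts",
    "fit_ace",
    "compare_models",
    "derived_estimates",
    "fit_model_ladder",
]

_PENALTY = 1e10
_TRAITS = ("trait1", "trait2")
_VAL_COLS = ["m1_trait1", "m1_trait2", "m2_trait1", "m2_trait2"]


@dataclass(frozen=True)
class AceModelSpec:
    """Which components are free, the measurement scale, and covariates.

    ``included`` is a subset of {"A", "C", "E"} applied to both traits
    (the e.g. AE-AE rung of the model ladder); E is always included.
    """

    included: tuple = ("A", "C", "E")
    measurement: str = "continuous"
    covariates: bool = True

    def __post_init__(self) -> None:
        if "E" not in self.included:
            raise ValueError("the nonshared environmental component E is always included")
        if not set(self.included) <= {"A", "C", "E"}:
            raise ValueError(f"unknown components in {self.included}")
        if self.measurement not in ("continuous", "binary"):
            raise ValueError("measurement must be 'continuous' or 'binary'")

    @property
    def label(self) -> str:
        order = [c for c in ("A", "C", "E") if c in self.included]
        tag = "".join(order)
        return f"{tag}-{tag}"

    @property
    def n_mean_coefs(self) -> int:
        return 3 if self.covariates else 1

    def param_names(self) -> list:
        names = []
        for comp in ("A", "C"):
            if comp in self.included:
                names += [f"{comp}11", f"{comp}12", f"{comp}22"]
        if self.measurement == "continuous":
            names += ["E11", "E12", "E22"]
        else:
            names += ["E12"]
        coef = ["b0"] + (["b_sex", "b_by"] if self.covariates else [])
        for t in (1, 2):
            names += [f"{c}_t{t}" for c in coef]
        return names

    @property
    def n_free(self) -> int:
        return len(self.param_names())


def _unpack(theta: np.ndarray, spec: AceModelSpec):
    """theta -> (ComponentMatrices, mean/threshold coefs per trait)."""
    i = 0
    mats = {}
    for comp in ("A", "C"):
        if comp in spec.included:
            v11, v12, v22 = theta[i:i + 3]
            mats[comp] = np.array([[v11, v12], [v12, v22]])
            i += 3
        else:
            mats[comp] = np.zeros((2, 2))
    if spec.measurement == "continuous":
        v11, v12, v22 = theta[i:i + 3]
        mats["E"] = np.array([[v11, v12], [v12, v22]])
        i += 3
    else:
        e12 = theta[i]
        i += 1
        e11 = 1.0 - mats["A"][0, 0] - mats["C"][0, 0]
        e22 = 1.0 - mats["A"][1, 1] - mats["C"][1, 1]
        mats["E"] = np.array([[e11, e12], [e12, e22]])
    k = spec.n_mean_coefs
    coefs = [theta[i:i + k], theta[i + k:i + 2 * k]]
    comps = ComponentMatrices(V_A=mats["A"], V_C=mats["C"], V_E=mats["E"])
    return comps, coefs


def implied_pair_covariance(components: ComponentMatrices,
                            pair_type: PairType | str) -> np.ndarray:
    """4x4 covariance [[P, R], [R, P]] for a pair of the given type.

    P = V_A + V_C + V_E within person; R = r_A V_A + r_C V_C across members.
    """
    if isinstance(pair_type, str):
        pair_type = PairType.from_label(pair_type)
    P = components.total
    R = pair_type.r_A * components.V_A + pair_type.r_C * components.V_C
    return np.block([[P, R], [R, P]])


def _pd_violation(sigma: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(sigma)
    return float(max(0.0, 1e-8 - ev.min()))


def _mean_matrix(coefs, sex: np.ndarray, byc: np.ndarray,
                 covariates: bool) -> np.ndarray:
    """(n, 4) mean of (m1t1, m1t2, m2t1, m2t2) from per-trait coefficients."""
    n = sex.shape[0]
    mu = np.empty((n, 4))
    for j in range(4):
        member, trait = divmod(j, 2)
        c = coefs[trait]
        mu[:, j] = c[0]
        if covariates:
            mu[:, j] += c[1] * sex[:, member] + c[2] * byc[:, member]
    return mu


def _prep_continuous(df: pd.DataFrame, by_ref: float):
    """Group pairs by (pair_type, missingness pattern) once, outside the objective."""
    groups = []
    for label, sub in df.groupby("pair_type", sort=True):
        X = sub[_VAL_COLS].to_numpy(dtype=float)
        sex = sub[["m1_sex", "m2_sex"]].to_numpy(dtype=float)
        byc = (sub[["m1_by", "m2_by"]].to_numpy(dtype=float) - by_ref) / 10.0
        obs = ~np.isnan(X)
        pattern = obs @ (1 << np.arange(4))
        for pat in np.unique(pattern):
            if pat == 0:
                continue
            m = pattern == pat
            idx = np.flatnonzero([(pat >> k) & 1 for k in range(4)])
            groups.append((label, idx, X[m][:, idx], sex[m], byc[m]))
    return groups


def continuous_pair_loglik(theta: np.ndarray, groups, spec: AceModelSpec) -> float:
    """FIML log-likelihood over prepared pattern groups (see ``_prep_continuous``)."""
    comps, coefs = _unpack(theta, spec)
    sigmas = {}
    for label in {g[0] for g in groups}:
        s = implied_pair_covariance(comps, label)
        v = _pd_violation(s)
        if v > 0:
            return -_PENALTY * (1.0 + v)
        sigmas[label] = s
    ll = 0.0
    for label, idx, x, sex, byc in groups:
        sub = sigmas[label][np.ix_(idx, idx)]
        try:
            L = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return -_PENALTY
        mu = _mean_matrix(coefs, sex, byc, spec.covariates)[:, idx]
        r = solve_triangular(L, (x - mu).T, lower=True)
        quad = np.einsum("ij,ij->j", r, r)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        k = idx.shape[0]
        ll += -0.5 * (quad.sum() + x.shape[0] * (logdet + k * np.log(2 * np.pi)))
    return float(ll)


def binary_cell_counts(df: pd.DataFrame, by_ref: float, bin_width: int = 10):
    """Aggregate binary pairs into 16-cell tables per pair type and stratum.

    Strata are (member sexes, member birth-decade bins); the stratum's
    birth-year covariate is the bin midpoint, centered and scaled to
    decades.  Returns {pair_type: (counts (S, 16), sex (S, 2), byc (S, 2))}.
    """
    df = df.copy()
    vals = df[_VAL_COLS].to_numpy()
    if np.isnan(vals.astype(float)).any():
        n0 = len(df)
        df = df.dropna(subset=_VAL_COLS)
        warnings.warn(f"dropped {n0 - len(df)} pairs with missing binary traits",
                      RuntimeWarning, stacklevel=2)
    cell = (df["m1_trait1"].astype(int) * 8 + df["m1_trait2"].astype(int) * 4
            + df["m2_trait1"].astype(int) * 2 + df["m2_trait2"].astype(int))
    for m in ("m1", "m2"):
        df[f"{m}_bin"] = (df[f"{m}_by"] // bin_width) * bin_width + bin_width / 2.0
    out = {}
    for label, sub in df.groupby("pair_type", sort=True):
        tab = (pd.crosstab([sub["m1_sex"], sub["m2_sex"], sub["m1_bin"], sub["m2_bin"]],
                           cell.loc[sub.index])
               .reindex(columns=range(16), fill_value=0))
        keys = np.array([list(k) for k in tab.index], dtype=float)
        out[label] = (tab.to_numpy(dtype=float), keys[:, 0:2],
                      (keys[:, 2:4] - by_ref) / 10.0)
    return out


# bit layout of a cell index: 8*y_m1t1 + 4*y_m1t2 + 2*y_m2t1 + y_m2t2
_CELL_BITS = np.array([[(c >> (3 - j)) & 1 for j in range(4)] for c in range(16)])


def binary_pair_loglik(theta: np.ndarray, strata: dict, spec: AceModelSpec,
                       n_points: int = 1024) -> float:
    """Liability-threshold log-likelihood over aggregated 16-cell tables.

    Equals the per-pair product likelihood exactly, since covariates are
    constant within a stratum.
    """
    comps, coefs = _unpack(theta, spec)
    ll = 0.0
    for label, (counts, sex, byc) in strata.items():
        sigma = implied_pair_covariance(comps, label)
        if _pd_violation(sigma) > 0:
            return -_PENALTY * (1.0 + _pd_violation(sigma))
        S = counts.shape[0]
        # threshold for variable j = intercept(trait) - covariate shift
        thr = np.empty((S, 4))
        for j in range(4):
            member, trait = divmod(j, 2)
            c = coefs[trait]
            shift = np.zeros(S)
            if spec.covariates:
                shift = c[1] * sex[:, member] + c[2] * byc[:, member]
            thr[:, j] = c[0] - shift
        lower = np.where(_CELL_BITS[None, :, :] == 1, thr[:, None, :], -np.inf)
        upper = np.where(_CELL_BITS[None, :, :] == 1, np.inf, thr[:, None, :])
        p = mvn_rectangles_batch(lower.reshape(-1, 4), upper.reshape(-1, 4),
                                 sigma, n_points=n_points).reshape(S, 16)
        mask = counts > 0
        if np.any(p[mask] <= 0):
            return -_PENALTY
        ll += float((counts[mask] * np.log(p[mask])).sum())
    return ll


def _moment_start_continuous(df: pd.DataFrame, spec: AceModelSpec, by_ref: float):
    """Falconer-style moment starting values from per-pair-type covariances."""
    rows = []
    for m in ("m1", "m2"):
        sub = pd.DataFrame({
            "t1": df[f"{m}_trait1"], "t2": df[f"{m}_trait2"],
            "sex": df[f"{m}_sex"], "byc": (df[f"{m}_by"] - by_ref) / 10.0,
        })
        rows.append(sub)
    persons = pd.concat(rows, ignore_index=True)
    coefs = []
    resid = {}
    for t in ("t1", "t2"):
        ok = persons[t].notna()
        X = np.column_stack([np.ones(ok.sum()), persons.loc[ok, "sex"],
                             persons.loc[ok, "byc"]])
        if not spec.covariates:
            X = X[:, :1]
        beta, *_ = np.linalg.lstsq(X, persons.loc[ok, t].to_numpy(), rcond=None)
        coefs.append(beta if spec.covariates else np.array([beta[0]]))
        r = pd.Series(np.nan, index=persons.index)
        r[ok] = persons.loc[ok, t].to_numpy() - X @ beta
        resid[t] = r
    n = len(df)
    r1 = np.column_stack([resid["t1"][:n], resid["t2"][:n]])
    r2 = np.column_stack([resid["t1"][n:], resid["t2"][n:]])
    both = np.vstack([r1, r2])
    P_hat = pd.DataFrame(both).dropna().cov().to_numpy()
    cross = {}
    for label, sub in df.groupby("pair_type", sort=True):
        i = sub.index.to_numpy()
        a = np.column_stack([r1[i], r2[i]])  # m1t1 m1t2 m2t1 m2t2
        C = pd.DataFrame(a).dropna().cov().to_numpy()
        cross[label] = 0.5 * (C[:2, 2:] + C[2:, :2].T)
    return P_hat, cross, coefs


def _solve_components(P_hat, cross, spec: AceModelSpec) -> dict:
    """Least-squares solve of cross-member covariances for V_A, V_C entries."""
    labels = sorted(cross)
    rA = np.array([PAIR_TYPES[lb][0] for lb in labels])
    cols = []
    if "A" in spec.included:
        cols.append(rA)
    if "C" in spec.included:
        cols.append(np.ones_like(rA))
    mats = {"A": np.zeros((2, 2)), "C": np.zeros((2, 2))}
    if cols:
        X = np.column_stack(cols)
        for i in range(2):
            for j in range(i, 2):
                y = np.array([cross[lb][i, j] for lb in labels])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                k = 0
                for comp in ("A", "C"):
                    if comp in spec.included:
                        mats[comp][i, j] = mats[comp][j, i] = beta[k]
                        k += 1
    mats["E"] = P_hat - mats["A"] - mats["C"]
    return mats


def _moment_start_binary(df: pd.DataFrame, spec: AceModelSpec):
    """Tetrachoric-correlation starting values."""
    y = df[_VAL_COLS].to_numpy(dtype=float)
    t0 = [threshold_from_prevalence(np.nanmean(np.r_[y[:, t], y[:, 2 + t]]))
          for t in range(2)]

    def tet(a, b):
        tab = np.zeros((2, 2))
        ok = ~np.isnan(a) & ~np.isnan(b)
        np.add.at(tab, (a[ok].astype(int), b[ok].astype(int)), 1)
        if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
            return 0.0
        try:
            return tetrachoric_mle(tab, compute_se=False).rho
        except ValueError:
            return 0.0

    cross = {}
    for label, sub in df.groupby("pair_type", sort=True):
        z = sub[_VAL_COLS].to_numpy(dtype=float)
        r11 = tet(z[:, 0], z[:, 2])
        r22 = tet(z[:, 1], z[:, 3])
        r12 = 0.5 * (tet(z[:, 0], z[:, 3]) + tet(z[:, 1], z[:, 2]))
        cross[label] = np.array([[r11, r12], [r12, r22]])
    rw = 0.5 * (tet(y[:, 0], y[:, 1]) + tet(y[:, 2], y[:, 3]))
    P_hat = np.array([[1.0, rw], [rw, 1.0]])
    return P_hat, cross, t0


def _pack_start(mats: dict, coefs, spec: AceModelSpec) -> np.ndarray:
    theta = []
    for comp in ("A", "C"):
        if comp in spec.included:
            m = mats[comp]
            theta += [m[0, 0], m[0, 1], m[1, 1]]
    if spec.measurement == "continuous":
        m = mats["E"]
        theta += [m[0, 0], m[0, 1], m[1, 1]]
    else:
        theta += [mats["E"][0, 1]]
    for c in coefs:
        theta += list(c)
    return np.array(theta, dtype=float)


def _shrink_to_pd(theta: np.ndarray, spec: AceModelSpec, objective) -> np.ndarray:
    """Pull the start toward a default interior point until the total is PD."""
    comps, coefs = _unpack(theta, spec)
    neutral = dict(A=0.2 * np.eye(2), C=0.1 * np.eye(2) if "C" in spec.included
                   else np.zeros((2, 2)))
    if spec.measurement == "continuous":
        neutral["E"] = 0.7 * np.eye(2)
    else:
        neutral["E"] = np.array([[0.0, 0.0], [0.0, 0.0]])  # e12 only
    base = _pack_start({k: neutral[k] for k in ("A", "C", "E")},
                       [np.zeros_like(c) + np.r_[c[0], np.zeros(len(c) - 1)]
                        for c in coefs], spec)
    for w in (1.0, 0.7, 0.4, 0.2, 0.0):
        cand = w * theta + (1 - w) * base
        if objective(cand) < _PENALTY:
            return cand
    return base


def fit_ace(df: pd.DataFrame, spec: AceModelSpec, by_ref: float | None = None,
            compute_se: bool = True, n_points: int = 1024,
            max_restarts: int = 5, seed: int = 0) -> FitResult:
    """Maximum-likelihood fit of a bivariate ACE model to pair data.

    ``df`` uses the pairs-table layout (pair_id, pair_type, m1_trait1, ...,
    m2_by).  At least two pair types with distinct genetic relatedness are
    required to separate A from C.  Starting values come from Falconer-style
    moment estimates (continuous) or tetrachoric correlations (binary);
    optimization is quasi-Newton on the unconstrained direct-symmetric
    parameters with a positive-definiteness penalty, with jittered restarts
    on failure.
    """
    df = df.reset_index(drop=True)
    labels = sorted(df["pair_type"].unique())
    for lb in labels:
        if lb not in PAIR_TYPES:
            raise ValueError(f"unknown pair type {lb!r}")
    r_As = {PAIR_TYPES[lb][0] for lb in labels}
    if len(r_As) < 2 and {"A", "C"} & set(spec.included):
        raise ValueError(
            "need >= 2 pair types with distinct genetic relatedness to "
            f"identify familial components; got {labels}")
    if len(df) == 0:
        raise ValueError("no pair data")
    if by_ref is None:
        by_ref = float(df[["m1_by", "m2_by"]].to_numpy().mean())

    if spec.measurement == "continuous":
        groups = _prep_continuous(df, by_ref)
        P_hat, cross, coefs = _moment_start_continuous(df, spec, by_ref)
        mats = _solve_components(P_hat, cross, spec)

        def objective(th):
            return -continuous_pair_loglik(th, groups, spec)
    else:
        strata = binary_cell_counts(df, by_ref)
        P_hat, cross, t0 = _moment_start_binary(df, spec)
        mats = _solve_components(P_hat, cross, spec)
        k = spec.n_mean_coefs
        coefs = [np.r_[t0[t], np.zeros(k - 1)] for t in range(2)]

        def objective(th):
            return -binary_pair_loglik(th, strata, spec, n_points=n_points)

    theta0 = _pack_start(mats, coefs, spec)
    theta0 = _shrink_to_pd(theta0, spec, objective)

    rng = np.random.default_rng(seed)
    best = None
    start = theta0
    for attempt in range(max_restarts + 1):
        res = minimize(objective, start, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12,
                                "gtol": 5e-4, "eps": 1e-6})
        ok = res.fun < _PENALTY
        if best is None or res.fun < best.fun:
            best = res
        if ok and res.success:
            break
        start = theta0 * (1.0 + 0.05 * rng.standard_normal(theta0.shape))
        start = _shrink_to_pd(start, spec, objective)
    res = best
    converged = bool(res.success and res.fun < _PENALTY)
    comps, coef_hat = _unpack(res.x, spec)

    param_cov = None
    if compute_se and converged:
        param_cov = _param_covariance(objective, res.x)

    coef_names = ["b0"] + (["b_sex", "b_by"] if spec.covariates else [])
    mean_coefs = {f"trait{t + 1}": dict(zip(coef_names, map(float, coef_hat[t])))
                  for t in range(2)}
    return FitResult(
        components=comps, mean_coefs=mean_coefs, loglik=float(-res.fun),
        n_free=spec.n_free, converged=converged, spec=spec,
        param_names=spec.param_names(), params=res.x.copy(),
        param_cov=param_cov,
        n_pairs={lb: int((df["pair_type"] == lb).sum()) for lb in labels},
        diagnostics={"by_ref": by_ref, "n_iter": int(res.nit),
                     "grad_norm": float(np.max(np.abs(res.jac))),
                     "message": str(res.message)},
    )


def _param_covariance(objective, x: np.ndarray) -> np.ndarray | None:
    """Inverse observed information by central finite differences."""
    n = x.shape[0]
    h = 1e-4 * np.maximum(np.abs(x), 0.1)
    H = np.empty((n, n))
    f0 = objective(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n); e[i] = h[i]
        fp[i] = objective(x + e)
        fm[i] = objective(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = objective(x + ei + ej)
            fmm = objective(x - ei - ej)
            H[i, j] = H[j, i] = ((fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm)
                                 / (2 * h[i] * h[j]))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("observed information singular; no SEs", RuntimeWarning,
                      stacklevel=2)
        return None
    if np.any(np.diag(cov) <= 0):
        warnings.warn("observed information not positive definite; SEs unreliable",
                      RuntimeWarning, stacklevel=2)
    return cov


def compare_models(full: FitResult, reduced: FitResult) -> ModelComparison:
    """Likelihood-ratio test of a reduced model nested in a full one.

    The reduced model is preferred when it is not significantly worse
    (p >= 0.05), mirroring standard model-ladder selection.
    """
    if not set(reduced.spec.included) < set(full.spec.included):
        raise ValueError(
            f"{reduced.spec.label} is not nested in {full.spec.label}")
    if reduced.spec.measurement != full.spec.measurement:
        raise ValueError("models fitted to different measurement scales")
    df_diff = full.n_free - reduced.n_free
    if df_diff < 1:
        raise ValueError("reduced model must have fewer free parameters")
    lrt = 2.0 * (full.loglik - reduced.loglik)
    if lrt < -1e-6 * max(1.0, abs(full.loglik)):
        warnings.warn(f"negative LRT statistic ({lrt:.3g}); reduced model "
                      "fits better than full — check convergence",
                      RuntimeWarning, stacklevel=2)
    lrt = max(lrt, 0.0)
    p = float(chi2.sf(lrt, df_diff)) if lrt > 0 else 1.0
    preferred = reduced.spec.label if p >= 0.05 else full.spec.label
    return ModelComparison(lrt=float(lrt), df=int(df_diff), p_value=p,
                           delta_aic=float(reduced.aic - full.aic),
                           preferred=preferred,
                           full_label=full.spec.label,
                           reduced_label=reduced.spec.label)


def _derived_vector(theta: np.ndarray, spec: AceModelSpec):
    """Flat vector of derived statistics (for delta-method gradients)."""
    comps, _ = _unpack(theta, spec)
    P = comps.total
    vals = {}
    for comp in ("A", "C", "E"):
        V = comps.component(comp)
        for t in range(2):
            vals[f"{comp.lower()}2_t{t + 1}"] = V[t, t] / P[t, t]
        if V[0, 0] > 0 and V[1, 1] > 0:
            vals[f"r_{comp}"] = V[0, 1] / np.sqrt(V[0, 0] * V[1, 1])
        else:
            vals[f"r_{comp}"] = np.nan
        if abs(P[0, 1]) > 0:
            vals[f"covshare_{comp}"] = V[0, 1] / P[0, 1]
        else:
            vals[f"covshare_{comp}"] = np.nan
    vals["r_ph"] = P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    return vals


def derived_estimates(fit: FitResult, alpha: float = 0.05) -> DerivedEstimates:
    """Standardized shares, component correlations, covariance decomposition.

    Correlations of a component with a negative estimated diagonal are
    reported as ``None`` (an expected artifact of the direct-symmetric
    parameterization) with a warning entry.  95% CIs by the delta method
    when the fit carries a parameter covariance.
    """
    if not fit.converged:
        warnings.warn("derived estimates from a non-converged fit",
                      RuntimeWarning, stacklevel=2)
    spec = fit.spec
    vals = _derived_vector(fit.params, spec)
    warn = []
    comps = fit.components
    for comp in ("A", "C", "E"):
        V = comps.component(comp)
        if (V[0, 0] < 0 or V[1, 1] < 0) and comp in spec.included:
            warn.append(f"component {comp} has a negative variance estimate; "
                        "its correlation is undefined")
    included = spec.included
    shares = {c: (vals[f"{c.lower()}2_t1"], vals[f"{c.lower()}2_t2"])
              for c in ("A", "C", "E") if c in included}
    correlations = {c: (None if np.isnan(vals[f"r_{c}"]) else float(vals[f"r_{c}"]))
                    for c in ("A", "C", "E") if c in included}
    cov_shares = {c: (None if np.isnan(vals[f"covshare_{c}"])
                      else float(vals[f"covshare_{c}"]))
                  for c in ("A", "C", "E") if c in included}

    ci = {}
    if fit.param_cov is not None:
        keys = [k for k, v in vals.items() if np.isfinite(v)]

        def fvec(th):
            v = _derived_vector(th, spec)
            return np.array([v[k] for k in keys])

        J = approx_fprime(fit.params, fvec, 1e-6 * np.maximum(np.abs(fit.params), 0.1))
        var = np.einsum("ij,jk,ik->i", J, fit.param_cov, J)
        zq = float(chi2.ppf(1 - alpha, 1) ** 0.5)
        for k, v, s2 in zip(keys, fvec(fit.params), var):
            s = np.sqrt(max(s2, 0.0))
            ci[k] = (float(v - zq * s), float(v + zq * s))
    return DerivedEstimates(shares=shares, correlations=correlations,
                            cov_shares=cov_shares,
                            phenotypic_correlation=float(vals["r_ph"]),
                            ci=ci, warnings=warn)


_LADDER = (("A", "C", "E"), ("A", "E"), ("C", "E"), ("E",))


def fit_model_ladder(df: pd.DataFrame, measurement: str, covariates: bool = True,
                     compute_se: bool = False, n_points: int = 1024,
                     seed: int = 0) -> dict:
    """Fit the ACE-ACE, AE-AE, CE-CE, E-E ladder and compare each to the full.

    Returns {"fits": {label: FitResult}, "comparisons": {label: ModelComparison},
    "best": label} where the best model is the most parsimonious one not
    significantly worse than the full ACE-ACE fit (AIC breaks ties).
    """
    fits = {}
    for included in _LADDER:
        spec = AceModelSpec(included=included, measurement=measurement,
                            covariates=covariates)
        fits[spec.label] = fit_ace(df, spec, compute_se=compute_se,
                                   n_points=n_points, seed=seed)
    full = fits["ACE-ACE"]
    comparisons = {lab: compare_models(full, fit)
                   for lab, fit in fits.items() if lab != "ACE-ACE"}
    candidates = [(fits[lab].n_free, fits[lab].aic, lab)
                  for lab, cmp_ in comparisons.items()
                  if cmp_.p_value >= 0.05]
    best = min(candidates)[2] if candidates else "ACE-ACE"
    return {"fits": fits, "comparisons": comparisons, "best": best}
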