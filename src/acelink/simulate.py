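"""Seeded synthetic-cohort generation.

Three generators produce every input the analysis pipeline consumes:

* ``simulate_kin_pairs`` — relative pairs (MZ/DZ twins, full and maternal
  half-siblings) whose two phenotypes follow a bivariate ACE covariance
  structure, optionally dichotomized at prevalence-calibrated liability
  cutoffs with sex/birth-year mean shifts;
* ``simulate_items`` — independent probit item responses around a latent
  score, for psychometric-scale emulation;
* ``simulate_registry`` — a follow-up registry on the age timescale with a
  time-varying diagnosis exposure and piecewise-constant proportional
  hazards for each outcome category.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` child streams, so identical seed + config
gives bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PAIR_TYPES, ComponentMatrices, PairType

__all__ = [
    "CovariateModel",
    "simulate_kin_pairs",
    "ItemPanel",
    "simulate_items",
    "cronbach_alpha",
    "simulate_registry",
]

PAIR_COLUMNS = ["pair_id", "pair_type", "m1_trait1", "m1_trait2",
                "m2_trait1", "m2_trait2", "m1_sex", "m2_sex", "m1_by", "m2_by"]


@dataclass
class CovariateModel:
    """Sex and birth-year covariates and their effects on trait means.

    Sex is Bernoulli(``p_female``) (1 = female); birth year is uniform on
    ``[by_low, by_high]``.  Effects enter the score/liability mean linearly:
    ``shift = sex_effect * sex + by_effect * (birth_year - by_ref) / 10``.
    """

    p_female: float = 0.5
    by_low: int = 1960
    by_high: int = 1989
    by_ref: float = 1975.0
    # per-trait (sex_effect, birth_year_effect_per_decade)
    effects: dict = field(default_factory=dict)

    def shift(self, trait: str, sex: np.ndarray, by: np.ndarray) -> np.ndarray:
        b_sex, b_by = self.effects.get(trait, (0.0, 0.0))
        return b_sex * sex + b_by * (by - self.by_ref) / 10.0


def _draw_covariates(pair_type: str, n: int, cov: CovariateModel,
                     rng: np.random.Generator, max_sib_gap: int = 5):
    if pair_type in ("MZ", "DZ"):
        by1 = rng.integers(cov.by_low, cov.by_high + 1, size=n)
        by2 = by1.copy()
        if pair_type == "MZ":
            sex1 = (rng.random(n) < cov.p_female).astype(int)
            sex2 = sex1.copy()
        else:
            sex1 = (rng.random(n) < cov.p_female).astype(int)
            sex2 = (rng.random(n) < cov.p_female).astype(int)
    else:
        # first- and second-born siblings at most `max_sib_gap` years apart
        by1 = rng.integers(cov.by_low, cov.by_high + 1, size=n)
        gap = rng.integers(1, max_sib_gap + 1, size=n)
        by2 = np.minimum(by1 + gap, cov.by_high)
        sex1 = (rng.random(n) < cov.p_female).astype(int)
        sex2 = (rng.random(n) < cov.p_female).astype(int)
    return sex1, sex2, by1, by2


def simulate_kin_pairs(components: ComponentMatrices, counts: dict,
                       thresholds: dict | None = None,
                       covariates: CovariateModel | None = None,
                       seed: int | np.random.SeedSequence = 0,
                       missing_rate: float = 0.0,
                       traits: tuple[str, str] | None = None) -> pd.DataFrame:
    """Simulate relative pairs under a bivariate ACE model.

    For each pair the 4-vector (m1 trait1, m1 trait2, m2 trait1, m2 trait2)
    is multivariate normal with within-person block ``V_A + V_C + V_E`` and
    cross-member block ``r_A V_A + r_C V_C``, mean-shifted by covariate
    effects.  With ``thresholds`` given (liability cutoffs keyed by trait)
    the traits are dichotomized as ``value >= threshold``.

    Parameters
    ----------
    counts
        Mapping pair-type label -> number of pairs, e.g. ``{"MZ": 4000}``.
    thresholds
        ``None`` for continuous traits, else ``{trait: cutoff}``.
    missing_rate
        Independent probability that any single trait value is missing.
    """
    components.validate_generation()
    if traits is None:
        traits = components.traits
    cov = covariates or CovariateModel()
    P = components.total
    frames = []
    offset = 0
    rng_root = (seed if isinstance(seed, np.random.SeedSequence)
                else np.random.SeedSequence(seed))
    streams = rng_root.spawn(len(counts))
    for (label, n), ss in zip(sorted(counts.items()), streams):
        if label not in PAIR_TYPES:
            raise ValueError(f"unknown pair type {label!r}")
        n = int(n)
        if n < 0:
            raise ValueError("pair counts must be >= 0")
        if n == 0:
            continue
        rng = np.random.default_rng(ss)
        pt = PairType.from_label(label)
        R = pt.r_A * components.V_A + pt.r_C * components.V_C
        sigma = np.block([[P, R], [R, P]])
        # PSD by construction for PSD components; tiny jitter guards the
        # boundary case (e.g. MZ with V_E = 0 has a singular 4x4)
        ev, Q = np.linalg.eigh(sigma)
        L = Q * np.sqrt(np.clip(ev, 0.0, None))
        latent = rng.standard_normal((n, 4)) @ L.T
        sex1, sex2, by1, by2 = _draw_covariates(label, n, cov, rng)
        vals = latent.copy()
        for j, (sx, by) in enumerate([(sex1, by1), (sex1, by1),
                                      (sex2, by2), (sex2, by2)]):
            vals[:, j] += cov.shift(traits[j % 2], sx, by)
        if thresholds is not None:
            cut = np.array([thresholds[traits[0]], thresholds[traits[1]]] * 2)
            vals = (vals >= cut).astype(float)
        if missing_rate > 0:
            vals[rng.random((n, 4)) < missing_rate] = np.nan
        frames.append(pd.DataFrame({
            "pair_id": np.arange(offset, offset + n),
            "pair_type": label,
            "m1_trait1": vals[:, 0], "m1_trait2": vals[:, 1],
            "m2_trait1": vals[:, 2], "m2_trait2": vals[:, 3],
            "m1_sex": sex1, "m2_sex": sex2, "m1_by": by1, "m2_by": by2,
        }))
        offset += n
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class ItemPanel:
    """Binary item responses generated around a latent trait."""

    loadings: np.ndarray
    item_thresholds: np.ndarray
    responses: np.ndarray

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def sum_score(self) -> np.ndarray:
        return self.responses.sum(axis=1)


def simulate_items(latent: np.ndarray, loadings: np.ndarray,
                   item_thresholds: np.ndarray,
                   seed: int | np.random.SeedSequence = 0) -> ItemPanel:
    """Independent probit item responses: 1 iff loading*latent + noise >= cutoff."""
    latent = np.asarray(latent, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    item_thresholds = np.asarray(item_thresholds, dtype=float)
    if loadings.shape != item_thresholds.shape:
        raise ValueError("loadings and item_thresholds must have equal length")
    if not np.all(np.isfinite(loadings)):
        raise ValueError("loadings must be finite")
    rng = np.random.default_rng(seed)
    k = loadings.shape[0]
    noise = rng.standard_normal((latent.shape[0], k))
    resp = (loadings[None, :] * latent[:, None] + noise
            >= item_thresholds[None, :]).astype(int)
    return ItemPanel(loadings=loadings, item_thresholds=item_thresholds,
                     responses=resp)


def cronbach_alpha(responses: np.ndarray) -> float:
    """Cronbach's alpha: (k/(k-1)) (1 - sum item variances / variance of sum)."""
    x = np.asarray(responses, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 persons and >= 2 items")
    if np.isnan(x).any():
        raise ValueError("missing responses not supported")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _piecewise_event_ages(entry: np.ndarray, exit_: np.ndarray,
                          band_edges: np.ndarray, band_rates: np.ndarray,
                          log_mult: np.ndarray, dx_age: np.ndarray,
                          log_hr_exposed: float,
                          rng: np.random.Generator) -> np.ndarray:
    """First-event age under a piecewise-constant hazard with one switch.

    Hazard at age t: ``band_rate(t) * exp(log_mult + log_hr_exposed * 1[t >= dx_age])``,
    integrated from each person's entry; inversion of the cumulative hazard
    against an Exp(1) draw.  Returns NaN where no event occurs before exit.
    """
    n = entry.shape[0]
    target = rng.exponential(size=n)
    event = np.full(n, np.nan)
    cum = np.zeros(n)
    base_mult = np.exp(log_mult)
    exp_mult = np.exp(log_mult + log_hr_exposed)
    # segment edges: band edges plus each person's exposure switch age
    for k in range(band_edges.shape[0] - 1):
        lo = np.maximum(band_edges[k], entry)
        hi = np.minimum(band_edges[k + 1], exit_)
        for exposed in (False, True):
            if exposed:
                s_lo = np.maximum(lo, dx_age)
                s_hi = hi
                mult = exp_mult
            else:
                s_lo = lo
                s_hi = np.minimum(hi, dx_age)
                mult = base_mult
            width = np.clip(s_hi - s_lo, 0.0, None)
            rate = band_rates[k] * mult
            seg = rate * width
            hit = np.isnan(event) & (cum + seg >= target) & (seg > 0)
            event[hit] = s_lo[hit] + (target[hit] - cum[hit]) / rate[hit]
            cum = cum + seg
    return event


def simulate_registry(config: dict, seed: int | np.random.SeedSequence = 0,
                      n: int | None = None) -> pd.DataFrame:
    """Simulate a follow-up registry on the age timescale.

    ``config`` follows the 'population-registry' preset structure: birth
    years and sex, study window (entry at the 15th birthday or study start,
    whichever is later), lifetime-diagnosis flag with a log-normal first
    diagnosis age, censoring by death/emigration/administrative end, and
    per-outcome piecewise-constant baseline hazards with log hazard ratios
    for the time-varying exposure, sex and birth year.  Outcome events are
    generated independently per category (no competing risks) and only
    within each person's observed window.
    """
    n = int(n if n is not None else config["n_persons"])
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    r_cov, r_ocd, r_cens, *r_out = [np.random.default_rng(s)
                                    for s in ss.spawn(3 + len(config["outcomes"]))]

    by_cfg = config["birth_year"]
    study = config["study"]
    by = r_cov.integers(by_cfg["low"], by_cfg["high"] + 1, size=n)
    sex = (r_cov.random(n) < config["p_female"]).astype(int)
    entry = np.maximum(float(study["min_age"]), study["start_year"] - by).astype(float)
    admin_exit = (study["end_year"] - by).astype(float)

    cens = config.get("censoring", {})
    death_rate = float(cens.get("death_rate", 0.0))
    emig_rate = float(cens.get("emigration_rate", 0.0))
    if death_rate < 0 or emig_rate < 0:
        raise ValueError("censoring rates must be >= 0")
    death_age = entry + (r_cens.exponential(size=n) / death_rate
                         if death_rate > 0 else np.inf)
    emig_age = entry + (r_cens.exponential(size=n) / emig_rate
                        if emig_rate > 0 else np.inf)
    exit_age = np.minimum.reduce([admin_exit, death_age, emig_age])
    exit_reason = np.select(
        [exit_age == admin_exit, exit_age == death_age],
        ["admin_censor", "death"], default="emigration")
    if np.any(exit_age <= entry):
        raise ValueError("follow-up window empty for some persons; "
                         "check birth-year window against study years")

    ocd_cfg = config["ocd"]
    prev = float(ocd_cfg["lifetime_prevalence"])
    if not 0.0 < prev < 1.0:
        raise ValueError("lifetime prevalence must be in (0, 1)")
    ocd = (r_ocd.random(n) < prev).astype(int)
    mu = np.log(float(ocd_cfg["dx_age"]["median"]))
    sigma = float(ocd_cfg["dx_age"]["sigma"])
    dx = np.exp(mu + sigma * r_ocd.standard_normal(n))
    dx = np.maximum(dx, float(ocd_cfg.get("min_dx_age", 6.0)))
    dx_age = np.where(ocd == 1, dx, np.nan)

    bands = np.asarray(config["age_bands"], dtype=float)
    byc = (by - by_cfg["reference"]) / 10.0
    out = {
        "person_id": np.arange(n), "sex": sex, "birth_year": by,
        "entry_age": entry, "exit_age": exit_age, "exit_reason": exit_reason,
        "ocd": ocd, "ocd_dx_age": dx_age,
    }
    for (name, oc), rng_o in zip(config["outcomes"].items(), r_out):
        rates = np.asarray(oc["band_rates"], dtype=float)
        if np.any(rates < 0):
            raise ValueError(f"negative baseline hazard for outcome {name!r}")
        if rates.shape[0] != bands.shape[0] - 1:
            raise ValueError(f"band_rates length mismatch for outcome {name!r}")
        log_mult = (oc.get("log_hr_male", 0.0) * (1 - sex)
                    + oc.get("log_hr_per_decade", 0.0) * byc
                    + oc.get("log_hr_lifetime_ocd", 0.0) * ocd)
        switch = np.where(np.isnan(dx_age), np.inf, dx_age)
        out[f"{name}_age"] = _piecewise_event_ages(
            entry, exit_age, bands, rates, log_mult, switch,
            float(oc.get("log_hr_exposed", 0.0)), rng_o)
    return pd.DataFrame(out)
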