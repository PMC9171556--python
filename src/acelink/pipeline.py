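"""Configuration-driven orchestration: generate -> fit -> compare -> report.

A pipeline run is fully described by a :class:`PipelineConfig` (preset,
analyses, output directory, root seed, replicate count).  Every stage
derives its random stream from the root seed, so re-running the same
configuration reproduces all numeric outputs bit-identically; the manifest
written next to the reports records the configuration hash, seed and
package version needed to re-create the run.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ace import derived_estimates, fit_model_ladder
from .epi import build_counting_process, cox_fit, km_cumulative_incidence
from .io import write_tsv
from .presets import load_preset, simulate_pairs_preset
from .simulate import simulate_registry

log = logging.getLogger("acelink")

ANALYSES = ("genetic", "phenotypic")


@dataclass
class PipelineConfig:
    preset: str
    analyses: tuple = ("genetic",)
    out_dir: str = "acelink-out"
    seed: int = 0
    replicates: int = 1
    counts: dict | None = None      # pairs presets: override pair counts
    n_persons: int | None = None    # registry preset: override cohort size

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        bad = set(self.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses {sorted(bad)}; expected {ANALYSES}")

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _fmt(x, nd=2):
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) \
        else f"{x:.{nd}f}"


def fmt_est_ci(est, lo=None, hi=None, nd=2) -> str:
    """'4.51 (4.25-4.79)' estimate-with-CI formatting; 'NA' for missing parts."""
    if est is None or (isinstance(est, float) and not np.isfinite(est)):
        return "NA"
    if lo is None or hi is None:
        return f"{est:.{nd}f} (NA)"
    return f"{est:.{nd}f} ({lo:.{nd}f}-{hi:.{nd}f})"


def fmt_pct(share) -> str:
    """'56%' percent rounding of a proportion; 'NA' for missing."""
    if share is None or (isinstance(share, float) and not np.isfinite(share)):
        return "NA"
    return f"{round(100 * share):.0f}%"


def render_tables(fit_results: dict | None = None,
                  comparisons: dict | None = None,
                  epi_results: dict | None = None) -> str:
    """Aligned text report mirroring the model-grid / HR-table layouts."""
    if not fit_results and not epi_results:
        raise ValueError("nothing to render")
    lines = []
    if fit_results:
        lines.append("Model grid (per-model fit and comparison to full ACE-ACE)")
        hdr = f"{'model':<10}{'loglik':>14}{'AIC':>14}{'LRT':>10}{'df':>4}{'p':>8}"
        lines.append(hdr)
        for label, fit in fit_results.items():
            cmp_ = (comparisons or {}).get(label)
            lines.append(
                f"{label:<10}{fit.loglik:>14.2f}{fit.aic:>14.2f}"
                + (f"{cmp_.lrt:>10.2f}{cmp_.df:>4d}{cmp_.p_value:>8.3f}"
                   if cmp_ else f"{'':>10}{'':>4}{'':>8}"))
        lines.append("")
        for label, fit in fit_results.items():
            d = derived_estimates(fit)
            shares = "  ".join(
                f"{c}: {fmt_pct(d.shares[c][0])}/{fmt_pct(d.shares[c][1])}"
                for c in d.shares)
            corrs = "  ".join(f"r{c}={_fmt(d.correlations[c])}"
                              for c in d.correlations)
            lines.append(f"{label:<10}{shares}   {corrs}   "
                         f"r_ph={_fmt(d.phenotypic_correlation)}")
        lines.append("")
    if epi_results:
        lines.append("Outcome associations (HR, 95% CI, adjusted for sex and birth year)")
        for outcome, res in epi_results.items():
            if "hr" in res:
                lo, hi = res["hr_ci"]["exposed"]
                lines.append(f"{outcome:<24}{fmt_est_ci(res['hr']['exposed'], lo, hi):>22}"
                             f"   events={res['n_events']}")
            elif "beta" in res:
                key = res.get("exposure", "exposure")
                lo, hi = res["ci"][key]
                lines.append(f"{outcome:<24}beta {fmt_est_ci(res['beta'][key], lo, hi)}"
                             f"   n={res['n']}")
        lines.append("")
    return "\n".join(lines)


def _fit_report(ladder: dict) -> dict:
    rep = {"best": ladder["best"], "models": {}}
    for label, fit in ladder["fits"].items():
        d = derived_estimates(fit)
        cmp_ = ladder["comparisons"].get(label)
        rep["models"][label] = {
            "loglik": fit.loglik, "aic": fit.aic, "n_free": fit.n_free,
            "converged": fit.converged,
            "components": {c: fit.components.component(c).tolist()
                           for c in ("A", "C", "E")},
            "shares": {c: list(map(float, v)) for c, v in d.shares.items()},
            "correlations": d.correlations,
            "cov_shares": d.cov_shares,
            "phenotypic_correlation": d.phenotypic_correlation,
            "lrt_vs_full": None if cmp_ is None else
                {"lrt": cmp_.lrt, "df": cmp_.df, "p": cmp_.p_value,
                 "delta_aic": cmp_.delta_aic, "preferred": cmp_.preferred},
        }
    return rep


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all requested stages; returns the run manifest."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_preset(config.preset)
    manifest = {"config": asdict(config), "config_hash": config.digest(),
                "version": __version__, "stages": {}}
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.spawn(config.replicates)

    def stage(name, fn):
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception:
            manifest["stages"][name] = {"status": "failed"}
            _write_manifest(out, manifest)
            log.exception("stage %s: FAILED", name)
            raise
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.time() - t0, 2)}
        log.info("stage %s: done in %.1fs", name, time.time() - t0)

    results = {}
    for rep, ss in enumerate(rep_seeds):
        tag = "" if config.replicates == 1 else f".rep{rep}"
        if cfg["kind"] == "pairs":
            df = {}

            def simulate():
                df["pairs"] = simulate_pairs_preset(cfg, seed=ss,
                                                    counts=config.counts)
                write_tsv(df["pairs"], out / f"pairs{tag}.tsv",
                          preset=config.preset, seed=config.seed)

            stage(f"simulate{tag}", simulate)
            if "genetic" in config.analyses:
                def genetic():
                    ladder = fit_model_ladder(df["pairs"], cfg["measurement"],
                                              seed=config.seed)
                    rep_d = _fit_report(ladder)
                    (out / f"fit_report{tag}.json").write_text(
                        json.dumps(rep_d, indent=1))
                    (out / f"fit_report{tag}.txt").write_text(
                        render_tables(ladder["fits"], ladder["comparisons"]))
                    results[f"genetic{tag}"] = rep_d

                stage(f"fit-ace{tag}", genetic)
            if "phenotypic" in config.analyses:
                def phenotypic():
                    res = _pairs_regression(df["pairs"], cfg)
                    (out / f"regression{tag}.json").write_text(
                        json.dumps(res, indent=1))
                    results[f"phenotypic{tag}"] = res

                stage(f"regression{tag}", phenotypic)
        elif cfg["kind"] == "registry":
            df = {}

            def simulate():
                df["reg"] = simulate_registry(cfg, seed=ss, n=config.n_persons)
                write_tsv(df["reg"], out / f"registry{tag}.tsv",
                          preset=config.preset, seed=config.seed)

            stage(f"simulate{tag}", simulate)
            if "phenotypic" in config.analyses:
                def phenotypic():
                    epi = {}
                    for outcome in cfg["outcomes"]:
                        rows = build_counting_process(df["reg"], outcome)
                        fit = cox_fit(rows)
                        epi[outcome] = {k: fit[k] for k in
                                        ("coef", "se", "hr", "hr_ci",
                                         "loglik", "n_events")}
                    curves = km_cumulative_incidence(df["reg"], "any_substance")
                    rowsc = []
                    for g, c in curves.items():
                        for a, s, lo, hi in zip(c.ages, c.survival,
                                                c.ci_lower, c.ci_upper):
                            rowsc.append((g, a, 1 - s, 1 - hi, 1 - lo))
                    write_tsv(pd.DataFrame(rowsc, columns=[
                        "group", "age", "cum_incidence", "ci_lower", "ci_upper"]),
                        out / f"km_curves{tag}.tsv", preset=config.preset,
                        seed=config.seed)
                    (out / f"epi_report{tag}.json").write_text(
                        json.dumps(epi, indent=1))
                    (out / f"epi_report{tag}.txt").write_text(
                        render_tables(epi_results=epi))
                    results[f"phenotypic{tag}"] = epi

                stage(f"epi{tag}", phenotypic)
        else:
            raise ValueError(f"preset kind {cfg['kind']!r} has no pipeline stages")

    manifest["seconds_total"] = round(time.time() - t_start, 2)
    _write_manifest(out, manifest)
    return manifest


def pairs_to_persons(pairs: pd.DataFrame, cfg: dict) -> pd.DataFrame:
    """Stack pair members into one row per individual (pair id retained)."""
    by_ref = float(cfg["covariates"]["birth_year"]["reference"])
    rows = []
    for m in ("m1", "m2"):
        rows.append(pd.DataFrame({
            "pair_id": pairs["pair_id"], "trait1": pairs[f"{m}_trait1"],
            "trait2": pairs[f"{m}_trait2"], "sex": pairs[f"{m}_sex"],
            "byc": (pairs[f"{m}_by"] - by_ref) / 10.0}))
    return pd.concat(rows, ignore_index=True)


def _pairs_regression(pairs: pd.DataFrame, cfg: dict,
                      n_persons: int | None = None) -> dict:
    """Individual-level standardized regression of trait2 on trait1."""
    from .epi import ols_cluster_robust
    persons = pairs_to_persons(pairs, cfg)
    if n_persons is not None:
        persons = persons.iloc[:n_persons]
    res = ols_cluster_robust(persons, outcome="trait2", exposure="trait1",
                             covariates=("sex", "byc"), cluster="pair_id")
    return {"beta": res["beta"], "se": res["se"], "ci": res["ci"],
            "n": res["n"], "n_clusters": res["n_clusters"],
            "exposure": "trait1"}


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
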