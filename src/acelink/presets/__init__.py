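"""Shipped generator presets.

Each preset is a YAML file under ``acelink/presets/`` holding a complete,
validated generator configuration whose true parameter values are
calibrated to the published cohort estimates the synthetic data emulate
(component shares and correlations, prevalences, hazard ratios,
diagnosis-age quantiles).  ``load_preset`` parses and validates one;
helpers turn the pairs presets into the objects ``simulate_kin_pairs``
expects.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from ..simulate import CovariateModel
from ..types import ComponentMatrices

PRESET_NAMES = ("population-registry", "population-liability",
                "catss-twin", "catss-bocs")


def load_preset(name: str) -> dict:
    """Load and validate a shipped preset configuration by name."""
    if name not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}")
    text = resources.files("acelink.presets").joinpath(f"{name}.yaml").read_text()
    cfg = yaml.safe_load(text)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    kind = cfg.get("kind")
    if kind == "pairs":
        comp = pair_components(cfg)
        comp.validate_generation()
        if cfg["measurement"] == "binary" and not cfg.get("thresholds"):
            raise ValueError("binary pairs preset requires thresholds")
    elif kind == "registry":
        for nm, oc in cfg["outcomes"].items():
            if np.any(np.asarray(oc["band_rates"]) < 0):
                raise ValueError(f"negative hazard in outcome {nm!r}")
    elif kind == "items":
        if int(cfg["n_items"]) < 2:
            raise ValueError("item preset needs >= 2 items")
    else:
        raise ValueError(f"unknown preset kind {kind!r}")


def pair_components(cfg: dict) -> ComponentMatrices:
    """ComponentMatrices of a pairs preset."""
    c = cfg["components"]
    return ComponentMatrices(V_A=np.array(c["V_A"]), V_C=np.array(c["V_C"]),
                             V_E=np.array(c["V_E"]), traits=tuple(cfg["traits"]))


def pair_covariates(cfg: dict) -> CovariateModel:
    """CovariateModel of a pairs preset."""
    cv = cfg["covariates"]
    effects = {t: (float(e.get("sex", 0.0)),
                   float(e.get("birth_year_per_decade", 0.0)))
               for t, e in cv.get("effects", {}).items()}
    return CovariateModel(p_female=float(cv.get("p_female", 0.5)),
                          by_low=int(cv["birth_year"]["low"]),
                          by_high=int(cv["birth_year"]["high"]),
                          by_ref=float(cv["birth_year"]["reference"]),
                          effects=effects)


def simulate_pairs_preset(cfg: dict, seed, counts: dict | None = None):
    """Run ``simulate_kin_pairs`` from a pairs preset configuration."""
    from ..simulate import simulate_kin_pairs
    thresholds = cfg.get("thresholds") or None
    return simulate_kin_pairs(
        components=pair_components(cfg),
        counts=counts or cfg["counts"],
        thresholds=thresholds,
        covariates=pair_covariates(cfg),
        seed=seed,
        traits=tuple(cfg["traits"]),
    )
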