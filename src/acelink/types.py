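"""Shared domain containers for kinship-structured variance decomposition.

The quantitative-genetic layer works with three latent variance components:
additive genetic (A), shared environmental (C) and nonshared environmental
(E).  Relative pairs differ only in how much A and C they share, which is
what identifies the decomposition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Genetic relatedness (r_A) and shared-environment (r_C) coefficients per
#: pair type: MZ twins are genetically identical, DZ twins and full siblings
#: share half their segregating genes, maternal half-siblings a quarter; all
#: pair types are assumed to share their rearing environment equally.
PAIR_TYPES: dict[str, tuple[float, float]] = {
    "MZ": (1.0, 1.0),
    "DZ": (0.5, 1.0),
    "FS": (0.5, 1.0),
    "MHS": (0.25, 1.0),
}


@dataclass(frozen=True)
class PairType:
    """A relative-pair class with its genetic/environmental sharing."""

    label: str
    r_A: float
    r_C: float

    @classmethod
    def from_label(cls, label: str) -> "PairType":
        try:
            r_A, r_C = PAIR_TYPES[label]
        except KeyError:
            raise ValueError(
                f"unknown pair type {label!r}; expected one of {sorted(PAIR_TYPES)}"
            ) from None
        return cls(label, r_A, r_C)


def _sym(m) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2):
        raise ValueError(f"component matrix must be 2x2, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("component matrix must be symmetric")
    return 0.5 * (m + m.T)


@dataclass
class ComponentMatrices:
    """The three 2x2 component (co)variance matrices of a bivariate ACE model.

    Under the direct-symmetric parameterization the matrix entries themselves
    are free parameters, so during fitting diagonals may go negative; the
    total phenotypic covariance ``V_A + V_C + V_E`` must stay positive
    definite.  Generation presets additionally require each matrix to be
    positive semidefinite and the total standardized (unit diagonal).
    """

    V_A: np.ndarray
    V_C: np.ndarray
    V_E: np.ndarray
    traits: tuple[str, str] = ("trait1", "trait2")

    def __post_init__(self) -> None:
        self.V_A = _sym(self.V_A)
        self.V_C = _sym(self.V_C)
        self.V_E = _sym(self.V_E)

    @property
    def total(self) -> np.ndarray:
        """Within-person phenotypic covariance P = V_A + V_C + V_E."""
        return self.V_A + self.V_C + self.V_E

    def component(self, name: str) -> np.ndarray:
        return {"A": self.V_A, "C": self.V_C, "E": self.V_E}[name]

    def validate_generation(self, atol: float = 1e-8) -> None:
        """Require PSD components and unit total variance per trait."""
        for name in ("A", "C", "E"):
            m = self.component(name)
            ev = np.linalg.eigvalsh(m)
            if ev.min() < -atol:
                raise ValueError(
                    f"V_{name} is not positive semidefinite (min eigenvalue {ev.min():.3g})"
                )
        d = np.diag(self.total)
        if not np.allclose(d, 1.0, atol=1e-6):
            raise ValueError(
                f"generation components must have unit total variance per trait, got diag {d}"
            )

    def is_total_pd(self, eps: float = 1e-10) -> bool:
        return bool(np.linalg.eigvalsh(self.total).min() > eps)


@dataclass
class FitResult:
    """Maximum-likelihood fit of a bivariate ACE model."""

    components: ComponentMatrices
    mean_coefs: dict
    loglik: float
    n_free: int
    converged: bool
    spec: object = None
    param_names: list = field(default_factory=list)
    params: np.ndarray | None = None
    param_cov: np.ndarray | None = None
    n_pairs: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of a reduced model nested in a full one."""

    lrt: float
    df: int
    p_value: float
    delta_aic: float
    preferred: str
    full_label: str = "full"
    reduced_label: str = "reduced"


@dataclass
class DerivedEstimates:
    """Standardized shares, component correlations and covariance decomposition."""

    shares: dict          # {"A": (a2_t1, a2_t2), ...}
    correlations: dict    # {"A": rg, "C": rc, "E": re}; None when undefined
    cov_shares: dict      # fraction of cross-trait covariance per component
    phenotypic_correlation: float
    ci: dict = field(default_factory=dict)   # same keys -> (lo, hi) or None
    warnings: list = field(default_factory=list)
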