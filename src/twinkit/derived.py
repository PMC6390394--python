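"""Derived quantities from fitted variance-component models.

Turns fitted loading matrices into the reporting layer: standardized
per-trait variance proportions and per-component cross-trait correlation
matrices (genetic, dominance, shared- and unique-environmental), plus the
phenotypic correlation matrix those imply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biometric import ModelSpec, ParamSet

__all__ = [
    "DerivedStats",
    "standardized_components",
    "component_correlation",
    "derive_stats",
    "implied_phenotypic_correlation",
]


def standardized_components(params: ParamSet, sex: str = "*") -> dict[str, np.ndarray]:
    """Per-trait variance proportions for each active component.

    ``proportion_X[t] = Sigma_X[t, t] / Sigma_total[t, t]``; proportions sum
    to 1 across active components for every trait.
    """
    total = np.diag(params.total_sigma(sex))
    if np.any(total <= 0):
        raise ValueError("zero total variance for at least one trait")
    return {
        comp: np.diag(params.sigma(comp, sex)) / total
        for comp in params.spec.active
    }


def component_correlation(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix of one component's covariance matrix.

    Traits whose component variance is (numerically) zero have undefined
    correlations: their rows/columns are returned as NaN, and the second
    return value is a boolean mask of the defined traits. Zero-variance
    correlations are deliberately NOT reported as 0 — absence of a
    component is not evidence of independence.
    """
    sigma = np.asarray(sigma, dtype=float)
    d = np.diag(sigma).copy()
    defined = d > 1e-10
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(defined, np.sqrt(d), np.nan)
        corr = sigma / np.outer(scale, scale)
    corr[np.ix_(defined, defined)] = np.clip(corr[np.ix_(defined, defined)], -1.0, 1.0)
    np.fill_diagonal(corr, np.where(defined, 1.0, np.nan))
    return corr, defined


@dataclass
class DerivedStats:
    """Standardized proportions and component correlations for one fit."""

    spec: ModelSpec
    proportions: dict[str, np.ndarray]  # component -> per-trait proportion
    correlations: dict[str, np.ndarray]  # component -> T x T correlation
    defined: dict[str, np.ndarray]  # component -> per-trait defined mask
    sex: str = "*"

    @property
    def total_genetic(self) -> np.ndarray:
        """Broad heritability per trait: proportion A plus proportion D."""
        T = self.spec.n_traits
        out = np.zeros(T)
        for comp in ("A", "D"):
            if comp in self.proportions:
                out += self.proportions[comp]
        return out

    def to_dict(self) -> dict:
        return {
            "traits": list(self.spec.traits),
            "sex": self.sex,
            "proportions": {c: p.tolist() for c, p in self.proportions.items()},
            "total_genetic": self.total_genetic.tolist(),
            "correlations": {c: r.tolist() for c, r in self.correlations.items()},
        }


def derive_stats(params: ParamSet, sex: str = "*") -> DerivedStats:
    proportions = standardized_components(params, sex)
    correlations = {}
    defined = {}
    for comp in params.spec.active:
        corr, mask = component_correlation(params.sigma(comp, sex))
        correlations[comp] = corr
        defined[comp] = mask
    return DerivedStats(params.spec, proportions, correlations, defined, sex)


def implied_phenotypic_correlation(derived: DerivedStats) -> np.ndarray:
    """Phenotypic correlation matrix implied by the component decomposition.

    ``r_P[i, j] = sum_X r_X[i, j] * sqrt(prop_X[i] * prop_X[j])`` over active
    components; components undefined for a trait contribute nothing there.
    """
    T = derived.spec.n_traits
    out = np.zeros((T, T))
    for comp in derived.spec.active:
        prop = derived.proportions[comp]
        corr = np.nan_to_num(derived.correlations[comp], nan=0.0)
        out += corr * np.sqrt(np.outer(prop, prop))
    np.fill_diagonal(out, 1.0)
    return out
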