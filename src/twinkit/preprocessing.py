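"""Data preparation: skewness assessment, square-root transformation, and
residualization on sex and age terms.

The preparation chain mirrors common practice for continuous twin phenotypes:
positively skewed traits are square-root transformed, then every trait is
regressed (pooled over individuals, both sexes combined) on
``{1, sex, age, sex*age, age^2}`` and replaced by its standardized residual,
so that downstream variance components are directly interpretable as
proportions of unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import TwinDataset

__all__ = [
    "skewness",
    "sqrt_transform",
    "residualize",
    "PreprocessReport",
    "preprocess_dataset",
]

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("intercept", "sex", "age", "age_x_sex", "age_sq")


def skewness(values) -> float:
    """Adjusted Fisher-Pearson standardized third moment.

    Requires at least 3 non-missing values and nonzero variance; a constant
    sample has undefined skewness and raises ``ValueError``.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError(f"skewness needs >= 3 non-missing values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("skewness undefined for a constant sample")
    return float(stats.skew(x, bias=False))


def sqrt_transform(values) -> np.ndarray:
    """Elementwise square root of scores in [0, 1] (NaN passes through)."""
    x = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (x < 0) | (x > 1)
    if bad.any():
        raise ValueError("sqrt_transform requires values in [0, 1]")
    return np.sqrt(x)


def _design_matrix(sex: np.ndarray, age: np.ndarray) -> np.ndarray:
    male = (sex == "M").astype(float)
    return np.column_stack(
        [np.ones_like(age), male, age, age * male, age**2]
    )


def residualize(values, sex, age, standardize: bool = True):
    """OLS residuals of a trait on ``{1, sex, age, sex*age, age^2}``.

    Rows with a missing trait value are ignored during fitting and stay NaN
    in the output. A rank-deficient design (e.g. single-sex, single-age data)
    is handled by a minimum-norm least-squares fit with a logged warning.

    Returns ``(residuals, coefficients)`` where coefficients are keyed by
    :data:`DESIGN_COLUMNS`. Residuals are standardized to unit variance by
    default.
    """
    y = np.asarray(values, dtype=float)
    sex = np.asarray(sex, dtype=object)
    age = np.asarray(age, dtype=float)
    obs = ~np.isnan(y)
    if np.isnan(age[obs]).any():
        raise ValueError("missing age for rows with a non-missing trait value")
    X = _design_matrix(sex, age)
    rank = np.linalg.matrix_rank(X[obs])
    if rank < X.shape[1]:
        logger.warning(
            "mean-model design is rank-deficient (rank %d < %d); "
            "using minimum-norm solution", rank, X.shape[1]
        )
    beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    resid = np.full_like(y, np.nan)
    resid[obs] = y[obs] - X[obs] @ beta
    if standardize:
        sd = np.nanstd(resid, ddof=1)
        # a residual SD at rounding-noise level means the mean model fits
        # exactly; rescaling would only amplify noise
        if sd > 1e-8 * max(float(np.nanstd(y)), 1.0):
            resid = resid / sd
    return resid, dict(zip(DESIGN_COLUMNS, beta))


@dataclass
class PreprocessReport:
    """Per-trait record of what the preparation chain did."""

    skew_before: dict[str, float] = field(default_factory=dict)
    skew_after: dict[str, float] = field(default_factory=dict)
    transform: dict[str, str] = field(default_factory=dict)  # none | sqrt
    mean_model: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "skew_before": self.skew_before,
            "skew_after": self.skew_after,
            "transform": self.transform,
            "mean_model": self.mean_model,
        }


def preprocess_dataset(
    data: TwinDataset,
    threshold: float = 0.5,
    per_trait: dict[str, str] | None = None,
) -> tuple[TwinDataset, PreprocessReport]:
    """Full preparation chain on a dataset.

    For each trait: compute skewness on the pooled individual scores, apply a
    square-root transform when ``|skewness| > threshold`` (overridable per
    trait with ``per_trait[name] in {"none", "sqrt"}``), then residualize on
    sex/age terms and standardize. Returns the transformed dataset and a
    :class:`PreprocessReport`.
    """
    per_trait = per_trait or {}
    report = PreprocessReport()
    n_fam = len(data.families)
    sex = np.array(
        [s.value for f in data.families for s in (f.sex1, f.sex2)], dtype=object
    )
    age = np.repeat([f.age for f in data.families], 2).astype(float)

    new_traits: dict[str, np.ndarray] = {}
    for j, name in enumerate(data.trait_names):
        # pooled individual-level scores, family-major order (twin1, twin2)
        y = np.concatenate([f.traits[:, j] for f in data.families])
        sk0 = skewness(y)
        report.skew_before[name] = sk0
        choice = per_trait.get(name)
        if choice is None:
            choice = "sqrt" if abs(sk0) > threshold else "none"
        if choice == "sqrt":
            y = sqrt_transform(y)
        elif choice != "none":
            raise ValueError(f"unknown transform {choice!r} for trait {name!r}")
        report.transform[name] = choice
        report.skew_after[name] = skewness(y)
        resid, beta = residualize(y, sex, age)
        report.mean_model[name] = {k: float(v) for k, v in beta.items()}
        new_traits[name] = resid.reshape(n_fam, 2)

    return data.with_traits(new_traits), report
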