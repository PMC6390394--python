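"""Variance-component twin models: model-implied covariances, FIML, fitting.

The model family covers univariate and multivariate ACE / ADE decompositions
with an optional general sex-limitation structure. Each active component
X in {A, C, D, E} is parameterized by a lower-triangular loading matrix
``L_X`` so that its covariance contribution ``Sigma_X = L_X @ L_X.T`` is
positive semi-definite by construction. Cross-twin covariance blocks scale
the genetic components by the zygosity coefficients (A: 1 / 0.5, D: 1 / 0.25,
C: 1 in all groups, E: 0).

The likelihood is full-information maximum likelihood over raw pairs: each
pair contributes the multivariate-normal -2 log-likelihood of its observed
cells, with means fixed at zero (the data are residualized upstream).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .data_model import TwinDataset, Zygosity, zygosity_coefficients

__all__ = [
    "ModelSpec",
    "ParamSet",
    "FitResult",
    "FitOptions",
    "component_covariance",
    "pair_covariance",
    "fiml_minus2ll",
    "fit",
    "compare",
    "profile_ci",
    "profile_interval",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("A", "C", "D", "E")
_PENALTY = 1e10  # returned for non-PD implied covariances (optimizer-safe)
_BOUNDARY_TOL = 1e-6  # diagonal loadings below this are pinned to zero


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which components are active and how they are structured.

    ``fixed_paths`` is a set of ``(component, i, j)`` lower-triangle loading
    positions constrained to zero; dropping all off-diagonal loadings of a
    component removes its cross-trait covariances while keeping its variances.
    ``sex_limitation``:

    * ``"none"`` — one loading matrix per component, shared by both sexes;
    * ``"common_effects"`` — loadings shared, but the opposite-sex genetic
      correlation may be freed via ``dos_rg_free``;
    * ``"general"`` — separate male and female loading matrices.
    """

    traits: tuple[str, ...]
    components: frozenset[str] = frozenset({"A", "C", "E"})
    sex_limitation: str = "none"
    fixed_paths: frozenset[tuple[str, int, int]] = frozenset()
    dos_rg_free: bool = False

    def __post_init__(self):
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "components", frozenset(self.components))
        object.__setattr__(self, "fixed_paths", frozenset(self.fixed_paths))
        unknown = self.components - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        if "E" not in self.components:
            raise ValueError("E must be active in every model")
        if {"C", "D"} <= self.components:
            raise ValueError(
                "C and D may not be active simultaneously (not separable in "
                "the classical twin design); fit ACE and ADE separately"
            )
        if self.sex_limitation not in ("none", "common_effects", "general"):
            raise ValueError(f"unknown sex_limitation {self.sex_limitation!r}")
        if self.dos_rg_free and self.sex_limitation == "none":
            raise ValueError("dos_rg_free requires a sex-limitation structure")
        for comp, i, j in self.fixed_paths:
            if comp not in self.components or not (0 <= j <= i < self.n_traits):
                raise ValueError(f"invalid fixed path {(comp, i, j)}")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(c for c in COMPONENTS if c in self.components)

    @property
    def sexes(self) -> tuple[str, ...]:
        return ("M", "F") if self.sex_limitation == "general" else ("*",)

    def free_positions(self, comp: str) -> list[tuple[int, int]]:
        T = self.n_traits
        return [
            (i, j)
            for i in range(T)
            for j in range(i + 1)
            if (comp, i, j) not in self.fixed_paths
        ]

    @property
    def n_params(self) -> int:
        n = sum(len(self.free_positions(c)) for c in self.active) * len(self.sexes)
        if self.dos_rg_free:
            n += 1
        return n

    def drop_covariances(self, comp: str) -> "ModelSpec":
        """Submodel with all cross-trait loadings of ``comp`` fixed at zero."""
        T = self.n_traits
        extra = {(comp, i, j) for i in range(T) for j in range(i) }
        return replace(self, fixed_paths=self.fixed_paths | extra)

    def drop_component(self, comp: str) -> "ModelSpec":
        """Submodel with ``comp`` removed entirely."""
        if comp == "E":
            raise ValueError("cannot drop E")
        return replace(
            self,
            components=self.components - {comp},
            fixed_paths=frozenset(p for p in self.fixed_paths if p[0] != comp),
        )

    def permute_traits(self, order: Sequence[int]) -> "ModelSpec":
        """Spec with traits reordered (fixed paths are not remapped; only
        valid for specs whose fixed paths are whole-component covariance
        drops, which are permutation-invariant)."""
        order = list(order)
        traits = tuple(self.traits[k] for k in order)
        return replace(self, traits=traits)


@dataclass
class ParamSet:
    """Loading matrices per active component (and per sex when applicable).

    ``loadings[comp][sex]`` is a T x T lower-triangular matrix; ``sex`` is
    ``"*"`` for sex-homogeneous specs. ``rg_dos`` is the free opposite-sex
    genetic correlation (None when fixed at the default DZ value).
    """

    spec: ModelSpec
    loadings: dict[str, dict[str, np.ndarray]]
    rg_dos: float | None = None

    def loading(self, comp: str, sex: str = "*") -> np.ndarray:
        by_sex = self.loadings[comp]
        if sex in by_sex:
            return by_sex[sex]
        return by_sex["*"]

    def sigma(self, comp: str, sex: str = "*") -> np.ndarray:
        return component_covariance(self.loading(comp, sex))

    def total_sigma(self, sex: str = "*") -> np.ndarray:
        T = self.spec.n_traits
        out = np.zeros((T, T))
        for comp in self.spec.active:
            out += self.sigma(comp, sex)
        return out

    def copy(self) -> "ParamSet":
        return ParamSet(
            self.spec,
            {c: {s: L.copy() for s, L in d.items()} for c, d in self.loadings.items()},
            self.rg_dos,
        )


@dataclass
class FitResult:
    estimates: ParamSet
    minus2ll: float
    n_params: int
    converged: bool
    n_restarts_used: int
    gradient_norm: float
    boundary_flags: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return self.minus2ll + 2 * self.n_params

    def to_dict(self) -> dict:
        return {
            "minus2ll": self.minus2ll,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "gradient_norm": self.gradient_norm,
            "boundary_flags": self.boundary_flags,
            "rg_dos": self.estimates.rg_dos,
            "loadings": {
                comp: {sex: L.tolist() for sex, L in by_sex.items()}
                for comp, by_sex in self.estimates.loadings.items()
            },
        }


# ---------------------------------------------------------------------------
# model-implied covariance
# ---------------------------------------------------------------------------

def component_covariance(L: np.ndarray) -> np.ndarray:
    """``Sigma = L @ L.T`` for a lower-triangular loading matrix."""
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("loading matrix must be square")
    if not np.allclose(L, np.tril(L)):
        raise ValueError("loading matrix must be lower-triangular")
    return L @ L.T


_GROUP_SEX_PAIR = {
    Zygosity.MZM: ("M", "M"),
    Zygosity.DZM: ("M", "M"),
    Zygosity.MZF: ("F", "F"),
    Zygosity.DZF: ("F", "F"),
    Zygosity.DOS: ("M", "F"),
}


def _cross_coefficients(params: ParamSet, group: Zygosity) -> dict[str, float]:
    coef = zygosity_coefficients(group)
    alpha = {"A": coef.alpha_A, "C": coef.alpha_C, "D": coef.alpha_D, "E": 0.0}
    if group == Zygosity.DOS and params.spec.dos_rg_free and params.rg_dos is not None:
        if "A" in params.spec.components:
            alpha["A"] = params.rg_dos
        elif "D" in params.spec.components:
            # rg_dos lives on [0, 0.5]; map onto the D coefficient's [0, 0.25]
            alpha["D"] = params.rg_dos * 0.5
    return alpha


def pair_covariance(params: ParamSet, group: Zygosity) -> np.ndarray:
    """Model-implied 2T x 2T covariance of a twin pair in ``group``.

    Within-twin blocks are the (sex-appropriate) total covariances; the
    cross-twin block is ``sum_X alpha_X * L_X(sex1) @ L_X(sex2).T`` with the
    zygosity coefficients for the group.
    """
    spec = params.spec
    T = spec.n_traits
    s1, s2 = _GROUP_SEX_PAIR[group]
    alpha = _cross_coefficients(params, group)
    within1 = params.total_sigma(s1)
    within2 = params.total_sigma(s2)
    cross = np.zeros((T, T))
    for comp in spec.active:
        a = alpha[comp]
        if a != 0.0:
            cross += a * params.loading(comp, s1) @ params.loading(comp, s2).T
    out = np.empty((2 * T, 2 * T))
    out[:T, :T] = within1
    out[T:, T:] = within2
    out[:T, T:] = cross
    out[T:, :T] = cross.T
    return out


# ---------------------------------------------------------------------------
# parameter vector <-> ParamSet
# ---------------------------------------------------------------------------

class _Parameterization:
    """Maps between a flat optimizer vector and a :class:`ParamSet`."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.slots: list[tuple[str, str, int, int]] = []  # (comp, sex, i, j)
        for sex in spec.sexes:
            for comp in spec.active:
                for (i, j) in spec.free_positions(comp):
                    self.slots.append((comp, sex, i, j))
        self.n = len(self.slots) + (1 if spec.dos_rg_free else 0)

    def bounds(self, scale: float = 10.0) -> list[tuple[float, float]]:
        b = []
        for comp, sex, i, j in self.slots:
            if i == j:
                b.append((0.0, scale))  # sign convention: diagonals >= 0
            else:
                b.append((-scale, scale))
        if self.spec.dos_rg_free:
            b.append((0.0, 0.5))
        return b

    def pack(self, params: ParamSet) -> np.ndarray:
        theta = np.empty(self.n)
        for k, (comp, sex, i, j) in enumerate(self.slots):
            theta[k] = params.loading(comp, sex)[i, j]
        if self.spec.dos_rg_free:
            theta[-1] = params.rg_dos if params.rg_dos is not None else 0.5
        return theta

    def unpack(self, theta: np.ndarray) -> ParamSet:
        T = self.spec.n_traits
        loadings: dict[str, dict[str, np.ndarray]] = {
            comp: {sex: np.zeros((T, T)) for sex in self.spec.sexes}
            for comp in self.spec.active
        }
        for k, (comp, sex, i, j) in enumerate(self.slots):
            loadings[comp][sex][i, j] = theta[k]
        rg = float(theta[-1]) if self.spec.dos_rg_free else None
        return ParamSet(self.spec, loadings, rg)

    def default_start(self) -> np.ndarray:
        # split unit variance evenly across active components
        k = len(self.spec.active)
        theta = np.zeros(self.n)
        for idx, (comp, sex, i, j) in enumerate(self.slots):
            if i == j:
                theta[idx] = math.sqrt(1.0 / k)
        if self.spec.dos_rg_free:
            theta[-1] = 0.4
        return theta


# ---------------------------------------------------------------------------
# FIML objective
# ---------------------------------------------------------------------------

class FimlObjective:
    """Precomputed sufficient statistics for fast repeated -2LL evaluation.

    Pairs are grouped by (zygosity, missingness pattern); each cell stores
    the count and the scatter matrix of its observed coordinates, so one
    likelihood evaluation costs a Cholesky factorization per cell rather
    than per pair. Means are fixed at zero (residualized data); pass
    ``free_means=True`` to profile out per-cell observed means instead.
    """

    def __init__(self, data: TwinDataset, spec: ModelSpec, free_means: bool = False):
        if tuple(data.trait_names) != tuple(spec.traits):
            raise ValueError(
                f"dataset traits {data.trait_names} do not match spec traits "
                f"{spec.traits}"
            )
        self.spec = spec
        self.param = _Parameterization(spec)
        self.cells: list[tuple[Zygosity, np.ndarray, int, np.ndarray]] = []
        self.n_pairs = 0
        for group in Zygosity:
            X = data.pair_matrix(group)
            if X.shape[0] == 0:
                continue
            obs = ~np.isnan(X)
            if not obs.any():
                continue
            # group rows by missingness pattern
            patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
            for p_idx in range(patterns.shape[0]):
                mask = patterns[p_idx]
                if not mask.any():
                    continue
                rows = X[inverse == p_idx][:, mask]
                if free_means:
                    rows = rows - rows.mean(axis=0, keepdims=True)
                idx = np.flatnonzero(mask)
                scatter = rows.T @ rows
                self.cells.append((group, idx, rows.shape[0], scatter))
                self.n_pairs += rows.shape[0]
        if not self.cells:
            raise ValueError("dataset contains no observed trait values")

    def minus2ll(self, params: ParamSet) -> float:
        total = 0.0
        sigma_cache: dict[Zygosity, np.ndarray] = {}
        for group, idx, n, scatter in self.cells:
            if group not in sigma_cache:
                sigma_cache[group] = pair_covariance(params, group)
            sub = sigma_cache[group][np.ix_(idx, idx)]
            try:
                c, low = linalg.cho_factor(sub, lower=True, check_finite=False)
            except linalg.LinAlgError:
                return _PENALTY + float(np.sum(np.abs(sub)))
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            inv_scatter = linalg.cho_solve((c, low), scatter, check_finite=False)
            total += n * (len(idx) * math.log(2.0 * math.pi) + logdet)
            total += float(np.trace(inv_scatter))
        return total

    def moment_start(self) -> np.ndarray | None:
        """Method-of-moments starting point from empirical twin covariances.

        Solves the component covariances from the pooled within-twin block W
        and the MZ / DZ cross-twin blocks (e.g. ADE: A = 4 C_dz - C_mz,
        D = 2 C_mz - 4 C_dz, E = W - C_mz), projects each onto the PSD cone,
        and packs the Cholesky factors. Returns None when the dataset lacks
        the complete-pair MZ and DZ cells the moments need.
        """
        spec = self.spec
        T = spec.n_traits
        full = 2 * T
        acc: dict[str, list] = {"W": [], "MZ": [], "DZ": []}
        for group, idx, n, scatter in self.cells:
            if len(idx) != full:
                continue
            S = scatter / n
            acc["W"].append((n, 0.5 * (S[:T, :T] + S[T:, T:])))
            cross = 0.5 * (S[:T, T:] + S[:T, T:].T)
            key = "MZ" if group in (Zygosity.MZM, Zygosity.MZF) else "DZ"
            acc[key].append((n, cross))

        def wavg(entries):
            tot = sum(n for n, _ in entries)
            return sum(n * m for n, m in entries) / tot

        if not acc["W"] or not acc["MZ"]:
            return None
        W = wavg(acc["W"])
        c_mz = wavg(acc["MZ"])
        c_dz = wavg(acc["DZ"]) if acc["DZ"] else None

        comps: dict[str, np.ndarray] = {}
        active = set(spec.components)
        if active == {"A", "D", "E"} and c_dz is not None:
            comps["A"] = 4 * c_dz - c_mz
            comps["D"] = 2 * c_mz - 4 * c_dz
        elif active == {"A", "C", "E"} and c_dz is not None:
            comps["A"] = 2 * (c_mz - c_dz)
            comps["C"] = 2 * c_dz - c_mz
        elif active == {"D", "E"}:
            comps["D"] = c_mz
        elif active == {"A", "E"}:
            comps["A"] = c_mz
        elif active == {"C", "E"}:
            comps["C"] = c_mz
        elif active == {"E"}:
            pass
        else:
            return None
        comps["E"] = W - c_mz

        def psd_chol(sigma):
            sigma = 0.5 * (sigma + sigma.T)
            vals, vecs = np.linalg.eigh(sigma)
            vals = np.clip(vals, 0.02 * max(float(np.mean(np.diag(W))), 1e-3), None)
            return np.linalg.cholesky((vecs * vals) @ vecs.T)

        theta = np.zeros(self.param.n)
        for k, (comp, sex, i, j) in enumerate(self.param.slots):
            if comp not in comps:
                return None
            L = psd_chol(comps[comp])
            theta[k] = L[i, j]
        if spec.dos_rg_free:
            theta[-1] = 0.4
        return theta

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """-2LL and its exact gradient with respect to the flat parameters.

        For each pattern cell, ``dF/dSigma_obs = n * inv - inv @ S @ inv``;
        these are scattered into a per-group 2T x 2T weight matrix ``W`` and
        mapped onto the loading matrices through the chain rule of
        ``Sigma_pair = [[sum L1 L1', sum a L1 L2'], [., sum L2 L2']]``.
        Non-PD cells contribute the penalty and its (sub)gradient instead.
        """
        params = self.param.unpack(theta)
        spec = self.spec
        T = spec.n_traits
        total = 0.0
        sigma_cache: dict[Zygosity, np.ndarray] = {}
        W_group: dict[Zygosity, np.ndarray] = {}
        for group, idx, n, scatter in self.cells:
            if group not in sigma_cache:
                sigma_cache[group] = pair_covariance(params, group)
                W_group[group] = np.zeros((2 * T, 2 * T))
            sub = sigma_cache[group][np.ix_(idx, idx)]
            ix = np.ix_(idx, idx)
            try:
                c, low = linalg.cho_factor(sub, lower=True, check_finite=False)
            except linalg.LinAlgError:
                total += _PENALTY + float(np.sum(np.abs(sub)))
                W_group[group][ix] += np.sign(sub)
                continue
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            inv = linalg.cho_solve(
                (c, low), np.eye(len(idx)), check_finite=False
            )
            total += n * (len(idx) * math.log(2.0 * math.pi) + logdet)
            total += float(np.sum(inv * scatter))
            W_group[group][ix] += n * inv - inv @ scatter @ inv

        grad_L: dict[str, dict[str, np.ndarray]] = {
            comp: {sex: np.zeros((T, T)) for sex in params.loadings[comp]}
            for comp in spec.active
        }
        grad_rg = 0.0
        for group, W in W_group.items():
            s1, s2 = _GROUP_SEX_PAIR[group]
            alpha = _cross_coefficients(params, group)
            W11, W22, W12 = W[:T, :T], W[T:, T:], W[:T, T:]
            for comp in spec.active:
                k1 = s1 if s1 in params.loadings[comp] else "*"
                k2 = s2 if s2 in params.loadings[comp] else "*"
                L1 = params.loadings[comp][k1]
                L2 = params.loadings[comp][k2]
                grad_L[comp][k1] += 2.0 * W11 @ L1
                grad_L[comp][k2] += 2.0 * W22 @ L2
                a = alpha[comp]
                if a != 0.0:
                    grad_L[comp][k1] += 2.0 * a * W12 @ L2
                    grad_L[comp][k2] += 2.0 * a * W12.T @ L1
            if (
                group == Zygosity.DOS
                and spec.dos_rg_free
                and params.rg_dos is not None
            ):
                if "A" in spec.components:
                    comp, scale = "A", 1.0
                elif "D" in spec.components:
                    comp, scale = "D", 0.5
                else:
                    comp = None
                if comp is not None:
                    k1 = s1 if s1 in params.loadings[comp] else "*"
                    k2 = s2 if s2 in params.loadings[comp] else "*"
                    L1 = params.loadings[comp][k1]
                    L2 = params.loadings[comp][k2]
                    grad_rg += scale * 2.0 * float(np.sum(W12 * (L1 @ L2.T)))

        grad = np.empty(self.param.n)
        for k, (comp, sex, i, j) in enumerate(self.param.slots):
            grad[k] = grad_L[comp][sex][i, j]
        if spec.dos_rg_free:
            grad[-1] = grad_rg
        return float(total), grad

    def __call__(self, theta: np.ndarray) -> float:
        return self.minus2ll(self.param.unpack(theta))


def fiml_minus2ll(
    data: TwinDataset, params: ParamSet, spec: ModelSpec | None = None
) -> float:
    """FIML -2 log-likelihood of a dataset under a parameter set."""
    spec = spec or params.spec
    return FimlObjective(data, spec).minus2ll(params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    n_restarts: int = 10
    seed: int = 0
    jitter: float = 0.25
    maxiter: int = 2000
    ftol: float = 1e-12
    gtol: float = 1e-8
    min_pairs_per_group: int = 20  # identification floor (warn only)


def fit(
    data: TwinDataset,
    spec: ModelSpec,
    options: FitOptions | None = None,
    start: ParamSet | None = None,
) -> FitResult:
    """Minimize the FIML -2LL by bounded quasi-Newton with seeded restarts.

    The best converged restart is returned. Diagonal loadings pinned within
    ``1e-6`` of zero are reported as exactly zero and flagged as boundary
    solutions.
    """
    options = options or FitOptions()
    from .data_model import group_counts

    for group, n in group_counts(data).items():
        if 0 < n < options.min_pairs_per_group:
            logger.warning(
                "group %s has only %d pairs (< %d); estimates may be weakly "
                "identified", group.value, n, options.min_pairs_per_group,
            )

    objective = FimlObjective(data, spec)
    parameterization = objective.param
    bounds = parameterization.bounds()
    if start is not None:
        theta0 = parameterization.pack(start)
    else:
        theta0 = objective.moment_start()
        if theta0 is None:
            theta0 = parameterization.default_start()

    rng = np.random.default_rng(options.seed)
    best = None
    values: list[float] = []
    n_used = 0
    for attempt in range(max(1, options.n_restarts)):
        if attempt == 0:
            x0 = theta0
        elif attempt == 1:
            x0 = parameterization.default_start()
        else:
            x0 = theta0 + options.jitter * rng.standard_normal(theta0.size)
            x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            objective.value_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": options.maxiter,
                "ftol": options.ftol,
                "gtol": options.gtol,
            },
        )
        n_used = attempt + 1
        values.append(float(res.fun))
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        # twin likelihoods are multimodal near boundaries: stop early only
        # once three independent starts have reproduced the current best
        matches = sum(1 for v in values if v < best.fun + 1e-6)
        if attempt >= 2 and matches >= 3:
            break

    theta = np.asarray(best.x, dtype=float)
    # pin boundary solutions to exactly zero
    boundary_flags: list[tuple[str, str, int]] = []
    for k, (comp, sex, i, j) in enumerate(parameterization.slots):
        if i == j and 0.0 <= theta[k] < _BOUNDARY_TOL:
            theta[k] = 0.0
            boundary_flags.append((comp, sex, i))
    minus2ll, grad = objective.value_and_grad(theta)
    # project the gradient: at an active bound only the inward direction counts
    proj = grad.copy()
    for k, (lo, hi) in enumerate(bounds):
        if theta[k] <= lo + 1e-9 and proj[k] > 0:
            proj[k] = 0.0
        if theta[k] >= hi - 1e-9 and proj[k] < 0:
            proj[k] = 0.0
    gradient_norm = float(np.max(np.abs(proj)))
    converged = bool(best.success) and minus2ll < _PENALTY / 2
    if boundary_flags:
        logger.info("boundary solutions at zero: %s", boundary_flags)
    return FitResult(
        estimates=parameterization.unpack(theta),
        minus2ll=minus2ll,
        n_params=parameterization.n,
        converged=converged,
        n_restarts_used=n_used,
        gradient_norm=gradient_norm,
        boundary_flags=boundary_flags,
    )


def compare(full: FitResult, nested: FitResult) -> dict[str, float]:
    """Likelihood-ratio comparison of a nested submodel against its parent.

    The -2LL difference is referred to a chi-square on the parameter-count
    difference. Note: for boundary parameters this naive reference is
    conservative.
    """
    if nested.n_params > full.n_params:
        raise ValueError(
            f"nested model has more parameters ({nested.n_params}) than the "
            f"full model ({full.n_params})"
        )
    delta = nested.minus2ll - full.minus2ll
    ddf = full.n_params - nested.n_params
    p = 1.0 if ddf == 0 else float(stats.chi2.sf(max(delta, 0.0), ddf))
    return {
        "delta_minus2LL": float(delta),
        "delta_df": int(ddf),
        "p_value": p,
        "delta_aic": float(nested.aic - full.aic),
    }


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def profile_interval(
    objective: Callable[[np.ndarray], float],
    theta_hat: np.ndarray,
    target: Callable[[np.ndarray], float],
    level: float = 0.95,
    bounds: Sequence[tuple[float, float]] | None = None,
    target_limits: tuple[float, float] | None = None,
    initial_step: float = 0.02,
    tol: float = 1e-3,
    max_expand: int = 30,
) -> tuple[float, float, dict]:
    """Likelihood-based interval for a scalar function of the parameters.

    Finds the values ``c`` on either side of ``target(theta_hat)`` at which
    the profiled objective (minimized subject to ``target(theta) == c``)
    exceeds its minimum by the chi-square(1) quantile for ``level``. Bounds
    that run into ``target_limits`` are reported at the limit and flagged.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    m0 = float(objective(theta_hat))
    c0 = float(target(theta_hat))
    crit = float(stats.chi2.ppf(level, 1))

    def profiled(c: float, x_start: np.ndarray) -> tuple[float, np.ndarray]:
        res = optimize.minimize(
            objective,
            x_start,
            method="SLSQP",
            bounds=bounds,
            constraints=[{"type": "eq", "fun": lambda th: target(th) - c}],
            options={"maxiter": 300, "ftol": 1e-10},
        )
        val = float(res.fun) if res.fun is not None else np.inf
        x = res.x if res.x is not None else x_start
        if abs(float(target(x)) - c) > 1e-4:  # constraint not met
            return np.inf, x_start
        return val, x

    flags = {"lower_at_boundary": False, "upper_at_boundary": False}
    out = {}
    for side, sign, flag_key in (
        ("low", -1.0, "lower_at_boundary"),
        ("high", +1.0, "upper_at_boundary"),
    ):
        step = initial_step
        c_in, x_in = c0, theta_hat
        c_out = None
        for _ in range(max_expand):
            c_try = c_in + sign * step
            if target_limits is not None:
                lo_lim, hi_lim = target_limits
                if c_try <= lo_lim or c_try >= hi_lim:
                    c_try = lo_lim if sign < 0 else hi_lim
            m, x = profiled(c_try, x_in)
            if m - m0 >= crit:
                c_out = c_try
                break
            c_in, x_in = c_try, x
            if target_limits is not None and (
                (sign < 0 and c_try <= target_limits[0])
                or (sign > 0 and c_try >= target_limits[1])
            ):
                break
            step *= 1.8
        if c_out is None:
            # ran out of room: boundary of the target's natural range
            out[side] = c_in
            flags[flag_key] = True
            continue
        # bisect between the last inside and first outside values
        lo_c, hi_c = (c_out, c_in) if sign < 0 else (c_in, c_out)
        for _ in range(60):
            if abs(hi_c - lo_c) < tol:
                break
            mid = 0.5 * (lo_c + hi_c)
            m, x = profiled(mid, x_in)
            inside = m - m0 < crit
            if not np.isfinite(m):
                inside = False
            if sign < 0:
                if inside:
                    hi_c = mid
                else:
                    lo_c = mid
            else:
                if inside:
                    lo_c = mid
                else:
                    hi_c = mid
            if inside:
                x_in = x
        out[side] = 0.5 * (lo_c + hi_c)
    return float(out["low"]), float(out["high"]), flags


def profile_ci(
    data: TwinDataset,
    spec: ModelSpec,
    fit_result: FitResult,
    target: Callable[[ParamSet], float],
    level: float = 0.95,
    target_limits: tuple[float, float] | None = None,
    initial_step: float = 0.02,
) -> tuple[float, float, dict]:
    """Profile-likelihood CI for a scalar function of the fitted parameters.

    ``target`` may be any smooth function of the :class:`ParamSet` — a raw
    loading, a standardized variance proportion, or a derived component
    correlation; the interval comes from constrained reoptimization, not the
    delta method, so it remains valid near parameter-space boundaries.
    """
    if not fit_result.converged:
        raise ValueError("profile CI requires a converged fit")
    objective = FimlObjective(data, spec)
    parameterization = objective.param

    def theta_target(theta: np.ndarray) -> float:
        return float(target(parameterization.unpack(theta)))

    theta_hat = parameterization.pack(fit_result.estimates)
    return profile_interval(
        objective,
        theta_hat,
        theta_target,
        level=level,
        bounds=parameterization.bounds(),
        target_limits=target_limits,
        initial_step=initial_step,
    )
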