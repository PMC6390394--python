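"""Synthetic five-group twin data with a known generative structure.

Simulates twin pairs whose trait vectors are sums of independent component
draws — A (cross-twin correlation 1 for MZ, 0.5 for DZ/DOS), D (1 / 0.25),
C (1 / 1) and E (uncorrelated across twins) — each from a multivariate
normal with a configured covariance matrix, optionally per sex. Mean effects
of sex and age, positive skew, and completely-at-random missingness can be
layered on top so that every stage of the analysis pipeline has something
real to exercise.

The component draws here are built directly from ``[[S, a*S], [a*S, S]]``
block matrices, independent of the model layer's ``pair_covariance``; the
two constructions cross-validate each other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .biometric import ModelSpec, ParamSet
from .data_model import Family, Sex, TwinDataset, Zygosity

__all__ = [
    "SimulationConfig",
    "simulate",
    "table7_config",
    "trivariate_de_params",
    "univariate_sexlim_params",
    "DEFAULT_GROUP_SIZES",
]

# pairs per zygosity group in the reference five-group design
DEFAULT_GROUP_SIZES: dict[Zygosity, int] = {
    Zygosity.MZM: 365,
    Zygosity.DZM: 173,
    Zygosity.MZF: 675,
    Zygosity.DZF: 271,
    Zygosity.DOS: 258,
}

# cross-twin coefficients per group: (alpha_A, alpha_C, alpha_D)
_ALPHAS = {
    Zygosity.MZM: (1.0, 1.0, 1.0),
    Zygosity.MZF: (1.0, 1.0, 1.0),
    Zygosity.DZM: (0.5, 1.0, 0.25),
    Zygosity.DZF: (0.5, 1.0, 0.25),
    Zygosity.DOS: (0.5, 1.0, 0.25),
}

_GROUP_SEXES = {
    Zygosity.MZM: (Sex.M, Sex.M),
    Zygosity.DZM: (Sex.M, Sex.M),
    Zygosity.MZF: (Sex.F, Sex.F),
    Zygosity.DZF: (Sex.F, Sex.F),
    Zygosity.DOS: (Sex.M, Sex.F),
}


@dataclass
class SimulationConfig:
    group_sizes: dict[Zygosity, int]
    trait_names: tuple[str, ...]
    params: ParamSet  # generating loadings (per sex when sex-limited)
    # per-trait mean-model coefficients: (sex, age, age*sex, age^2);
    # ages are centered at age_mean before entering the mean model
    mean_coefs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    age_mean: float = 19.1
    age_sd: float = 3.1
    age_range: tuple[float, float] = (11.0, 29.0)
    transform: str = "none"  # none | square
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.transform not in ("none", "square"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for comp in self.params.spec.active:
            for sex in self.params.spec.sexes:
                eig = np.linalg.eigvalsh(self.params.sigma(comp, sex))
                if eig.min() < -1e-10:
                    raise ValueError(
                        f"generating covariance for component {comp} is not PSD"
                    )


def _draw_ages(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.age_range
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm.rvs(
        a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n, random_state=rng
    )


def _pair_component_draw(
    rng: np.random.Generator,
    L1: np.ndarray,
    L2: np.ndarray,
    alpha: float,
    n: int,
) -> np.ndarray:
    """Draw n pairs of one component: 2T-dim MVN with cross coefficient alpha."""
    T = L1.shape[0]
    s1 = L1 @ L1.T
    s2 = L2 @ L2.T
    cross = alpha * (L1 @ L2.T)
    cov = np.block([[s1, cross], [cross.T, s2]])
    return rng.multivariate_normal(np.zeros(2 * T), cov, size=n, method="eigh")


def simulate(config: SimulationConfig) -> TwinDataset:
    """Generate a five-group twin dataset under the configured model.

    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.params.spec
    T = spec.n_traits
    names = tuple(config.trait_names)
    if len(names) != T:
        raise ValueError("trait_names length does not match generating params")

    families: list[Family] = []
    fid = 0
    for group in Zygosity:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        sex1, sex2 = _GROUP_SEXES[group]
        a_A, a_C, a_D = _ALPHAS[group]
        alpha = {"A": a_A, "C": a_C, "D": a_D, "E": 0.0}
        total = np.zeros((n, 2 * T))
        for comp in spec.active:
            L1 = config.params.loading(comp, sex1.value)
            L2 = config.params.loading(comp, sex2.value)
            total += _pair_component_draw(rng, L1, L2, alpha[comp], n)
        ages = _draw_ages(rng, n, config)

        # mean effects per twin member
        y = total.reshape(n, 2, T).copy()
        age_c = ages - config.age_mean
        for j, name in enumerate(names):
            b_sex, b_age, b_agesex, b_age2 = config.mean_coefs.get(
                name, (0.0, 0.0, 0.0, 0.0)
            )
            for k, sex in enumerate((sex1, sex2)):
                male = 1.0 if sex == Sex.M else 0.0
                y[:, k, j] += (
                    b_sex * male
                    + b_age * age_c
                    + b_agesex * age_c * male
                    + b_age2 * age_c**2
                )

        if config.transform == "square":
            # map each score through the standard-normal CDF (rank-preserving,
            # approximately uniform) and square: positive skew ~0.6, bounded
            # in [0, 1], and exactly undone to symmetric by a sqrt transform
            flat = y.reshape(-1, T)
            sd = flat.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            z = (flat - flat.mean(axis=0)) / sd
            y = (stats.norm.cdf(z) ** 2).reshape(n, 2, T)

        if config.missing_rate > 0:
            mask = rng.random(size=y.shape) < config.missing_rate
            y[mask] = np.nan

        for i in range(n):
            families.append(
                Family(f"fam{fid:05d}", group, sex1, sex2, float(ages[i]), y[i].copy())
            )
            fid += 1

    return TwinDataset(families, names, age_range=config.age_range)


def _corr_to_cov(variances: np.ndarray, corr: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.asarray(variances, dtype=float))
    return np.outer(sd, sd) * np.asarray(corr, dtype=float)


def trivariate_de_params(
    d2=(0.76, 0.70, 0.47),
    rd=(-0.92, -0.55, 0.19),
    e2=(0.24, 0.30, 0.53),
    re=(-0.62, -0.44, -0.40),
    traits=("TE", "SE", "SY"),
) -> ParamSet:
    """D+E trivariate parameter set from variances and correlations.

    ``rd``/``re`` are the lower-triangle correlations in order
    (1,2), (1,3), (2,3). Raises if either implied covariance is not PSD.
    """
    Rd = np.array([[1, rd[0], rd[1]], [rd[0], 1, rd[2]], [rd[1], rd[2], 1.0]])
    Re = np.array([[1, re[0], re[1]], [re[0], 1, re[2]], [re[1], re[2], 1.0]])
    sig_d = _corr_to_cov(np.asarray(d2), Rd)
    sig_e = _corr_to_cov(np.asarray(e2), Re)
    for name, sig in (("D", sig_d), ("E", sig_e)):
        eig = np.linalg.eigvalsh(sig)
        if eig.min() <= 0:
            raise ValueError(
                f"implied {name} covariance is not positive definite "
                f"(min eigenvalue {eig.min():.3g})"
            )
    spec = ModelSpec(traits=tuple(traits), components=frozenset({"D", "E"}))
    loadings = {
        "D": {"*": np.linalg.cholesky(sig_d)},
        "E": {"*": np.linalg.cholesky(sig_e)},
    }
    return ParamSet(spec, loadings)


def table7_config(
    group_sizes: dict[Zygosity, int] | None = None,
    seed: int = 0,
    transform: str = "none",
    mean_coefs: dict | None = None,
    missing_rate: float = 0.0,
) -> SimulationConfig:
    """Reference trivariate D+E generating configuration.

    Component variances (0.76, 0.70, 0.47) and (0.24, 0.30, 0.53) sum to a
    total variance of exactly 1 per trait; the D and E correlation structures
    carry the cross-trait signal.
    """
    params = trivariate_de_params()
    return SimulationConfig(
        group_sizes=dict(group_sizes or DEFAULT_GROUP_SIZES),
        trait_names=("TE", "SE", "SY"),
        params=params,
        mean_coefs=mean_coefs or {},
        transform=transform,
        missing_rate=missing_rate,
        seed=seed,
    )


def univariate_sexlim_params(
    male: tuple[float, float],
    female: tuple[float, float],
    trait: str = "TE",
) -> ParamSet:
    """Univariate ADE parameter set with sex-specific (a2, d2) splits.

    ``male``/``female`` give the additive and dominance variance fractions
    for each sex; the E variance is the per-sex remainder to unit total.
    """
    spec = ModelSpec(
        traits=(trait,),
        components=frozenset({"A", "D", "E"}),
        sex_limitation="general",
    )
    loadings: dict[str, dict[str, np.ndarray]] = {"A": {}, "D": {}, "E": {}}
    for sex, (a2, d2) in (("M", male), ("F", female)):
        e2 = 1.0 - a2 - d2
        if min(a2, d2, e2) < 0:
            raise ValueError(f"invalid variance split for sex {sex}")
        loadings["A"][sex] = np.array([[np.sqrt(a2)]])
        loadings["D"][sex] = np.array([[np.sqrt(d2)]])
        loadings["E"][sex] = np.array([[np.sqrt(e2)]])
    return ParamSet(spec, loadings)
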