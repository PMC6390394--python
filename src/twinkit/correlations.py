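"""Maximum-likelihood twin correlations and descriptive correlation layers.

Within-trait twin correlations per zygosity group are estimated under a
bivariate normal with means and variances constrained equal across twin
order (for same-sex groups), by full-information maximum likelihood over
pairs with a possibly missing member, with profile-likelihood confidence
intervals. Cross-twin cross-trait and phenotypic correlations form the
descriptive layer computed on preprocessed scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import TwinDataset, Zygosity

__all__ = [
    "CorrelationEstimate",
    "ml_twin_correlation",
    "cross_twin_cross_trait",
    "phenotypic_correlations",
]


@dataclass(frozen=True)
class CorrelationEstimate:
    r: float
    ci_low: float
    ci_high: float
    n_pairs: int
    method: str  # ml_constrained | pearson_pooled

    def __post_init__(self):
        if not (-1.0 <= self.r <= 1.0):
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if not (self.ci_low - 1e-9 <= self.r <= self.ci_high + 1e-9):
            raise ValueError("confidence bounds do not bracket the estimate")


def _pair_minus2ll(
    x: np.ndarray, mu: np.ndarray, var: np.ndarray, r: float
) -> float:
    """-2LL of twin pairs under a bivariate normal, FIML over partial pairs.

    ``x`` is (n, 2) with NaN for missing members; ``mu``/``var`` are
    per-member means and variances (length 2).
    """
    total = 0.0
    both = ~np.isnan(x).any(axis=1)
    only1 = ~np.isnan(x[:, 0]) & np.isnan(x[:, 1])
    only2 = np.isnan(x[:, 0]) & ~np.isnan(x[:, 1])
    cov = r * math.sqrt(var[0] * var[1])
    sigma = np.array([[var[0], cov], [cov, var[1]]])
    det = var[0] * var[1] * (1.0 - r * r)
    if det <= 0 or var[0] <= 0 or var[1] <= 0:
        return 1e10
    inv = np.linalg.inv(sigma)
    if both.any():
        d = x[both] - mu
        q = np.einsum("ni,ij,nj->n", d, inv, d)
        total += both.sum() * (2 * math.log(2 * math.pi) + math.log(det)) + q.sum()
    for only, k in ((only1, 0), (only2, 1)):
        if only.any():
            d = x[only, k] - mu[k]
            total += only.sum() * (
                math.log(2 * math.pi) + math.log(var[k])
            ) + float(np.sum(d * d / var[k]))
    return float(total)


def ml_twin_correlation(
    pairs: np.ndarray,
    constrain_order: bool = True,
    level: float = 0.95,
) -> CorrelationEstimate:
    """ML twin correlation for one trait in one zygosity group.

    ``pairs`` is (n, 2); NaN marks a missing member (FIML). With
    ``constrain_order`` (same-sex groups) means and variances are equal
    across twin order; without it (opposite-sex pairs, fixed male-first
    order) each member gets its own mean and variance. The CI is
    profile-likelihood (-2LL increase of the chi-square(1) quantile), with
    Fisher-z as the optimizer's internal unconstrained scale.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    usable = ~np.isnan(x).all(axis=1)
    x = x[usable]
    n_complete = int((~np.isnan(x).any(axis=1)).sum())
    if x.shape[0] < 3 or n_complete == 0:
        raise ValueError(
            "correlation unidentified: need >= 3 usable pairs including at "
            "least one complete pair"
        )

    pooled = x[~np.isnan(x)]
    mu0, sd0 = float(pooled.mean()), float(pooled.std(ddof=1))

    def unpack(theta):
        if constrain_order:
            mu = np.array([theta[0], theta[0]])
            var = np.array([math.exp(theta[1]) ** 2] * 2)
            z = theta[2]
        else:
            mu = np.array([theta[0], theta[1]])
            var = np.array([math.exp(theta[2]) ** 2, math.exp(theta[3]) ** 2])
            z = theta[4]
        return mu, var, math.tanh(z)

    def nll(theta):
        mu, var, r = unpack(theta)
        return _pair_minus2ll(x, mu, var, r)

    if constrain_order:
        theta0 = np.array([mu0, math.log(max(sd0, 1e-6)), 0.0])
    else:
        m = np.array([np.nanmean(x[:, 0]), np.nanmean(x[:, 1])])
        s = np.array(
            [max(np.nanstd(x[:, 0], ddof=1), 1e-6), max(np.nanstd(x[:, 1], ddof=1), 1e-6)]
        )
        theta0 = np.array([m[0], m[1], math.log(s[0]), math.log(s[1]), 0.0])

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    best = optimize.minimize(nll, res.x, method="Nelder-Mead",
                             options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 5000})
    mu, var, r_hat = unpack(best.x)
    m2ll_hat = float(best.fun)

    # profile CI over r, re-optimizing the nuisance parameters at each r
    crit = float(stats.chi2.ppf(level, 1))
    nuisance_idx = list(range(len(best.x) - 1))

    def profiled(r):
        def nll_r(eta):
            theta = np.append(eta, math.atanh(np.clip(r, -0.999999, 0.999999)))
            return nll(theta)
        res_r = optimize.minimize(nll_r, best.x[nuisance_idx], method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10})
        return float(res_r.fun)

    def find_bound(sign):
        # expand outward until the profile crosses the threshold, then bisect
        step = 0.02
        r_in, r_out = r_hat, None
        while True:
            r_try = r_in + sign * step
            if (sign > 0 and r_try >= 1.0) or (sign < 0 and r_try <= -1.0):
                return float(sign)  # boundary of the correlation scale
            if profiled(r_try) - m2ll_hat >= crit:
                r_out = r_try
                break
            r_in = r_try
            step *= 1.6
        lo, hi = (r_in, r_out) if sign > 0 else (r_out, r_in)
        for _ in range(40):
            if hi - lo < 1e-4:
                break
            mid = 0.5 * (lo + hi)
            inside = profiled(mid) - m2ll_hat < crit
            if sign > 0:
                lo, hi = (mid, hi) if inside else (lo, mid)
            else:
                lo, hi = (lo, mid) if inside else (mid, hi)
        return 0.5 * (lo + hi)

    ci_high = find_bound(+1)
    ci_low = find_bound(-1)
    return CorrelationEstimate(
        r=float(np.clip(r_hat, -1.0, 1.0)),
        ci_low=float(min(ci_low, r_hat)),
        ci_high=float(max(ci_high, r_hat)),
        n_pairs=int(x.shape[0]),
        method="ml_constrained",
    )


_MZ_GROUPS = (Zygosity.MZM, Zygosity.MZF)
_DZ_GROUPS = (Zygosity.DZM, Zygosity.DZF, Zygosity.DOS)


def cross_twin_cross_trait(
    data: TwinDataset,
    trait_i: str,
    trait_j: str,
    zygosity_class: str,
    level: float = 0.95,
) -> CorrelationEstimate:
    """Cross-twin cross-trait correlation for MZ or DZ pairs.

    Correlation between one twin's ``trait_i`` and the cotwin's ``trait_j``,
    under the order-constrained model: per-trait means and variances pooled
    over both twins, and the cross-covariance symmetrized over the two
    twin-order assignments for same-sex pairs (opposite-sex pairs keep their
    fixed male-first order). CI by Fisher z on the effective pair count.
    """
    groups = _MZ_GROUPS if zygosity_class.upper() == "MZ" else _DZ_GROUPS
    i = data.trait_index(trait_i)
    j = data.trait_index(trait_j)
    x1i, x2j, x1j, x2i, sym = [], [], [], [], []
    for fam in data.families:
        if fam.zygosity not in groups:
            continue
        t = fam.traits
        x1i.append(t[0, i]); x2j.append(t[1, j])
        x1j.append(t[0, j]); x2i.append(t[1, i])
        sym.append(fam.zygosity != Zygosity.DOS)
    x1i, x2j = np.array(x1i), np.array(x2j)
    x1j, x2i = np.array(x1j), np.array(x2i)
    sym = np.array(sym, dtype=bool)

    # pooled per-trait moments over both twins
    pool_i = np.concatenate([x1i, x2i])
    pool_j = np.concatenate([x1j, x2j])
    mi, si = np.nanmean(pool_i), np.nanstd(pool_i, ddof=1)
    mj, sj = np.nanmean(pool_j), np.nanstd(pool_j, ddof=1)

    prod_a = (x1i - mi) * (x2j - mj)  # ordering 1: twin1 trait_i x twin2 trait_j
    prod_b = (x1j - mj) * (x2i - mi)  # ordering 2
    cross = np.where(sym, 0.5 * (np.where(np.isnan(prod_a), prod_b, prod_a)
                                 + np.where(np.isnan(prod_b), prod_a, prod_b)),
                     prod_a)
    ok = ~np.isnan(cross)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need >= 3 usable pairs")
    r = float(np.clip(cross[ok].mean() / (si * sj), -1.0, 1.0))
    zcrit = stats.norm.ppf(0.5 + level / 2)
    if n > 3 and abs(r) < 1.0:
        z = math.atanh(r)
        half = zcrit / math.sqrt(n - 3)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    else:
        lo, hi = -1.0, 1.0
    return CorrelationEstimate(r, min(lo, r), max(hi, r), n, "pearson_pooled")


def phenotypic_correlations(data: TwinDataset) -> pd.DataFrame:
    """Within-person trait correlation matrix, pooled over all individuals.

    Pairwise-complete Pearson correlations; symmetric with unit diagonal.
    """
    table = data.individual_table()[list(data.trait_names)]
    return table.corr(method="pearson")
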