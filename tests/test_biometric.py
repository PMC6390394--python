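import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twinkit.biometric import (
    FitOptions,
    ModelSpec,
    ParamSet,
    compare,
    component_covariance,
    fiml_minus2ll,
    fit,
    pair_covariance,
    profile_interval,
)
from twinkit.data_model import TwinDataset, Zygosity
from twinkit.derived import derive_stats
from twinkit.preprocessing import preprocess_dataset
from twinkit.synthetic import (
    DEFAULT_GROUP_SIZES,
    SimulationConfig,
    simulate,
    table7_config,
    trivariate_de_params,
)

from conftest import make_family


def univariate_params(a2=0.0, c2=0.0, d2=0.0, e2=1.0):
    comps = {"E"}
    loadings = {"E": {"*": np.array([[np.sqrt(e2)]])}}
    for name, v in (("A", a2), ("C", c2), ("D", d2)):
        if v > 0:
            comps.add(name)
            loadings[name] = {"*": np.array([[np.sqrt(v)]])}
    spec = ModelSpec(traits=("X",), components=frozenset(comps))
    return ParamSet(spec, loadings)


class TestModelSpec:
    def test_c_and_d_exclusive(self):
        with pytest.raises(ValueError, match="separately"):
            ModelSpec(traits=("X",), components=frozenset({"A", "C", "D", "E"}))

    def test_e_required(self):
        with pytest.raises(ValueError, match="E"):
            ModelSpec(traits=("X",), components=frozenset({"A", "C"}))

    def test_param_counts(self):
        spec = ModelSpec(traits=("a", "b", "c"), components=frozenset({"D", "E"}))
        assert spec.n_params == 12  # two full 3x3 lower triangles
        assert spec.drop_covariances("D").n_params == 9
        assert spec.drop_component("D").n_params == 6

    def test_general_sexlim_doubles_params(self):
        spec = ModelSpec(traits=("X",), components=frozenset({"A", "D", "E"}),
                         sex_limitation="general")
        assert spec.n_params == 6
        assert spec.sexes == ("M", "F")


class TestComponentCovariance:
    def test_identity(self):
        np.testing.assert_array_equal(component_covariance(np.eye(3)), np.eye(3))

    def test_rank_one_common_factor(self):
        L = np.array([[0.8, 0.0], [0.8, 0.0]])
        sigma = component_covariance(L)
        r = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert r == pytest.approx(1.0)

    def test_brute_force_summation_oracle(self, rng):
        L = np.tril(rng.standard_normal((4, 4)))
        sigma = component_covariance(L)
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    expected[i, j] += L[i, k] * L[j, k]
        np.testing.assert_allclose(sigma, expected, atol=1e-12)

    def test_non_triangular_rejected(self):
        with pytest.raises(ValueError, match="triangular"):
            component_covariance(np.ones((2, 2)))


class TestPairCovariance:
    def test_univariate_closed_form(self):
        params = univariate_params(a2=0.4, d2=0.3, e2=0.3)
        mz = pair_covariance(params, Zygosity.MZM)
        dz = pair_covariance(params, Zygosity.DZF)
        assert mz[0, 1] == pytest.approx(0.7)
        assert dz[0, 1] == pytest.approx(0.5 * 0.4 + 0.25 * 0.3)
        assert mz[0, 0] == pytest.approx(1.0)

    def test_e_only_zero_cross(self):
        params = univariate_params(e2=1.0)
        for g in Zygosity:
            assert pair_covariance(params, g)[0, 1] == 0.0

    def test_simulation_oracle(self):
        """Model-implied pair covariance matches brute-force simulation."""
        params = trivariate_de_params()
        n = 100_000
        config = SimulationConfig(
            group_sizes={Zygosity.DZM: n}, trait_names=("TE", "SE", "SY"),
            params=params, seed=77,
        )
        emp = np.cov(simulate(config).pair_matrix(Zygosity.DZM).T)
        model = pair_covariance(params, Zygosity.DZM)
        # 3 MC standard errors for a covariance of unit-variance scores
        assert np.max(np.abs(emp - model)) < 3.5 / np.sqrt(n)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_psd_property(self, seed):
        r = np.random.default_rng(seed)
        spec = ModelSpec(traits=("a", "b"), components=frozenset({"A", "D", "E"}))
        loadings = {
            c: {"*": np.tril(r.standard_normal((2, 2)))} for c in ("A", "D", "E")
        }
        for c in loadings:
            np.fill_diagonal(loadings[c]["*"], np.abs(np.diag(loadings[c]["*"])))
        params = ParamSet(spec, loadings)
        for g in Zygosity:
            sigma = pair_covariance(params, g)
            np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
            assert np.linalg.eigvalsh(sigma).min() > -1e-10


@pytest.fixture(scope="module")
def small_de_data():
    config = table7_config(
        group_sizes={Zygosity.MZM: 80, Zygosity.DZM: 40, Zygosity.MZF: 80,
                     Zygosity.DZF: 40, Zygosity.DOS: 40},
        seed=31,
    )
    return simulate(config)


class TestFiml:
    def test_brute_force_logpdf_oracle(self, small_de_data):
        """FIML -2LL equals the per-pair multivariate-normal -2 logpdf sum."""
        params = trivariate_de_params()
        value = fiml_minus2ll(small_de_data, params)
        brute = 0.0
        for fam in small_de_data.families:
            sigma = pair_covariance(params, fam.zygosity)
            x = fam.traits.reshape(-1)
            obs = ~np.isnan(x)
            brute += -2.0 * stats.multivariate_normal.logpdf(
                x[obs], mean=np.zeros(obs.sum()),
                cov=sigma[np.ix_(np.flatnonzero(obs), np.flatnonzero(obs))],
            )
        assert value == pytest.approx(brute, rel=1e-10)

    def test_brute_force_oracle_with_missingness(self):
        config = table7_config(
            group_sizes={Zygosity.MZF: 60, Zygosity.DOS: 30}, seed=13,
            missing_rate=0.25,
        )
        data = simulate(config)
        params = trivariate_de_params()
        value = fiml_minus2ll(data, params)
        brute = 0.0
        for fam in data.families:
            sigma = pair_covariance(params, fam.zygosity)
            x = fam.traits.reshape(-1)
            obs = np.flatnonzero(~np.isnan(x))
            if obs.size == 0:
                continue
            brute += -2.0 * stats.multivariate_normal.logpdf(
                x[obs], mean=np.zeros(obs.size), cov=sigma[np.ix_(obs, obs)]
            )
        assert value == pytest.approx(brute, rel=1e-10)

    def test_saturated_closed_form(self):
        """At the empirical-MLE covariance the -2LL takes its closed form
        n * (k log 2pi + log|S| + k)."""
        config = table7_config(group_sizes={Zygosity.MZM: 500}, seed=21)
        base = simulate(config)
        # double-enter so the MLE covariance is exactly exchange-symmetric
        # and therefore reachable by a D+E twin structure
        swapped = [
            make_family(f"sw{i}", f.zygosity.value, f.traits[::-1], age=f.age)
            for i, f in enumerate(base.families)
        ]
        data = TwinDataset(list(base.families) + swapped, base.trait_names)
        X = data.pair_matrix(Zygosity.MZM)
        n, k = X.shape
        S = (X.T @ X) / n  # MLE covariance (means fixed at zero)
        # reconstruct a D+E parameter set whose MZ pair covariance equals S
        T = 3
        sig_d = S[:T, T:]
        sig_e = S[:T, :T] - sig_d
        spec = ModelSpec(traits=data.trait_names, components=frozenset({"D", "E"}))
        params = ParamSet(spec, {
            "D": {"*": np.linalg.cholesky(sig_d)},
            "E": {"*": np.linalg.cholesky(sig_e)},
        })
        implied = pair_covariance(params, Zygosity.MZM)
        np.testing.assert_allclose(implied, S, atol=1e-10)
        expected = n * (k * np.log(2 * np.pi) + np.linalg.slogdet(S)[1] + k)
        assert fiml_minus2ll(data, params) == pytest.approx(expected, rel=1e-10)

    def test_duplication_doubles(self, small_de_data):
        params = trivariate_de_params()
        doubled = TwinDataset(
            small_de_data.families
            + [make_family(f"dup{i}", f.zygosity.value, f.traits, age=f.age)
               for i, f in enumerate(small_de_data.families)],
            small_de_data.trait_names,
        )
        assert fiml_minus2ll(doubled, params) == pytest.approx(
            2 * fiml_minus2ll(small_de_data, params), rel=1e-12
        )

    def test_missing_twin_is_marginal(self):
        """A pair with one twin absent contributes the observed twin's
        marginal T-variate likelihood."""
        params = trivariate_de_params()
        x = np.array([0.3, -0.5, 1.1])
        fam = make_family("m", "MZf", np.vstack([x, [np.nan] * 3]))
        data = TwinDataset([fam], ("TE", "SE", "SY"))
        sigma = pair_covariance(params, Zygosity.MZF)[:3, :3]
        expected = -2.0 * stats.multivariate_normal.logpdf(
            x, mean=np.zeros(3), cov=sigma
        )
        assert fiml_minus2ll(data, params) == pytest.approx(expected, rel=1e-12)

    def test_non_pd_penalized(self, small_de_data):
        spec = ModelSpec(traits=("TE", "SE", "SY"), components=frozenset({"D", "E"}))
        zero = {"D": {"*": np.zeros((3, 3))}, "E": {"*": np.zeros((3, 3))}}
        assert fiml_minus2ll(small_de_data, ParamSet(spec, zero)) > 1e9


class TestFit:
    def test_univariate_de_recovery(self):
        gen = univariate_params(d2=0.76, e2=0.24)
        config = SimulationConfig(
            group_sizes=dict(DEFAULT_GROUP_SIZES), trait_names=("X",),
            params=gen, seed=99,
        )
        data = simulate(config)
        prepped, _ = preprocess_dataset(data)
        spec = ModelSpec(traits=("X",), components=frozenset({"A", "D", "E"}))
        res = fit(prepped, spec, options=FitOptions(n_restarts=3, seed=1))
        assert res.converged
        d2 = derive_stats(res.estimates).proportions["D"][0]
        a2 = derive_stats(res.estimates).proportions["A"][0]
        assert a2 + d2 == pytest.approx(0.76, abs=0.05)

    def test_e_only_null_recovery(self):
        gen = univariate_params(e2=1.0)
        sizes = {g: n // 2 for g, n in DEFAULT_GROUP_SIZES.items()}
        config = SimulationConfig(group_sizes=sizes, trait_names=("X",),
                                  params=gen, seed=5)
        data = simulate(config)
        prepped, _ = preprocess_dataset(data)
        full_spec = ModelSpec(traits=("X",), components=frozenset({"A", "D", "E"}))
        full = fit(prepped, full_spec, options=FitOptions(n_restarts=3, seed=2))
        props = derive_stats(full.estimates).proportions
        assert props["A"][0] + props["D"][0] < 0.12
        sub = fit(prepped, full_spec.drop_component("A").drop_component("D"),
                  options=FitOptions(n_restarts=3, seed=2))
        result = compare(full, sub)
        assert result["p_value"] > 0.05

    def test_aic_identity(self, small_de_data):
        prepped, _ = preprocess_dataset(small_de_data)
        spec = ModelSpec(traits=prepped.trait_names, components=frozenset({"D", "E"}))
        res = fit(prepped, spec, options=FitOptions(n_restarts=2, seed=0))
        assert res.aic == pytest.approx(res.minus2ll + 2 * res.n_params)

    def test_trait_order_invariance(self, small_de_data):
        prepped, _ = preprocess_dataset(small_de_data)
        spec = ModelSpec(traits=prepped.trait_names, components=frozenset({"D", "E"}))
        base = fit(prepped, spec, options=FitOptions(n_restarts=3, seed=0))
        perm = [2, 0, 1]
        permuted = prepped.with_traits({
            name: np.array([f.traits[:, prepped.trait_index(name)]
                            for f in prepped.families])
            for name in prepped.trait_names
        })
        # reorder the trait axis
        reordered = TwinDataset(
            [make_family(f.family_id, f.zygosity.value, f.traits[:, perm], f.age)
             for f in prepped.families],
            tuple(prepped.trait_names[k] for k in perm),
        )
        spec_p = ModelSpec(traits=reordered.trait_names,
                           components=frozenset({"D", "E"}))
        alt = fit(reordered, spec_p, options=FitOptions(n_restarts=3, seed=1))
        assert alt.minus2ll == pytest.approx(base.minus2ll, abs=1e-4)
        assert alt.aic == pytest.approx(base.aic, abs=1e-4)
        base_d = derive_stats(base.estimates)
        alt_d = derive_stats(alt.estimates)
        inv = np.argsort(perm)
        np.testing.assert_allclose(
            alt_d.total_genetic[inv], base_d.total_genetic, atol=1e-3
        )
        np.testing.assert_allclose(
            alt_d.correlations["D"][np.ix_(inv, inv)],
            base_d.correlations["D"], atol=1e-3,
        )


class TestCompare:
    def test_identical_models(self, small_de_data):
        prepped, _ = preprocess_dataset(small_de_data)
        spec = ModelSpec(traits=prepped.trait_names, components=frozenset({"D", "E"}))
        res = fit(prepped, spec, options=FitOptions(n_restarts=2, seed=0))
        out = compare(res, res)
        assert out["delta_minus2LL"] == 0.0 and out["p_value"] == 1.0

    def test_chi_square_quantile(self):
        from twinkit.biometric import FitResult
        dummy = ParamSet(
            ModelSpec(traits=("X",), components=frozenset({"E"})),
            {"E": {"*": np.array([[1.0]])}},
        )
        full = FitResult(dummy, 100.0, 5, True, 1, 0.0)
        nested = FitResult(dummy, 103.84, 4, True, 1, 0.0)
        out = compare(full, nested)
        assert out["p_value"] == pytest.approx(0.05, abs=0.001)

    def test_nested_with_more_params_rejected(self):
        from twinkit.biometric import FitResult
        dummy = ParamSet(
            ModelSpec(traits=("X",), components=frozenset({"E"})),
            {"E": {"*": np.array([[1.0]])}},
        )
        with pytest.raises(ValueError):
            compare(FitResult(dummy, 1.0, 3, True, 1, 0.0),
                    FitResult(dummy, 1.0, 4, True, 1, 0.0))

    def test_dropping_d_covariances_rejected_on_de_data(self, small_de_data):
        prepped, _ = preprocess_dataset(small_de_data)
        spec = ModelSpec(traits=prepped.trait_names,
                         components=frozenset({"A", "D", "E"}))
        full = fit(prepped, spec, options=FitOptions(n_restarts=3, seed=0))
        sub = fit(prepped, spec.drop_covariances("D"),
                  options=FitOptions(n_restarts=3, seed=0))
        assert compare(full, sub)["p_value"] < 0.05


class TestProfileInterval:
    def test_gaussian_mean_toy(self):
        """Quadratic likelihood: interval must equal mean +/- 1.96 SE."""
        n, sd = 50, 2.0
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, sd, size=n)
        xbar = x.mean()

        def m2ll(theta):
            return float(np.sum((x - theta[0]) ** 2) / sd**2)

        lo, hi, flags = profile_interval(
            m2ll, np.array([xbar]), lambda th: float(th[0]),
            level=0.95, initial_step=0.05,
        )
        se = sd / np.sqrt(n)
        assert lo == pytest.approx(xbar - 1.959964 * se, abs=2e-3)
        assert hi == pytest.approx(xbar + 1.959964 * se, abs=2e-3)
        assert not flags["lower_at_boundary"]

    def test_level_monotonicity(self):
        x = np.random.default_rng(1).normal(0, 1, size=40)

        def m2ll(theta):
            return float(np.sum((x - theta[0]) ** 2))

        args = (np.array([x.mean()]), lambda th: float(th[0]))
        lo95, hi95, _ = profile_interval(m2ll, *args, level=0.95)
        lo99, hi99, _ = profile_interval(m2ll, *args, level=0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_boundary_flagged(self):
        x = np.abs(np.random.default_rng(2).normal(0.1, 1, size=30))

        def m2ll(theta):
            return float(np.sum((x - theta[0]) ** 2))

        lo, hi, flags = profile_interval(
            m2ll, np.array([x.mean()]), lambda th: float(th[0]),
            bounds=[(0.0, 10.0)], target_limits=(0.0, 10.0),
        )
        # wide data, mean near zero: lower bound pinned at the limit
        assert lo >= 0.0
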