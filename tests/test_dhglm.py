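"""The double-hierarchical model: densities, conditionals, sampler, diagnostics."""

import dataclasses

import numpy as np
import pytest

from rapskill.dhglm import (
    DHGLMData,
    DHGLMSpec,
    _a_conditional,
    _beta_conditional,
    build_design,
    convergence_diagnostics,
    log_posterior,
    pseudo_p,
    run_dhglm_suite,
    sample_posterior,
)
from rapskill.preprocess import build_report

LOG_2PI = np.log(2 * np.pi)


def make_data(y, idx, Z, means=None, sds=None):
    Z = np.asarray(Z, dtype=float)
    n_ind = Z.shape[0]
    return DHGLMData(
        y=np.asarray(y, dtype=float),
        idx=np.asarray(idx, dtype=int),
        Z=Z,
        cov_means=np.zeros(3) if means is None else np.asarray(means),
        cov_sds=np.ones(3) if sds is None else np.asarray(sds),
        fight_ids=tuple(f"f{i}" for i in range(n_ind)),
        response="scaled_dist_B",
        poi_filter="whole",
        n_single_poi=0,
    )


def toy_data(seed=0, n_ind=3, n_per=4):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n_ind, 3))
    idx = np.repeat(np.arange(n_ind), n_per)
    y = rng.normal(5.0, 1.0, idx.size)
    return make_data(y, idx, Z)


def naive_log_posterior(params, data, spec):
    """Observation-by-observation oracle written with explicit loops."""
    X = np.column_stack([np.ones(data.n_ind), data.Z])
    beta, gamma = params["beta"], params.get("gamma")
    a = params.get("a", np.zeros(data.n_ind))
    b = params.get("b", np.zeros(data.n_ind))
    lp = 0.0
    for j in range(data.n_obs):
        i = data.idx[j]
        mu = X[i] @ beta + a[i]
        if gamma is not None:
            sd = np.exp(X[i] @ gamma + b[i])
        else:
            sd = spec.fixed_sigma
        lp += -0.5 * LOG_2PI - np.log(sd) - 0.5 * ((data.y[j] - mu) / sd) ** 2
    for coef in beta:
        lp += -0.5 * LOG_2PI - np.log(spec.tau_fix) - 0.5 * (coef / spec.tau_fix) ** 2
    if spec.include_random_effects:
        sa = params["sigma_a"]
        for ai in a:
            lp += -0.5 * LOG_2PI - np.log(sa) - 0.5 * (ai / sa) ** 2
        lp += np.log(2 / (np.pi * spec.hc_scale)) - np.log1p((sa / spec.hc_scale) ** 2)
    if spec.include_sd_model:
        sb = params["sigma_b"]
        for coef in gamma:
            lp += -0.5 * LOG_2PI - np.log(spec.tau_fix) - 0.5 * (coef / spec.tau_fix) ** 2
        for bi in b:
            lp += -0.5 * LOG_2PI - np.log(sb) - 0.5 * (bi / sb) ** 2
        lp += np.log(2 / (np.pi * spec.hc_scale)) - np.log1p((sb / spec.hc_scale) ** 2)
    return lp


class TestLogPosterior:
    def test_matches_direct_summation_oracle(self):
        data = toy_data()
        spec = DHGLMSpec()
        rng = np.random.default_rng(1)
        params = {
            "beta": rng.normal(size=4),
            "a": rng.normal(size=3),
            "sigma_a": 0.7,
            "gamma": rng.normal(scale=0.3, size=4),
            "b": rng.normal(scale=0.2, size=3),
            "sigma_b": 0.4,
        }
        assert log_posterior(params, data, spec) == pytest.approx(
            naive_log_posterior(params, data, spec), abs=1e-10
        )

    def test_single_standard_normal_observation(self):
        # one y=0 with sigma=1 and all effects zero adds exactly -log(2pi)/2
        spec = DHGLMSpec(
            include_random_effects=False, include_sd_model=False, fixed_sigma=1.0
        )
        Z = np.array([[0.1, -0.2, 0.3], [-0.1, 0.2, -0.3]])
        with_obs = make_data([0.0], [0], Z)
        no_obs = make_data([], np.empty(0, dtype=int), Z)
        params = {"beta": np.zeros(4)}
        delta = log_posterior(params, with_obs, spec) - log_posterior(
            params, no_obs, spec
        )
        assert delta == pytest.approx(-0.5 * LOG_2PI, abs=1e-12)

    def test_location_equivariance(self):
        # shifting y and the intercept together changes only the prior term
        data = toy_data(seed=2)
        spec = DHGLMSpec()
        params = {
            "beta": np.array([5.0, 0.2, -0.1, 0.05]),
            "a": np.zeros(3),
            "sigma_a": 1.0,
            "gamma": np.array([0.1, 0.0, 0.0, 0.0]),
            "b": np.zeros(3),
            "sigma_b": 0.3,
        }
        c = 2.5
        shifted = dict(params, beta=params["beta"] + np.array([c, 0, 0, 0]))
        shifted_data = make_data(data.y + c, data.idx, data.Z)
        prior = lambda b0: -0.5 * (b0 / spec.tau_fix) ** 2  # noqa: E731
        expected_delta = prior(5.0 + c) - prior(5.0)
        delta = log_posterior(shifted, shifted_data, spec) - log_posterior(
            params, data, spec
        )
        assert delta == pytest.approx(expected_delta, abs=1e-10)

    def test_nonfinite_input_rejected(self):
        data = toy_data()
        with pytest.raises(ValueError):
            log_posterior({"beta": np.array([np.nan, 0, 0, 0])}, data, DHGLMSpec())


class TestGibbsConditionals:
    def test_match_observation_level_algebra(self):
        # two individuals, explicit per-observation normal-normal algebra
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(2, 3))
        X = np.column_stack([np.ones(2), Z])
        idx = np.array([0, 0, 0, 1, 1])
        y = rng.normal(5, 1, 5)
        data = make_data(y, idx, Z)
        n_i, sum_y, _ = data.suffstats()
        w = np.array([0.8, 1.3])
        a = np.array([0.2, -0.4])
        tau = 10.0
        mean, cov = _beta_conditional(X, n_i, sum_y, w, a, tau)
        Xo = X[idx]
        Wo = np.diag(w[idx])
        prec_o = Xo.T @ Wo @ Xo + np.eye(4) / tau**2
        mean_o = np.linalg.solve(prec_o, Xo.T @ Wo @ (y - a[idx]))
        assert np.allclose(cov, np.linalg.inv(prec_o), atol=1e-8)
        assert np.allclose(mean, mean_o, atol=1e-8)

        beta = rng.normal(size=4)
        sigma_a = 0.6
        mean_a, var_a = _a_conditional(X, n_i, sum_y, w, beta, sigma_a)
        for i in range(2):
            resid = y[idx == i] - X[i] @ beta
            prec_i = w[i] * (idx == i).sum() + 1 / sigma_a**2
            assert var_a[i] == pytest.approx(1 / prec_i, abs=1e-10)
            assert mean_a[i] == pytest.approx(w[i] * resid.sum() / prec_i, abs=1e-8)


class TestPseudoP:
    def test_half_positive_gives_one(self):
        draws = np.concatenate([np.ones(500), -np.ones(500)])
        assert pseudo_p(draws) == 1.0

    def test_point_0975_positive_gives_0_05(self):
        draws = np.concatenate([np.ones(975), -np.ones(25)])
        assert pseudo_p(draws) == pytest.approx(0.05)

    def test_floor_at_two_over_n(self):
        assert pseudo_p(np.ones(1000)) == pytest.approx(0.002)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(0.3, 1.0, 4000)
        assert pseudo_p(draws) == pytest.approx(pseudo_p(-draws))

    def test_monotone_in_shift(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 4000)
        ps = [pseudo_p(base + shift) for shift in (0.0, 0.5, 1.0, 2.0)]
        assert ps == sorted(ps, reverse=True)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            pseudo_p(np.ones(50))


class TestConvergenceDiagnostics:
    def test_iid_chains_look_converged(self):
        rng = np.random.default_rng(10)
        chains = rng.standard_normal((4, 2000))
        rhat, ess = convergence_diagnostics(chains)
        assert 0.99 <= rhat <= 1.01
        assert ess > 0.75 * chains.size

    def test_duplicated_chains_have_unit_rhat(self):
        rng = np.random.default_rng(11)
        one = rng.standard_normal(1000)
        rhat, _ = convergence_diagnostics(np.stack([one, one]))
        assert rhat == pytest.approx(1.0, abs=0.02)

    def test_disjoint_constant_chains_flagged(self):
        chains = np.stack([np.zeros(100), np.ones(100)])
        rhat, ess = convergence_diagnostics(chains)
        assert np.isinf(rhat) and ess == 0.0

    def test_against_arviz_cross_check(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(12)
        # mildly autocorrelated chains via AR(1)
        chains = np.empty((4, 3000))
        for c in range(4):
            e = rng.standard_normal(3000)
            x = np.empty(3000)
            x[0] = e[0]
            for t in range(1, 3000):
                x[t] = 0.5 * x[t - 1] + e[t]
            chains[c] = x
        rhat, ess = convergence_diagnostics(chains)
        ref_rhat = float(az.rhat(chains))
        ref_ess = float(az.ess(chains))
        assert rhat == pytest.approx(ref_rhat, abs=0.02)
        assert ess == pytest.approx(ref_ess, rel=0.25)


class TestBuildDesign:
    def test_one_row_per_poi_and_standardized_columns(
        self, small_dataset, small_report
    ):
        spec = DHGLMSpec()
        data = build_design(small_dataset.fights, small_report.scaled_pois, spec)
        assert data.n_obs == len(small_report.scaled_pois)
        assert data.n_ind == len(small_report.zone_summaries)
        assert np.allclose(data.Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(data.Z.std(axis=0), 1.0, atol=1e-12)
        assert data.idx.max() == data.n_ind - 1

    def test_zone1_filter_drops_exactly_other_zones(
        self, small_dataset, small_report
    ):
        spec = dataclasses.replace(DHGLMSpec(), poi_filter="zone1")
        data = build_design(small_dataset.fights, small_report.scaled_pois, spec)
        n_zone1 = sum(1 for p in small_report.scaled_pois if p.zone == "1")
        assert data.n_obs == n_zone1

    def test_no_pois_after_filter_rejected(self, small_dataset, small_report):
        only_other = [
            dataclasses.replace(p, zone="other") for p in small_report.scaled_pois
        ]
        spec = dataclasses.replace(DHGLMSpec(), poi_filter="zone1")
        with pytest.raises(ValueError, match="no POIs"):
            build_design(small_dataset.fights, only_other, spec)

    def test_single_individual_rejected(self, small_dataset, small_report):
        fid = small_report.scaled_pois[0].fight_id
        subset = [p for p in small_report.scaled_pois if p.fight_id == fid]
        with pytest.raises(ValueError, match="one individual"):
            build_design(small_dataset.fights, subset, DHGLMSpec())


@pytest.mark.usefixtures("quiet_convergence")
class TestSampler:
    def test_prior_only_run_recovers_priors(self):
        # zero observations: the sampler must reproduce its own priors
        Z = np.array([[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        data = make_data([], np.empty(0, dtype=int), Z)
        spec = DHGLMSpec(
            n_chains=2, n_iter=4000, burn_in=1000, thin=1, seed=21
        )
        post = sample_posterior(data, spec)
        b = post.draws["mean.rwd"]
        assert abs(b.mean()) < 1.0  # prior mean 0, prior sd 10
        assert 8.5 < b.std() < 11.5
        # half-Cauchy(2.5) median is 2.5
        med = np.median(post.draws["sigma_a"])
        assert 1.5 < med < 4.0

    def test_input_order_permutation_leaves_results_identical(
        self, small_dataset, small_report
    ):
        spec = DHGLMSpec(n_chains=2, n_iter=600, burn_in=200, thin=2, seed=3)
        data1 = build_design(small_dataset.fights, small_report.scaled_pois, spec)
        rng = np.random.default_rng(0)
        fights = list(small_dataset.fights)
        pois = list(small_report.scaled_pois)
        rng.shuffle(fights)
        rng.shuffle(pois)
        data2 = build_design(fights, pois, spec)
        p1 = sample_posterior(data1, spec)
        p2 = sample_posterior(data2, spec)
        # identical up to float summation order in the sufficient statistics
        for name in p1.summaries:
            for key, v1 in p1.summaries[name].items():
                assert p2.summaries[name][key] == pytest.approx(v1, rel=1e-9, nan_ok=True)

    def test_same_seed_reproducible(self, small_dataset, small_report):
        spec = DHGLMSpec(n_chains=2, n_iter=500, burn_in=100, thin=2, seed=5)
        data = build_design(small_dataset.fights, small_report.scaled_pois, spec)
        p1 = sample_posterior(data, spec)
        p2 = sample_posterior(data, spec)
        assert all(
            np.array_equal(p1.draws[k], p2.draws[k]) for k in p1.draws
        )

    def test_suite_structure(self, small_dataset, small_report):
        spec = DHGLMSpec(n_chains=2, n_iter=400, burn_in=100, thin=1, seed=1)
        suite = run_dhglm_suite(small_dataset.fights, small_report.scaled_pois, spec)
        assert set(suite) == {
            "dist_A_whole",
            "dist_B_whole",
            "dist_A_zone1",
            "dist_B_zone1",
        }
        effect_rows = [
            name
            for post in suite.values()
            for name in post.summaries
            if name.split(".")[-1] in ("rwd", "outcome", "vigour")
        ]
        assert len(effect_rows) == 24  # 4 runs x 2 submodels x 3 effects
        for post in suite.values():
            assert {"sigma_a", "sigma_b", "mean.intercept", "sd.intercept"} <= set(
                post.summaries
            )
            d = post.to_json_dict()
            assert d["meta"]["n_ind"] == post.n_ind

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DHGLMSpec(burn_in=500, n_iter=400).validate()
        with pytest.raises(ValueError):
            DHGLMSpec(n_chains=1).validate()
        with pytest.raises(ValueError):
            DHGLMSpec(include_sd_model=False).validate()
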