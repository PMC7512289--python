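"""Product-of-experts fusion, the marginalized coupling kernel, entropy and
initial-state terms, and the collapsed dynamics bound."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vcgpdm import dynamics as dyn
from vcgpdm import kernels as kr
from vcgpdm.variational import InducingSet
from oracles import mc_dynamics_ell, product_of_gaussians_on_grid


def build_experts(raw, jitter=1e-6):
    out = []
    for r in raw:
        bel = kr.GaussianBelief(r["ar_mu"], r["ar_var"])
        Kuu = kr.gram(r["kernel"], r["Z"]) \
            + jitter * r["kernel"].variance * np.eye(r["Z"].shape[0])
        out.append({"Kuu": Kuu, "Psi1": kr.psi1(r["kernel"], r["Z"], bel),
                    "Phi": kr.psi2(r["kernel"], r["Z"], bel),
                    "psi0": kr.psi0(r["kernel"], bel), "alpha": r["alpha"]})
    return out


def random_raw(seed, M=2, Td=7, Qin=2, P=3):
    rng = np.random.default_rng(seed)
    raw = []
    for i in range(M):
        raw.append({
            "kernel": kr.ArdSeKernel(rng.uniform(0.5, 2.0, Qin), 1.0),
            "Z": rng.normal(0, 1, (P + i, Qin)),
            "ar_mu": rng.normal(0, 1, (Td, Qin)),
            "ar_var": rng.uniform(0.02, 0.3, (Td, Qin)),
            "alpha": float(rng.uniform(0.4, 2.0)),
        })
    tmu = rng.normal(0, 1, (Td, 2))
    tvar = rng.uniform(0.02, 0.3, (Td, 2))
    return tmu, tvar, raw


class TestPoECombine:
    def test_single_expert_identity(self):
        m, v = dyn.poe_combine([np.array([1.5, -2.0])], [0.7])
        assert np.allclose(m, [1.5, -2.0]) and v == pytest.approx(0.7)

    def test_equal_precision_average(self):
        m, v = dyn.poe_combine([np.array([0.0]), np.array([2.0])], [1.0, 1.0])
        assert m[0] == pytest.approx(1.0) and v == pytest.approx(0.5)

    def test_matches_grid_density_product(self):
        rng = np.random.default_rng(3)
        means = [float(m) for m in rng.normal(0, 1, 3)]
        variances = [float(v) for v in rng.uniform(0.3, 2.0, 3)]
        grid = np.linspace(-12, 12, 20001)
        _, gmean, gvar = product_of_gaussians_on_grid(means, variances, grid)
        m, v = dyn.poe_combine([np.array([x]) for x in means], variances)
        assert m[0] == pytest.approx(gmean, abs=1e-6)
        assert v == pytest.approx(gvar, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_combined_variance_below_every_expert(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 5))
        variances = rng.uniform(0.1, 5.0, n).tolist()
        means = [rng.normal(0, 1, 2) for _ in range(n)]
        _, v = dyn.poe_combine(means, variances)
        assert v <= min(variances) + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            dyn.poe_combine([], [])
        with pytest.raises(ValueError):
            dyn.poe_combine([np.zeros(2)], [0.0])


class TestMarginalizedKernel:
    def _coupling(self, alpha, Qin=2, seed=0):
        rng = np.random.default_rng(seed)
        return dyn.CouplingGP(
            source=0, target=0,
            kernel=kr.ArdSeKernel(rng.uniform(0.5, 2.0, Qin), 1.0),
            inducing=InducingSet(rng.normal(0, 1, (3, Qin))), alpha=alpha)

    def test_single_part_reduces_to_own_kernel(self):
        c = self._coupling(0.7)
        X = np.random.default_rng(1).normal(0, 1, (4, 2))
        K = dyn.marginalized_kernel([c], [X])
        assert np.allclose(K, kr.gram(c.kernel, X))

    def test_two_equal_couplings_quarter_sum(self):
        c1, c2 = self._coupling(1.0, seed=1), self._coupling(1.0, seed=2)
        rng = np.random.default_rng(3)
        X1, X2 = rng.normal(0, 1, (4, 2)), rng.normal(0, 1, (4, 2))
        K = dyn.marginalized_kernel([c1, c2], [X1, X2])
        expect = (kr.gram(c1.kernel, X1) + kr.gram(c2.kernel, X2)) / 4.0
        assert np.allclose(K, expect)

    def test_matches_brute_force_poe_marginalization(self):
        """Covariance of the PoE mean prediction with coupling-function values
        marginalized under their GP priors, on a 3-point instance."""
        rng = np.random.default_rng(4)
        c1, c2 = self._coupling(0.6, seed=5), self._coupling(1.7, seed=6)
        X1, X2 = rng.normal(0, 1, (3, 2)), rng.normal(0, 1, (3, 2))
        # stack f = (f1(X1), f2(X2)) ~ N(0, blockdiag(K1, K2)); the PoE mean
        # is the linear map  m = a_j [f1/a1, f2/a2]
        K1 = kr.gram(c1.kernel, X1)
        K2 = kr.gram(c2.kernel, X2)
        Sigma = np.block([[K1, np.zeros((3, 3))], [np.zeros((3, 3)), K2]])
        aj = 1.0 / (1.0 / c1.alpha + 1.0 / c2.alpha)
        L = aj * np.hstack([np.eye(3) / c1.alpha, np.eye(3) / c2.alpha])
        brute = L @ Sigma @ L.T
        K = dyn.marginalized_kernel([c1, c2], [X1, X2])
        assert np.allclose(K, brute)

    def test_inconsistent_targets_rejected(self):
        c1 = self._coupling(1.0)
        c2 = self._coupling(1.0)
        c2.target = 1
        with pytest.raises(ValueError):
            dyn.marginalized_kernel([c1, c2], [np.zeros((2, 2))] * 2)


class TestEntropyAndInitialState:
    def test_scalar_gaussian_entropy(self):
        assert dyn.entropy(np.zeros((1, 1)), np.ones((1, 1))) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e))

    def test_factorizes_over_dimensions(self):
        rng = np.random.default_rng(0)
        var = rng.uniform(0.1, 2.0, (4, 3))
        total = dyn.entropy(np.zeros_like(var), var)
        parts = sum(dyn.entropy(np.zeros((4, 1)), var[:, [q]]) for q in range(3))
        assert total == pytest.approx(parts)

    def test_entropy_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        var = rng.uniform(0.2, 1.5, (2, 2))
        x = np.sqrt(var) * rng.standard_normal((200_000, 2, 2))
        logq = np.sum(-0.5 * x ** 2 / var - 0.5 * np.log(2 * np.pi * var),
                      axis=(1, 2))
        mc = -logq.mean()
        se = logq.std() / np.sqrt(logq.size)
        assert abs(dyn.entropy(np.zeros_like(var), var) - mc) < 3 * se

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dyn.entropy(np.zeros((1, 1)), np.zeros((1, 1)))

    def test_initial_state_standard_normal_case(self):
        val = dyn.initial_state_term(np.zeros((1, 1)), np.ones((1, 1)))
        assert val == pytest.approx(-0.5 * (1 + np.log(2 * np.pi)))

    def test_initial_state_decreases_with_mean_magnitude(self):
        vals = [dyn.initial_state_term(np.full((1, 2), m), 0.3 * np.ones((1, 2)))
                for m in (0.0, 0.5, 1.5, 3.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_initial_state_matches_monte_carlo(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(0, 1, (2, 2))
        var = rng.uniform(0.1, 0.8, (2, 2))
        x = mu + np.sqrt(var) * rng.standard_normal((200_000, 2, 2))
        logp = np.sum(-0.5 * x ** 2 - 0.5 * np.log(2 * np.pi), axis=(1, 2))
        se = logp.std() / np.sqrt(logp.size)
        assert abs(dyn.initial_state_term(mu, var) - logp.mean()) < 3 * se


class TestDynamicsBound:
    def test_collapsed_equals_ell_minus_kl_at_optimum(self):
        tmu, tvar, raw = random_raw(0)
        term = dyn.DynamicsTerm(tmu, tvar, build_experts(raw))
        post = term.optimal_posterior()
        val = term.expected_loglik(post.mean, post.covariance) \
            - term.kl_u(post.mean, post.covariance)
        assert val == pytest.approx(term.value, rel=1e-10)
        # any other q(u) gives a smaller free energy
        worse = term.expected_loglik(post.mean + 0.5, post.covariance) \
            - term.kl_u(post.mean + 0.5, post.covariance)
        assert worse < term.value

    def test_expected_loglik_matches_monte_carlo(self):
        tmu, tvar, raw = random_raw(1, M=2, Td=6)
        experts = build_experts(raw)
        term = dyn.DynamicsTerm(tmu, tvar, experts)
        post = term.optimal_posterior()
        for e, r in zip(experts, raw):
            cf = kr.jittered_cholesky(e["Kuu"], 1e-12, 1e-4)
            r["G"] = kr.chol_inv(cf)
        mc, se = mc_dynamics_ell(
            tmu, tvar, raw, post.mean, post.covariance,
            [r["alpha"] for r in raw], 50_000, np.random.default_rng(0))
        analytic = term.expected_loglik(post.mean, post.covariance)
        assert abs(analytic - mc) < 3 * se

    def test_single_expert_equals_dedicated_vgpdm_path(self):
        tmu, tvar, raw = random_raw(2, M=1)
        e = build_experts(raw)
        term = dyn.DynamicsTerm(tmu, tvar, e)
        other = dyn.vgpdm_dynamics_bound(tmu, tvar, e[0]["Kuu"], e[0]["Psi1"],
                                         e[0]["Phi"], e[0]["psi0"],
                                         e[0]["alpha"])
        assert term.value == other

    def test_huge_alpha_removes_expert_influence(self):
        tmu, tvar, raw = random_raw(3, M=2)
        e = build_experts(raw)
        e[1]["alpha"] = 1e8
        coupled = dyn.DynamicsTerm(tmu, tvar, e).value
        alone = dyn.vgpdm_dynamics_bound(tmu, tvar, e[0]["Kuu"], e[0]["Psi1"],
                                         e[0]["Phi"], e[0]["psi0"],
                                         e[0]["alpha"])
        assert coupled == pytest.approx(alone, rel=1e-4)

    def test_gradients_match_finite_differences(self):
        import copy

        from conftest import finite_difference

        tmu, tvar, raw = random_raw(4, M=2, Td=5)
        term = dyn.DynamicsTerm(tmu, tvar, build_experts(raw))
        g = term.grads()
        value = lambda tm, tv, rw: dyn.DynamicsTerm(tm, tv, build_experts(rw)).value
        assert np.allclose(g["target_mean"],
                           finite_difference(lambda m: value(m, tvar, raw), tmu),
                           atol=1e-6)
        assert np.allclose(g["target_var"],
                           finite_difference(lambda v: value(tmu, v, raw), tvar),
                           atol=1e-6)
        for i in range(2):
            def f_alpha(a):
                rw = copy.deepcopy(raw)
                rw[i]["alpha"] = float(a[0])
                return value(tmu, tvar, rw)
            fd = finite_difference(f_alpha, np.array([raw[i]["alpha"]]))
            assert g["alphas"][i] == pytest.approx(fd[0], rel=1e-5, abs=1e-7)
            for name in ("Z", "ar_mu", "ar_var"):
                def f(x, i=i, name=name):
                    rw = copy.deepcopy(raw)
                    rw[i][name] = x
                    return value(tmu, tvar, rw)
                fd = finite_difference(f, raw[i][name])
                # chain the psi-statistic backward pass by hand
                c = raw[i]
                bel = kr.GaussianBelief(c["ar_mu"], c["ar_var"])
                d1 = kr.psi1_backward(c["kernel"], c["Z"], bel, g["Psi1"][i])
                d2 = kr.psi2_backward(c["kernel"], c["Z"], bel, g["Phi"][i])
                gA, gB, _, _ = kr.gram_backward(c["kernel"], c["Z"], c["Z"],
                                                g["Kuu"][i])
                got = {"ar_mu": d1[0] + d2[0], "ar_var": d1[1] + d2[1],
                       "Z": d1[2] + d2[2] + gA + gB}[name]
                assert np.allclose(got, fd, atol=2e-5), (i, name)

    def test_bound_invariant_to_expert_relabeling(self):
        tmu, tvar, raw = random_raw(5, M=3)
        a = dyn.DynamicsTerm(tmu, tvar, build_experts(raw)).value
        b = dyn.DynamicsTerm(tmu, tvar, build_experts(raw[::-1])).value
        assert a == pytest.approx(b, rel=1e-10)
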