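import numpy as np
import pytest
from scipy import stats

from fidlme import (
    ChainConfig,
    DegenerateFitError,
    ParamState,
    conditional_u_moments,
    gibbs_chain,
    log_fiducial_density,
    mh_reference_sampler,
    sample_sigma2_trimmed,
    sample_theta,
    sample_u,
)
from fidlme.model import projection_quantities, stack_xu
from fidlme.sampler import UConditionalMoments, effective_sample_size


class _FixedUniform:
    """Generator stand-in returning a fixed uniform value."""

    def __init__(self, value):
        self.value = value

    def uniform(self):
        return self.value


class _ZeroNormal:
    def standard_normal(self, size):
        return np.zeros(size)


class TestTrimmedSigma2:
    def test_uniform_one_hits_floor(self):
        # F^{-1}(F(rss/c0) * 1) = rss/c0, so the draw is exactly c0
        out = sample_sigma2_trimmed(rss=3.0, dof=7, c0=0.25, rng=_FixedUniform(1.0))
        assert out == pytest.approx(0.25)

    def test_mean_matches_inverse_chi_square(self):
        # untrimmed limit: E[rss/chi2_dof] = rss/(dof-2)
        rng = np.random.default_rng(42)
        draws = np.array(
            [sample_sigma2_trimmed(10.0, 5, 1e-12, rng) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(10.0 / 3.0, rel=0.05)

    def test_support_floor_exact(self):
        rng = np.random.default_rng(0)
        draws = [sample_sigma2_trimmed(0.05, 3, 0.01, rng) for _ in range(5000)]
        assert min(draws) >= 0.01

    def test_untrimmed_limit_ks(self):
        # c0 -> 0: law converges to rss/chi2_dof
        rss, dof = 4.0, 9
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_sigma2_trimmed(rss, dof, 1e-12, rng) for _ in range(10_000)]
        )
        cdf = lambda t: stats.chi2.sf(rss / t, dof)
        stat = stats.kstest(draws, cdf).statistic
        assert stat < 1.63 / np.sqrt(10_000)  # 1% critical value

    def test_degenerate_and_config_errors(self):
        with pytest.raises(DegenerateFitError):
            sample_sigma2_trimmed(0.0, 5, 0.01, _FixedUniform(0.5))
        with pytest.raises(ValueError):
            sample_sigma2_trimmed(1.0, 0, 0.01, _FixedUniform(0.5))


class TestThetaDraw:
    def test_zero_noise_returns_gls(self):
        rng = np.random.default_rng(1)
        xu = rng.standard_normal((9, 3))
        quant = projection_quantities(xu, rng.standard_normal(9))
        draw = sample_theta(quant, 2.0, _ZeroNormal())
        assert np.allclose(draw, quant.gls)

    def test_gaussian_covariance(self):
        rng = np.random.default_rng(2)
        xu = rng.standard_normal((12, 2))
        quant = projection_quantities(xu, rng.standard_normal(12))
        draws = np.array([sample_theta(quant, 4.0, rng) for _ in range(40_000)])
        target = 4.0 * np.linalg.inv(xu.T @ xu)
        assert np.allclose(draws.mean(axis=0), quant.gls, atol=0.02)
        assert np.allclose(np.cov(draws.T), target, atol=0.05 * np.abs(target).max())

    def test_orthonormal_identity_covariance(self):
        rng = np.random.default_rng(3)
        xu, _ = np.linalg.qr(rng.standard_normal((10, 3)))
        y = rng.standard_normal(10)
        quant = projection_quantities(xu, y)
        draws = np.array([sample_theta(quant, 1.0, rng) for _ in range(30_000)])
        assert np.allclose(draws.mean(axis=0), xu.T @ y, atol=0.02)
        assert np.allclose(np.cov(draws.T), np.eye(3), atol=0.05)


class TestUConditional:
    def test_null_delta_gives_standard_moments(self, tiny_design):
        eta = ParamState(beta=[0.5], delta=[0.0], sigma2=1.3)
        mom = conditional_u_moments(tiny_design, eta)
        assert np.allclose(mom.mean, 0.0)
        assert np.allclose(mom.var, np.eye(1)[None, :, :].repeat(3, axis=0))

    def test_scalar_closed_form(self, design_factory):
        # q=1, n_i=1, z=1, delta=1, sigma2=1, residual=2:
        # mean = |d| z r / (s2 + z^2 d^2) = 1, var = s2/(s2 + z^2 d^2) = 0.5
        d = design_factory(
            y=np.array([2.0, 0.0, 0.0]), X=np.zeros((3, 1)),
            Z=np.ones((3, 1)), sizes=[1, 1, 1],
        )
        mom = conditional_u_moments(d, ParamState(beta=[0.0], delta=[1.0], sigma2=1.0))
        assert mom.mean[0, 0] == pytest.approx(1.0)
        assert mom.var[0, 0, 0] == pytest.approx(0.5)

    def test_large_noise_limit(self, tiny_design):
        eta = ParamState(beta=[0.0], delta=[1.0], sigma2=1e10)
        mom = conditional_u_moments(tiny_design, eta)
        assert np.allclose(mom.mean, 0.0, atol=1e-4)
        assert np.allclose(mom.var, np.eye(1), atol=1e-4)

    def test_sign_of_delta_irrelevant(self, example2_design):
        design, _ = example2_design
        a = conditional_u_moments(design, ParamState([0.5], [0.3, -1.2], 0.6))
        b = conditional_u_moments(design, ParamState([0.5], [0.3, 1.2], 0.6))
        assert np.allclose(a.mean, b.mean) and np.allclose(a.var, b.var)

    @pytest.mark.parametrize("seed", range(6))
    def test_var_eigenvalues_bounded(self, seed, example2_design):
        design, _ = example2_design
        rng = np.random.default_rng(seed)
        eta = ParamState(
            beta=rng.standard_normal(1), delta=rng.standard_normal(2) * 2,
            sigma2=float(rng.uniform(0.05, 4.0)),
        )
        mom = conditional_u_moments(design, eta)
        eigs = np.linalg.eigvalsh(mom.var)
        assert eigs.min() > -1e-10 and eigs.max() < 1.0 + 1e-10

    def test_balanced_matches_per_subject_loop(self, example2_design):
        design, _ = example2_design
        eta = ParamState([0.7], [0.4, 0.9], 0.5)
        mom = conditional_u_moments(design, eta)
        for i in range(design.m):
            yi, xi, zi = design.block(i)
            d = np.diag(eta.delta**2)
            dh = np.diag(np.abs(eta.delta))
            vi = eta.sigma2 * np.eye(len(yi)) + zi @ d @ zi.T
            mean = dh @ zi.T @ np.linalg.solve(vi, yi - xi @ eta.beta)
            var = np.eye(2) - dh @ zi.T @ np.linalg.solve(vi, zi @ dh)
            assert np.allclose(mom.mean[i], mean, atol=1e-12)
            assert np.allclose(mom.var[i], var, atol=1e-12)


class TestSampleU:
    def test_degenerate_variance_returns_mean(self):
        mom = UConditionalMoments(
            mean=np.array([[1.5, -2.0]]), var=np.zeros((1, 2, 2))
        )
        u = sample_u(mom, np.random.default_rng(0))
        assert np.allclose(u, mom.mean)

    def test_moments_recovered(self):
        cov = np.array([[1.0, 0.4], [0.4, 0.5]])
        mom = UConditionalMoments(mean=np.array([[0.3, -0.7]]), var=cov[None])
        rng = np.random.default_rng(5)
        draws = np.array([sample_u(mom, rng)[0] for _ in range(30_000)])
        assert np.allclose(draws.mean(axis=0), mom.mean[0], atol=0.02)
        assert np.allclose(np.cov(draws.T), cov, atol=0.03)


class TestGibbsChain:
    def test_deterministic_given_seed(self, tiny_design, short_config):
        a = gibbs_chain(tiny_design, short_config)
        b = gibbs_chain(tiny_design, short_config)
        assert np.array_equal(a.draws, b.draws)

    def test_sigma2_respects_floor_and_shape(self, example2_design, short_config):
        design, _ = example2_design
        s = gibbs_chain(design, short_config)
        assert s.n_draws == short_config.n_draws
        assert s.draws.shape == (300, design.p + design.q + 1)
        assert np.all(np.isfinite(s.draws))
        assert s.column("sigma2").min() >= short_config.c0

    def test_default_protocol_draw_count(self):
        assert ChainConfig().n_draws == 1900
        assert ChainConfig(chain_length=6300).n_draws == 2000

    def test_compiled_and_reference_paths_agree(self, example2_design):
        design, _ = example2_design
        cfg = ChainConfig(chain_length=120, warmup=20, thin=1, seed=3)
        fast = gibbs_chain(design, cfg, use_compiled=True)
        slow = gibbs_chain(design, cfg, use_compiled=False)
        assert np.allclose(fast.draws, slow.draws, atol=1e-9)

    def test_unbalanced_design_runs(self, design_factory, short_config):
        rng = np.random.default_rng(9)
        sizes = [3, 2, 4, 2]
        n = sum(sizes)
        z = rng.standard_normal((n, 1))
        d = design_factory(
            y=rng.standard_normal(n), X=np.ones((n, 1)), Z=z, sizes=sizes
        )
        s = gibbs_chain(d, short_config)
        assert np.all(np.isfinite(s.draws))
        assert np.array_equal(s.draws, gibbs_chain(d, short_config).draws)


class TestLogFiducialDensity:
    def test_null_delta_reduces_to_iid_loglik(self, tiny_design):
        beta, sigma2 = np.array([0.4]), 0.9
        eta = ParamState(beta, [0.0], sigma2)
        got = log_fiducial_density(tiny_design, eta)
        resid = tiny_design.y - tiny_design.X @ beta
        expect = stats.norm.logpdf(resid, scale=np.sqrt(sigma2)).sum() - np.log(sigma2)
        assert got == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_delta_sign_flip_symmetry_exact(self, seed, example2_design):
        design, _ = example2_design
        rng = np.random.default_rng(seed)
        beta = rng.standard_normal(1)
        delta = rng.standard_normal(2)
        s2 = float(rng.uniform(0.1, 2.0))
        base = log_fiducial_density(design, ParamState(beta, delta, s2))
        for flip in ([-1, 1], [1, -1], [-1, -1]):
            flipped = log_fiducial_density(design, ParamState(beta, delta * flip, s2))
            assert flipped == base  # exact: delta enters only through delta^2

    def test_matches_monte_carlo_u_integration(self, design_factory):
        # r_y(eta) = E_u[N(y; X_u theta, sigma2 I)] / sigma2 with u ~ N(0, I)
        rng = np.random.default_rng(12)
        sizes = [2, 2, 2]
        z = rng.standard_normal((6, 1))
        d = design_factory(
            y=rng.standard_normal(6) + 1.0, X=np.ones((6, 1)), Z=z, sizes=sizes
        )
        etas = [ParamState([0.8], [0.6], 0.5), ParamState([0.2], [1.1], 1.4)]

        def mc_log_ry(eta, n_mc=400_000):
            us = rng.standard_normal((n_mc, 3))
            mean = (d.X @ eta.beta)[None, :] + (z[:, 0] * eta.delta[0])[None, :] * us[
                :, d.group_index
            ]
            ll = stats.norm.logpdf(
                d.y[None, :], loc=mean, scale=np.sqrt(eta.sigma2)
            ).sum(axis=1)
            from scipy.special import logsumexp

            return logsumexp(ll) - np.log(n_mc) - np.log(eta.sigma2)

        diff_exact = log_fiducial_density(d, etas[0]) - log_fiducial_density(d, etas[1])
        diff_mc = mc_log_ry(etas[0]) - mc_log_ry(etas[1])
        assert diff_exact == pytest.approx(diff_mc, abs=0.05)


class TestMHReference:
    def test_deterministic(self, tiny_design):
        a = mh_reference_sampler(tiny_design, n_draws=200, seed=4, warmup=50)
        b = mh_reference_sampler(tiny_design, n_draws=200, seed=4, warmup=50)
        assert np.array_equal(a.draws, b.draws)
        assert 0.0 < a.meta["acceptance_rate"] < 1.0

    def test_delta_frozen_recovers_inverse_chi_square(self, example1_design):
        # with delta fixed at 0 the beta-integrated sigma2 marginal satisfies
        # rss0/sigma2 ~ chi2_{n-p}
        design, _ = example1_design
        mask = np.array([True, False, True])  # sample beta0 and log sigma2 only
        init = ParamState(beta=[0.0], delta=[0.0], sigma2=1.0)
        s = mh_reference_sampler(
            design, n_draws=4000, seed=8, step=0.45, warmup=3000, thin=15,
            init=init, sample_mask=mask,
        )
        assert np.all(s.column("delta0") == 0.0)
        beta_hat = np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        rss0 = float(np.sum((design.y - design.X @ beta_hat) ** 2))
        pulls = rss0 / s.column("sigma2")
        stat = stats.kstest(pulls, stats.chi2(design.n - design.p).cdf).statistic
        assert stat < 0.05  # thinned chain, generous 1%-level-style bound


def test_effective_sample_size_behaviour():
    rng = np.random.default_rng(0)
    iid = rng.standard_normal(4000)
    assert effective_sample_size(iid) > 2000
    slow = np.cumsum(rng.standard_normal(4000))  # random walk: tiny ESS
    assert effective_sample_size(slow) < 100
    assert effective_sample_size(np.ones(50)) == 50.0
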