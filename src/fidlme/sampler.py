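"""Gibbs sampler for the fiducial distribution of an LME.

Given the latent standardized effects U = u, the conditional fiducial
quantities are

    sigma^2 | u  =  y'(I - P_u)y / xi,              xi ~ chi^2_{n-p-q},
    theta   | u  =  (X_u'X_u)^{-1}X_u'y + sigma (X_u'X_u)^{-1/2} zeta,

with zeta ~ N(0, I_{p+q}); the sampler trims the chi-square so that
sigma^2 >= c0, preventing degeneracy when u nearly interpolates y.  The
latent effects are then refreshed from their Gaussian conditional given
eta = (beta, delta, sigma^2).  Sweeping sigma^2 -> theta -> U yields a
reversible chain whose stationary density is the fiducial density

    r_y(eta)  proportional to  p(y | eta) / sigma^2,

where p(y|eta) is the likelihood with U integrated out (per-subject
covariance sigma^2 I + z_i D z_i', D = diag(delta_j^2)).  A log evaluator
of r_y and a random-walk Metropolis sampler targeting it are provided as
independent cross-checks of the Gibbs chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaincinv

from . import _kernels
from .model import (
    DesignError,
    LMEDesign,
    ParamState,
    ProjectionQuantities,
    projection_quantities,
    stack_xu,
)

__all__ = [
    "ChainConfig",
    "FiducialSample",
    "UConditionalMoments",
    "DegenerateFitError",
    "SamplerError",
    "sample_sigma2_trimmed",
    "sample_theta",
    "conditional_u_moments",
    "sample_u",
    "gibbs_chain",
    "log_fiducial_density",
    "mh_reference_sampler",
    "effective_sample_size",
]

logger = logging.getLogger(__name__)

_MAX_DEGENERATE_RETRIES = 10


class SamplerError(RuntimeError):
    """Raised when the chain cannot proceed (repeated degenerate fits)."""


class DegenerateFitError(SamplerError):
    """y lies (numerically) in the span of X_u: the conditional fit is exact."""


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings.

    Defaults follow the common single-chain protocol for this sampler:
    6000 sweeps, 300 discarded as warmup, every 3rd retained, and the
    trimming floor c0 = 0.01 on sigma^2.
    """

    chain_length: int = 6000
    warmup: int = 300
    thin: int = 3
    c0: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.warmup < self.chain_length):
            raise ValueError("need 0 <= warmup < chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.n_draws < 1:
            raise ValueError("settings leave no retained draws")

    @property
    def n_draws(self) -> int:
        """Retained sample size N = floor((chain_length - warmup)/thin)."""
        return (self.chain_length - self.warmup) // self.thin


@dataclass(frozen=True)
class FiducialSample:
    """Retained draws of eta = (beta, delta, sigma^2), one row per draw.

    ``delta`` columns are signed; sigma^2 is bounded below by c0 whenever
    the draws come from the trimmed Gibbs sampler.
    """

    draws: np.ndarray            # (N, p+q+1)
    columns: tuple               # beta0..beta{p-1}, delta0..delta{q-1}, sigma2
    config: ChainConfig
    dims: dict                   # m, n, p, q
    fixed_names: tuple = ()
    random_names: tuple = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return int(self.draws.shape[0])

    @property
    def p(self) -> int:
        return int(self.dims["p"])

    @property
    def q(self) -> int:
        return int(self.dims["q"])

    def column(self, name: str) -> np.ndarray:
        """Draws for one named column; ``"sigma"`` gives sqrt(sigma2)."""
        if name == "sigma":
            return np.sqrt(self.column("sigma2"))
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(f"no column {name!r}; have {self.columns}") from None
        return self.draws[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.columns))


@dataclass(frozen=True)
class UConditionalMoments:
    """Per-subject Gaussian moments of U_i given eta and y.

    ``var`` is I_q minus a PSD form bounded by I_q, so its eigenvalues lie
    in [0, 1] up to roundoff.
    """

    mean: np.ndarray   # (m, q)
    var: np.ndarray    # (m, q, q)


def _chi2_cdf(x, k):
    return gammainc(k / 2.0, np.asarray(x) / 2.0)


def _chi2_ppf(prob, k):
    return 2.0 * gammaincinv(k / 2.0, np.asarray(prob))


def sample_sigma2_trimmed(rss: float, dof: int, c0: float, rng: np.random.Generator) -> float:
    """Draw sigma^2 from the trimmed conditional fiducial quantity.

    The untrimmed quantity is rss/xi with xi ~ chi^2_dof; trimming caps xi
    at rss/c0 (inverse-CDF construction), so the draw is always >= c0 and
    converges in law to the untrimmed draw as c0 -> 0.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    if not (rss > 0):
        raise DegenerateFitError("rss is zero: y interpolated by X_u")
    cap = float(_chi2_cdf(rss / c0, dof))
    if cap <= 0.0:
        # rss so far below c0 that the truncated chi-square has no float mass
        raise DegenerateFitError("rss is numerically indistinguishable from zero")
    xi = float(_chi2_ppf(cap * rng.uniform(), dof))
    if xi <= 0.0:
        return np.inf  # uniform draw hit 0 exactly; measure-zero guard
    return max(rss / xi, c0)


def sample_theta(
    quantities: ProjectionQuantities, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw theta = (beta, delta) given u and sigma^2.

    Returns gls + sqrt(sigma2) * S zeta with S S' = (X_u'X_u)^{-1} and
    zeta standard normal.
    """
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise ValueError("sigma2 must be finite and positive")
    s = quantities.chol_inv
    zeta = rng.standard_normal(s.shape[1])
    draw = quantities.gls + np.sqrt(sigma2) * (s @ zeta)
    if not np.all(np.isfinite(draw)):
        raise SamplerError("non-finite theta draw")
    return draw


def conditional_u_moments(design: LMEDesign, eta: ParamState) -> UConditionalMoments:
    """Gaussian conditional moments of each U_i given eta and y.

    mean_i = D^{1/2} z_i' V_i^{-1} (y_i - x_i beta),
    var_i  = I_q - D^{1/2} z_i' V_i^{-1} z_i D^{1/2},
    with V_i = sigma^2 I + z_i D z_i' and D^{1/2} = diag(|delta_j|).
    Using the magnitude anchors the orientation of U to the data rather
    than to the current sign of delta, which keeps each delta_j marginal
    on a single side of zero (the sign-flipped configuration is an exact
    symmetry of the stationary density, so sign-invariant functionals are
    unaffected by this convention).
    """
    if eta.beta.shape[0] != design.p or eta.delta.shape[0] != design.q:
        raise DesignError("parameter dimensions do not match the design")
    dhalf = np.abs(eta.delta)
    d = eta.delta ** 2
    m, q = design.m, design.q
    if design.balanced:
        y3, x3, z3 = design.blocks3d()
        mean, var = _u_moments_balanced(y3, x3, z3, eta.beta, dhalf, eta.sigma2)
        return UConditionalMoments(mean=mean, var=var)
    mean = np.empty((m, q))
    var = np.empty((m, q, q))
    for i in range(m):
        yi, xi, zi = design.block(i)
        resid = yi - xi @ eta.beta
        vi = eta.sigma2 * np.eye(yi.size) + (zi * d) @ zi.T
        sol = np.linalg.solve(vi, np.column_stack([resid, zi]))
        mean[i] = dhalf * (zi.T @ sol[:, 0])
        vq = np.eye(q) - (dhalf[:, None] * (zi.T @ sol[:, 1:])) * dhalf[None, :]
        var[i] = 0.5 * (vq + vq.T)
    return UConditionalMoments(mean=mean, var=var)


def _u_moments_balanced(y3, x3, z3, beta, dhalf, sigma2):
    """Batched per-subject conditional moments of U; balanced designs.

    ``dhalf`` is the caller-supplied D^{1/2} diagonal (|delta_j| under the
    package's convention): mean_i = diag(dhalf) z_i' V_i^{-1} r_i,
    var_i = I - diag(dhalf) z_i' V_i^{-1} z_i diag(dhalf) with
    V_i = sigma^2 I + z_i diag(dhalf^2) z_i'.
    """
    ni = y3.shape[1]
    q = z3.shape[2]
    d = dhalf * dhalf
    resid = y3 - x3 @ beta                              # (m, ni)
    vi = np.einsum("mjk,mlk->mjl", z3 * d, z3)
    idx = np.arange(ni)
    vi[:, idx, idx] += sigma2
    rhs = np.concatenate([resid[:, :, None], z3], axis=2)
    sol = np.linalg.solve(vi, rhs)                      # (m, ni, 1+q)
    zt_vr = np.einsum("mjk,mj->mk", z3, sol[:, :, 0])   # z'V^{-1}r
    zt_vz = np.einsum("mjk,mjl->mkl", z3, sol[:, :, 1:])
    mean = dhalf * zt_vr
    var = np.eye(q) - dhalf[:, None] * zt_vz * dhalf[None, :]
    var = 0.5 * (var + np.swapaxes(var, 1, 2))
    return mean, var


def _sample_u_from(mean, var, rng):
    if mean.shape[1] == 1:                 # scalar conditional
        sd = np.sqrt(np.clip(var[:, 0, 0], 0.0, None))
        return mean + sd[:, None] * rng.standard_normal(mean.shape)
    w, v = np.linalg.eigh(var)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)[:, None, :]
    noise = rng.standard_normal(mean.shape)
    return mean + np.einsum("mij,mj->mi", factor, noise)


def sample_u(moments: UConditionalMoments, rng: np.random.Generator) -> np.ndarray:
    """Draw each row U_i ~ N_q(mean_i, var_i).

    Covariances are factored by symmetric eigendecomposition with negative
    eigenvalues clipped to zero, so exactly singular conditionals (e.g.
    var_i = 0 when the data pin U_i down) are handled without jitter.
    """
    return _sample_u_from(moments.mean, moments.var, rng)


def gibbs_chain(
    design: LMEDesign, config: ChainConfig, use_compiled: bool = True
) -> FiducialSample:
    """Run the Gibbs sampler and return the retained fiducial sample.

    Per sweep: draw sigma^2 from the trimmed quantity, theta from its
    Gaussian conditional at that sigma^2, then refresh U from its Gaussian
    conditional at the new eta.  The first ``warmup`` sweeps are discarded
    and every ``thin``-th sweep thereafter is retained.  Fully reproducible
    from ``config.seed``: one seeded stream per sweep component.

    Balanced full-rank designs run through compiled kernels that repeat
    the numpy arithmetic with explicit loops (``use_compiled=False`` forces
    the reference numpy path, used by the equivalence tests); ill-
    conditioned or rank-deficient sweeps always take the rank-revealing
    numpy path.
    """
    m, p, q, dof = design.m, design.p, design.q, design.dof
    rng_sigma, rng_theta, rng_u = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)
    )
    u = rng_u.standard_normal((m, q))
    n_keep = config.n_draws
    draws = np.empty((n_keep, p + q + 1))
    kept = 0
    blocks = design.blocks3d() if design.balanced else None
    fast = use_compiled and blocks is not None and _kernels.HAVE_NUMBA
    tol_factor = np.sqrt(max(design.n, p + q) * np.finfo(float).eps)
    for sweep in range(1, config.chain_length + 1):
        for attempt in range(_MAX_DEGENERATE_RETRIES + 1):
            quant = None
            if fast:
                try:
                    gls, smat, rss, ok = _kernels.ls_sweep(
                        blocks[1], blocks[2], blocks[0], u, design.y, tol_factor
                    )
                    if ok:
                        quant = ProjectionQuantities(
                            gls=gls, rss=float(rss), chol_inv=smat,
                            rank=p + q, full_rank=True,
                        )
                except np.linalg.LinAlgError:
                    quant = None
            if quant is None:
                quant = projection_quantities(stack_xu(design, u), design.y)
            try:
                sigma2 = sample_sigma2_trimmed(quant.rss, dof, config.c0, rng_sigma)
                break
            except DegenerateFitError:
                if attempt == _MAX_DEGENERATE_RETRIES:
                    raise SamplerError(
                        f"sweep {sweep}: {_MAX_DEGENERATE_RETRIES} consecutive "
                        "degenerate fits (rss = 0); data may be exactly interpolable"
                    ) from None
                u = rng_u.standard_normal((m, q))
        theta = sample_theta(quant, sigma2, rng_theta)
        if fast:
            noise = rng_u.standard_normal((m, q))
            u = _kernels.u_sweep(
                blocks[1], blocks[2], blocks[0], theta[:p], theta[p:], sigma2, noise
            )
        elif blocks is not None:
            mean, var = _u_moments_balanced(*blocks, theta[:p], np.abs(theta[p:]), sigma2)
            u = _sample_u_from(mean, var, rng_u)
        else:
            eta = ParamState(beta=theta[:p], delta=theta[p:], sigma2=sigma2)
            u = sample_u(conditional_u_moments(design, eta), rng_u)
        pos = sweep - config.warmup
        if pos > 0 and pos % config.thin == 0:
            draws[kept, :p + q] = theta
            draws[kept, p + q] = sigma2
            kept += 1
    columns = tuple(
        [f"beta{j}" for j in range(p)] + [f"delta{j}" for j in range(q)] + ["sigma2"]
    )
    sample = FiducialSample(
        draws=draws,
        columns=columns,
        config=config,
        dims={"m": m, "n": design.n, "p": p, "q": q},
        fixed_names=design.fixed_names,
        random_names=design.random_names,
    )
    _warn_if_poorly_mixed(sample)
    return sample


def _warn_if_poorly_mixed(sample: FiducialSample, threshold: float = 100.0) -> None:
    """Log (never raise) when any marginal's effective sample size is small."""
    try:
        ess = np.array([effective_sample_size(sample.draws[:, j])
                        for j in range(sample.draws.shape[1])])
    except Exception:  # diagnostics must never break a run
        return
    if np.any(ess < threshold):
        worst = sample.columns[int(np.argmin(ess))]
        logger.warning(
            "low effective sample size: min %.0f of %d draws (column %s)",
            float(ess.min()), sample.n_draws, worst,
        )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence on FFT autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    acov = np.fft.irfft(np.abs(np.fft.rfft(xc, nfft)) ** 2)[:n] / n
    rho = acov / acov[0]
    # Geyer pair sums G_k = rho_{2k} + rho_{2k+1}, summed while positive
    acc = 0.0
    for k in range(0, (n - 1) // 2):
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        acc += g
    tau = max(-1.0 + 2.0 * acc, 1.0 / n)
    return float(min(n / tau, n))


def log_fiducial_density(design: LMEDesign, eta: ParamState) -> float:
    """Unnormalized log of the stationary fiducial density r_y(eta).

    Equals the U-integrated Gaussian log-likelihood minus log sigma^2:
    subject i contributes log N(y_i; x_i beta, sigma^2 I + z_i D z_i').
    """
    if eta.beta.shape[0] != design.p or eta.delta.shape[0] != design.q:
        raise DesignError("parameter dimensions do not match the design")
    d = eta.delta ** 2
    if design.balanced:
        y3, x3, z3 = design.blocks3d()
        ni = y3.shape[1]
        cov = np.einsum("mjk,mlk->mjl", z3 * d, z3)
        idx = np.arange(ni)
        cov[:, idx, idx] += eta.sigma2
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("per-subject covariance not positive definite") from exc
        resid = y3 - x3 @ eta.beta
        sol = np.linalg.solve(chol, resid[:, :, None])[:, :, 0]
        return float(
            -0.5 * design.n * np.log(2.0 * np.pi)
            - np.log(chol[:, idx, idx]).sum()
            - 0.5 * np.sum(sol * sol)
            - np.log(eta.sigma2)
        )
    total = 0.0
    for i in range(design.m):
        yi, xi, zi = design.block(i)
        cov = eta.sigma2 * np.eye(yi.size) + (zi * d) @ zi.T
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("per-subject covariance not positive definite") from exc
        resid = yi - xi @ eta.beta
        sol = np.linalg.solve(chol, resid)
        total += (
            -0.5 * yi.size * np.log(2.0 * np.pi)
            - np.log(np.diag(chol)).sum()
            - 0.5 * float(sol @ sol)
        )
    return total - np.log(eta.sigma2)


def mh_reference_sampler(
    design: LMEDesign,
    n_draws: int,
    seed: int,
    step: float = 0.25,
    warmup: int = 1000,
    thin: int = 1,
    init: ParamState | None = None,
    sample_mask: np.ndarray | None = None,
) -> FiducialSample:
    """Random-walk Metropolis draws targeting the stationary fiducial density.

    A validation utility for small designs: the state is (beta, delta,
    log sigma^2) with a spherical Gaussian proposal of scale ``step``;
    ``sample_mask`` (length p+q+1) can freeze components at their initial
    values, e.g. to check a closed-form marginal with delta fixed at 0.
    The acceptance rate is logged and stored in ``meta``.
    """
    p, q = design.p, design.q
    k = p + q + 1
    mask = np.ones(k, dtype=bool) if sample_mask is None else np.asarray(sample_mask, bool)
    if mask.shape != (k,):
        raise ValueError(f"sample_mask must have length {k}")
    rng = np.random.default_rng(seed)
    if init is None:
        init = ParamState(beta=np.zeros(p), delta=np.full(q, 0.5), sigma2=1.0)
    state = np.concatenate([init.beta, init.delta, [np.log(init.sigma2)]])

    def logtarget(phi):
        # in log-sigma^2 coordinates the Jacobian sigma^2 cancels the 1/sigma^2
        eta = ParamState(beta=phi[:p], delta=phi[p:p + q], sigma2=np.exp(phi[-1]))
        return log_fiducial_density(design, eta) + phi[-1]

    lp = logtarget(state)
    total = warmup + n_draws * thin
    draws = np.empty((n_draws, k))
    accepted = 0
    kept = 0
    for it in range(1, total + 1):
        prop = state.copy()
        prop[mask] = state[mask] + step * rng.standard_normal(int(mask.sum()))
        lp_prop = logtarget(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            state, lp = prop, lp_prop
            accepted += 1
        if it > warmup and (it - warmup) % thin == 0:
            draws[kept, :p + q] = state[:p + q]
            draws[kept, p + q] = np.exp(state[-1])
            kept += 1
    rate = accepted / total
    logger.info("mh_reference_sampler acceptance rate: %.3f", rate)
    columns = tuple(
        [f"beta{j}" for j in range(p)] + [f"delta{j}" for j in range(q)] + ["sigma2"]
    )
    cfg = ChainConfig(chain_length=total, warmup=warmup, thin=thin, seed=seed)
    return FiducialSample(
        draws=draws,
        columns=columns,
        config=cfg,
        dims={"m": design.m, "n": design.n, "p": p, "q": q},
        fixed_names=design.fixed_names,
        random_names=design.random_names,
        meta={"acceptance_rate": rate, "step": step},
    )
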