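"""Sparse inducing-point GP machinery with uncertain inputs.

Implements the collapsed (Titsias-style) evidence lower bound for a GP
regression layer whose inputs carry diagonal-Gaussian beliefs, the closed-form
optimal Gaussian posterior over inducing values attaining that bound, and
sparse prediction from a trained inducing posterior.  Used both for the
kinematics (latent-to-observed) mapping and, through the dynamics module, for
the coupled latent transition functions.

For targets Y (T x D), inducing inputs Z (P x Q), noise variance beta and psi
statistics (psi0, Psi1, Phi = sum_t Psi2_t) the bound reads

    F = -TD/2 log(2 pi beta) - |Y|^2/(2 beta)
        + 1/(2 beta^2) tr(W^-1 Psi1' Y Y' Psi1)
        + D/2 log|Kuu| - D/2 log|W|
        - D/(2 beta) psi0 + D/(2 beta) tr(Kuu^-1 Phi),      W = Kuu + Phi/beta.

With point-mass beliefs and Z equal to the inputs this collapses to the exact
GP log marginal likelihood; for any inducing set it is a lower bound.  The
noise is isotropic across the D output dimensions, so a single inducing
covariance is shared across outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve

from .kernels import (
    ArdSeKernel,
    GaussianBelief,
    chol_inv,
    chol_logdet,
    gram,
    gram_backward,
    jittered_cholesky,
    psi0,
    psi1,
    psi1_backward,
    psi2,
    psi2_backward,
)

__all__ = [
    "InducingSet",
    "InducingPosterior",
    "collapsed_bound",
    "collapsed_bound_with_grads",
    "optimal_inducing_posterior",
    "uncollapsed_free_energy",
    "sparse_predict",
    "exact_gp_log_marginal",
]

JITTER = 1e-6


@dataclass
class InducingSet:
    """Inducing input locations, (P, Q)."""

    locations: np.ndarray

    def __post_init__(self) -> None:
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        if self.locations.shape[0] < 1 or not np.all(np.isfinite(self.locations)):
            raise ValueError("need >= 1 finite inducing location")

    @property
    def P(self) -> int:
        return self.locations.shape[0]


@dataclass
class InducingPosterior:
    """Gaussian posterior over inducing values; covariance shared across outputs."""

    mean: np.ndarray        # (P, D_out)
    covariance: np.ndarray  # (P, P)

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (self.mean.shape[0],) * 2:
            raise ValueError("covariance shape must match number of inducing points")


def _stats(kernel, inducing, beliefs, jitter):
    Z = inducing.locations
    p0 = psi0(kernel, beliefs)
    P1 = psi1(kernel, Z, beliefs)
    Phi = psi2(kernel, Z, beliefs)
    Kuu = gram(kernel, Z) + jitter * kernel.variance * np.eye(Z.shape[0])
    return Z, p0, P1, Phi, Kuu


def collapsed_bound(
    targets: np.ndarray,
    kernel: ArdSeKernel,
    inducing: InducingSet,
    beliefs: GaussianBelief,
    noise_variance: float,
    jitter: float = JITTER,
) -> float:
    """Collapsed variational lower bound on sum_d log p(targets[:, d])."""
    value, _ = _bound_core(targets, kernel, inducing, beliefs, noise_variance,
                           jitter, want_grads=False)
    return value


def collapsed_bound_with_grads(
    targets: np.ndarray,
    kernel: ArdSeKernel,
    inducing: InducingSet,
    beliefs: GaussianBelief,
    noise_variance: float,
    jitter: float = JITTER,
) -> tuple[float, dict]:
    """Bound plus gradients w.r.t. belief mean/variance, Z, lengthscales,
    signal variance and noise variance."""
    return _bound_core(targets, kernel, inducing, beliefs, noise_variance,
                       jitter, want_grads=True)


def _bound_core(targets, kernel, inducing, beliefs, noise_variance, jitter,
                want_grads):
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    if Y.shape[0] != beliefs.T:
        raise ValueError("targets and beliefs disagree on T")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite targets")
    if noise_variance <= 0:
        raise ValueError("noise_variance must be positive")
    T, D = Y.shape
    beta = float(noise_variance)
    Z, p0, P1, Phi, Kuu = _stats(kernel, inducing, beliefs, jitter)

    # numerically stable evaluation: with L = chol(Kuu) and
    # B = I + L^-1 Phi L^-T / beta, the log|Kuu| terms cancel analytically
    # (log|W| = log|Kuu| + log|B|) and all solves are triangular.
    from scipy.linalg import solve_triangular

    cf_K = jittered_cholesky(Kuu, jitter=1e-12, max_jitter=1e-4)
    L = np.tril(cf_K[0])
    LiPhi = solve_triangular(L, Phi, lower=True)
    Amat = solve_triangular(L, LiPhi.T, lower=True) / beta   # L^-1 Phi L^-T/beta
    B = np.eye(L.shape[0]) + 0.5 * (Amat + Amat.T)
    cf_B = jittered_cholesky(B, jitter=1e-14, max_jitter=1e-6)
    LB = np.tril(cf_B[0])

    U = P1.T @ Y                         # (P, D)
    LiU = solve_triangular(L, U, lower=True)
    c = solve_triangular(LB, LiU, lower=True)
    yy = float(np.sum(Y ** 2))
    tr_KinvPhi = float(np.trace(Amat)) * beta

    F = (
        -0.5 * T * D * np.log(2.0 * np.pi * beta)
        - 0.5 * yy / beta
        + 0.5 * float(np.sum(c ** 2)) / beta ** 2
        - 0.5 * D * chol_logdet(cf_B)
        - 0.5 * D * p0 / beta
        + 0.5 * D * tr_KinvPhi / beta
    )
    if not want_grads:
        return float(F), None

    W = Kuu + Phi / beta
    cf_W = jittered_cholesky(W, jitter=1e-12, max_jitter=1e-4)
    WiU = cho_solve(cf_W, U)             # (P, D)
    Kinv = chol_inv(cf_K)
    Winv = chol_inv(cf_W)
    dP1 = Y @ WiU.T / beta ** 2                                   # (T, P)
    dW = -0.5 * WiU @ WiU.T / beta ** 2 - 0.5 * D * Winv
    KiPhiKi = Kinv @ Phi @ Kinv
    dPhi = dW / beta + 0.5 * D * Kinv / beta
    dKuu = dW + 0.5 * D * Kinv - 0.5 * D * KiPhiKi / beta
    dp0 = -0.5 * D / beta
    dbeta = (
        -0.5 * T * D / beta
        + 0.5 * yy / beta ** 2
        - float(np.sum(U * WiU)) / beta ** 3
        + 0.5 * D * p0 / beta ** 2
        - 0.5 * D * tr_KinvPhi / beta ** 2
        + float(np.sum(dW * (-Phi))) / beta ** 2
    )

    dmu1, dvar1, dZ1, dlam1, dsf1 = psi1_backward(kernel, Z, beliefs, dP1)
    dmu2, dvar2, dZ2, dlam2, dsf2 = psi2_backward(kernel, Z, beliefs, dPhi)
    gA, gB, dlamK, dsfK = gram_backward(kernel, Z, Z, dKuu)
    grads = {
        "mean": dmu1 + dmu2,
        "variance": dvar1 + dvar2,
        "Z": dZ1 + dZ2 + gA + gB,
        "lengthscales": dlam1 + dlam2 + dlamK,
        "signal_variance": dsf1 + dsf2 + dsfK
        + dp0 * beliefs.T                      # psi0 = T * sf
        + jitter * float(np.trace(dKuu)),      # jitter scales with sf
        "noise_variance": float(dbeta),
    }
    return float(F), grads


def optimal_inducing_posterior(
    targets: np.ndarray,
    kernel: ArdSeKernel,
    inducing: InducingSet,
    beliefs: GaussianBelief,
    noise_variance: float,
    jitter: float = JITTER,
) -> InducingPosterior:
    """The q(u) attaining the collapsed bound:

    mean = Kuu W^-1 Psi1' Y / beta,   cov = Kuu W^-1 Kuu.
    """
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    beta = float(noise_variance)
    Z, _, P1, Phi, Kuu = _stats(kernel, inducing, beliefs, jitter)
    W = Kuu + Phi / beta
    cf_W = jittered_cholesky(W, jitter=1e-12, max_jitter=1e-4)
    mean = Kuu @ cho_solve(cf_W, P1.T @ Y) / beta
    cov = Kuu @ cho_solve(cf_W, Kuu)
    return InducingPosterior(mean, 0.5 * (cov + cov.T))


def uncollapsed_free_energy(
    targets: np.ndarray,
    kernel: ArdSeKernel,
    inducing: InducingSet,
    beliefs: GaussianBelief,
    noise_variance: float,
    posterior: InducingPosterior,
    jitter: float = JITTER,
) -> float:
    """Free energy F(q(u)) for an explicit Gaussian q(u).

    Maximized over q(u) this reproduces :func:`collapsed_bound`; used to verify
    the closed-form optimum.
    """
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    T, D = Y.shape
    beta = float(noise_variance)
    Z, p0, P1, Phi, Kuu = _stats(kernel, inducing, beliefs, jitter)
    cf_K = jittered_cholesky(Kuu, jitter=1e-12, max_jitter=1e-4)
    Kinv = chol_inv(cf_K)
    M, S = posterior.mean, posterior.covariance
    A = Kinv @ Phi @ Kinv
    fit = (
        -0.5 * T * D * np.log(2.0 * np.pi * beta)
        - 0.5 / beta * (
            float(np.sum(Y ** 2))
            - 2.0 * float(np.sum((P1.T @ Y) * (Kinv @ M)))
            + float(np.sum(A * (M @ M.T)))
            + D * float(np.sum(A * S))
            + D * (p0 - float(np.sum(Kinv * Phi)))
        )
    )
    # KL(q(u) || p(u)) summed over the D output dims, covariance shared
    cf_S = jittered_cholesky(S, jitter=1e-12, max_jitter=1e-4)
    P = Kuu.shape[0]
    kl = 0.5 * (
        D * float(np.sum(Kinv * S))
        + float(np.sum(M * (Kinv @ M)))
        - D * P
        + D * (chol_logdet(cf_K) - chol_logdet(cf_S))
    )
    return float(fit - kl)


def sparse_predict(
    x_star,
    kernel: ArdSeKernel,
    inducing: InducingSet,
    posterior: InducingPosterior,
    noise_variance: float | None = None,
    jitter: float = JITTER,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and per-output variance of the GP layer at ``x_star``.

    ``x_star`` is either a point array (N, Q) or a :class:`GaussianBelief`;
    with point input this is standard sparse GP prediction.
    """
    Z = inducing.locations
    Kuu = gram(kernel, Z) + jitter * kernel.variance * np.eye(Z.shape[0])
    cf_K = jittered_cholesky(Kuu, jitter=1e-12, max_jitter=1e-4)
    Kinv = chol_inv(cf_K)
    alpha = Kinv @ posterior.mean                     # (P, D)
    B = Kinv @ posterior.covariance @ Kinv - Kinv     # (P, P)

    if isinstance(x_star, GaussianBelief):
        P1 = psi1(kernel, Z, x_star)
        mean = P1 @ alpha
        P2 = psi2(kernel, Z, x_star, per_time=True)   # (N, P, P)
        kss = kernel.variance
        var_shared = kss + np.einsum("npq,pq->n", P2, B)
        # spread of the mean under q(x): E[m(x)^2] - E[m(x)]^2 per output dim
        m2 = np.einsum("pd,npq,qd->nd", alpha, P2, alpha)
        var = var_shared[:, None] + m2 - mean ** 2
    else:
        X = np.atleast_2d(np.asarray(x_star, dtype=float))
        Ksu = gram(kernel, X, Z)
        mean = Ksu @ alpha
        var_shared = kernel.variance + np.einsum("np,pq,nq->n", Ksu, B, Ksu)
        var = np.repeat(var_shared[:, None], posterior.mean.shape[1], axis=1)
    var = np.maximum(var, 0.0)
    if noise_variance is not None:
        var = var + noise_variance
    return mean, var


def exact_gp_log_marginal(
    targets: np.ndarray,
    kernel: ArdSeKernel,
    X: np.ndarray,
    noise_variance: float,
    jitter: float = 0.0,
) -> float:
    """Exact GP log marginal likelihood (Cholesky), independent oracle path."""
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    T, D = Y.shape
    K = gram(kernel, X) + (noise_variance + jitter * kernel.variance) * np.eye(T)
    cf = jittered_cholesky(K, jitter=1e-12, max_jitter=1e-6)
    a = cho_solve(cf, Y)
    return float(
        -0.5 * np.sum(Y * a) - 0.5 * D * chol_logdet(cf)
        - 0.5 * T * D * np.log(2.0 * np.pi)
    )
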