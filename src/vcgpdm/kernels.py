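"""ARD squared-exponential kernel and its expectations under Gaussian input beliefs.

The collapsed variational bounds used throughout this package require, besides
plain Gram matrices, the first three kernel expectations ("psi statistics")
under a diagonal-Gaussian belief q(x) = prod_q N(mu_q, var_q):

    psi0 = sum_t E[k(x_t, x_t)]
    psi1[t, p]  = E[k(x_t, z_p)]
    psi2[t, p, p'] = E[k(x_t, z_p) k(x_t, z_p')]

For the ARD-SE kernel all three are available in closed form, and so are their
derivatives with respect to every argument.  Each forward routine here has a
matching ``*_backward`` routine implementing the vector-Jacobian product; the
pairs are verified against finite differences in the test-suite.

The kernel is parameterized as

    k(x, x') = variance * exp(-0.5 * sum_q (x_q - x'_q)^2 / lengthscales_q)

i.e. ``lengthscales`` divide the squared distance directly (they are squared
lengthscales in the usual GP convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ArdSeKernel",
    "GaussianBelief",
    "gram",
    "gram_backward",
    "psi0",
    "psi1",
    "psi1_backward",
    "psi2",
    "psi2_backward",
    "jittered_cholesky",
]


@dataclass
class ArdSeKernel:
    """ARD squared-exponential (RBF) kernel.

    Parameters
    ----------
    lengthscales : (Q,) array of positive floats, the per-coordinate squared
        lengthscales dividing the squared distances.
    variance : positive signal variance (kernel value at zero distance).
    """

    lengthscales: np.ndarray
    variance: float = 1.0

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if self.lengthscales.ndim != 1:
            raise ValueError("lengthscales must be a vector")
        if not np.all(np.isfinite(self.lengthscales)) or np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be strictly positive and finite")
        if not np.isfinite(self.variance) or self.variance <= 0:
            raise ValueError("variance must be strictly positive and finite")

    @property
    def input_dim(self) -> int:
        return self.lengthscales.shape[0]


@dataclass
class GaussianBelief:
    """Diagonal-Gaussian belief over a sequence of input points.

    ``mean`` and ``variance`` are both (T, Q); ``variance`` elementwise >= 0,
    with zeros denoting point masses.
    """

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        self.variance = np.atleast_2d(np.asarray(self.variance, dtype=float))
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance must have the same shape")
        if np.any(self.variance < 0):
            raise ValueError("variance must be elementwise nonnegative")

    @property
    def T(self) -> int:
        return self.mean.shape[0]

    @property
    def Q(self) -> int:
        return self.mean.shape[1]

    @classmethod
    def point(cls, x: np.ndarray) -> "GaussianBelief":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return cls(x, np.zeros_like(x))


def _check_dims(kernel: ArdSeKernel, *mats: np.ndarray) -> None:
    for m in mats:
        if m.shape[-1] != kernel.input_dim:
            raise ValueError(
                f"input dimension {m.shape[-1]} does not match kernel dimension "
                f"{kernel.input_dim}"
            )


def gram(kernel: ArdSeKernel, A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix k(A_n, B_m); symmetric when B is None (B = A)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = A if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    _check_dims(kernel, A, B)
    diff = A[:, None, :] - B[None, :, :]
    d2 = np.sum(diff ** 2 / kernel.lengthscales, axis=-1)
    return kernel.variance * np.exp(-0.5 * d2)


def gram_backward(
    kernel: ArdSeKernel, A: np.ndarray, B: np.ndarray, dK: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """VJP of ``gram``: returns (dA, dB, dlengthscales, dvariance).

    When the forward call was gram(k, Z, Z) with a single array, pass A=B=Z and
    add dA + dB for the total gradient on Z.
    """
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    K = gram(kernel, A, B)
    W = dK * K
    lam = kernel.lengthscales
    diff = A[:, None, :] - B[None, :, :]            # (N, M, Q)
    scaled = diff / lam                              # (N, M, Q)
    dA = -np.einsum("nm,nmq->nq", W, scaled)
    dB = np.einsum("nm,nmq->mq", W, scaled)
    dlam = 0.5 * np.einsum("nm,nmq->q", W, diff ** 2) / lam ** 2
    dvar = float(np.sum(dK * K) / kernel.variance)
    return dA, dB, dlam, dvar


def psi0(kernel: ArdSeKernel, beliefs: GaussianBelief) -> float:
    """sum_t E[k(x_t, x_t)] = T * variance (ARD-SE is stationary)."""
    if beliefs.Q != kernel.input_dim:
        raise ValueError("belief dimension does not match kernel")
    return float(beliefs.T * kernel.variance)


def psi1(kernel: ArdSeKernel, Z: np.ndarray, beliefs: GaussianBelief) -> np.ndarray:
    """(T, P) matrix of E_{q(x_t)}[k(x_t, z_p)]."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    _check_dims(kernel, Z, beliefs.mean)
    lam = kernel.lengthscales
    denom = lam + beliefs.variance                   # (T, Q)
    diff = beliefs.mean[:, None, :] - Z[None, :, :]  # (T, P, Q)
    logdet = 0.5 * np.sum(np.log(lam / denom), axis=-1)          # (T,)
    expo = -0.5 * np.sum(diff ** 2 / denom[:, None, :], axis=-1)  # (T, P)
    return kernel.variance * np.exp(logdet[:, None] + expo)


def psi1_backward(
    kernel: ArdSeKernel, Z: np.ndarray, beliefs: GaussianBelief, dPsi1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """VJP of ``psi1``: returns (dmean, dvariance, dZ, dlengthscales, dvariance_signal)."""
    Z = np.atleast_2d(Z)
    lam = kernel.lengthscales
    denom = lam + beliefs.variance                   # (T, Q)
    diff = beliefs.mean[:, None, :] - Z[None, :, :]  # (T, P, Q)
    P1 = psi1(kernel, Z, beliefs)
    W = dPsi1 * P1                                   # (T, P)
    r = diff / denom[:, None, :]                     # (T, P, Q)
    dmu = -np.einsum("tp,tpq->tq", W, r)
    dvar = np.einsum(
        "tp,tpq->tq", W, 0.5 * r ** 2 - 0.5 / denom[:, None, :]
    )
    dZ = np.einsum("tp,tpq->pq", W, r)
    dlam = np.einsum(
        "tp,tpq->q",
        W,
        0.5 * (1.0 / lam - 1.0 / denom)[:, None, :] + 0.5 * r ** 2,
    )
    dsf = float(np.sum(W) / kernel.variance)
    return dmu, dvar, dZ, dlam, dsf


def psi2(
    kernel: ArdSeKernel,
    Z: np.ndarray,
    beliefs: GaussianBelief,
    per_time: bool = False,
) -> np.ndarray:
    """Closed-form E_{q(x_t)}[k(x_t, z_p) k(x_t, z_p')].

    Returns the (P, P) sum over t by default, or the full (T, P, P) tensor when
    ``per_time`` is set.  Symmetric and PSD in (p, p').
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    _check_dims(kernel, Z, beliefs.mean)
    lam = kernel.lengthscales
    e = lam + 2.0 * beliefs.variance                 # (T, Q)
    zbar = 0.5 * (Z[:, None, :] + Z[None, :, :])     # (P, P, Q)
    dz2 = (Z[:, None, :] - Z[None, :, :]) ** 2       # (P, P, Q)
    logdet = 0.5 * np.sum(np.log(lam / e), axis=-1)  # (T,)
    # exponent: -sum_q dz^2/(4 lam) - sum_q (mu - zbar)^2 / e
    a = -np.sum(dz2 / (4.0 * lam), axis=-1)          # (P, P)
    mzb = beliefs.mean[:, None, None, :] - zbar[None, :, :, :]   # (T, P, P, Q)
    b = -np.einsum("tijq,tq->tij", mzb ** 2, 1.0 / e)
    out = kernel.variance ** 2 * np.exp(logdet[:, None, None] + a[None, :, :] + b)
    return out if per_time else out.sum(axis=0)


def psi2_backward(
    kernel: ArdSeKernel, Z: np.ndarray, beliefs: GaussianBelief, dPsi2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """VJP of ``psi2``.

    ``dPsi2`` may be (P, P) — interpreted as the gradient of the t-summed
    statistic, i.e. broadcast over t — or the full (T, P, P) tensor.
    Returns (dmean, dvariance, dZ, dlengthscales, dvariance_signal).
    """
    Z = np.atleast_2d(Z)
    lam = kernel.lengthscales
    T = beliefs.T
    e = lam + 2.0 * beliefs.variance                 # (T, Q)
    zbar = 0.5 * (Z[:, None, :] + Z[None, :, :])     # (P, P, Q)
    dz = Z[:, None, :] - Z[None, :, :]               # (P, P, Q)
    P2 = psi2(kernel, Z, beliefs, per_time=True)     # (T, P, P)
    if dPsi2.ndim == 2:
        W = dPsi2[None, :, :] * P2
    else:
        W = dPsi2 * P2                               # (T, P, P)
    mzb = beliefs.mean[:, None, None, :] - zbar[None, :, :, :]   # (T, P, P, Q)
    inv_e = 1.0 / e                                  # (T, Q)
    r = mzb * inv_e[:, None, None, :]                # (T, P, P, Q)
    dmu = -2.0 * np.einsum("tij,tijq->tq", W, r)
    dvar = np.einsum("tij,tijq->tq", W, 2.0 * r ** 2 - inv_e[:, None, None, :])
    dlam = np.einsum(
        "tij,tijq->q",
        W,
        0.5 * (1.0 / lam - inv_e)[:, None, None, :]
        + (dz ** 2 / (4.0 * lam ** 2))[None, :, :, :]
        + r ** 2,
    )
    # z_p enters entry (i=p, j) via dz and zbar, and entry (i, j=p) likewise.
    g_first = np.einsum(
        "tij,tijq->iq", W, -(dz / (2.0 * lam))[None, :, :, :] + r
    )
    g_second = np.einsum(
        "tij,tijq->jq", W, (dz / (2.0 * lam))[None, :, :, :] + r
    )
    dZ = g_first + g_second
    dsf = float(2.0 * np.sum(W) / kernel.variance)
    return dmu, dvar, dZ, dlam, dsf


def jittered_cholesky(
    K: np.ndarray, jitter: float = 1e-6, max_jitter: float = 1e-4
) -> tuple:
    """Cholesky factorization with escalating diagonal jitter.

    Jitter is scaled by the mean diagonal; escalates tenfold from ``jitter`` up
    to ``max_jitter`` before failing.
    """
    K = np.asarray(K, dtype=float)
    scale = float(np.mean(np.diag(K)))
    if scale <= 0 or not np.isfinite(scale):
        scale = 1.0
    j = jitter
    last_err: Exception | None = None
    while j <= max_jitter * (1.0 + 1e-12):
        try:
            return cho_factor(K + j * scale * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare path
            last_err = err
            j *= 10.0
    raise np.linalg.LinAlgError(
        f"Cholesky failed even with jitter {max_jitter}: {last_err}"
    )


def chol_inv(cf: tuple) -> np.ndarray:
    """Inverse from a cho_factor, symmetrized."""
    n = cf[0].shape[0]
    inv = cho_solve(cf, np.eye(n))
    return 0.5 * (inv + inv.T)


def chol_logdet(cf: tuple) -> float:
    return float(2.0 * np.sum(np.log(np.diag(cf[0]))))
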