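"""Coupled latent dynamics: product-of-experts fusion and the collapsed bound.

Each part j of the model receives Gaussian predictions of its next latent
state from every part i (including itself) through a coupling function
f^{i,j} with variance alpha^{i,j}.  The normalized product of experts is

    p(x_t^j | f, alpha) = N(x_t^j ; alpha_j sum_i f^{i,j}_t / alpha^{i,j}, alpha_j),
    alpha_j = (sum_i 1/alpha^{i,j})^{-1},

so small alpha^{i,j} means strong influence of part i on part j.

Sparsifying every coupling GP with inducing points z^{i,j} / values u^{i,j}
and taking expectations under the factorized latent posterior q makes the
expected log PoE likelihood quadratic in the stacked inducing values: because
q factorizes over parts, dimensions and time steps, cross-expert terms factor
into products of psi1 rows, same-expert squares produce psi2, and the target
x_t^j is independent of the autoregressive inputs (which involve only earlier
time steps).  The optimal joint Gaussian posterior over the stacked u then
integrates out in closed form (a Gaussian integral of exp of a quadratic
against the blockdiagonal GP prior), yielding the collapsed dynamics bound.
The Monte-Carlo validation of this closed form lives in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, block_diag

from .kernels import (
    ArdSeKernel,
    GaussianBelief,
    chol_inv,
    chol_logdet,
    gram,
    jittered_cholesky,
)
from .variational import InducingPosterior, InducingSet

__all__ = [
    "CouplingGP",
    "poe_combine",
    "marginalized_kernel",
    "entropy",
    "initial_state_term",
    "DynamicsTerm",
    "vgpdm_dynamics_bound",
]


@dataclass
class CouplingGP:
    """One ordered part pair (source i -> target j).

    The kernel acts on part i's stacked past states (order * Q_i inputs);
    ``alpha`` is the coupling variance alpha^{i,j} (> 0, small = strong
    influence).  ``posterior`` is filled in after training.
    """

    source: int
    target: int
    kernel: ArdSeKernel
    inducing: InducingSet
    alpha: float
    posterior: InducingPosterior | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("coupling variance must be positive")
        if self.kernel.input_dim != self.inducing.locations.shape[1]:
            raise ValueError("kernel input dimension does not match inducing points")


def poe_combine(means, variances) -> tuple[np.ndarray, float]:
    """Precision-weighted product-of-experts combination.

    ``means``: sequence of expert mean vectors (broadcastable arrays);
    ``variances``: the per-expert variances alpha^{i,j}.  Returns the combined
    mean and the combined variance alpha_j = (sum_i 1/alpha^{i,j})^{-1}.
    """
    means = [np.asarray(m, dtype=float) for m in means]
    variances = [float(v) for v in variances]
    if len(means) == 0 or len(means) != len(variances):
        raise ValueError("need at least one expert with matching variances")
    if any(v <= 0 for v in variances):
        raise ValueError("expert variances must be positive")
    prec = sum(1.0 / v for v in variances)
    combined_var = 1.0 / prec
    combined_mean = combined_var * sum(m / v for m, v in zip(means, variances))
    return combined_mean, combined_var


def marginalized_kernel(couplings, inputs, inputs2=None) -> np.ndarray:
    """Exactly marginalized PoE dynamics kernel for one target part.

    k_f^j(., .) = alpha_j^2 * sum_i k^{i,j}(., .) / (alpha^{i,j})^2

    ``couplings`` all share the same target part; ``inputs`` is a list of
    point matrices, one per coupling, holding part i's stacked past states at
    the same set of time steps.  This is the covariance of the PoE mean
    prediction when the coupling-function values are marginalized under their
    GP priors; with a single part it reduces to that part's dynamics kernel.
    """
    targets = {c.target for c in couplings}
    if len(targets) != 1:
        raise ValueError("couplings must share a single target part")
    if len(inputs) != len(couplings):
        raise ValueError("need one input matrix per coupling")
    if inputs2 is None:
        inputs2 = inputs
    _, alpha_j = poe_combine(
        [np.zeros(1) for _ in couplings], [c.alpha for c in couplings]
    )
    out = None
    for c, Xi, Xi2 in zip(couplings, inputs, inputs2):
        K = gram(c.kernel, Xi, Xi2) / c.alpha ** 2
        out = K if out is None else out + K
    return alpha_j ** 2 * out


def entropy(means: np.ndarray, variances: np.ndarray) -> float:
    """Shannon entropy of the factorized Gaussian posterior, summed over all
    time steps and dimensions: sum 0.5 log(2 pi e var)."""
    variances = np.asarray(variances, dtype=float)
    if np.any(variances <= 0):
        raise ValueError("entropy requires strictly positive variances")
    return float(0.5 * np.sum(np.log(2.0 * np.pi * np.e * variances)))


def initial_state_term(mu0: np.ndarray, var0: np.ndarray) -> float:
    """E_q[log p(x_init)] under independent unit Gaussians:
    -1/2 sum (mu^2 + var + log 2 pi) over the initial states."""
    mu0 = np.asarray(mu0, dtype=float)
    var0 = np.asarray(var0, dtype=float)
    return float(-0.5 * np.sum(mu0 ** 2 + var0 + np.log(2.0 * np.pi)))


class DynamicsTerm:
    """Collapsed PoE-likelihood bound for one target part j.

    Parameters
    ----------
    target_mean, target_var : (Td, Qj) moments of q over the predicted states
        x_t^j (time steps with a full autoregressive history).
    experts : list of dicts, one per source part i, with keys
        ``Kuu`` (P_i, P_i) jittered inducing Gram,
        ``Psi1`` (Td, P_i), ``Phi`` (P_i, P_i) summed psi2,
        ``psi0`` scalar sum_t E[k(x,x)], ``alpha`` scalar.

    The object exposes the collapsed bound value, its gradients with respect
    to every input, the optimal joint posterior over stacked inducing values,
    and the expected log-likelihood at an arbitrary Gaussian q(u) (used by the
    Monte-Carlo oracle tests).
    """

    def __init__(self, target_mean, target_var, experts):
        self.mu = np.atleast_2d(np.asarray(target_mean, dtype=float))
        self.var = np.atleast_2d(np.asarray(target_var, dtype=float))
        if self.mu.shape != self.var.shape:
            raise ValueError("target mean/var shape mismatch")
        self.experts = experts
        self.Td, self.Q = self.mu.shape
        self.alphas = np.array([float(e["alpha"]) for e in experts])
        if np.any(self.alphas <= 0):
            raise ValueError("coupling variances must be positive")
        self.alpha_j = 1.0 / np.sum(1.0 / self.alphas)
        self.sizes = [e["Kuu"].shape[0] for e in experts]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        self._forward()

    # ------------------------------------------------------------------ #
    def _forward(self) -> None:
        M = len(self.experts)
        aj = self.alpha_j
        self._cfs = [jittered_cholesky(e["Kuu"], 1e-12, 1e-4) for e in self.experts]
        self.G = [chol_inv(cf) for cf in self._cfs]
        self.Wmat = [e["Psi1"] @ Gi for e, Gi in zip(self.experts, self.G)]
        Ptot = self.offsets[-1]

        # b and A of the quadratic C(u) = const + b'u - 1/2 u'Au (per output dim)
        self.b = np.zeros((Ptot, self.Q))
        self.A = np.zeros((Ptot, Ptot))
        self._A_raw_diag = []
        sl = [slice(self.offsets[i], self.offsets[i + 1]) for i in range(M)]
        self._slices = sl
        for i, e in enumerate(self.experts):
            self.b[sl[i]] = self.Wmat[i].T @ self.mu / self.alphas[i]
            raw = self.G[i] @ e["Phi"] @ self.G[i]
            self._A_raw_diag.append(raw)
            self.A[sl[i], sl[i]] = (aj / self.alphas[i] ** 2) * raw
            for k in range(i + 1, M):
                blk = (aj / (self.alphas[i] * self.alphas[k])) * (
                    self.Wmat[i].T @ self.Wmat[k]
                )
                self.A[sl[i], sl[k]] = blk
                self.A[sl[k], sl[i]] = blk.T

        self.K = block_diag(*[e["Kuu"] for e in self.experts])
        L_K = np.linalg.cholesky(self.K)
        B = np.eye(Ptot) + L_K.T @ self.A @ L_K
        cf_B = jittered_cholesky(B, 1e-14, 1e-6)
        self._L_K = L_K
        self.logdetB = chol_logdet(cf_B)
        # posterior moments of stacked u: S = (K^-1 + A)^-1, m = S b
        Binv = chol_inv(cf_B)
        self.S = L_K @ Binv @ L_K.T
        self.S = 0.5 * (self.S + self.S.T)
        self.m = self.S @ self.b

        # conditional-variance deficit per expert: sum_t [E k(x,x) - tr(G Phi_t)]
        self.sbar = np.array(
            [
                float(e["psi0"] - np.sum(Gi * e["Phi"]))
                for e, Gi in zip(self.experts, self.G)
            ]
        )
        self.const = (
            -0.5 * self.Td * self.Q * np.log(2.0 * np.pi * aj)
            - 0.5 * float(np.sum(self.mu ** 2 + self.var)) / aj
            - 0.5 * aj * self.Q * float(np.sum(self.sbar / self.alphas ** 2))
        )
        self.value = (
            self.const
            + 0.5 * float(np.sum(self.b * self.m))
            - 0.5 * self.Q * self.logdetB
        )

    # ------------------------------------------------------------------ #
    def optimal_posterior(self) -> InducingPosterior:
        """Joint Gaussian q over the stacked inducing values of all couplings
        into this target part (covariance shared across the Qj output dims)."""
        return InducingPosterior(self.m, self.S)

    def coupling_posteriors(self) -> list[InducingPosterior]:
        """Marginal q(u^{i,j}) per source part."""
        return [InducingPosterior(self.m[s], self.S[s, s]) for s in self._slices]

    def expected_loglik(self, u_mean: np.ndarray, u_cov: np.ndarray) -> float:
        """E_{q(x) q(u)} E_{p(f|x,u)} [log PoE likelihood] at an explicit q(u)."""
        quad = float(np.sum(self.b * u_mean)) - 0.5 * float(
            np.einsum("pq,pr,rq->", u_mean, self.A, u_mean)
        )
        return self.const + quad - 0.5 * self.Q * float(np.sum(self.A * u_cov))

    def kl_u(self, u_mean: np.ndarray, u_cov: np.ndarray) -> float:
        """KL(q(u) || p(u)) with blockdiagonal GP prior, summed over output dims."""
        cf_K = jittered_cholesky(self.K, 1e-14, 1e-6)
        Kinv = chol_inv(cf_K)
        cf_S = jittered_cholesky(u_cov, 1e-14, 1e-6)
        P = self.K.shape[0]
        return 0.5 * (
            self.Q * float(np.sum(Kinv * u_cov))
            + float(np.sum(u_mean * (Kinv @ u_mean)))
            - self.Q * P
            + self.Q * (chol_logdet(cf_K) - chol_logdet(cf_S))
        )

    # ------------------------------------------------------------------ #
    def grads(self) -> dict:
        """Gradients of the collapsed value.

        Returns a dict with ``target_mean``, ``target_var``, ``alphas`` (M,),
        and per-expert lists ``Psi1``, ``Phi``, ``Kuu``, ``psi0``.
        """
        M = len(self.experts)
        aj = self.alpha_j
        sl = self._slices
        db = self.m.copy()                                   # (Ptot, Q)
        dA = -0.5 * (self.m @ self.m.T) - 0.5 * self.Q * self.S
        # K enters the prior: dL/dK = 1/2 Pm Pm' - Q/2 (K^-1 - K^-1 S K^-1)
        cf_K = jittered_cholesky(self.K, 1e-14, 1e-6)
        Kinv = chol_inv(cf_K)
        Pm = Kinv @ self.m
        KiSKi = Kinv @ self.S @ Kinv
        dK = 0.5 * (Pm @ Pm.T) - 0.5 * self.Q * (Kinv - KiSKi)

        dmu = -self.mu / aj
        dvar = -0.5 * np.ones_like(self.var) / aj
        d_aj = (
            -0.5 * self.Td * self.Q / aj
            + 0.5 * float(np.sum(self.mu ** 2 + self.var)) / aj ** 2
            - 0.5 * self.Q * float(np.sum(self.sbar / self.alphas ** 2))
        )
        d_alphas = np.zeros(M)
        dPsi1 = [np.zeros_like(e["Psi1"]) for e in self.experts]
        dPhi = [np.zeros_like(e["Phi"]) for e in self.experts]
        dKuu = [dK[s, s].copy() for s in sl]
        dG = [np.zeros_like(Gi) for Gi in self.G]
        dW = [np.zeros_like(Wi) for Wi in self.Wmat]
        dpsi0 = np.zeros(M)

        for i, e in enumerate(self.experts):
            ai = self.alphas[i]
            # b block: b_i = G_i Psi1_i' mu / alpha_i
            db_i = db[sl[i]]
            c_i = e["Psi1"].T @ self.mu                       # (P_i, Q)
            dc_i = self.G[i] @ db_i / ai
            dPsi1[i] += self.mu @ dc_i.T
            dmu += e["Psi1"] @ dc_i
            dG[i] += db_i @ c_i.T / ai
            d_alphas[i] += -float(np.sum(self.b[sl[i]] * db_i)) / ai
            # diagonal A block: coef * G Phi G
            coef = aj / ai ** 2
            dA_ii = dA[sl[i], sl[i]]
            dPhi[i] += coef * self.G[i] @ dA_ii @ self.G[i]
            GPhi = self.G[i] @ e["Phi"]
            dG[i] += coef * (dA_ii @ GPhi + GPhi.T @ dA_ii)
            dcoef = float(np.sum(dA_ii * self._A_raw_diag[i]))
            d_aj += dcoef / ai ** 2
            d_alphas[i] += dcoef * (-2.0 * aj / ai ** 3)
            # off-diagonal A blocks, each ordered pair handled once
            for k in range(M):
                if k == i:
                    continue
                ak = self.alphas[k]
                coef_ik = aj / (ai * ak)
                dA_ik = dA[sl[i], sl[k]]
                dW[i] += coef_ik * self.Wmat[k] @ dA_ik.T
                dW[k] += coef_ik * self.Wmat[i] @ dA_ik
                raw = float(np.sum(dA_ik * (self.Wmat[i].T @ self.Wmat[k])))
                d_aj += raw / (ai * ak)
                d_alphas[i] += -coef_ik * raw / ai
                d_alphas[k] += -coef_ik * raw / ak
            # const: -(aj Q / 2) sbar_i / ai^2,  sbar_i = psi0_i - tr(G_i Phi_i)
            dpsi0[i] += -0.5 * aj * self.Q / ai ** 2
            dPhi[i] += 0.5 * aj * self.Q / ai ** 2 * self.G[i]
            dG[i] += 0.5 * aj * self.Q / ai ** 2 * e["Phi"]
            d_alphas[i] += aj * self.Q * self.sbar[i] / ai ** 3

        for i in range(M):
            dPsi1[i] += dW[i] @ self.G[i]
            dG[i] += self.experts[i]["Psi1"].T @ dW[i]
            dKuu[i] += -self.G[i] @ dG[i] @ self.G[i]

        # chain alpha_j = (sum 1/alpha_i)^-1
        d_alphas += d_aj * (aj ** 2 / self.alphas ** 2)
        return {
            "target_mean": dmu,
            "target_var": dvar,
            "alphas": d_alphas,
            "Psi1": dPsi1,
            "Phi": dPhi,
            "Kuu": dKuu,
            "psi0": dpsi0,
        }


def vgpdm_dynamics_bound(
    target_mean, target_var, Kuu, Psi1, Phi, psi0_sum, alpha
) -> float:
    """Single-part (uncoupled) dynamics bound, dedicated code path.

    Identical in structure to :class:`DynamicsTerm` with one expert; kept as a
    separate, loop-free implementation so the coupled code can be checked
    against it exactly.
    """
    mu = np.atleast_2d(np.asarray(target_mean, dtype=float))
    var = np.atleast_2d(np.asarray(target_var, dtype=float))
    Td, Q = mu.shape
    alpha = float(alpha)
    aj = 1.0 / np.sum(1.0 / np.array([alpha]))
    cf = jittered_cholesky(Kuu, 1e-12, 1e-4)
    G = chol_inv(cf)
    Wmat = Psi1 @ G
    b = Wmat.T @ mu / alpha
    A = (aj / alpha ** 2) * (G @ Phi @ G)
    L_K = np.linalg.cholesky(Kuu)
    B = np.eye(Kuu.shape[0]) + L_K.T @ A @ L_K
    cf_B = jittered_cholesky(B, 1e-14, 1e-6)
    Binv = chol_inv(cf_B)
    S = L_K @ Binv @ L_K.T
    S = 0.5 * (S + S.T)
    m = S @ b
    sbar = float(psi0_sum - np.sum(G * Phi))
    const = (
        -0.5 * Td * Q * np.log(2.0 * np.pi * aj)
        - 0.5 * float(np.sum(mu ** 2 + var)) / aj
        - 0.5 * aj * Q * sbar / alpha ** 2
    )
    return const + 0.5 * float(np.sum(b * m)) - 0.5 * Q * chol_logdet(cf_B)
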