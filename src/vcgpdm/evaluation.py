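"""Trajectory generation and DTW-warped mean-squared-error scoring.

Generation iterates the *mean* dynamics: each coupling GP contributes its
sparse predictive mean at the stacked previous latent states of its source
part, the experts are product-of-experts combined with the learned coupling
variances, and the resulting latent means are pushed through the kinematics
predictive mean.  No sampling is involved, so generation is repeatable.

Scoring aligns the generated trajectory onto a reference with classic dynamic
time warping (symmetric step pattern, no window, squared-Euclidean local
cost) and reports the mean squared frame difference along the optimal path,
averaged over both path steps and degrees of freedom.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import sem

from . import kernels as kr
from .dynamics import poe_combine
from .io import TrajectorySet
from .model import VCGPDM

__all__ = ["rollout", "dtw_mse", "dtw_path", "infer_latents", "cross_validate"]


def _coupling_predictor(model: VCGPDM, i: int, j: int):
    """Sparse predictive-mean function of coupling (i -> j)."""
    c = model.couplings[(i, j)]
    if c.posterior is None:
        raise ValueError("untrained posterior; call update_posteriors() or fit()")
    Z = c.inducing.locations
    Kuu = kr.gram(c.kernel, Z) + model.jitter * c.kernel.variance * np.eye(Z.shape[0])
    cf = kr.jittered_cholesky(Kuu, 1e-12, 1e-4)
    A = kr.chol_inv(cf) @ c.posterior.mean          # (P, Q_j)

    def predict(x_stacked: np.ndarray) -> np.ndarray:
        k = kr.gram(c.kernel, np.atleast_2d(x_stacked), Z)
        return (k @ A)[0]

    return predict


def _kinematics_predictor(model: VCGPDM, i: int):
    p = model.parts[i]
    if p.kin_posterior is None:
        raise ValueError("untrained posterior; call update_posteriors() or fit()")
    R = p.kin_inducing.locations
    Kuu = kr.gram(p.kin_kernel, R) + model.jitter * p.kin_kernel.variance \
        * np.eye(R.shape[0])
    cf = kr.jittered_cholesky(Kuu, 1e-12, 1e-4)
    A = kr.chol_inv(cf) @ p.kin_posterior.mean      # (P, D_i)

    def predict(x: np.ndarray) -> np.ndarray:
        k = kr.gram(p.kin_kernel, np.atleast_2d(x), R)
        return k @ A

    return predict, A, R, p.kin_kernel


def rollout(model: VCGPDM, T: int, init_latents=None, init_frames=None):
    """Iterate the mean dynamics for T steps and map to observed space.

    ``init_latents``: list per part of (order, Q_i) starting latent states; or
    ``init_frames``: (order, D) observed frames, mapped to latent starting
    states by :func:`infer_latents` (the held-out-trial protocol).  Defaults
    to the first ``order`` fitted latent means.

    Returns (latents, observed): list of (T, Q_i) per part and (T, D) overall.
    """
    order, M = model.order, model.M
    if T < order:
        raise ValueError("T must be at least the model order")
    if init_frames is not None:
        init_latents = infer_latents(model, np.atleast_2d(init_frames))
    if init_latents is None:
        if any(p.latent is None for p in model.parts):
            raise ValueError("no latent posterior; provide initial states")
        init_latents = [p.latent.mean[:order] for p in model.parts]
    init_latents = [np.atleast_2d(np.asarray(x, dtype=float))
                    for x in init_latents]
    for i, x in enumerate(init_latents):
        if x.shape != (order, model.parts[i].Q):
            raise ValueError(f"part {i}: initial states must be "
                             f"({order}, {model.parts[i].Q})")

    dyn_pred = {(i, j): _coupling_predictor(model, i, j)
                for i in range(M) for j in range(M)}
    kin = [_kinematics_predictor(model, i)[0] for i in range(M)]

    lat = [np.zeros((T, model.parts[i].Q)) for i in range(M)]
    for i in range(M):
        lat[i][:order] = init_latents[i]
    for t in range(order, T):
        stacked = [lat[i][t - order:t].ravel() for i in range(M)]
        for j in range(M):
            means = [dyn_pred[(i, j)](stacked[i]) for i in range(M)]
            alphas = [model.couplings[(i, j)].alpha for i in range(M)]
            mean, _ = poe_combine(means, alphas)
            if not np.all(np.isfinite(mean)):
                raise FloatingPointError(
                    f"non-finite latent state at step {t}, part {j}")
            lat[j][t] = mean

    D = model.data.D
    obs = np.zeros((T, D))
    for i in range(M):
        obs[:, model.data.part_columns(i)] = kin[i](lat[i])
    return lat, obs


def infer_latents(model: VCGPDM, frames: np.ndarray):
    """Latent states matching observed frames, per part.

    Minimizes the squared kinematics-mean reconstruction error over the latent
    point, starting from the best of the inducing locations and (when
    available) the fitted latent means.  Returns a list of (n_frames, Q_i).
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    out = []
    for i in range(model.M):
        p = model.parts[i]
        predict, A, R, kern = _kinematics_predictor(model, i)
        Yp = frames[:, model.data.part_columns(i)]
        candidates = R
        if p.latent is not None and p.latent.mean.shape[0] > model.order:
            candidates = np.vstack([R, p.latent.mean])
        sol = np.zeros((frames.shape[0], p.Q))
        for n, y in enumerate(Yp):
            errs = np.sum((predict(candidates) - y) ** 2, axis=1)
            x0 = candidates[np.argmin(errs)]

            def objective(x):
                k = kr.gram(kern, x[None, :], R)          # (1, P)
                resid = (k @ A)[0] - y                     # (D,)
                dk = -k[0][:, None] * (x[None, :] - R) / kern.lengthscales
                grad = 2.0 * dk.T @ (A @ resid)
                return float(np.sum(resid ** 2)), grad

            res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                           options={"maxiter": 100})
            sol[n] = res.x if res.fun <= objective(x0)[0] else x0
        out.append(sol)
    return out


# ---------------------------------------------------------------------- #
def dtw_path(a: np.ndarray, b: np.ndarray):
    """Optimal DTW alignment (symmetric steps, unit weights, no window).

    Local cost is the squared Euclidean frame distance.  Returns
    (path, total_cost) where path is a list of (i, j) index pairs.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty sequence")
    if a.shape[1] != b.shape[1]:
        raise ValueError("column counts differ")
    n, m = a.shape[0], b.shape[0]
    cost = cdist(a, b, metric="sqeuclidean")
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 1:] = cost[i - 1]
        prev = D[i - 1]
        run = D[i]
        for j in range(1, m + 1):
            run[j] += min(prev[j - 1], prev[j], run[j - 1])
    # traceback
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        moves = ((D[i - 1, j - 1], i - 1, j - 1),
                 (D[i - 1, j], i - 1, j),
                 (D[i, j - 1], i, j - 1))
        _, i, j = min(moves, key=lambda t: t[0])
    path.reverse()
    return path, float(D[n, m])


def dtw_mse(generated: np.ndarray, reference: np.ndarray) -> float:
    """Mean squared error per frame and degree of freedom along the optimal
    DTW path (identical sequences score exactly zero)."""
    generated = np.atleast_2d(np.asarray(generated, dtype=float))
    path, total = dtw_path(generated, reference)
    return total / (len(path) * generated.shape[1])


# ---------------------------------------------------------------------- #
def cross_validate(data: TrajectorySet, k: int | None = None,
                   model_kwargs: dict | None = None,
                   fit_kwargs: dict | None = None) -> dict:
    """Leave-one-trial-out (or k-fold over trials) DTW-MSE.

    Each fold trains on the remaining trials, generates a trajectory of the
    held-out trial's length starting from its first ``order`` frames, and
    scores it against the complete held-out trial.  Returns per-fold scores
    plus their mean and standard error of the mean.
    """
    n = len(data.sequences)
    if n < 2:
        raise ValueError("cross-validation needs at least two trials")
    k = n if k is None else min(k, n)
    folds = [list(g) for g in np.array_split(np.arange(n), k)]
    model_kwargs = dict(model_kwargs or {})
    fit_kwargs = dict(fit_kwargs or {})
    scores = []
    for fold in folds:
        train_idx = [i for i in range(n) if i not in fold]
        train = data.subset(train_idx)
        model = VCGPDM(train, **model_kwargs)
        model.fit(**fit_kwargs)
        for h in fold:
            held = data.sequences[h]
            _, gen = rollout(model, held.shape[0],
                             init_frames=held[: model.order])
            scores.append(dtw_mse(gen, held))
    scores = np.asarray(scores)
    return {
        "fold_scores": scores,
        "mean": float(scores.mean()),
        "sem": float(sem(scores)) if scores.size > 1 else float("nan"),
    }


def write_report(path, result: dict) -> None:
    """Delimited-text cross-validation report: one line per fold + summary."""
    with open(path, "w") as fh:
        fh.write("fold\tdtw_mse\n")
        for i, s in enumerate(result["fold_scores"]):
            fh.write(f"{i}\t{s:.10g}\n")
        fh.write(f"# mean {result['mean']:.10g} sem {result['sem']:.10g}\n")
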