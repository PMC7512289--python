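"""Initialization and ELBO optimization.

Latent trajectories are initialized with PCA of each part's observed columns;
inducing points are selected by time-stratified subsampling of the initial
latent trajectory.  Training runs one joint L-BFGS-B stage over all free
parameters, then cycles of blocked optimization over three groups — latent
means/variances, kernel parameters + couplings, and inducing points —
recording the ELBO after every block and stopping when a full cycle no longer
improves it (relative tolerance) or the cycle budget is exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.decomposition import PCA

from .io import TrajectorySet
from .model import LatentPosterior, VCGPDM, VCGPDMResults

__all__ = ["TrainingConfig", "init_latent", "init_inducing",
           "median_lengthscales", "fit"]


@dataclass
class TrainingConfig:
    """Knobs of the joint-then-blocked optimization.

    ``blocks`` must cover each trainable group exactly once per cycle.
    ``tol`` is the relative ELBO change between cycles below which training
    stops ("converged"); ``seed`` only matters where an operation is randomized
    (inducing selection handles its own seed at model construction).
    """

    blocks: tuple = ("latents", "hypers", "inducing")
    joint_maxiter: int = 500
    block_maxiter: int = 100
    max_cycles: int = 4
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if sorted(self.blocks) != sorted(set(self.blocks)):
            raise ValueError("blocks must list each parameter group once")

    @classmethod
    def from_file(cls, path) -> "TrainingConfig":
        """Build from a plain ``key = value`` text file; ``blocks`` is a
        comma-separated list."""
        from .io import read_config

        cfg = read_config(path)
        if "blocks" in cfg:
            cfg["blocks"] = tuple(s.strip() for s in str(cfg["blocks"]).split(","))
        return cls(**cfg)


def init_latent(data: TrajectorySet, part: int, Q: int,
                init_variance: float = 0.1) -> LatentPosterior:
    """PCA initialization of one part's latent posterior.

    Means are the first Q principal-component scores of the part's observed
    columns (sequences concatenated, computed once on the pooled data),
    standardized to unit variance per dimension; variances start at a small
    constant.  The standardization keeps the latent trajectory on the scale
    the model's priors assume — unit-Gaussian initial states and
    unit-amplitude transition GPs — so the dynamics prior neither shrinks nor
    has to stretch the learned mean map.  Zero-variance columns are dropped
    from the PCA rather than failing.
    """
    Y = np.vstack(data.part_data(part))
    keep = np.flatnonzero(np.var(Y, axis=0) > 0)
    if keep.size == 0:
        raise ValueError(f"part {part} has no varying columns")
    Yv = Y[:, keep]
    if Y.shape[0] < Q:
        raise ValueError(f"need at least Q={Q} frames for PCA initialization")
    q_eff = min(Q, Yv.shape[1])
    scores = PCA(n_components=q_eff, svd_solver="full").fit_transform(Yv)
    scores = scores / scores.std(axis=0)
    if q_eff < Q:
        warnings.warn(f"part {part}: only {q_eff} informative directions; "
                      f"padding latent dims to {Q}")
        scores = np.hstack([scores, np.zeros((scores.shape[0], Q - q_eff))])
    return LatentPosterior(scores, init_variance * np.ones_like(scores))


def init_inducing(points: np.ndarray, P: int, seed: int = 0) -> np.ndarray:
    """Select P inducing locations from a trajectory, stratified by time.

    Deterministic given the seed; the seed is only consulted when P exceeds
    the number of available points, in which case the selection is padded with
    small Gaussian perturbations of existing points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    N = points.shape[0]
    if P <= N:
        idx = np.unique(np.round(np.linspace(0, N - 1, P)).astype(int))
        # rounding can merge neighbours for P close to N; backfill if so
        while idx.size < P:
            missing = np.setdiff1d(np.arange(N), idx)
            idx = np.sort(np.concatenate([idx, missing[: P - idx.size]]))
        return points[idx].copy()
    warnings.warn(f"requested {P} inducing points from {N} frames; padding")
    rng = np.random.default_rng(seed)
    scale = 0.01 * (points.std(axis=0) + 1e-6)
    extra = points[rng.integers(0, N, P - N)] + rng.normal(
        0, 1, (P - N, points.shape[1])) * scale
    return np.vstack([points, extra])


def median_lengthscales(X: np.ndarray, floor: float = 1e-3,
                        max_points: int = 256) -> np.ndarray:
    """Per-dimension median of pairwise squared coordinate differences, the
    usual median heuristic adapted to the ARD squared-distance parameterization."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > max_points:
        step = X.shape[0] // max_points + 1
        X = X[::step]
    d2 = (X[:, None, :] - X[None, :, :]) ** 2
    iu = np.triu_indices(X.shape[0], k=1)
    med = np.median(d2[iu], axis=0)
    return np.maximum(med, floor)


def _optimize_block(model: VCGPDM, keys, maxiter: int) -> float:
    """L-BFGS-B over one parameter block; returns the ELBO reached.

    Log-scale parameters get box bounds (e^-25 .. e^25) to keep exploratory
    line-search steps finite; never leaves the model worse than it entered
    (best-so-far guard)."""
    if not keys:
        return model.elbo()
    theta0 = model.pack(keys)
    transforms = {key: tr for key, _, tr in model._param_entries()}
    bounds = []
    for k in keys:
        n = model._get(k).size
        if transforms[k] != "log":
            b = (None, None)
        elif k[0] in ("logbeta", "logvar"):
            # noise and posterior variances: keep well inside the range where
            # the bound evaluation stays numerically trustworthy
            b = (-14.0, 14.0)
        else:
            b = (-25.0, 25.0)
        bounds += [b] * n
    state = {"best_f": None, "best_x": None}

    def objective(theta):
        model.unpack(keys, theta)
        try:
            val, grads = model.elbo_with_grads()
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e300, np.zeros_like(theta)
        if not np.isfinite(val):
            return 1e300, np.zeros_like(theta)
        if state["best_f"] is None or -val < state["best_f"]:
            state["best_f"], state["best_x"] = -val, theta.copy()
        grad = np.concatenate([np.ravel(grads[k]) for k in keys])
        return -val, -grad

    f0, _ = objective(theta0)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": maxiter})
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        warnings.warn(f"optimizer stopped early: {res.message}")
    if state["best_f"] is not None and state["best_f"] <= min(res.fun, f0):
        model.unpack(keys, state["best_x"])
    else:  # pragma: no cover - defensive
        model.unpack(keys, theta0)
    return model.elbo()


def fit(model: VCGPDM, config: TrainingConfig | None = None) -> VCGPDMResults:
    """Joint optimization followed by blocked cycles; see module docstring."""
    if config is None:
        config = TrainingConfig()
    model.initialize()
    trace = [("init", model.elbo())]

    val = _optimize_block(model, model.free_keys(None), config.joint_maxiter)
    trace.append(("joint", val))

    converged = False
    prev = val
    for cycle in range(config.max_cycles):
        for block in config.blocks:
            val = _optimize_block(model, model.free_keys(block),
                                  config.block_maxiter)
            trace.append((f"cycle{cycle}/{block}", val))
        rel = abs(val - prev) / max(1.0, abs(prev))
        if rel < config.tol:
            converged = True
            break
        prev = val
    return VCGPDMResults(model, trace, config=config, converged=converged)
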