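"""The variational coupled Gaussian process dynamical model (vCGPDM).

A vCGPDM is a set of M "parts" — latent autoregressive dynamical systems with
GP-distributed transition and kinematics functions — coupled through
product-of-experts predictions of each other's next latent state.  Part i has
a Q_i-dimensional latent space mapped to its observed columns by a GP with
isotropic noise beta_i; every ordered pair (i, j) carries a coupling GP with
variance alpha^{i,j}.  All GPs are sparsified with inducing points, and the
model is trained by maximizing a fully collapsed evidence lower bound

    ELBO = sum_i L_kin^i + L_dyn

where L_kin^i is the Bayesian-GPLVM bound for part i's kinematics (without
the latent entropy) and L_dyn collects the collapsed PoE dynamics likelihood,
the initial-state cross-entropy and the entropy of q(x), which therefore
enters the ELBO exactly once.

The public surface follows the Model/Results convention: build a
:class:`VCGPDM` from a :class:`~vcgpdm.io.TrajectorySet` (or via
``from_dataframe``), call :meth:`VCGPDM.fit` to obtain a
:class:`VCGPDMResults` carrying the fitted state, ELBO trace, learned
couplings and generation utilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import dynamics as dyn
from . import kernels as kr
from . import variational as vgp
from .io import TrajectorySet, format_column_map, parse_column_map

__all__ = ["LatentPosterior", "PartModel", "VCGPDM", "VCGPDMResults",
           "save", "load", "compose"]

ARCHIVE_VERSION = 1


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior over one part's latent trajectory,
    concatenated across training sequences: mean and variance are (Ttot, Q)."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        self.variance = np.atleast_2d(np.asarray(self.variance, dtype=float))
        if self.mean.shape != self.variance.shape:
            raise ValueError("latent mean/variance shape mismatch")
        if np.any(self.variance <= 0):
            raise ValueError("latent variances must be positive")


@dataclass
class PartModel:
    """One body part: latent space, kinematics GP and its inducing set."""

    index: int
    Q: int
    D: int
    kin_kernel: kr.ArdSeKernel
    kin_inducing: vgp.InducingSet
    beta: float
    latent: LatentPosterior | None = None
    kin_posterior: vgp.InducingPosterior | None = None


class VCGPDM:
    """Variational coupled GPDM model bound to a trajectory dataset.

    Parameters
    ----------
    data : TrajectorySet
        Observed sequences plus the column-to-part assignment.
    latent_dims : int or sequence of int
        Latent dimensionality per part (default 2 each).
    order : int
        Autoregressive order of the latent dynamics (default 2); the coupling
        kernels act on the concatenation of the last ``order`` states.
    n_dyn_ips, n_kin_ips : int
        Inducing-point counts for every coupling GP / kinematics GP.
    seed : int
        Controls inducing-point initialization.
    """

    def __init__(self, data: TrajectorySet, latent_dims=2, order: int = 2,
                 n_dyn_ips: int = 8, n_kin_ips: int = 10, seed: int = 0,
                 jitter: float = 1e-6):
        if order < 1:
            raise ValueError("order must be >= 1")
        if n_dyn_ips < 1 or n_kin_ips < 1:
            raise ValueError("need at least one inducing point per GP")
        self.data = data
        M = data.n_parts
        if np.isscalar(latent_dims):
            latent_dims = [int(latent_dims)] * M
        self.latent_dims = [int(q) for q in latent_dims]
        if len(self.latent_dims) != M:
            raise ValueError("latent_dims must give one dimension per part")
        if any(s < order + 1 for s in data.lengths):
            raise ValueError(f"sequences must have at least order+1={order + 1} frames")
        self.order = int(order)
        self.n_dyn_ips = int(n_dyn_ips)
        self.n_kin_ips = int(n_kin_ips)
        self.seed = int(seed)
        self.jitter = float(jitter)
        self.parts: list[PartModel] = []
        self.couplings: dict = {}
        self.frozen: set = set()
        self._build_time_index()
        self._initialized = False

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(cls, df, parts: str, sequence_col: str | None = None,
                       **kwargs) -> "VCGPDM":
        """Build from a pandas DataFrame of numeric columns.

        ``parts`` is a column-map string like ``"0:0-9,1:10-19"`` (over the
        numeric columns, in order).  If ``sequence_col`` is given, rows are
        split into separate sequences by that column's value.
        """
        if sequence_col is not None:
            groups = [g.drop(columns=[sequence_col]).to_numpy(dtype=float)
                      for _, g in df.groupby(sequence_col, sort=True)]
        else:
            groups = [df.to_numpy(dtype=float)]
        cmap = parse_column_map(parts, groups[0].shape[1])
        names = [c for c in df.columns if c != sequence_col]
        data = TrajectorySet(groups, cmap, names=names)
        return cls(data, **kwargs)

    # ------------------------------------------------------------------ #
    def _build_time_index(self) -> None:
        lengths = self.data.lengths
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.seq_slices = [slice(int(offsets[n]), int(offsets[n + 1]))
                           for n in range(len(lengths))]
        self.Ttot = int(offsets[-1])
        inputs, targets = [], []
        for sl in self.seq_slices:
            for t in range(sl.start + self.order, sl.stop):
                inputs.append(range(t - self.order, t))
                targets.append(t)
        self._ar_inputs = np.array([list(r) for r in inputs], dtype=int)
        self._ar_targets = np.array(targets, dtype=int)
        self.Td = len(targets)

    @property
    def M(self) -> int:
        return self.data.n_parts

    # ------------------------------------------------------------------ #
    def initialize(self) -> "VCGPDM":
        """PCA latent initialization, inducing-point selection and heuristic
        hyperparameter defaults.  Idempotent once called."""
        if self._initialized:
            return self
        from .training import init_latent, init_inducing, median_lengthscales

        rng = np.random.default_rng(self.seed)
        self.parts = []
        for i in range(self.M):
            Q = self.latent_dims[i]
            Y = np.vstack(self.data.part_data(i))
            latent = init_latent(self.data, i, Q)
            lam = median_lengthscales(latent.mean)
            sf = float(max(np.mean(np.var(Y, axis=0)), 1e-8))
            beta = max(0.01 * sf, 1e-8)
            R = init_inducing(latent.mean, self.n_kin_ips,
                              int(rng.integers(2 ** 31)))
            self.parts.append(PartModel(
                index=i, Q=Q, D=Y.shape[1],
                kin_kernel=kr.ArdSeKernel(lam, sf),
                kin_inducing=vgp.InducingSet(R), beta=beta, latent=latent,
            ))
        self.couplings = {}
        for i in range(self.M):
            ar = self._ar_stack(self.parts[i].latent.mean)
            lam = median_lengthscales(ar)
            for j in range(self.M):
                Z = init_inducing(ar, self.n_dyn_ips, int(rng.integers(2 ** 31)))
                self.couplings[(i, j)] = dyn.CouplingGP(
                    source=i, target=j,
                    kernel=kr.ArdSeKernel(lam.copy(), 1.0),
                    inducing=vgp.InducingSet(Z), alpha=1.0,
                )
        self._initialized = True
        return self

    def _ar_stack(self, arr: np.ndarray) -> np.ndarray:
        """(Ttot, Q) -> (Td, order*Q): concatenated past states per target."""
        return arr[self._ar_inputs].reshape(self.Td, -1)

    # ------------------------------------------------------------------ #
    # parameter packing
    def _param_entries(self):
        entries = []
        for i in range(self.M):
            entries += [
                (("mu", i), "latents", "id"),
                (("logvar", i), "latents", "log"),
                (("kin_loglam", i), "hypers", "log"),
                (("kin_logsf", i), "hypers", "log"),
                (("logbeta", i), "hypers", "log"),
                (("R", i), "inducing", "id"),
            ]
        for (i, j) in sorted(self.couplings):
            entries += [
                (("dyn_loglam", i, j), "hypers", "log"),
                (("logalpha", i, j), "hypers", "log"),
                (("Z", i, j), "inducing", "id"),
            ]
        return entries

    def _get(self, key) -> np.ndarray:
        kind = key[0]
        if kind == "mu":
            return self.parts[key[1]].latent.mean
        if kind == "logvar":
            return np.log(self.parts[key[1]].latent.variance)
        if kind == "kin_loglam":
            return np.log(self.parts[key[1]].kin_kernel.lengthscales)
        if kind == "kin_logsf":
            return np.array([np.log(self.parts[key[1]].kin_kernel.variance)])
        if kind == "logbeta":
            return np.array([np.log(self.parts[key[1]].beta)])
        if kind == "R":
            return self.parts[key[1]].kin_inducing.locations
        c = self.couplings[(key[1], key[2])]
        if kind == "dyn_loglam":
            return np.log(c.kernel.lengthscales)
        if kind == "logalpha":
            return np.array([np.log(c.alpha)])
        if kind == "Z":
            return c.inducing.locations
        raise KeyError(key)

    def _set(self, key, value: np.ndarray) -> None:
        kind = key[0]
        if kind == "mu":
            self.parts[key[1]].latent.mean = value
        elif kind == "logvar":
            self.parts[key[1]].latent.variance = np.exp(value)
        elif kind == "kin_loglam":
            self.parts[key[1]].kin_kernel.lengthscales = np.exp(value)
        elif kind == "kin_logsf":
            self.parts[key[1]].kin_kernel.variance = float(np.exp(value[0]))
        elif kind == "logbeta":
            self.parts[key[1]].beta = float(np.exp(value[0]))
        elif kind == "R":
            self.parts[key[1]].kin_inducing.locations = value
        elif kind == "dyn_loglam":
            self.couplings[(key[1], key[2])].kernel.lengthscales = np.exp(value)
        elif kind == "logalpha":
            self.couplings[(key[1], key[2])].alpha = float(np.exp(value[0]))
        elif kind == "Z":
            self.couplings[(key[1], key[2])].inducing.locations = value
        else:
            raise KeyError(key)

    def free_keys(self, group: str | None = None):
        """Parameter keys optimized in a given block (None = all groups),
        minus any frozen by :func:`compose`."""
        return [key for key, g, _ in self._param_entries()
                if (group is None or g == group) and key not in self.frozen]

    def pack(self, keys) -> np.ndarray:
        return np.concatenate([np.ravel(self._get(k)) for k in keys]) \
            if keys else np.zeros(0)

    def unpack(self, keys, theta: np.ndarray) -> None:
        pos = 0
        for k in keys:
            cur = self._get(k)
            n = cur.size
            self._set(k, theta[pos:pos + n].reshape(cur.shape))
            pos += n

    # ------------------------------------------------------------------ #
    def elbo(self) -> float:
        """Total evidence lower bound on log p(Y) at the current parameters."""
        value, _ = self._elbo_core(want_grads=False)
        return value

    def elbo_parts(self) -> dict:
        """ELBO decomposition: per-part kinematics terms and the dynamics term
        (which includes entropy and initial-state contributions)."""
        _, _, decomp = self._elbo_core(want_grads=False, want_decomp=True)
        return decomp

    def elbo_with_grads(self) -> tuple[float, dict]:
        """ELBO and its gradient w.r.t. every parameter key (log-space for
        positives)."""
        return self._elbo_core(want_grads=True)

    def _elbo_core(self, want_grads: bool, want_decomp: bool = False):
        if not self._initialized:
            self.initialize()
        M, order = self.M, self.order
        g = {key: np.zeros_like(self._get(key), dtype=float)
             for key, _, _ in self._param_entries()} if want_grads else None
        total = 0.0
        decomp = {"kin": [], "dyn": None}

        # --- kinematics bounds (no entropy; it lives in the dynamics term)
        for i, part in enumerate(self.parts):
            beliefs = kr.GaussianBelief(part.latent.mean, part.latent.variance)
            Y = np.vstack(self.data.part_data(i))
            if want_grads:
                val, gr = vgp.collapsed_bound_with_grads(
                    Y, part.kin_kernel, part.kin_inducing, beliefs, part.beta,
                    self.jitter)
                g[("mu", i)] += gr["mean"]
                g[("logvar", i)] += gr["variance"] * part.latent.variance
                g[("R", i)] += gr["Z"]
                g[("kin_loglam", i)] += gr["lengthscales"] * part.kin_kernel.lengthscales
                g[("kin_logsf", i)] += gr["signal_variance"] * part.kin_kernel.variance
                g[("logbeta", i)] += gr["noise_variance"] * part.beta
            else:
                val = vgp.collapsed_bound(Y, part.kin_kernel, part.kin_inducing,
                                          beliefs, part.beta, self.jitter)
            total += val
            decomp["kin"].append(val)

        # --- dynamics: psi statistics of every coupling over AR beliefs
        ar_beliefs, stats = [], {}
        for i, part in enumerate(self.parts):
            ar_beliefs.append(kr.GaussianBelief(
                self._ar_stack(part.latent.mean),
                self._ar_stack(part.latent.variance)))
        for (i, j), c in self.couplings.items():
            Z = c.inducing.locations
            P1 = kr.psi1(c.kernel, Z, ar_beliefs[i])
            Phi = kr.psi2(c.kernel, Z, ar_beliefs[i])
            Kuu = kr.gram(c.kernel, Z) \
                + self.jitter * c.kernel.variance * np.eye(Z.shape[0])
            stats[(i, j)] = {"Kuu": Kuu, "Psi1": P1, "Phi": Phi,
                             "psi0": kr.psi0(c.kernel, ar_beliefs[i]),
                             "alpha": c.alpha}

        dyn_total = 0.0
        for j in range(M):
            part = self.parts[j]
            tmu = part.latent.mean[self._ar_targets]
            tvar = part.latent.variance[self._ar_targets]
            experts = [stats[(i, j)] for i in range(M)]
            term = dyn.DynamicsTerm(tmu, tvar, experts)
            dyn_total += term.value
            if want_grads:
                tg = term.grads()
                np.add.at(g[("mu", j)], self._ar_targets, tg["target_mean"])
                np.add.at(g[("logvar", j)], self._ar_targets,
                          tg["target_var"] * tvar)
                for i in range(M):
                    c = self.couplings[(i, j)]
                    Z = c.inducing.locations
                    bel = ar_beliefs[i]
                    dmu1, dvar1, dZ1, dlam1, _ = kr.psi1_backward(
                        c.kernel, Z, bel, tg["Psi1"][i])
                    dmu2, dvar2, dZ2, dlam2, _ = kr.psi2_backward(
                        c.kernel, Z, bel, tg["Phi"][i])
                    gA, gB, dlamK, _ = kr.gram_backward(c.kernel, Z, Z,
                                                        tg["Kuu"][i])
                    g[("Z", i, j)] += dZ1 + dZ2 + gA + gB
                    g[("dyn_loglam", i, j)] += (dlam1 + dlam2 + dlamK) \
                        * c.kernel.lengthscales
                    g[("logalpha", i, j)] += tg["alphas"][i] * c.alpha
                    dmu_ar = (dmu1 + dmu2).reshape(self.Td, order, -1)
                    dvar_ar = (dvar1 + dvar2).reshape(self.Td, order, -1)
                    np.add.at(g[("mu", i)], self._ar_inputs, dmu_ar)
                    np.add.at(g[("logvar", i)], self._ar_inputs,
                              dvar_ar * self.parts[i].latent.variance[self._ar_inputs])

        # --- entropy of q(x) (once, inside the dynamics term) and the
        #     initial-state cross-entropy under unit Gaussian priors
        for i, part in enumerate(self.parts):
            dyn_total += dyn.entropy(part.latent.mean, part.latent.variance)
            if want_grads:
                g[("logvar", i)] += 0.5 * np.ones_like(part.latent.variance)
            for sl in self.seq_slices:
                head = slice(sl.start, sl.start + order)
                dyn_total += dyn.initial_state_term(
                    part.latent.mean[head], part.latent.variance[head])
                if want_grads:
                    g[("mu", i)][head] += -part.latent.mean[head]
                    g[("logvar", i)][head] += -0.5 * part.latent.variance[head]

        total += dyn_total
        decomp["dyn"] = dyn_total
        if want_decomp:
            return float(total), g, decomp
        return float(total), g

    # ------------------------------------------------------------------ #
    def update_posteriors(self) -> None:
        """Compute the optimal inducing-value posteriors at the current
        parameters (kinematics per part, coupling GPs per target part)."""
        for i, part in enumerate(self.parts):
            beliefs = kr.GaussianBelief(part.latent.mean, part.latent.variance)
            Y = np.vstack(self.data.part_data(i))
            part.kin_posterior = vgp.optimal_inducing_posterior(
                Y, part.kin_kernel, part.kin_inducing, beliefs, part.beta,
                self.jitter)
        ar_beliefs = [kr.GaussianBelief(self._ar_stack(p.latent.mean),
                                        self._ar_stack(p.latent.variance))
                      for p in self.parts]
        for j in range(self.M):
            experts = []
            for i in range(self.M):
                c = self.couplings[(i, j)]
                Z = c.inducing.locations
                experts.append({
                    "Kuu": kr.gram(c.kernel, Z)
                    + self.jitter * c.kernel.variance * np.eye(Z.shape[0]),
                    "Psi1": kr.psi1(c.kernel, Z, ar_beliefs[i]),
                    "Phi": kr.psi2(c.kernel, Z, ar_beliefs[i]),
                    "psi0": kr.psi0(c.kernel, ar_beliefs[i]),
                    "alpha": c.alpha,
                })
            term = dyn.DynamicsTerm(
                self.parts[j].latent.mean[self._ar_targets],
                self.parts[j].latent.variance[self._ar_targets], experts)
            for i, post in enumerate(term.coupling_posteriors()):
                self.couplings[(i, j)].posterior = post

    def alphas(self) -> np.ndarray:
        """(M, M) matrix of coupling variances, entry (i, j) = alpha^{i,j}."""
        out = np.zeros((self.M, self.M))
        for (i, j), c in self.couplings.items():
            out[i, j] = c.alpha
        return out

    # ------------------------------------------------------------------ #
    def fit(self, config=None, **kwargs) -> "VCGPDMResults":
        """Maximize the ELBO (joint stage then blocked cycles); see
        :class:`vcgpdm.training.TrainingConfig` for the knobs."""
        from .training import TrainingConfig, fit as _fit

        if config is None:
            config = TrainingConfig(**kwargs)
        return _fit(self, config)


# ---------------------------------------------------------------------- #
class VCGPDMResults:
    """Fitted vCGPDM: final parameters, ELBO trace and generation utilities."""

    def __init__(self, model: VCGPDM, trace, config=None, converged=False):
        self.model = model
        self.trace = list(trace)
        self.config = config
        self.converged = converged
        self.elbo = model.elbo()
        model.update_posteriors()

    @property
    def alphas(self) -> np.ndarray:
        return self.model.alphas()

    def simulate(self, T: int, init_latents=None, init_frames=None):
        """Generate a mean trajectory by iterating the learned dynamics; see
        :func:`vcgpdm.evaluation.rollout`."""
        from .evaluation import rollout

        return rollout(self.model, T, init_latents=init_latents,
                       init_frames=init_frames)

    def save(self, path, include_posterior: bool = False) -> None:
        save(self.model, path, include_posterior=include_posterior)

    def summary(self) -> str:
        m = self.model
        lines = [
            "vCGPDM results",
            "=" * 54,
            f"parts: {m.M}   order: {m.order}   sequences: {len(m.data.sequences)}"
            f"   frames: {m.Ttot}",
            f"ELBO: {self.elbo:.4f}   converged: {self.converged}",
            "",
            f"{'part':>4} {'Q':>3} {'D':>4} {'kin IPs':>8} {'beta':>12} {'signal var':>12}",
        ]
        for p in m.parts:
            lines.append(
                f"{p.index:>4} {p.Q:>3} {p.D:>4} {p.kin_inducing.P:>8} "
                f"{p.beta:>12.4g} {p.kin_kernel.variance:>12.4g}")
        lines.append("")
        lines.append("coupling variances alpha^(i,j) (row = source i, col = target j;"
                     " small = strong influence)")
        A = self.alphas
        header = "      " + "".join(f"{f'j={j}':>12}" for j in range(m.M))
        lines.append(header)
        for i in range(m.M):
            lines.append(f"  i={i} " + "".join(f"{A[i, j]:>12.4g}"
                                               for j in range(m.M)))
        return "\n".join(lines)

    def plot_latents(self, ax=None):
        """Scatter the fitted latent means (first two dims per part)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for p in self.model.parts:
            xy = p.latent.mean[:, :2]
            ax.plot(xy[:, 0], xy[:, 1], label=f"part {p.index}")
        ax.set_xlabel("latent dim 1")
        ax.set_ylabel("latent dim 2")
        ax.legend()
        return ax


# ---------------------------------------------------------------------- #
# serialization: compact archive, storage independent of training length
def save(model: VCGPDM, path, include_posterior: bool = False) -> None:
    """Write the model to a single structured archive (numpy ``.npz``).

    The compact archive stores inducing points and value posteriors, kernel
    and coupling parameters, noise variances, the order and the column map —
    nothing that grows with the training length.  ``include_posterior=True``
    additionally stores the latent posterior so that the ELBO round-trips
    bit-exactly on identical data.
    """
    if any(c.posterior is None for c in model.couplings.values()):
        model.update_posteriors()
    arrays = {}
    meta = {
        "version": ARCHIVE_VERSION,
        "order": model.order,
        "column_map": format_column_map(model.data.column_map),
        "n_columns": model.data.D,
        "latent_dims": model.latent_dims,
        "jitter": model.jitter,
        "include_posterior": bool(include_posterior),
        "M": model.M,
    }
    for p in model.parts:
        i = p.index
        arrays[f"part{i}/R"] = p.kin_inducing.locations
        arrays[f"part{i}/kin_lengthscales"] = p.kin_kernel.lengthscales
        arrays[f"part{i}/kin_variance"] = np.array([p.kin_kernel.variance])
        arrays[f"part{i}/beta"] = np.array([p.beta])
        arrays[f"part{i}/v_mean"] = p.kin_posterior.mean
        arrays[f"part{i}/v_cov"] = p.kin_posterior.covariance
        if include_posterior:
            arrays[f"part{i}/latent_mean"] = p.latent.mean
            arrays[f"part{i}/latent_var"] = p.latent.variance
    for (i, j), c in model.couplings.items():
        pre = f"coupling{i}_{j}/"
        arrays[pre + "Z"] = c.inducing.locations
        arrays[pre + "lengthscales"] = c.kernel.lengthscales
        arrays[pre + "alpha"] = np.array([c.alpha])
        arrays[pre + "u_mean"] = c.posterior.mean
        arrays[pre + "u_cov"] = c.posterior.covariance
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load(path, data: TrajectorySet | None = None) -> VCGPDM:
    """Rebuild a model from :func:`save`'s archive.

    If ``data`` is omitted, a placeholder dataset consistent with the column
    map is attached; generation works either way, while ELBO evaluation needs
    the real training data (and a stored or re-initialized latent posterior).
    """
    with np.load(path) as npz:
        try:
            meta = json.loads(bytes(npz["meta"]).decode())
        except Exception as err:
            raise ValueError(f"corrupted archive {path}: {err}") from err
        if meta.get("version") != ARCHIVE_VERSION:
            raise ValueError(
                f"archive version {meta.get('version')} unsupported "
                f"(expected {ARCHIVE_VERSION})")
        arrays = {k: npz[k] for k in npz.files}
    cmap = parse_column_map(meta["column_map"], meta["n_columns"])
    order = meta["order"]
    if data is None:
        dummy = np.zeros((order + 1, meta["n_columns"]))
        data = TrajectorySet([dummy], cmap)
    model = VCGPDM(data, latent_dims=meta["latent_dims"], order=order,
                   jitter=meta["jitter"])
    M = meta["M"]
    model.parts = []
    for i in range(M):
        Q = meta["latent_dims"][i]
        R = arrays[f"part{i}/R"]
        kern = kr.ArdSeKernel(arrays[f"part{i}/kin_lengthscales"],
                              float(arrays[f"part{i}/kin_variance"][0]))
        if meta["include_posterior"]:
            latent = LatentPosterior(arrays[f"part{i}/latent_mean"],
                                     arrays[f"part{i}/latent_var"])
        else:
            latent = LatentPosterior(np.zeros((model.Ttot, Q)),
                                     0.1 * np.ones((model.Ttot, Q)))
        part = PartModel(
            index=i, Q=Q, D=int(np.sum(cmap == i)), kin_kernel=kern,
            kin_inducing=vgp.InducingSet(R),
            beta=float(arrays[f"part{i}/beta"][0]), latent=latent,
            kin_posterior=vgp.InducingPosterior(arrays[f"part{i}/v_mean"],
                                                arrays[f"part{i}/v_cov"]),
        )
        model.parts.append(part)
    model.couplings = {}
    for i in range(M):
        for j in range(M):
            pre = f"coupling{i}_{j}/"
            model.couplings[(i, j)] = dyn.CouplingGP(
                source=i, target=j,
                kernel=kr.ArdSeKernel(arrays[pre + "lengthscales"], 1.0),
                inducing=vgp.InducingSet(arrays[pre + "Z"]),
                alpha=float(arrays[pre + "alpha"][0]),
                posterior=vgp.InducingPosterior(arrays[pre + "u_mean"],
                                                arrays[pre + "u_cov"]),
            )
    model._initialized = True
    return model


def compose(parts, couplings, data: TrajectorySet, order: int = 2,
            retrain_alphas: bool = True, trainable=(),
            jitter: float = 1e-6) -> VCGPDM:
    """Assemble a vCGPDM from previously learned components.

    ``parts`` is a list of :class:`PartModel` (e.g. a shared lower-body
    movement primitive plus one upper-body variant) and ``couplings`` a dict
    ``(i, j) -> CouplingGP`` covering every ordered pair.  All component
    parameters are frozen except the coupling variances alpha^{i,j} (when
    ``retrain_alphas``) and any parameter kinds listed in ``trainable``
    (e.g. ``("Z",)`` to re-learn dynamics inducing points, or
    ``("mu", "logvar")`` to re-fit the latent posterior on new data).
    """
    import copy

    model = VCGPDM(data, latent_dims=[p.Q for p in parts], order=order,
                   jitter=jitter)
    model.parts = [copy.deepcopy(p) for p in parts]
    model.couplings = {k: copy.deepcopy(c) for k, c in couplings.items()}
    for i, p in enumerate(model.parts):
        p.index = i
        if p.latent is None or p.latent.mean.shape[0] != model.Ttot:
            from .training import init_latent

            p.latent = init_latent(data, i, p.Q)
    model._initialized = True
    allowed = set(trainable) | ({"logalpha"} if retrain_alphas else set())
    model.frozen = {key for key, _, _ in model._param_entries()
                    if key[0] not in allowed}
    return model
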