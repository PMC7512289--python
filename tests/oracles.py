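"""Independent oracles: brute-force / enumeration / closed-form references
that the implementation is checked against.  These deliberately avoid the
package's own computational paths."""

import itertools

import numpy as np


def exact_gp_loglik(Y, X, lengthscales, signal_variance, noise_variance):
    """Dense-covariance GP log marginal likelihood, written from the density
    formula (no shared code with the sparse bound)."""
    Y = np.atleast_2d(Y)
    T, D = Y.shape
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2 / lengthscales, axis=-1)
    K = signal_variance * np.exp(-0.5 * d2) + noise_variance * np.eye(T)
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    Kinv = np.linalg.inv(K)
    return float(
        -0.5 * np.einsum("td,ts,sd->", Y, Kinv, Y)
        - 0.5 * D * logdet - 0.5 * T * D * np.log(2 * np.pi)
    )


def mc_psi(kernel, Z, mean, var, n_samples, rng):
    """Monte-Carlo estimates of psi1/psi2.

    Returns elementwise estimates and standard errors, plus estimates/SEs of
    the entry sums (computed from per-sample aggregates, so the correlations
    between entries are accounted for).  The aggregate is the statistically
    well-posed quantity for a single 3-SE comparison; elementwise SEs serve a
    wider multiple-comparison guard band.
    """
    T, Q = mean.shape
    x = mean[:, None, :] + np.sqrt(var)[:, None, :] * rng.standard_normal(
        (T, n_samples, Q))
    d2 = np.sum((x[:, :, None, :] - Z[None, None, :, :]) ** 2
                / kernel.lengthscales, axis=-1)
    kv = kernel.variance * np.exp(-0.5 * d2)        # (T, N, P)
    psi1_mc = kv.mean(axis=1)
    psi1_se = kv.std(axis=1) / np.sqrt(n_samples)
    s1 = kv.sum(axis=(0, 2))                         # per-sample sum over (t,p)
    outer = np.einsum("tnp,tnq->tpq", kv, kv) / n_samples
    psi2_mc = outer.sum(axis=0)
    per_t_sq = np.einsum("tnp,tnq->tnpq", kv, kv)
    psi2_se = np.sqrt(np.sum(per_t_sq.var(axis=1), axis=0) / n_samples)
    s2 = np.einsum("tnp,tnq->n", kv, kv)             # per-sample sum over (t,p,q)
    return {
        "psi1": psi1_mc, "psi1_se": psi1_se,
        "psi2": psi2_mc, "psi2_se": psi2_se,
        "psi1_sum": float(s1.mean()),
        "psi1_sum_se": float(s1.std() / np.sqrt(n_samples)),
        "psi2_sum": float(s2.mean()),
        "psi2_sum_se": float(s2.std() / np.sqrt(n_samples)),
    }


def enumerate_dtw(a, b):
    """Exhaustive enumeration of ALL monotone alignment paths from (0,0) to
    (n-1,m-1) with diagonal/vertical/horizontal unit steps.

    Returns (min_cost, lengths): the minimum cumulative squared-Euclidean cost
    over every path, and the set of lengths of the paths attaining it (ties
    are common on small alphabets, where any optimal path is acceptable)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n, m = a.shape[0], b.shape[0]
    local = lambda i, j: float(np.sum((a[i] - b[j]) ** 2))

    min_cost = np.inf
    lengths = set()
    stack = [(0, 0, local(0, 0), 1)]
    while stack:
        i, j, c, length = stack.pop()
        if i == n - 1 and j == m - 1:
            if c < min_cost - 1e-12:
                min_cost, lengths = c, {length}
            elif abs(c - min_cost) <= 1e-12:
                lengths.add(length)
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                stack.append((ni, nj, c + local(ni, nj), length + 1))
    return float(min_cost), lengths


def all_sequences(alphabet, max_len):
    """All sequences over the alphabet with lengths 1..max_len."""
    out = []
    for L in range(1, max_len + 1):
        out.extend(itertools.product(alphabet, repeat=L))
    return [np.array(s, dtype=float)[:, None] for s in out]


def product_of_gaussians_on_grid(means, variances, grid):
    """Pointwise product of Gaussian densities, renormalized on the grid."""
    dens = np.ones_like(grid)
    for m, v in zip(means, variances):
        dens = dens * np.exp(-0.5 * (grid - m) ** 2 / v) / np.sqrt(2 * np.pi * v)
    Z = np.trapezoid(dens, grid)
    dens = dens / Z
    mean = np.trapezoid(grid * dens, grid)
    var = np.trapezoid((grid - mean) ** 2 * dens, grid)
    return dens, float(mean), float(var)


def mc_dynamics_ell(target_mu, target_var, experts_raw, u_mean, u_cov,
                    alphas, n_samples, rng):
    """Monte-Carlo estimate of the expected log product-of-experts likelihood.

    Samples latent AR inputs and targets from q(x), stacked inducing values
    from q(u), coupling-function values from their sparse GP conditionals, and
    averages the log of the normalized PoE density.  ``experts_raw`` is a list
    of dicts with keys kernel, Z, ar_mu, ar_var, and G (inv of jittered Kuu).
    Returns (estimate, standard_error).
    """
    Td, Q = target_mu.shape
    alphas = np.asarray(alphas, dtype=float)
    aj = 1.0 / np.sum(1.0 / alphas)
    N = n_samples
    Ptot = u_mean.shape[0]
    Lu = np.linalg.cholesky(u_cov + 1e-12 * np.eye(Ptot))
    u = u_mean[None] + np.einsum(
        "pr,nrq->npq", Lu, rng.standard_normal((N, Ptot, Q)))
    x_t = target_mu[None] + np.sqrt(target_var)[None] \
        * rng.standard_normal((N, Td, Q))

    offset = 0
    poe_sum = np.zeros((N, Td, Q))
    for e, alpha in zip(experts_raw, alphas):
        Z, G, kern = e["Z"], e["G"], e["kernel"]
        P = Z.shape[0]
        xbar = e["ar_mu"][None] + np.sqrt(e["ar_var"])[None] \
            * rng.standard_normal((N, Td, e["ar_mu"].shape[1]))
        d2 = np.sum((xbar[:, :, None, :] - Z[None, None, :, :]) ** 2
                    / kern.lengthscales, axis=-1)
        kx = kern.variance * np.exp(-0.5 * d2)                # (N, Td, P)
        ui = u[:, offset:offset + P, :]                        # (N, P, Q)
        mean_f = np.einsum("ntp,pr,nrq->ntq", kx, G, ui)
        var_f = kern.variance - np.einsum("ntp,pr,ntr->nt", kx, G, kx)
        var_f = np.maximum(var_f, 0.0)
        f = mean_f + np.sqrt(var_f)[:, :, None] \
            * rng.standard_normal((N, Td, Q))
        poe_sum += f / alpha
        offset += P
    poe_mean = aj * poe_sum
    ll = -0.5 * np.sum((x_t - poe_mean) ** 2, axis=(1, 2)) / aj \
        - 0.5 * Td * Q * np.log(2 * np.pi * aj)
    return float(ll.mean()), float(ll.std() / np.sqrt(N))
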