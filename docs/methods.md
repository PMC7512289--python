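# Methods

## The model

A vCGPDM describes multivariate trajectories (e.g. joint angles of a moving
body) as M interacting "parts". Part i carries a Q_i-dimensional latent state
x^i_t evolving in discrete time with autoregressive order o (default 2), and
D_i observed columns

    y^i_t = g^i(x^i_t) + noise,      noise ~ N(0, beta_i I),

with the components of g^i drawn from a GP prior (RBF kernel with trainable
signal variance).  Parts interact through M x M coupling functions: part i
predicts part j's next state through f^{i,j}(x^i_{t-o}, ..., x^i_{t-1}) with
coupling variance alpha^{i,j}.  The components of f^{i,j} are GP-distributed
with an ARD squared-exponential kernel of unit amplitude over the stacked
o * Q_i past states (so the coupling variances, not the kernels, set the
prediction scales).  The predictions are fused by a normalized product of
experts,

    p(x^j_t | f, alpha) = N(alpha_j sum_i f^{i,j}_t / alpha^{i,j},  alpha_j I),
    alpha_j = (sum_i 1 / alpha^{i,j})^{-1},

so a *small* alpha^{i,j} means a *strong* influence of part i on part j, and
the fused prediction is the precision-weighted average of the experts.  The
first o latent states of every sequence have independent unit-Gaussian priors.

## The variational bound

Exact inference is intractable; the posterior over latent trajectories is
approximated by a Gaussian that factorizes over parts, time steps and latent
dimensions, q(x) = prod N(mu^i_{t,q}, sigma^2 i_{t,q}).  Every GP is
sparsified with inducing points (variational parameters) and inducing values
(random, with the GP prior): r/v for kinematics, z^{i,j}/u^{i,j} for the
couplings.  The resulting evidence lower bound decomposes as

    ELBO = sum_i L_kin^i + L_dyn.

L_kin^i is the collapsed Bayesian-GPLVM regression bound for part i's
observed columns given q(x^i): with psi statistics psi0, Psi1, Phi (the
closed-form expectations of the kernel under q) and W = Kuu + Phi/beta,

    L_kin = -TD/2 log(2 pi beta) - |Y|^2/(2 beta)
            + tr(W^-1 Psi1' Y Y' Psi1)/(2 beta^2)
            + D/2 (log|Kuu| - log|W|)
            - D/(2 beta) (psi0 - tr(Kuu^-1 Phi)).

L_dyn handles the coupled transitions.  Under the factorized q the expected
log PoE likelihood of target part j is *quadratic* in the stacked inducing
values U_j = (u^{1,j}, ..., u^{M,j}): writing G_i = Kuu_i^{-1},

    E[log PoE] = const + sum_q ( b_q' U_q - 1/2 U_q' A U_q ),
    b_i  = G_i Psi1_i' mu^j / alpha^{i,j},
    A_ii = (alpha_j / alpha_{i,j}^2) G_i Phi_i G_i,
    A_ik = (alpha_j / (alpha_{i,j} alpha_{k,j})) G_i Psi1_i' Psi1_k G_k  (i != k),
    const = -Td Q_j/2 log(2 pi alpha_j) - sum(mu^2 + sigma^2)/(2 alpha_j)
            - (alpha_j Q_j / 2) sum_i (psi0_i - tr(G_i Phi_i)) / alpha_{i,j}^2.

Three structural facts make this exact rather than approximate given q:
(1) q factorizes over time, so the target x^j_t is independent of the
autoregressive inputs (which only involve earlier steps); (2) q factorizes
over parts, so cross-expert second moments factor into products of Psi1 rows,
while same-expert squares produce Psi2; (3) the sparse GP conditionals
contribute their expected conditional variance, the psi0 - tr(G Phi) deficit.
Optimizing over the joint Gaussian q(U_j) in closed form (a Gaussian integral
against the block-diagonal GP prior K) collapses the bound to

    L_dyn^j = const + 1/2 sum_q b_q' (K^-1 + A)^-1 b_q - Q_j/2 log|I + K A|,

and the optimal posterior q(U_j) = N((K^-1+A)^-1 b, (K^-1+A)^-1) is what
generation uses.  L_dyn additionally carries the initial-state cross-entropy
and the entropy of q(x), which therefore enters the ELBO exactly once (it is
deliberately excluded from L_kin to avoid double counting).  The closed form
is validated against Monte-Carlo estimates of the expected log likelihood in
the test-suite.

## Gradients and optimization

No automatic-differentiation framework is used: all gradients are analytic.
Each psi statistic and Gram matrix has a hand-derived vector-Jacobian product;
the two bounds expose gradients with respect to their direct inputs, and the
model chains them into the latent moments, kernel parameters, coupling
variances and inducing locations.  Every positive parameter (lengthscales,
signal/noise/coupling variances, latent variances) is optimized in log space;
finite-difference agreement to better than 1e-4 relative error is part of the
test-suite.  The bound evaluation is arranged so the inducing-Gram log
determinants cancel analytically (triangular-solve form), which keeps the
full-capacity case numerically exact; Cholesky factorizations add an
escalating diagonal jitter (1e-6 of the mean diagonal, up to 1e-4).

Training initializes the latent means with the first Q PCA scores of each
part's columns, standardized to unit variance per dimension (posterior
variances at 0.1).  The standardization matters: the coupling kernels have
unit amplitude and the initial states unit-Gaussian priors, so the model's
priors assume O(1) latents.  Raw PC scores live on the eigenvalue scale
(variances of 10+ are common); at that scale the inducing-value KL shrinks
the transition means toward zero and closed-loop rollouts spiral into a
contracted attractor.  Inducing points start as a time-stratified subsample
of the initial latent trajectory, lengthscales from a per-dimension median
heuristic, the noise variance at 1% of the data variance, and all coupling
variances at 1.  Optimization is L-BFGS-B: one joint stage over all
parameters (at most 500 iterations by default), then up to 4 cycles of
blocked optimization over three groups — latents, kernel+coupling parameters,
inducing points — with the ELBO recorded after every block and convergence
declared when a cycle changes it by less than 1e-6 relative.  Log parameters
are box-bounded (+-25; +-14 for noise and latent variances, inside which the
bound evaluation is numerically trustworthy), and each block keeps its
best-so-far iterate, so the trace is non-decreasing by construction.

Multiple training sequences are concatenated; the autoregressive statistics
skip the first `order` steps of each sequence and each sequence contributes
its own initial-state term.

## Generation and evaluation

Trajectories are generated by iterating the *mean* dynamics (no sampling):
each coupling contributes its sparse predictive mean at the source part's
stacked past states, the experts are PoE-combined with the learned alphas, and
latent means are pushed through the kinematics predictive mean.  Held-out
evaluation initializes from the first `order` frames of the held-out trial by
minimizing the kinematics reconstruction error over the latent point.

Generated and reference trajectories are compared with dynamic time warping:
symmetric step pattern (diagonal/horizontal/vertical, unit weights), no
window, squared-Euclidean local cost; the score is the accumulated cost along
the optimal path divided by path length *and* by the number of degrees of
freedom (the mean squared error per frame and per column — averaging over
columns as well as time is a documented choice, since either convention only
rescales comparisons by a constant).  Cross-validation is leave-one-trial-out
(or k-fold over trials), reporting the mean and standard error over folds.

## Synthetic study conditions

The generator draws two transition functions g1, g2 : R^2 -> R^2 from a GP
prior (RBF kernel) and iterates first-order coupled systems at T = 300 steps
(scaled study: 150): x^1_t = g1(x^1_{t-1}) and
x^2_t = 0.1 g1(x^1_{t-1}) + 0.9 g2(x^2_{t-1}), so part 1 is autonomous and
part 2 weakly driven.  Each part is observed through 10 GP-drawn functions of
its (unit-variance-scaled) latent trajectory plus isotropic noise 1e-4.  GP
draws are realized by incremental conditioning on all previous evaluations,
so each draw is one consistent function.  Transition and observation
lengthscales default to 1 in squared-distance units on unit-scaled
coordinates: at this scale the drawn maps are near the boundary between
contraction and expansion, where the bounded limit-cycle behaviour that makes
the coupled-dynamics task meaningful is the typical non-degenerate outcome.
Draws that diverge or collapse to a fixed point (leaving no dynamics to
identify) are rejected with re-seed advice; `valid_seeds` scans seeds in
order, so replicate studies are reproducible from a base seed.

The generator's latents are first-order while the fitted models are
second-order, deliberately: the model class does not contain the generator.
What passing the synthetic study shows is that the collapsed bound can be
optimized, that learning improves closed-loop generation, and that the PoE
coupling variances recover the built-in asymmetry (alpha^{2,1} >>
alpha^{1,1}).  It does not show robustness to real movement data's
properties — strong observation noise, nonstationarity, shared skeletal
constraints across parts — and the *magnitudes* of fitted alphas on the weakly
coupled side are draw-specific and not stable across seeds.

## Scaled problem sizes

The replicated study behind `scripts/acceptance.py` uses T = 150, three
replicate seeds, 8 dynamics / 10 kinematics inducing points for the main
comparison and 10-vs-4 dynamics IPs for the capacity comparison, with the
optimizer capped at 400 joint iterations and 3 blocked cycles of 120
iterations per block — problem sizes chosen so the whole study re-runs from
scratch in a few minutes on one CPU while leaving every qualitative
conclusion intact.

## Serialization and modular reuse

A fitted model is stored as a single `.npz` archive holding, per part, the
kinematics inducing points, kernel parameters, noise variance and the optimal
inducing-value posterior, and per ordered part pair the coupling inducing
points, kernel lengthscales, coupling variance and inducing-value posterior,
plus a JSON metadata record (format version, order, column map).  Nothing in
the compact archive grows with the training length; `include_posterior=True`
additionally stores the latent posterior so the ELBO round-trips bit-exactly
on identical data.  `compose()` assembles a model from previously learned
parts and couplings — e.g. one shared lower-body primitive and interchangeable
upper-body variants — freezing all component parameters except the coupling
variances (and any explicitly listed groups), which are re-learned on the
composition data.

## Known limitations

- The factorized q ignores temporal posterior correlations; the bound can be
  loose for strongly stochastic dynamics (the mean rollout is still accurate
  when the learned dynamics are near-deterministic).
- Couplings that explain little variance are unidentifiable up to rescaling
  against the GP amplitudes; only strong asymmetries are reliably recovered.
- Rollout propagates means only; no uncertainty propagation through time.
- Training cost is linear in T but cubic in inducing-point counts, and the
  blocked optimizer is sensitive to initialization like any nonconvex fit.
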