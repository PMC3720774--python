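# Methods

## Model

BACON (BAyesian Clustering Over Networks) couples a linear-Gaussian dynamic
Bayesian network with a Gaussian-mixture clustering of genes and fits both
jointly. Given K clusters and G genes, each of S independent time-course
series carries its own latent cluster-expression trajectory
x_t ∈ R^K (t = 1..T) obeying

    x_{t+1} = B x_t + d + η_t,          η_t ~ N(0, diag(ρ)^{-1})

where B is the K×K transition matrix whose (k, j) element maps cluster j at
time t to cluster k at time t+1, and d is a per-cluster trend absorbing
linear drifts so they are not mistaken for interactions. Each gene i
belongs to exactly one cluster z_i; every observation (and technical
replicate) of gene i at time t is its cluster's expression plus measurement
noise:

    y_{i,t} = x_{z_i, t} + ε,           ε ~ N(0, 1/τ).

B, d and the memberships z are shared across all series from the same
network; the state trajectories, the scalar observation precision τ and the
diagonal state-noise precision vector ρ are per-series. Priors: zero-mean
normals with per-element precisions on every element of B, d and the
initial state (the precisions are re-estimated against the evidence —
automatic relevance determination); Gamma(a0, b0) on τ and each ρ_j;
uniform over the K clusters for each z_i.

The observation equation deliberately has no gene-specific offset or gain.
To make that tenable, each gene is standardized to zero mean and unit
variance within each series before fitting; the transform is recorded and
invertible. Time stamps are read but the dynamics treat steps as uniform
(a discrete-time map), which matches evenly sampled benchmark series.

## Inference

The posterior is approximated by a fully factorized variational family:
one multivariate normal per state vector x_t per series (per-timepoint
factorization, not a structured smoother — this keeps coordinate updates in
closed form and the evidence lower bound (ELBO) monotone, at the cost of
discarding posterior temporal cross-covariances), one multivariate normal
per augmented dynamics row (B_j, d_j) (rows are independent because the
state-noise precision matrix is diagonal), one categorical per gene, and
gammas for τ and each ρ_j. Cross-moments such as E[x_{t+1,j} x_{k,t}]
factorize as products of means, forced by the family.

A sweep updates, in order: states, dynamics rows, memberships, precisions,
and finally the ARD prior precisions (set to their evidence-maximizing
fixed point 1/E[param²], clipped to [1e-6, 1e6] so pruned elements cannot
collapse the numerics). Every step is the exact coordinate-ascent optimum
given the other factors, so the ELBO never decreases; the fit stops when
the relative ELBO change drops below `rel_tol` (default 1e-6) or after
`max_sweeps` (default 2000). Fits abort with a diagnostic naming the
offending factor if the ELBO turns non-finite.

Model selection runs the fit over a grid of cluster counts with several
random restarts each (the protocol uses 10 restarts by default, exposed as
`--restarts`) and accepts the single fit with the highest final ELBO as the
marginal-likelihood surrogate; no model averaging. `likelihood_gap` reports
how far the best competitor at a different K falls short — a diagnostic
only, never used for selection.

### Initialization

Each restart draws a seeded random round-robin partition of the genes
(every cluster non-empty). State means start at the partition centroids of
the standardized series plus small jitter, and the responsibilities start
one-hot on that same partition. Starting the responsibilities at the
uniform 1/K instead is tempting but destructive: the sweep updates states
first, and under uniform responsibilities the observation message pulls
every cluster centroid to the global gene mean, after which all restarts
converge to the same merged-cluster optimum. Dynamics rows start at their
prior; gamma factors start at theirs.

### Edge ranking

Memberships are hardened by argmax responsibility (ties to the lowest
cluster index). Each directed cluster pair j→k is scored by the posterior
mean of the corresponding transition element divided by its posterior
standard deviation; the signed score is copied to every ordered gene pair
across (and within) the two clusters, self-pairs excluded, and pairs are
ranked by absolute score with lexicographic tie-breaks. A flag can instead
zero out within-cluster pairs. With K = G the ranking reduces exactly to a
non-clustering dynamic network ranking, and the dedicated no-clustering
mode is implemented as K = G with memberships clamped to the identity, so
the two paths are one code path and agree byte-for-byte.

### Evaluation

AUROC uses the tie-averaged Mann–Whitney convention on the |score|
ranking; AUPR is step-wise average precision with no interpolation across
recall gaps (both via scikit-learn). Gold standards are unsigned, so the
metric ignores the sign; a ranking must cover exactly the G·(G−1)
candidate pairs and a gold standard must contain at least one true edge
and one negative.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `K` | — | number of clusters (swept 1..G by default) |
| `rel_tol` | 1e-6 | relative ELBO change stopping rule |
| `max_sweeps` | 2000 | sweep cap per fit |
| `a0`, `b0` | 1.0 | gamma prior shape/rate on τ and ρ (precision scale 1 on standardized data) |
| `ard_init` | 1.0 | initial prior precision on dynamics/initial-state elements |
| `ard_bounds` | [1e-6, 1e6] | clip range for evidence-maximized precisions |
| restarts | 10 | random initializations per K (CLI default) |

The gamma hyperprior default is the unit-information Gamma(1, 1), not a
near-improper broad gamma. This is a considered choice: with shape and
rate near zero the objective acquires a degenerate optimum in which a
flatlined state trajectory drives a state-noise precision to the 1/b0
ceiling and collects an essentially unbounded 0.5·(T−1)·E[log ρ] evidence
reward. That artifact systematically favored K = 1 and inverted model
selection on uncorrelated data. On standardized data, precision scale 1 is
the natural unit-information choice; both parameters remain exposed in
`HyperPriors`.

## Synthetic data generator

`simulate` draws a sparse ±`coeff_magnitude` off-diagonal transition matrix
at `edge_density`, a positively biased diagonal (persistence), rescales to
spectral radius ≤ `spectral_cap` (0.9), draws a trend of scale
`trend_scale`, assigns memberships round-robin then shuffles (every
cluster non-empty), rolls the dynamics from x_1 ~ N(0, I) with state noise,
and emits per-gene observations with technical noise. Defaults (K=3, G=12,
T=20, 5 series, 1 replicate, state and observation noise sd 0.1 on
unit-scale trajectories, i.e. signal-to-noise about 10) mirror the 10-gene
benchmark scale the model targets: ~20 evenly spaced time points and a
handful of independent series per network. The emitted gold standard marks
every ordered gene pair whose cluster-pair transition coefficient is
nonzero — exactly the estimand of the clustered model; with K = G it is a
conventional gene-level network. `dream4_like_fixture` fixes the
10-gene × 20-time-point × 5-series shape with a gene-level network.

What the generator does not emulate: the nonlinear ODE kinetics,
saturation and perturbation designs of the DREAM4 simulator, gene-specific
observation gains, missing values, and non-uniform sampling. Tests passing
on this generator therefore demonstrate correct inference under the
model's own assumptions, not performance on kinetic benchmark data.

## Study sizes used by tests and the acceptance script

Desk-scale runs use: membership recovery and selection on K=3, G=12, T=20,
2 series with 5 restarts over K ∈ 1..6; end-to-end edge recovery on 5
series with 3 restarts over K ∈ {2,3,4}; the uncorrelated-profile
selection arm uses G=6 independent AR(1) cluster trajectories (diagonal
transition with persistence 0.5, state noise sd 0.2, 5 series). The
independent-profile arm intentionally uses smooth, mutually independent
trajectories rather than temporally white ones: white profiles are
maximally unpredictable, and under the per-timepoint mean-field family a
dynamic network model gains nothing from tracking them, so no cluster
count is preferred over K = 1 there — uncorrelatedness across genes, not
whiteness in time, is the property of interest.

## Numerical notes

- Covariances are symmetrized after every inversion; log-determinants via
  `slogdet` with a hard error if positive definiteness is lost.
- Responsibility rows are normalized with log-sum-exp; rows sum to 1
  within 1e-12.
- Per-(K, restart) seeds derive from the base seed through
  `numpy.random.SeedSequence([base, K, restart])`, so sweeps are
  reproducible and order-independent.
- Degenerate (empty) clusters keep prior-driven updates; nothing is
  deleted mid-fit, keeping ELBO comparisons across K clean.
- Constant genes standardize with scale 1 instead of 0.

## Known limitations

- The per-timepoint mean-field family underestimates evidence more for
  models that must track unpredictable trajectories; comparisons across K
  inherit that bias (mitigated, not removed, by the unit-information
  prior).
- τ is a per-series scalar; per-gene observation precision is out of
  scope.
- Hard memberships for ranking discard residual membership uncertainty;
  soft-weighted ranking is exposed only at the cluster-score level.
- The two-regulator module treats its noise precision as known; it exists
  as the analytic oracle for the engine, not as a user-facing estimator.
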