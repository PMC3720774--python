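"""Coordinate-ascent variational Bayes for the clustered dynamic network model.

Model
-----
K latent cluster expression trajectories per series follow linear dynamics

    x_{t+1} = B x_t + d + eta_t,     eta_t ~ N(0, diag(rho)^{-1})

with a K x K transition matrix B (shared across series), a trend vector d
(shared) absorbing linear drifts, and per-series diagonal state-noise
precision rho.  Each gene i belongs to exactly one cluster z_i (shared across
series, uniform prior over K), and every observation/replicate of gene i at
time t is its cluster's expression plus technical noise with per-series
precision tau:

    y_{i,t} = x_{z_i, t} + eps,      eps ~ N(0, 1/tau).

Rows (B_j, d_j) carry zero-mean normal priors with per-element precisions
(automatic relevance determination) re-estimated against the evidence; tau
and every rho_j carry broad Gamma(a0, b0) priors; the initial state x_1
carries a zero-mean normal prior with per-element evidence-tuned precision.

Inference
---------
The posterior is approximated by a fully factorized distribution: one
multivariate normal per state vector x_t (per series), one per augmented
dynamics row (B_j, d_j), a categorical per gene membership, and gammas for
tau and rho.  Each update below is the exact coordinate-ascent optimum of
the evidence lower bound (ELBO) given the other factors, so the ELBO is
non-decreasing across updates; the prior precisions are point estimates set
to their ELBO-maximizing fixed point 1/E[param^2] and clipped.  The final
ELBO is the marginal-likelihood lower bound used for model selection.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Sequence

import numpy as np
from scipy.special import digamma, gammaln

from .formats_io import SeriesTable, TimeSeriesSet
from .linear_model_core import HyperPriors

__all__ = [
    "ModelConfig",
    "PosteriorState",
    "NumericalError",
    "standardize",
    "init_posterior",
    "update_states",
    "update_dynamics",
    "update_memberships",
    "update_precisions",
    "update_hyperparameters",
    "compute_elbo",
    "fit",
    "fit_no_clustering",
    "hard_memberships",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class NumericalError(RuntimeError):
    """Raised when a fit produces non-finite quantities."""


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Fit configuration: cluster count, stopping rule, seed, hyper-priors.

    ``clamp_memberships`` fixes the gene->cluster map (one-hot
    responsibilities, never updated); with K equal to the number of genes and
    an identity clamp this is the plain non-clustering dynamic network.
    """

    K: int
    max_sweeps: int = 2000
    rel_tol: float = 1e-6
    seed: int = 0
    hyper: HyperPriors = dataclasses.field(default_factory=HyperPriors)
    clamp_memberships: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.max_sweeps < 0:
            raise ValueError("max_sweeps must be >= 0")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.clamp_memberships is not None:
            object.__setattr__(self, "clamp_memberships",
                               tuple(int(c) for c in self.clamp_memberships))
            if any(c < 0 or c >= self.K for c in self.clamp_memberships):
                raise ValueError("clamped memberships must lie in 0..K-1")


@dataclasses.dataclass
class PosteriorState:
    """All variational factor parameters plus the ELBO trace for one fit.

    Shapes: ``beta_mean`` (K, K+1) holds the posterior mean of the augmented
    row (B_{j,1..K}, d_j); ``beta_cov`` (K, K+1, K+1) its row covariances
    (rows independent because the state-noise precision is diagonal).
    ``x_mean[s]`` is (K, T_s), ``x_cov[s]`` (T_s, K, K).  ``resp`` (G, K)
    rows sum to one.  ``tau_a/tau_b`` (S,), ``rho_a/rho_b`` (S, K) are gamma
    shape/rate.  ``ard_beta`` (K, K+1) and ``ard_x1`` (S, K) are the current
    point-estimate prior precisions.
    """

    beta_mean: np.ndarray
    beta_cov: np.ndarray
    x_mean: list[np.ndarray]
    x_cov: list[np.ndarray]
    resp: np.ndarray
    tau_a: np.ndarray
    tau_b: np.ndarray
    rho_a: np.ndarray
    rho_b: np.ndarray
    ard_beta: np.ndarray
    ard_x1: np.ndarray
    elbo_trace: list[float]
    config: ModelConfig
    gene_names: list[str]
    n_sweeps: int = 0
    converged: bool = False

    @property
    def K(self) -> int:
        return self.config.K

    @property
    def n_series(self) -> int:
        return len(self.x_mean)

    def copy(self) -> "PosteriorState":
        return copy.deepcopy(self)

    # expectation helpers -------------------------------------------------

    def e_tau(self) -> np.ndarray:
        return self.tau_a / self.tau_b

    def e_log_tau(self) -> np.ndarray:
        return digamma(self.tau_a) - np.log(self.tau_b)

    def e_rho(self) -> np.ndarray:
        return self.rho_a / self.rho_b

    def e_log_rho(self) -> np.ndarray:
        return digamma(self.rho_a) - np.log(self.rho_b)

    def beta_second_moment(self) -> np.ndarray:
        """E[(B_j,d_j)(B_j,d_j)^T] per row, shape (K, K+1, K+1)."""
        m = self.beta_mean
        return np.einsum("ja,jb->jab", m, m) + self.beta_cov


def hard_memberships(state: PosteriorState) -> np.ndarray:
    """Argmax cluster per gene; ties break to the lowest cluster index."""
    return np.argmax(state.resp, axis=1)


# ---------------------------------------------------------------------------
# preprocessing


def standardize(data: TimeSeriesSet) -> tuple[TimeSeriesSet, list[dict]]:
    """Standardize each gene to zero mean / unit variance within each series.

    The per-gene mean and standard deviation are computed across all
    replicates of the series and recorded so the transform is invertible.
    Constant genes keep scale 1.  Returns the standardized set and the
    per-series transform records.
    """
    out_series = []
    records = []
    for table in data.series:
        stacked = np.stack(table.all_replicates())  # (R, G, T)
        mean = stacked.mean(axis=(0, 2))
        sd = stacked.std(axis=(0, 2))
        sd = np.where(sd > 0, sd, 1.0)
        transformed = (stacked - mean[None, :, None]) / sd[None, :, None]
        out_series.append(SeriesTable(
            gene_names=list(table.gene_names),
            time_points=table.time_points.copy(),
            values=transformed[0],
            replicate_values=[transformed[r] for r in range(1, transformed.shape[0])] or None,
        ))
        records.append({"mean": mean, "sd": sd})
    return TimeSeriesSet(series=out_series, network_id=data.network_id), records


def _series_obs(data: TimeSeriesSet) -> list[np.ndarray]:
    """Observations per series as (R, G, T) arrays."""
    return [np.stack(t.all_replicates()) for t in data.series]


# ---------------------------------------------------------------------------
# initialization


def init_posterior(data: TimeSeriesSet, config: ModelConfig) -> PosteriorState:
    """Seeded random initialization of every variational factor.

    State means start at the centroids of a random partition of the gene
    series (plus small jitter); responsibilities start one-hot on that same
    partition (or at the clamp), so the centroid structure survives the
    first observation-weighted state update instead of collapsing every
    cluster onto the global mean.  Dynamics start at the prior, and the
    gamma factors at their priors.  Deterministic given ``config.seed``.
    """
    G = data.n_genes
    K = config.K
    if K > G:
        raise ValueError(f"K={K} exceeds the number of genes G={G}")
    if config.clamp_memberships is not None and len(config.clamp_memberships) != G:
        raise ValueError("clamp_memberships length must equal the number of genes")
    hyper = config.hyper
    rng = np.random.default_rng(config.seed)
    S = len(data.series)

    partition = np.empty(G, dtype=int)
    perm = rng.permutation(G)
    for k in range(K):
        partition[perm[k::K]] = k  # round-robin over a random order: non-empty

    x_mean, x_cov = [], []
    for table in data.series:
        T = table.n_times
        Ybar = np.stack(table.all_replicates()).mean(axis=0)  # (G, T)
        centroids = np.zeros((K, T))
        for k in range(K):
            centroids[k] = Ybar[partition == k].mean(axis=0)
        x_mean.append(centroids + 0.01 * rng.standard_normal((K, T)))
        x_cov.append(np.broadcast_to(0.1 * np.eye(K), (T, K, K)).copy())

    resp = np.zeros((G, K))
    if config.clamp_memberships is not None:
        resp[np.arange(G), list(config.clamp_memberships)] = 1.0
    else:
        resp[np.arange(G), partition] = 1.0

    ard_beta = np.full((K, K + 1), hyper.ard_init)
    beta_mean = np.zeros((K, K + 1))
    beta_cov = np.stack([np.diag(1.0 / ard_beta[j]) for j in range(K)])

    return PosteriorState(
        beta_mean=beta_mean,
        beta_cov=beta_cov,
        x_mean=x_mean,
        x_cov=x_cov,
        resp=resp,
        tau_a=np.full(S, hyper.a0),
        tau_b=np.full(S, hyper.b0),
        rho_a=np.full((S, K), hyper.a0),
        rho_b=np.full((S, K), hyper.b0),
        ard_beta=ard_beta,
        ard_x1=np.full((S, K), hyper.ard_init),
        elbo_trace=[],
        config=config,
        gene_names=list(data.gene_names),
    )


# ---------------------------------------------------------------------------
# coordinate updates (each is the exact optimum given the other factors and
# mutates the state in place, returning it)


def update_states(state: PosteriorState, data: TimeSeriesSet) -> PosteriorState:
    """Refresh q(x_t) for every series and time point (forward sequential).

    Each q(x_t) combines the dynamics message from t-1, the reversed dynamics
    message from t+1 (or the initial-state prior at t=1), and the
    responsibility-weighted observation message.
    """
    K = state.K
    e_tau = state.e_tau()
    e_rho = state.e_rho()
    Bm = state.beta_mean[:, :K]            # (K, K) rows = target clusters
    dm = state.beta_mean[:, K]             # (K,)
    M2 = state.beta_second_moment()        # (K, K+1, K+1)
    obs = _series_obs(data)

    for s, Y in enumerate(obs):
        T = Y.shape[2]
        m = state.x_mean[s]
        V = state.x_cov[s]
        rho = e_rho[s]
        # reversed-message precompute: sum_j rho_j * E[B_j B_j^T] and the
        # constant part of the linear term sum_j rho_j (B_j d_j cross-moment)
        W_rev = np.einsum("j,jab->ab", rho, M2[:, :K, :K])          # (K, K)
        cross = np.einsum("j,ja->a", rho, M2[:, :K, K])             # (K,) E[B_j d_j]
        A = rho[:, None] * Bm                                        # (K, K)
        # observation sufficient stats
        Nk = state.resp.sum(axis=0) * Y.shape[0]                     # (K,)
        Ysum = np.einsum("ik,rit->kt", state.resp, Y)                # (K, T)
        obs_prec = e_tau[s] * Nk
        for t in range(T):
            P = np.diag(obs_prec.copy())
            h = e_tau[s] * Ysum[:, t]
            if t == 0:
                P[np.diag_indices(K)] += state.ard_x1[s]
            else:
                P[np.diag_indices(K)] += rho
                h = h + rho * (Bm @ m[:, t - 1] + dm)
            if t < T - 1:
                P = P + W_rev
                h = h + A.T @ m[:, t + 1] - cross
            cov = np.linalg.inv(P)
            cov = 0.5 * (cov + cov.T)
            m[:, t] = cov @ h
            V[t] = cov
    return state


def _transition_stats(state: PosteriorState) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-series E[w_t w_t^T] stacks and mean targets for transitions.

    Returns ``(Eww, wbar)`` with ``Eww[s]`` of shape (T-1, K+1, K+1) and
    ``wbar[s]`` of shape (T-1, K+1), where w_t = (x_t, 1).
    """
    K = state.K
    Eww_all, wbar_all = [], []
    for s in range(state.n_series):
        m = state.x_mean[s]
        V = state.x_cov[s]
        T = m.shape[1]
        wbar = np.concatenate([m[:, :-1].T, np.ones((T - 1, 1))], axis=1)
        Eww = np.einsum("ta,tb->tab", wbar, wbar)
        Eww[:, :K, :K] += V[:-1]
        Eww_all.append(Eww)
        wbar_all.append(wbar)
    return Eww_all, wbar_all


def update_dynamics(state: PosteriorState, data: TimeSeriesSet) -> PosteriorState:
    """Refresh q(B_j, d_j) per row, pooling transitions from all series."""
    K = state.K
    e_rho = state.e_rho()
    Eww, wbar = _transition_stats(state)
    Sww = [e.sum(axis=0) for e in Eww]                      # (K+1, K+1) per series
    Swx = [wb.T @ state.x_mean[s][:, 1:].T for s, wb in enumerate(wbar)]  # (K+1, K)
    for j in range(K):
        Lam = np.diag(state.ard_beta[j]).astype(float)
        h = np.zeros(K + 1)
        for s in range(state.n_series):
            Lam += e_rho[s, j] * Sww[s]
            h += e_rho[s, j] * Swx[s][:, j]
        cov = np.linalg.inv(Lam)
        cov = 0.5 * (cov + cov.T)
        state.beta_cov[j] = cov
        state.beta_mean[j] = cov @ h
    return state


def _obs_sq_dev(state: PosteriorState, data: TimeSeriesSet) -> list[np.ndarray]:
    """Per-series (G, K) matrices of sum_{r,t} E[(y_{i,t} - x_{k,t})^2]."""
    out = []
    for s, Y in enumerate(_series_obs(data)):
        m = state.x_mean[s]                       # (K, T)
        V = state.x_cov[s]                        # (T, K, K)
        R = Y.shape[0]
        y_sq = np.einsum("rit->i", Y**2)          # (G,)
        y_sum = Y.sum(axis=0)                     # (G, T)
        m_sq = (m**2).sum(axis=1) + np.einsum("tkk->k", V)  # (K,)
        D = y_sq[:, None] + R * m_sq[None, :] - 2.0 * y_sum @ m.T
        out.append(D)
    return out


def update_memberships(state: PosteriorState, data: TimeSeriesSet) -> PosteriorState:
    """Refresh gene responsibilities from the observation likelihood.

    No-op when memberships are clamped.  The uniform prior over clusters
    cancels in the normalization; rows are normalized with log-sum-exp.
    """
    if state.config.clamp_memberships is not None:
        return state
    e_tau = state.e_tau()
    log_r = np.zeros_like(state.resp)
    for s, D in enumerate(_obs_sq_dev(state, data)):
        log_r += -0.5 * e_tau[s] * D
    log_r -= log_r.max(axis=1, keepdims=True)
    r = np.exp(log_r)
    r /= r.sum(axis=1, keepdims=True)
    state.resp = r
    return state


def _transition_sq_dev(state: PosteriorState) -> list[np.ndarray]:
    """Per-series (K, T-1) matrices of E[(x_{j,t+1} - B_j x_t - d_j)^2]."""
    K = state.K
    M2 = state.beta_second_moment()
    Eww, wbar = _transition_stats(state)
    out = []
    for s in range(state.n_series):
        m = state.x_mean[s]
        V = state.x_cov[s]
        tgt_sq = m[:, 1:] ** 2 + np.einsum("tjj->jt", V[1:])          # (K, T-1)
        lin = (wbar[s] @ state.beta_mean.T).T * m[:, 1:]              # (K, T-1)
        quad = np.einsum("tab,jab->jt", Eww[s], M2)                   # (K, T-1)
        out.append(tgt_sq - 2.0 * lin + quad)
    return out


def update_precisions(state: PosteriorState, data: TimeSeriesSet) -> PosteriorState:
    """Refresh the gamma factors for tau (per series) and rho (per series/cluster)."""
    a0, b0 = state.config.hyper.a0, state.config.hyper.b0
    D = _obs_sq_dev(state, data)
    Q = _transition_sq_dev(state)
    for s, table in enumerate(data.series):
        n_obs = table.n_genes * table.n_times * table.n_replicates
        state.tau_a[s] = a0 + 0.5 * n_obs
        state.tau_b[s] = b0 + 0.5 * float(np.sum(state.resp * D[s]))
        state.rho_a[s, :] = a0 + 0.5 * (table.n_times - 1)
        state.rho_b[s, :] = b0 + 0.5 * Q[s].sum(axis=1)
    return state


def update_hyperparameters(state: PosteriorState) -> PosteriorState:
    """Evidence-maximizing fixed point for every prior precision, clipped.

    Each precision moves to 1/E[param^2] under its factor, the maximizer of
    the ELBO profiled over that precision.
    """
    lo, hi = state.config.hyper.ard_bounds
    M2 = state.beta_second_moment()
    state.ard_beta = np.clip(1.0 / np.einsum("jaa->ja", M2), lo, hi)
    for s in range(state.n_series):
        ex1_sq = state.x_mean[s][:, 0] ** 2 + np.diag(state.x_cov[s][0])
        state.ard_x1[s, :] = np.clip(1.0 / ex1_sq, lo, hi)
    return state


# ---------------------------------------------------------------------------
# ELBO


def _gamma_cross_entropy(a0: float, b0: float, a: np.ndarray, b: np.ndarray) -> float:
    """E_q[log Gamma(theta; a0, b0)] summed over factors."""
    e = a / b
    e_log = digamma(a) - np.log(b)
    return float(np.sum(a0 * np.log(b0) - gammaln(a0) + (a0 - 1.0) * e_log - b0 * e))


def _gamma_entropy(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(a - np.log(b) + gammaln(a) + (1.0 - a) * digamma(a)))


def compute_elbo(state: PosteriorState, data: TimeSeriesSet) -> float:
    """Evidence lower bound E_q[log p(data, params)] - E_q[log q]."""
    K = state.K
    G = len(state.gene_names)
    e_tau, e_log_tau = state.e_tau(), state.e_log_tau()
    e_rho, e_log_rho = state.e_rho(), state.e_log_rho()
    hyper = state.config.hyper
    M2 = state.beta_second_moment()

    elbo = 0.0
    # observation likelihood
    for s, D in enumerate(_obs_sq_dev(state, data)):
        n_obs = data.series[s].n_genes * data.series[s].n_times * data.series[s].n_replicates
        elbo += 0.5 * n_obs * (e_log_tau[s] - _LOG2PI)
        elbo += -0.5 * e_tau[s] * float(np.sum(state.resp * D))
    # transition likelihood
    for s, Q in enumerate(_transition_sq_dev(state)):
        Tm1 = Q.shape[1]
        elbo += 0.5 * Tm1 * float(np.sum(e_log_rho[s] - _LOG2PI))
        elbo += -0.5 * float(e_rho[s] @ Q.sum(axis=1))
    # initial-state prior
    for s in range(state.n_series):
        ex1_sq = state.x_mean[s][:, 0] ** 2 + np.diag(state.x_cov[s][0])
        elbo += 0.5 * float(np.sum(np.log(state.ard_x1[s]) - _LOG2PI
                                   - state.ard_x1[s] * ex1_sq))
    # dynamics-row priors
    diag_m2 = np.einsum("jaa->ja", M2)
    elbo += 0.5 * float(np.sum(np.log(state.ard_beta) - _LOG2PI
                               - state.ard_beta * diag_m2))
    # precision priors
    elbo += _gamma_cross_entropy(hyper.a0, hyper.b0, state.tau_a, state.tau_b)
    elbo += _gamma_cross_entropy(hyper.a0, hyper.b0, state.rho_a.ravel(), state.rho_b.ravel())
    # membership prior (uniform over K)
    elbo += -G * np.log(K)

    # entropies
    for s in range(state.n_series):
        sign, logdet = np.linalg.slogdet(state.x_cov[s])
        if np.any(sign <= 0):
            raise NumericalError("state covariance lost positive definiteness")
        elbo += float(np.sum(0.5 * (K * (_LOG2PI + 1.0) + logdet)))
    sign, logdet = np.linalg.slogdet(state.beta_cov)
    if np.any(sign <= 0):
        raise NumericalError("dynamics-row covariance lost positive definiteness")
    elbo += float(np.sum(0.5 * ((K + 1) * (_LOG2PI + 1.0) + logdet)))
    r = state.resp
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(r > 0, r * np.log(r), 0.0)
    elbo += float(ent.sum())
    elbo += _gamma_entropy(state.tau_a, state.tau_b)
    elbo += _gamma_entropy(state.rho_a.ravel(), state.rho_b.ravel())
    return float(elbo)


# ---------------------------------------------------------------------------
# fit loop


_FACTOR_ARRAYS = ("beta_mean", "beta_cov", "resp", "tau_a", "tau_b",
                  "rho_a", "rho_b", "ard_beta", "ard_x1")


def _diagnose_nonfinite(state: PosteriorState) -> str:
    for name in _FACTOR_ARRAYS:
        if not np.all(np.isfinite(getattr(state, name))):
            return name
    for s in range(state.n_series):
        if not np.all(np.isfinite(state.x_mean[s])) or \
                not np.all(np.isfinite(state.x_cov[s])):
            return f"q_x (series {s + 1})"
    return "elbo"


def fit(data: TimeSeriesSet, config: ModelConfig, *,
        standardize_input: bool = True,
        init_state: PosteriorState | None = None) -> PosteriorState:
    """Run coordinate-ascent sweeps until the ELBO stabilizes.

    Sweep order: states, dynamics, memberships, precisions, hyper-precisions,
    then one ELBO evaluation appended to the trace.  Stops when the relative
    ELBO change drops below ``config.rel_tol`` or after ``config.max_sweeps``.
    Deterministic given ``config.seed``.  Input series are standardized per
    gene unless ``standardize_input=False``.
    """
    if standardize_input:
        data, _ = standardize(data)
    state = init_state.copy() if init_state is not None else init_posterior(data, config)
    prev = -np.inf
    for sweep in range(config.max_sweeps):
        update_states(state, data)
        update_dynamics(state, data)
        update_memberships(state, data)
        update_precisions(state, data)
        update_hyperparameters(state)
        elbo = compute_elbo(state, data)
        if not np.isfinite(elbo):
            raise NumericalError(
                f"non-finite ELBO at sweep {sweep + 1}; offending factor: "
                f"{_diagnose_nonfinite(state)}")
        state.elbo_trace.append(elbo)
        state.n_sweeps = sweep + 1
        if np.isfinite(prev) and abs(elbo - prev) < config.rel_tol * max(1.0, abs(prev)):
            state.converged = True
            break
        prev = elbo
    return state


def fit_no_clustering(data: TimeSeriesSet, config: ModelConfig | None = None,
                      **kwargs) -> PosteriorState:
    """Plain dynamic-network fit: K = G with memberships clamped to identity.

    This is the same code path as the clustered fit, so a clustered fit that
    selects K = G with identity memberships produces identical results.
    """
    G = data.n_genes
    base = config or ModelConfig(K=G)
    cfg = dataclasses.replace(base, K=G, clamp_memberships=tuple(range(G)))
    return fit(data, cfg, **kwargs)
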