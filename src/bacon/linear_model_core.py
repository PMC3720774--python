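"""Core mathematical objects of the clustered dynamic network model.

This module houses the generative parameters and hyper-priors used across the
package, plus a fully analytic two-regulator problem: gene Z observed as a
noisy inner product of two candidate regulators X and Y.  The conjugate
posterior of the two interaction coefficients has a closed form, which makes
this module the analytic oracle for the variational engine, and it exhibits
the correlated-regressor singularity that motivates clustering: as the X and
Y profiles become collinear the posterior precision loses rank and the
coefficient variances diverge.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "GenerativeParams",
    "HyperPriors",
    "TwoRegulatorProblem",
    "two_regulator_posterior",
    "singularity_profile",
]


@dataclasses.dataclass
class GenerativeParams:
    """True model parameters: cluster dynamics, memberships and noise precisions.

    Dynamics follow ``x_{t+1} = B x_t + d + noise`` on the K cluster
    expression levels; gene i observes cluster ``z[i]`` plus technical noise.
    ``B[k, j]`` is the coefficient mapping cluster j at time t to cluster k at
    time t+1.  ``state_noise_prec`` is per-series (n_series, K); ``obs_prec``
    is per-series (n_series,).
    """

    n_clusters: int
    n_genes: int
    transition: np.ndarray          # (K, K)
    trend: np.ndarray               # (K,)
    membership: np.ndarray          # (G,) cluster index in 0..K-1
    state_noise_prec: np.ndarray    # (S, K)
    obs_prec: np.ndarray            # (S,)
    init_state_prec: float = 1.0

    def __post_init__(self) -> None:
        K, G = self.n_clusters, self.n_genes
        if K > G:
            raise ValueError("more clusters than genes")
        self.transition = np.asarray(self.transition, dtype=float)
        self.trend = np.asarray(self.trend, dtype=float)
        self.membership = np.asarray(self.membership, dtype=int)
        self.state_noise_prec = np.atleast_2d(np.asarray(self.state_noise_prec, dtype=float))
        self.obs_prec = np.atleast_1d(np.asarray(self.obs_prec, dtype=float))
        if self.transition.shape != (K, K):
            raise ValueError("transition must be K x K")
        if self.trend.shape != (K,):
            raise ValueError("trend must have length K")
        if self.membership.shape != (G,) or self.membership.min() < 0 \
                or self.membership.max() >= K:
            raise ValueError("membership must map each gene into 0..K-1")
        if np.any(self.state_noise_prec <= 0) or np.any(self.obs_prec <= 0) \
                or self.init_state_prec <= 0:
            raise ValueError("all precisions must be positive")


@dataclasses.dataclass(frozen=True)
class HyperPriors:
    """Hyper-priors shared by the variational engine.

    ``a0``/``b0`` parameterize the Gamma(shape, rate) prior on the
    observation and state-noise precisions.  The unit-information default
    Gamma(1, 1) is deliberately not vaguer: a near-improper gamma prior
    admits a degenerate optimum where a flatlined state trajectory lets a
    state-noise precision diverge and its expected log harvest an unbounded
    evidence reward, which inverts model selection.  ``ard_init`` is the starting
    prior precision on every dynamics coefficient, trend element and initial
    state element; these precisions are re-estimated against the evidence and
    clipped to ``ard_bounds`` so pruned coefficients cannot collapse the
    numerics.
    """

    a0: float = 1.0
    b0: float = 1.0
    ard_init: float = 1.0
    ard_bounds: tuple[float, float] = (1e-6, 1e6)

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.b0 <= 0 or self.ard_init <= 0:
            raise ValueError("hyper-prior parameters must be positive")
        lo, hi = self.ard_bounds
        if not lo < hi:
            raise ValueError("ard_bounds must satisfy min < max")


@dataclasses.dataclass
class TwoRegulatorProblem:
    """Gene Z regressed on candidate regulators X and Y across one time step.

    ``z[t+1]`` is a noisy observation (known precision ``phi``) of
    ``b1*x[t] + b2*y[t]``; the coefficient vector carries a bivariate normal
    prior N(mu0, Lambda0^{-1}).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    phi: float
    mu0: np.ndarray
    Lambda0: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.Lambda0 = np.asarray(self.Lambda0, dtype=float)
        T = self.x.size
        if self.y.size != T or self.z.size != T:
            raise ValueError("x, y, z must have equal length")
        if T < 2:
            raise ValueError("need at least 2 time points (one transition)")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if self.mu0.shape != (2,) or self.Lambda0.shape != (2, 2):
            raise ValueError("mu0 must be length 2, Lambda0 2 x 2")
        if not np.allclose(self.Lambda0, self.Lambda0.T):
            raise ValueError("Lambda0 must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Lambda0) <= 0):
            raise ValueError("Lambda0 must be positive definite")


def two_regulator_posterior(problem: TwoRegulatorProblem) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form conjugate posterior of the two interaction coefficients.

    Returns ``(mean, precision)`` of the bivariate normal posterior.  The
    posterior precision is the prior precision plus ``phi`` times the
    regressor scatter accumulated over transitions t -> t+1.
    """
    p = problem
    W = np.stack([p.x[:-1], p.y[:-1]], axis=1)        # (T-1, 2)
    target = p.z[1:]
    precision = p.Lambda0 + p.phi * (W.T @ W)
    precision = 0.5 * (precision + precision.T)
    rhs = p.Lambda0 @ p.mu0 + p.phi * (W.T @ target)
    mean = np.linalg.solve(precision, rhs)
    return mean, precision


def singularity_profile(r_values, eps: float, *, phi: float = 1.0,
                        T: int = 50, seed: int = 0) -> np.ndarray:
    """Posterior variance of the first coefficient as regressor correlation grows.

    For each correlation level r in ``r_values`` the second regressor is
    ``y = r*x + (1-r)*noise`` rescaled to unit sample variance, and the
    posterior variance of the X coefficient under a weak N(0, (eps*I)^{-1})
    prior is returned.  Variances increase toward the collinear limit r=1,
    where with a vanishing prior precision the posterior variance diverges.
    """
    r_values = np.atleast_1d(np.asarray(r_values, dtype=float))
    if np.any((r_values < 0) | (r_values > 1)):
        raise ValueError("correlation levels must lie in [0, 1]")
    if eps <= 0:
        raise ValueError("prior precision must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(T)
    x = (x - x.mean()) / x.std()
    noise = rng.standard_normal(T)
    # orthogonalize the noise against x so r=0 gives uncorrelated regressors
    noise = noise - (noise @ x) / (x @ x) * x
    noise = (noise - noise.mean()) / noise.std()
    out = np.empty(r_values.size)
    for i, r in enumerate(r_values):
        y = r * x + (1.0 - r) * noise
        sd = y.std()
        if sd > 0:
            y = y / sd
        z = rng.standard_normal(T)  # target series; variance profile is data-independent
        prob = TwoRegulatorProblem(x=x, y=y, z=z, phi=phi,
                                   mu0=np.zeros(2), Lambda0=eps * np.eye(2))
        _, precision = two_regulator_posterior(prob)
        out[i] = np.linalg.inv(precision)[0, 0]
    return out
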