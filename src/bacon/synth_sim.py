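"""Synthetic networks and time-course data from the model's own generative process.

The simulator draws a sparse stable cluster transition matrix, a trend
vector, round-robin (shuffled) cluster memberships, then rolls the linear
dynamics forward per series and emits per-gene observations with technical
noise.  The emitted gold standard marks every ordered gene pair whose
cluster-pair transition coefficient is nonzero, which is exactly the
estimand of the clustered model; with K = G it reduces to a conventional
gene-level network.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .formats_io import GoldStandard, SeriesTable, TimeSeriesSet
from .linear_model_core import GenerativeParams

__all__ = ["SimSpec", "simulate", "dream4_like_fixture"]


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated network.

    Defaults mirror the 10-gene benchmark scale this model targets: a
    handful of clusters over ~a dozen genes, 20 uniformly sampled time
    points, several independent series, no technical replicates, and a
    signal-to-noise ratio of about 10 (unit-scale trajectories with
    observation noise sd 0.1).  ``spectral_cap`` keeps the dynamics stable;
    ``diag_bias`` adds positive self-persistence to the transition diagonal.
    """

    K: int = 3
    G: int = 12
    T: int = 20
    n_series: int = 5
    n_replicates: int = 1
    edge_density: float = 0.3
    coeff_magnitude: float = 1.0
    trend_scale: float = 0.1
    state_noise_sd: float = 0.1
    obs_noise_sd: float = 0.1
    spectral_cap: float = 0.9
    diag_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.G < 1 or self.K > self.G:
            raise ValueError("need 1 <= K <= G")
        if self.T < 2 or self.n_series < 1 or self.n_replicates < 1:
            raise ValueError("need T >= 2, n_series >= 1, n_replicates >= 1")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if not 0 < self.spectral_cap < 1:
            raise ValueError("spectral_cap must be in (0, 1)")
        if self.coeff_magnitude <= 0 or self.state_noise_sd <= 0 or self.obs_noise_sd <= 0:
            raise ValueError("scales must be positive")
        if self.trend_scale < 0 or self.diag_bias < 0:
            raise ValueError("trend_scale and diag_bias must be non-negative")


def _draw_transition(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Sparse +/-coeff_magnitude off-diagonal, positive diagonal, stable."""
    K = spec.K
    for _ in range(100):
        B = np.zeros((K, K))
        mask = rng.random((K, K)) < spec.edge_density
        np.fill_diagonal(mask, False)
        signs = rng.choice([-1.0, 1.0], size=(K, K))
        B[mask] = (signs * spec.coeff_magnitude)[mask]
        np.fill_diagonal(B, spec.diag_bias * spec.coeff_magnitude)
        radius = float(np.max(np.abs(np.linalg.eigvals(B))))
        if radius <= spec.spectral_cap:
            return B
        if radius > 0:
            return B * (spec.spectral_cap / radius)
    raise RuntimeError("could not satisfy the spectral cap after 100 attempts")


def simulate(spec: SimSpec) -> tuple[TimeSeriesSet, GenerativeParams, GoldStandard]:
    """Draw a network and roll out observed series; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    K, G, T = spec.K, spec.G, spec.T
    B = _draw_transition(spec, rng)
    d = spec.trend_scale * rng.standard_normal(K)
    z = np.arange(G) % K           # round-robin: every cluster non-empty
    rng.shuffle(z)

    genes = [f"G{i + 1}" for i in range(G)]
    times = 50.0 * np.arange(T)
    series = []
    for _ in range(spec.n_series):
        x = np.zeros((K, T))
        x[:, 0] = rng.standard_normal(K)
        for t in range(T - 1):
            x[:, t + 1] = B @ x[:, t] + d + spec.state_noise_sd * rng.standard_normal(K)
        reps = [x[z] + spec.obs_noise_sd * rng.standard_normal((G, T))
                for _ in range(spec.n_replicates)]
        series.append(SeriesTable(
            gene_names=genes, time_points=times, values=reps[0],
            replicate_values=reps[1:] or None))

    params = GenerativeParams(
        n_clusters=K, n_genes=G, transition=B, trend=d, membership=z,
        state_noise_prec=np.full((spec.n_series, K), spec.state_noise_sd**-2),
        obs_prec=np.full(spec.n_series, spec.obs_noise_sd**-2),
        init_state_prec=1.0,
    )
    edges = {(genes[i], genes[j]) for i in range(G) for j in range(G)
             if i != j and B[z[j], z[i]] != 0.0}
    gold = GoldStandard(edges=edges, universe=genes)
    data = TimeSeriesSet(series=series, network_id=f"sim-seed{spec.seed}")
    return data, params, gold


def dream4_like_fixture(seed: int) -> tuple[TimeSeriesSet, GoldStandard]:
    """A 10-gene, 20-time-point, 5-series fixture shaped like the DREAM4
    time-series sub-challenge, with a conventional gene-level (K = G) network."""
    spec = SimSpec(K=10, G=10, T=20, n_series=5, n_replicates=1,
                   edge_density=0.15, seed=seed)
    data, _, gold = simulate(spec)
    return data, gold
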