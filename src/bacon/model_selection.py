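"""Restart x cluster-count sweep with maximum-marginal-likelihood selection.

Every (K, restart) combination is fitted from an independent seeded
initialization; the single fit with the highest final ELBO (the
marginal-likelihood lower bound) wins.  No model averaging is performed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .formats_io import TimeSeriesSet
from .vb_engine import ModelConfig, NumericalError, PosteriorState, fit

__all__ = ["SweepRecord", "SweepResult", "sweep", "likelihood_gap", "derive_seed"]


@dataclasses.dataclass(frozen=True)
class SweepRecord:
    K: int
    restart: int
    seed: int
    final_elbo: float
    converged: bool
    n_sweeps: int
    failed: bool = False


@dataclasses.dataclass
class SweepResult:
    """All (K, restart) fit records plus the winning posterior."""

    records: list[SweepRecord]
    best: PosteriorState
    best_K: int

    def records_tsv(self) -> str:
        lines = ["K\tseed\telbo\tconverged\tsweeps"]
        for r in self.records:
            elbo = "nan" if r.failed else format(r.final_elbo, ".10g")
            lines.append(f"{r.K}\t{r.seed}\t{elbo}\t{int(r.converged)}\t{r.n_sweeps}")
        return "\n".join(lines) + "\n"


def derive_seed(base_seed: int, K: int, restart: int) -> int:
    """Deterministic per-(K, restart) seed below 2^31."""
    ss = np.random.SeedSequence([int(base_seed), int(K), int(restart)])
    return int(ss.generate_state(1)[0] % (2**31))


def sweep(data: TimeSeriesSet, K_values: Sequence[int], restarts: int,
          base_seed: int, config: ModelConfig | None = None) -> SweepResult:
    """Fit every (K, restart) and keep the maximum-ELBO model.

    Individual fits that abort numerically are recorded as failed and
    excluded from selection; if every fit fails the sweep raises.
    Deterministic given ``base_seed``; selection is a pure argmax over final
    ELBOs (ties resolved by sequential (K, restart) order).
    """
    G = data.n_genes
    K_values = list(K_values)
    if not K_values:
        raise ValueError("K_values must be non-empty")
    if any(k < 1 or k > G for k in K_values):
        raise ValueError(f"every K must lie in 1..{G}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    base = config or ModelConfig(K=K_values[0])

    records: list[SweepRecord] = []
    best_state: PosteriorState | None = None
    best_elbo = -np.inf
    for K in K_values:
        for restart in range(restarts):
            seed = derive_seed(base_seed, K, restart)
            cfg = dataclasses.replace(base, K=K, seed=seed)
            try:
                state = fit(data, cfg)
            except NumericalError:
                records.append(SweepRecord(K=K, restart=restart, seed=seed,
                                           final_elbo=float("nan"), converged=False,
                                           n_sweeps=0, failed=True))
                continue
            elbo = state.elbo_trace[-1] if state.elbo_trace else -np.inf
            records.append(SweepRecord(K=K, restart=restart, seed=seed,
                                       final_elbo=float(elbo),
                                       converged=state.converged,
                                       n_sweeps=state.n_sweeps))
            if elbo > best_elbo:
                best_elbo = elbo
                best_state = state
    if best_state is None:
        raise NumericalError("every (K, restart) fit failed")
    return SweepResult(records=records, best=best_state, best_K=best_state.K)


def likelihood_gap(result: SweepResult) -> float:
    """Best ELBO minus the best ELBO achieved at any other cluster count.

    A closeness diagnostic only; selection never uses it.
    """
    ok = [r for r in result.records if not r.failed]
    if len(ok) < 2:
        raise ValueError("need at least two successful records")
    best = max(ok, key=lambda r: r.final_elbo)
    rivals = [r for r in ok if r.K != best.K]
    if not rivals:
        raise ValueError("no record at a different K to compare against")
    second = max(rivals, key=lambda r: r.final_elbo)
    return float(best.final_elbo - second.final_elbo)
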