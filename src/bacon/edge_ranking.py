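"""Gene-level edge ranking from a fitted posterior.

Each cluster-pair interaction j -> k is scored by the posterior mean of the
corresponding transition element divided by its posterior standard
deviation; that signed score is assigned to every ordered gene pair whose
regulator sits in cluster j and target in cluster k (self-pairs excluded),
and pairs are ranked by absolute score.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .formats_io import EdgeScoreTable
from .vb_engine import PosteriorState, hard_memberships

__all__ = ["cluster_scores", "gene_ranking"]


def cluster_scores(state: PosteriorState) -> np.ndarray:
    """Signed statistical-strength score for every directed cluster pair.

    ``scores[j, k]`` = posterior mean / posterior sd of the transition
    element mapping cluster j at time t to cluster k at time t+1.
    """
    K = state.K
    means = state.beta_mean[:, :K]                       # row k = target cluster
    variances = np.einsum("kjj->kj", state.beta_cov[:, :K, :K])
    if np.any(variances <= 0):
        raise ValueError("zero posterior variance: degenerate fit")
    scores = (means / np.sqrt(variances)).T              # index [regulator, target]
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite cluster scores")
    return scores


def gene_ranking(state: PosteriorState, gene_names: Sequence[str] | None = None,
                 *, include_within_cluster: bool = True) -> EdgeScoreTable:
    """Rank every directed gene pair by the |score| of its cluster pair.

    Memberships are hardened by argmax responsibility (ties to the lowest
    cluster index).  Within-cluster pairs receive the cluster's
    self-interaction score unless ``include_within_cluster=False`` pushes
    them to score zero.  Ties in |score| break by (regulator, target)
    lexicographic order.
    """
    names = list(gene_names) if gene_names is not None else list(state.gene_names)
    if len(names) != len(state.gene_names):
        raise ValueError("gene list length mismatch with the fitted state")
    unknown = set(names) - set(state.gene_names)
    if unknown:
        raise ValueError(f"unknown genes: {sorted(unknown)}")
    order = {g: i for i, g in enumerate(state.gene_names)}
    scores = cluster_scores(state)
    assign = hard_memberships(state)
    entries = []
    for u in names:
        cu = assign[order[u]]
        for v in names:
            if u == v:
                continue
            cv = assign[order[v]]
            if cu == cv and not include_within_cluster:
                s = 0.0
            else:
                s = float(scores[cu, cv])
            entries.append((u, v, s))
    entries.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return EdgeScoreTable(entries=entries, derived_from=(state.K, scores))
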