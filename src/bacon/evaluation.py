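"""AUROC / AUPR scoring of a ranked edge list against a gold standard.

The ranking statistic is |score| (gold standards are unsigned).  AUROC uses
the tie-averaged Mann-Whitney convention; AUPR is the step-wise average
precision at each recall increment, with no interpolation across recall
gaps.  Both are delegated to scikit-learn's metric implementations.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from .formats_io import (EdgeScoreTable, GoldStandard, read_edge_ranking,
                         read_gold_standard)

__all__ = ["EvalResult", "evaluate", "evaluate_file"]


@dataclasses.dataclass
class EvalResult:
    auroc: float
    aupr: float
    n_true: int
    n_candidates: int
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]

    def to_tsv(self) -> str:
        return f"auroc\t{self.auroc:.6g}\naupr\t{self.aupr:.6g}\n"


def evaluate(ranking: EdgeScoreTable, gold: GoldStandard) -> EvalResult:
    """Score a full candidate-pair ranking against the gold standard.

    The ranking must cover exactly the G*(G-1) ordered non-self pairs of the
    gold universe; a gold standard with zero true edges is rejected (AUPR is
    undefined there).
    """
    candidates = set(gold.candidate_pairs())
    ranked = ranking.pairs()
    if set(ranked) != candidates or len(ranked) != len(candidates):
        missing = candidates - set(ranked)
        extra = set(ranked) - candidates
        raise ValueError(
            f"ranking does not cover the candidate pairs exactly "
            f"(missing {len(missing)}, extraneous {len(extra)})")
    y_true = np.array([1 if (u, v) in gold.edges else 0
                       for u, v, _ in ranking.entries])
    y_score = np.array([abs(s) for _, _, s in ranking.entries])
    n_true = int(y_true.sum())
    if n_true == 0:
        raise ValueError("gold standard has no true edges; AUPR undefined")
    if n_true == y_true.size:
        raise ValueError("gold standard has no negatives; AUROC undefined")
    auroc = float(roc_auc_score(y_true, y_score))
    aupr = float(average_precision_score(y_true, y_score))
    fpr, tpr, _ = roc_curve(y_true, y_score)
    prec, rec, _ = precision_recall_curve(y_true, y_score)
    return EvalResult(
        auroc=auroc,
        aupr=aupr,
        n_true=n_true,
        n_candidates=y_true.size,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        pr_points=list(zip(rec.tolist(), prec.tolist())),
    )


def evaluate_file(ranking_path: str | Path, gold_path: str | Path,
                  genes: Sequence[str] | None = None) -> EvalResult:
    """File-based wrapper: read a ranking and a gold standard, then evaluate.

    When ``genes`` is omitted the universe is taken from the genes named in
    the ranking (a full ranking names every gene).
    """
    ranking = read_edge_ranking(ranking_path)
    if genes is None:
        seen: list[str] = []
        for u, v, _ in ranking.entries:
            for g in (u, v):
                if g not in seen:
                    seen.append(g)
        genes = seen
    gold = read_gold_standard(gold_path, genes)
    return evaluate(ranking, gold)
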