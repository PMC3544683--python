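"""Filter criteria for ranking genes by NTAC/NTAB class separability.

Four classical per-feature scores, computed without a classifier: absolute
pooled-variance t, symmetric Kullback-Leibler divergence between Gaussian
class fits ("entropy"), Gaussian Bhattacharyya distance, and the absolute
tie-corrected rank-sum z.  Ordinal scores are treated as continuous for the
Gaussian-fit criteria, as the classical feature-selection toolboxes do, and
class variances are floored at a small epsilon because an ordinal column can
be constant within a class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import NTAB, NTAC, ScoreMatrix
from .ranktests import wilcoxon_rank_sum

__all__ = [
    "CRITERIA",
    "RankResult",
    "t_score",
    "entropy_score",
    "bhattacharyya_score",
    "wilcoxon_score",
    "criterion_score",
    "rank_genes",
]

#: Variance floor for the Gaussian-fit criteria.
EPS_VAR = 1e-9

CRITERIA = ("ttest", "entropy", "bhattacharyya", "wilcoxon")


@dataclass(frozen=True)
class RankResult:
    """Genes ordered best-first under one filter criterion."""

    criterion: str
    ordered_genes: tuple[str, ...]
    scores: tuple[float, ...]  # non-increasing, aligned with ordered_genes


def _moments(v: np.ndarray, name: str) -> tuple[float, float, int]:
    if v.size < 2:
        raise ValueError(f"group {name} needs >= 2 samples, got {v.size}")
    return float(v.mean()), max(float(v.var(ddof=1)), EPS_VAR), v.size


def t_score(x, y) -> float:
    """Absolute two-sample t with pooled variance (Welch via welch_t_score)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m1, v1, n1 = _moments(x, "x")
    m2, v2, n2 = _moments(y, "y")
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def welch_t_score(x, y) -> float:
    """Absolute Welch t (unequal-variance variant), offered alongside."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m1, v1, n1 = _moments(x, "x")
    m2, v2, n2 = _moments(y, "y")
    return abs(m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)


def entropy_score(x, y) -> float:
    """Symmetric KL divergence between Gaussian class fits.

    J = (s1^2 + d^2) / (2 s2^2) + (s2^2 + d^2) / (2 s1^2) - 1 with
    d = m1 - m2; zero iff the fitted Gaussians coincide.
    """
    m1, v1, _ = _moments(np.asarray(x, dtype=float), "x")
    m2, v2, _ = _moments(np.asarray(y, dtype=float), "y")
    d2 = (m1 - m2) ** 2
    return (v1 + d2) / (2.0 * v2) + (v2 + d2) / (2.0 * v1) - 1.0


def bhattacharyya_score(x, y) -> float:
    """Gaussian Bhattacharyya distance between the two class fits.

    B = (m1 - m2)^2 / (4 (s1^2 + s2^2)) + 0.5 ln((s1^2 + s2^2) / (2 s1 s2)).
    """
    m1, v1, _ = _moments(np.asarray(x, dtype=float), "x")
    m2, v2, _ = _moments(np.asarray(y, dtype=float), "y")
    return 0.25 * (m1 - m2) ** 2 / (v1 + v2) + 0.5 * np.log((v1 + v2) / (2.0 * np.sqrt(v1 * v2)))


def wilcoxon_score(x, y) -> float:
    """|z| of the tie-corrected rank-sum statistic (delegates to ranktests)."""
    return abs(wilcoxon_rank_sum(x, y, method="normal").z)


_SCORE_FNS = {
    "ttest": t_score,
    "entropy": entropy_score,
    "bhattacharyya": bhattacharyya_score,
    "wilcoxon": wilcoxon_score,
}


def criterion_score(x, y, criterion: str) -> float:
    try:
        fn = _SCORE_FNS[criterion]
    except KeyError:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}") from None
    return float(fn(x, y))


def rank_genes(matrix: ScoreMatrix, criterion: str) -> RankResult:
    """Order the panel best-first by one criterion, ties by panel order."""
    scores = np.array(
        [
            criterion_score(
                matrix.class_values(g, NTAC), matrix.class_values(g, NTAB), criterion
            )
            for g in matrix.genes
        ]
    )
    order = np.argsort(-scores, kind="stable")  # stable: ties keep panel order
    return RankResult(
        criterion=criterion,
        ordered_genes=tuple(matrix.genes[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
    )
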