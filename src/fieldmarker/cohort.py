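"""Synthetic RISH score cohorts with the study's sample structure.

The study design is a fixed eight-group cohort: six malignant tumor types
whose adjacent normal tissue is labelled NTAC, and two benign tumor types
whose adjacent normal tissue is labelled NTAB.  Scores are semi-quantitative
RNA in situ hybridization composites on the ordinal scale 0..6.  Because the
patient score matrix was never deposited, analyses run on cohorts simulated
from class-conditional score distributions (:class:`GeneEffect`), with the
class separation of each gene calibrated to an exact analytic AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
from zlib import crc32

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "NTAC",
    "NTAB",
    "SCORE_LEVELS",
    "TissueGroup",
    "CohortDesign",
    "GeneEffect",
    "ScoreMatrix",
    "CalibrationError",
    "default_design",
    "default_panel",
    "null_effect",
    "analytic_auc",
    "effect_from_auc",
    "simulate_cohort",
]

NTAC = "NTAC"
NTAB = "NTAB"

#: Ordinal composite-score support: ratio category (0-3) + density category (0-3).
SCORE_LEVELS = np.arange(7)

#: Latent-Gaussian discretization cut points (8 points incl. the infinite ends):
#: a standard-normal latent value falls into one of 7 bins -> score 0..6.
LATENT_CUTS = np.array([-np.inf, -1.25, -0.75, -0.25, 0.25, 0.75, 1.25, np.inf])


class CalibrationError(ValueError):
    """Requested class separation is unreachable within the latent family."""


@dataclass(frozen=True)
class TissueGroup:
    """One tumor type contributing adjacent-tissue samples to the cohort."""

    tissue_name: str
    tumor_class: str  # "malignant" or "benign"
    n_cases: int

    def __post_init__(self) -> None:
        if self.tumor_class not in ("malignant", "benign"):
            raise ValueError(f"tumor_class must be malignant/benign, got {self.tumor_class!r}")
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases}")

    @property
    def adjacent_label(self) -> str:
        """Class label of the adjacent normal tissue (malignant -> NTAC)."""
        return NTAC if self.tumor_class == "malignant" else NTAB


@dataclass(frozen=True)
class CohortDesign:
    """Ordered list of tissue groups making up a cohort."""

    groups: tuple[TissueGroup, ...]

    def __post_init__(self) -> None:
        names = [g.tissue_name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("tissue group names must be unique")
        if not self.groups:
            raise ValueError("design needs at least one group")

    @property
    def n_total(self) -> int:
        return sum(g.n_cases for g in self.groups)

    def n_class(self, label: str) -> int:
        return sum(g.n_cases for g in self.groups if g.adjacent_label == label)


def default_design() -> CohortDesign:
    """The 314-patient, eight-group cohort (244 NTAC / 70 NTAB)."""
    return CohortDesign(
        (
            TissueGroup("hepatocellular carcinoma", "malignant", 26),
            TissueGroup("rectal adenocarcinoma", "malignant", 48),
            TissueGroup("esophageal squamous cell carcinoma", "malignant", 34),
            TissueGroup("gastric adenocarcinoma", "malignant", 66),
            TissueGroup("thyroid carcinoma", "malignant", 32),
            TissueGroup("breast carcinoma", "malignant", 38),
            TissueGroup("thyroid adenoma", "benign", 32),
            TissueGroup("breast fibroadenoma", "benign", 38),
        )
    )


def default_panel() -> list[str]:
    """The 15 tumor-related genes of the screening panel, in panel order."""
    return [
        "MYC",
        "CCND1",
        "TP53",
        "UVRAG",
        "RB1",
        "PTEN",
        "PTCH1",
        "BRCA1",
        "BRCA2",
        "FHIT",
        "BECN1",
        "BCL10",
        "APC",
        "CD82",
        "NME1-NME2",
    ]


def _validate_pmf(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (7,):
        raise ValueError(f"{name} must have 7 entries (scores 0..6), got shape {p.shape}")
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} sums to {p.sum()!r}, not 1 within 1e-9")
    return p


@dataclass(frozen=True)
class GeneEffect:
    """Class-conditional score distributions for one gene.

    ``p_ntac[s]`` (``p_ntab[s]``) is the probability that an NTAC (NTAB)
    sample scores ``s`` on this gene, s in 0..6.
    """

    gene: str
    p_ntac: np.ndarray
    p_ntab: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_ntac", _validate_pmf(self.p_ntac, "p_ntac"))
        object.__setattr__(self, "p_ntab", _validate_pmf(self.p_ntab, "p_ntab"))


def null_effect(gene: str) -> GeneEffect:
    """A no-separation effect: both classes score from the latent null bins."""
    p = _latent_pmf(0.0)
    return GeneEffect(gene, p, p.copy())


def analytic_auc(effect: GeneEffect) -> float:
    """Exact P(S_ntac > S_ntab) + 0.5 P(S_ntac = S_ntab) over the 7x7 grid.

    This is the population AUC of the single-gene score as a classifier of
    NTAC vs NTAB, with the conventional one-half credit for ties.
    """
    joint = np.outer(effect.p_ntac, effect.p_ntab)  # [ntac score, ntab score]
    greater = np.tril(joint, k=-1).sum()
    equal = np.trace(joint)
    return float(greater + 0.5 * equal)


def _latent_pmf(shift: float) -> np.ndarray:
    """Bin probabilities of N(shift, 1) under the fixed cut points."""
    cdf = norm.cdf(LATENT_CUTS - shift)
    return np.diff(cdf)


def effect_from_auc(gene: str, target_auc: float, tolerance: float = 0.005) -> GeneEffect:
    """Calibrate a GeneEffect to a target analytic AUC by bisection.

    The one-parameter family shifts the NTAC latent mean: NTAB scores come
    from N(0,1), NTAC from N(shift,1), both discretized at the fixed cuts.
    AUC is strictly increasing in the shift, so bisection on [0, 10] is
    well-posed.  The family saturates below 1 (NTAB keeps mass in the top
    bin), so a target beyond its reach raises :class:`CalibrationError`.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError(f"target_auc must be in [0.5, 1), got {target_auc}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    p_ntab = _latent_pmf(0.0)

    def auc_at(shift: float) -> float:
        return analytic_auc(GeneEffect(gene, _latent_pmf(shift), p_ntab))

    lo, hi = 0.0, 10.0
    if abs(target_auc - 0.5) <= tolerance * 0.5:
        return GeneEffect(gene, _latent_pmf(0.0), p_ntab)  # exact null case
    if auc_at(hi) < target_auc - tolerance:
        raise CalibrationError(
            f"target AUC {target_auc} unreachable within the latent-shift family "
            f"(max ~{auc_at(hi):.3f})"
        )
    # bisection: auc_at is monotone increasing in the shift
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        a = auc_at(mid)
        if abs(a - target_auc) <= tolerance * 0.5:
            break
        if a < target_auc:
            lo = mid
        else:
            hi = mid
    else:  # pragma: no cover - bisection on a monotone map always terminates above
        raise CalibrationError("bisection failed to converge")
    return GeneEffect(gene, _latent_pmf(mid), p_ntab)


@dataclass(frozen=True)
class ScoreMatrix:
    """Samples x genes ordinal RISH score matrix with sample metadata.

    ``scores`` is an integer DataFrame (rows: sample ids, columns: genes,
    values in 0..6); ``tissue`` and ``class_label`` are Series aligned on the
    same index; ``class_label`` takes values NTAC/NTAB.
    """

    scores: pd.DataFrame
    tissue: pd.Series
    class_label: pd.Series
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = self.scores.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicated sample id {dup!r}")
        if not (self.tissue.index.equals(idx) and self.class_label.index.equals(idx)):
            raise ValueError("tissue/class_label index must match the score rows")
        vals = self.scores.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("scores must be integers")
        if vals.size and (vals.min() < 0 or vals.max() > 6):
            raise ValueError("scores must lie in 0..6")
        bad = set(self.class_label.unique()) - {NTAC, NTAB}
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)!r}")
        if len(set(self.scores.columns)) != self.scores.shape[1]:
            raise ValueError("gene names must be unique")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def class_values(self, gene: str, label: str) -> np.ndarray:
        """Scores of one gene restricted to one class."""
        return self.scores.loc[self.class_label == label, gene].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame with tissue/class metadata columns first."""
        out = pd.DataFrame(
            {"tissue": self.tissue, "class": self.class_label}, index=self.scores.index
        )
        return pd.concat([out, self.scores], axis=1)

    def equals(self, other: "ScoreMatrix") -> bool:
        return (
            self.scores.equals(other.scores)
            and self.tissue.equals(other.tissue)
            and self.class_label.equals(other.class_label)
        )


def _gene_rng(seed: int, gene: str) -> np.random.Generator:
    """Counter-based per-gene stream: keyed by (seed, crc32(gene name)).

    Keying by gene name rather than panel position means adding or removing
    a gene never perturbs the draws of the others.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(crc32(gene.encode()),)))


def simulate_cohort(
    design: CohortDesign,
    effects: Sequence[GeneEffect],
    seed: int,
    tissue_shift: Mapping[str, int] | None = None,
) -> ScoreMatrix:
    """Draw a cohort: each sample's gene scores i.i.d. from its class pmf.

    Parameters
    ----------
    design
        Tissue-group composition; class counts are matched exactly (group
        sizes are design constants, not sampled).
    effects
        One :class:`GeneEffect` per panel gene; order defines column order.
    seed
        Master seed; per-gene substreams are derived from it by name.
    tissue_shift
        Optional robustness hook: integer score offset per tissue name,
        added after class-conditional sampling and clipped to 0..6.
    """
    genes = [e.gene for e in effects]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene in effects panel")
    if not genes:
        raise ValueError("effects panel is empty")

    sample_ids: list[str] = []
    tissues: list[str] = []
    labels: list[str] = []
    for g in design.groups:
        stem = g.tissue_name.replace(" ", "_")
        for i in range(g.n_cases):
            sample_ids.append(f"{stem}-{i + 1:03d}")
            tissues.append(g.tissue_name)
            labels.append(g.adjacent_label)

    is_ntac = np.array([lab == NTAC for lab in labels])
    n = len(sample_ids)
    cols = {}
    for eff in effects:
        rng = _gene_rng(seed, eff.gene)
        u = rng.random(n)
        # inverse-cdf under the sample's own class distribution
        cum_ntac = np.cumsum(eff.p_ntac)
        cum_ntab = np.cumsum(eff.p_ntab)
        s = np.where(
            is_ntac,
            np.searchsorted(cum_ntac, u, side="right"),
            np.searchsorted(cum_ntab, u, side="right"),
        )
        cols[eff.gene] = np.minimum(s, 6)  # guard the u ~ 1.0 edge

    scores = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"), dtype=np.int64)
    if tissue_shift:
        offsets = np.array([tissue_shift.get(t, 0) for t in tissues])[:, None]
        scores = pd.DataFrame(
            np.clip(scores.to_numpy() + offsets, 0, 6),
            index=scores.index,
            columns=scores.columns,
            dtype=np.int64,
        )
    return ScoreMatrix(
        scores=scores,
        tissue=pd.Series(tissues, index=scores.index, name="tissue"),
        class_label=pd.Series(labels, index=scores.index, name="class"),
        seed=seed,
    )
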