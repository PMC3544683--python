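"""Semi-quantitative RISH scoring of tissue-microarray cores.

A core is read out as (i) the fraction of positive cells and (ii) an ordinal
staining-density category (0 none, 1 light, 2 deep, 3 black).  The fraction
is binned into a ratio category 0-3 and the composite expression score is
the sum of the two categories, 0-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ScoreMatrix

__all__ = ["CoreMeasurement", "ratio_score", "composite_score", "score_cores"]

# Ratio-category bin edges. The printed bins ("<25%", "25% to 50%",
# "51% to 75%", ">75%") leave the gaps (50%, 51%) and the point 75%
# ambiguous on a continuous fraction; boundaries are resolved as
# [0,.25) -> 0, [.25,.50] -> 1, (.50,.75] -> 2, (.75,1] -> 3 so that every
# fraction in [0,1] maps to exactly one category with the printed anchor
# points preserved.


@dataclass(frozen=True)
class CoreMeasurement:
    """One core's readout: positive-cell fraction and density category."""

    positive_fraction: float
    density_category: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError(
                f"positive_fraction must be in [0, 1], got {self.positive_fraction}"
            )
        if self.density_category not in (0, 1, 2, 3):
            raise ValueError(
                f"density_category must be one of 0..3, got {self.density_category}"
            )


def ratio_score(positive_fraction: float) -> int:
    """Bin a positive-cell fraction into the ratio category 0-3."""
    f = float(positive_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"positive_fraction must be in [0, 1], got {f}")
    if f < 0.25:
        return 0
    if f <= 0.50:
        return 1
    if f <= 0.75:
        return 2
    return 3


def composite_score(m: CoreMeasurement) -> int:
    """Composite expression score 0-6: ratio category + density category."""
    return ratio_score(m.positive_fraction) + m.density_category


def score_cores(
    measurements: pd.DataFrame,
    tissue: pd.Series,
    class_label: pd.Series,
) -> ScoreMatrix:
    """Apply the composite rule to a full sample x gene table of cores.

    ``measurements`` holds a :class:`CoreMeasurement` in every cell (rows:
    sample ids, columns: genes); ``tissue``/``class_label`` are metadata
    Series on the same index, passed through to the resulting
    :class:`~fieldmarker.cohort.ScoreMatrix`.
    """
    if measurements.isna().any().any():
        r, c = np.argwhere(measurements.isna().to_numpy())[0]
        raise ValueError(
            f"incomplete measurement table: missing core at sample "
            f"{measurements.index[r]!r}, gene {measurements.columns[c]!r}"
        )
    scores = measurements.map(composite_score).astype(np.int64)
    return ScoreMatrix(scores=scores, tissue=tissue, class_label=class_label)
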