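"""Score-matrix TSV I/O and heat-map export scaling.

The on-disk dialect is a UTF-8, LF-terminated TSV with header
``sample_id<TAB>tissue<TAB>class<TAB><gene1>...`` ; class is NTAC or NTAB
and scores are integers 0..6.  Reading validates and names the offending
row/column on failure; write-then-read round-trips losslessly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import NTAB, NTAC, ScoreMatrix

__all__ = ["FormatError", "read_score_matrix", "write_score_matrix", "zscale_for_heatmap"]

META_COLS = ("sample_id", "tissue", "class")


class FormatError(ValueError):
    """Score-matrix file violates the declared TSV dialect."""


def read_score_matrix(path) -> ScoreMatrix:
    """Read and validate a score matrix from the TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str, "class": str})
    for col in META_COLS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    genes = [c for c in df.columns if c not in META_COLS]
    if not genes:
        raise FormatError("no gene columns found")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicated sample id {dup.iloc[0]!r}")
    bad = df.loc[~df["class"].isin([NTAC, NTAB]), ["sample_id", "class"]]
    if not bad.empty:
        raise FormatError(
            f"unknown class label {bad['class'].iloc[0]!r} at sample {bad['sample_id'].iloc[0]!r}"
        )
    scores = df[genes]
    for g in genes:
        col = pd.to_numeric(scores[g], errors="coerce")
        ok = col.notna() & (col == col.round()) & (col >= 0) & (col <= 6)
        if not ok.all():
            row = df["sample_id"][~ok].iloc[0]
            raise FormatError(f"score out of range 0..6 at sample {row!r}, gene {g!r}")
    idx = pd.Index(df["sample_id"], name="sample_id")
    return ScoreMatrix(
        scores=scores.astype(np.int64).set_axis(idx, axis=0),
        tissue=df["tissue"].set_axis(idx).rename("tissue"),
        class_label=df["class"].set_axis(idx).rename("class"),
    )


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    """Write a score matrix in the TSV dialect (lossless round trip)."""
    matrix.to_frame().to_csv(path, sep="\t", index=True, lineterminator="\n")


def zscale_for_heatmap(matrix: ScoreMatrix, eps: float = 1e-12) -> pd.DataFrame:
    """Per-gene z-scores (sample-SD convention, ddof=1) clipped to [-3, 3].

    A constant gene maps to all zeros via the epsilon-floored SD.
    """
    x = matrix.scores.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    z = (x - mu) / np.maximum(sd, eps)
    return pd.DataFrame(
        np.clip(z, -3.0, 3.0), index=matrix.scores.index, columns=matrix.scores.columns
    )
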