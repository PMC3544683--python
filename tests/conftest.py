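import numpy as np
import pandas as pd
import pytest

from fieldmarker import (
    ScoreMatrix,
    default_design,
    default_panel,
    effect_from_auc,
    null_effect,
    simulate_cohort,
)


def make_matrix(scores_by_gene: dict, labels: list, tissues: list | None = None) -> ScoreMatrix:
    """Build a small ScoreMatrix from per-gene score lists and class labels."""
    n = len(labels)
    idx = pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id")
    scores = pd.DataFrame(scores_by_gene, index=idx, dtype=np.int64)
    return ScoreMatrix(
        scores=scores,
        tissue=pd.Series(tissues or ["liver"] * n, index=idx, name="tissue"),
        class_label=pd.Series(labels, index=idx, name="class"),
    )


@pytest.fixture(scope="session")
def strong_effect():
    """TP53-like effect calibrated to analytic AUC 0.87."""
    return effect_from_auc("TP53", 0.87, tolerance=0.005)


@pytest.fixture(scope="session")
def spiked_cohort(strong_effect):
    """Default 314-sample cohort: TP53 at AUC 0.87 among 14 null genes."""
    effects = [
        strong_effect if g == "TP53" else null_effect(g) for g in default_panel()
    ]
    return simulate_cohort(default_design(), effects, seed=20260101)
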