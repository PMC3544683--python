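"""Model/results front end tying the pipeline stages together.

:class:`MarkerDiscovery` is built from a :class:`~fieldmarker.cohort.ScoreMatrix`
(or a flat DataFrame) plus the analysis configuration; :meth:`MarkerDiscovery.fit`
runs the three analysis stages — per-gene rank-sum testing, single-gene CV
AUC, and filter-ranked incremental subset selection — and returns a
:class:`MarkerDiscoveryResults` carrying the tables, traces and best subsets,
with a ``summary()`` text report and a ``save()`` that writes the full
report bundle.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import ScoreMatrix
from .filters import CRITERIA
from .io import write_score_matrix, zscale_for_heatmap
from .ranktests import GeneTestResult, differential_panel
from .selection import (
    BestSubset,
    ClassifierSpec,
    CVSpec,
    SelectionTrace,
    best_subset,
    incremental_selection,
    single_gene_aucs,
)

__all__ = ["MarkerDiscovery", "MarkerDiscoveryResults"]


def _tests_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results]).set_index("gene")
    return df[["rank_sum_W", "z", "p_two_sided", "p_adjusted", "direction", "mean_difference"]]


class MarkerDiscovery:
    """Marker-discovery analysis of an NTAC/NTAB ordinal score cohort."""

    def __init__(
        self,
        data: ScoreMatrix,
        alpha: float = 0.05,
        criteria: Sequence[str] = CRITERIA,
        classifier: ClassifierSpec | None = None,
        cv: CVSpec | None = None,
    ) -> None:
        unknown = set(criteria) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria {sorted(unknown)}")
        self.data = data
        self.alpha = alpha
        self.criteria = tuple(criteria)
        self.classifier = classifier or ClassifierSpec()
        self.cv = cv or CVSpec()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "MarkerDiscovery":
        """Build from a flat DataFrame with sample_id/tissue/class columns."""
        idx = pd.Index(df["sample_id"].astype(str), name="sample_id")
        genes = [c for c in df.columns if c not in ("sample_id", "tissue", "class")]
        matrix = ScoreMatrix(
            scores=df[genes].astype("int64").set_axis(idx, axis=0),
            tissue=df["tissue"].set_axis(idx).rename("tissue"),
            class_label=df["class"].set_axis(idx).rename("class"),
        )
        return cls(matrix, **kwargs)

    def fit(self) -> "MarkerDiscoveryResults":
        timings: dict[str, float] = {}
        t0 = time.perf_counter()
        tests = differential_panel(self.data, alpha=self.alpha)
        timings["differential"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        per_gene_auc = single_gene_aucs(self.data, self.classifier, self.cv)
        timings["single_gene_auc"] = time.perf_counter() - t0

        traces: dict[str, SelectionTrace] = {}
        bests: dict[str, BestSubset] = {}
        for crit in self.criteria:
            t0 = time.perf_counter()
            tr = incremental_selection(self.data, crit, self.classifier, self.cv)
            traces[crit] = tr
            bests[crit] = best_subset(tr)
            timings[f"selection[{crit}]"] = time.perf_counter() - t0

        return MarkerDiscoveryResults(
            model=self,
            gene_tests=_tests_frame(tests),
            single_gene_auc=per_gene_auc,
            traces=traces,
            best_subsets=bests,
            timings=timings,
        )


@dataclass
class MarkerDiscoveryResults:
    """Fitted marker-discovery analysis: tables, traces and best subsets."""

    model: MarkerDiscovery
    gene_tests: pd.DataFrame
    single_gene_auc: pd.DataFrame
    traces: dict[str, SelectionTrace]
    best_subsets: dict[str, BestSubset]
    timings: dict[str, float]

    def config(self) -> dict:
        m = self.model
        return {
            "alpha": m.alpha,
            "criteria": list(m.criteria),
            "classifier": asdict(m.classifier),
            "cv": asdict(m.cv),
            "n_samples": m.data.n_samples,
            "n_genes": len(m.data.genes),
            "cohort_seed": m.data.seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def summary(self) -> str:
        """Plain-text report of the three analysis stages."""
        m = self.model
        lines = []
        lines.append("Marker discovery: NTAC vs NTAB")
        lines.append("=" * 64)
        n_ntac = int((m.data.class_label == "NTAC").sum())
        n_ntab = int((m.data.class_label == "NTAB").sum())
        lines.append(
            f"Samples: {m.data.n_samples} ({n_ntac} NTAC / {n_ntab} NTAB)   "
            f"Genes: {len(m.data.genes)}"
        )
        lines.append(
            f"CV: {m.cv.n_repeats} x {m.cv.n_folds}-fold stratified, seed {m.cv.seed}   "
            f"alpha = {m.alpha}"
        )
        lines.append("")
        lines.append("Per-gene rank-sum tests (NTAC vs NTAB)")
        lines.append("-" * 64)
        tab = self.gene_tests.copy()
        tab["single_gene_auc"] = self.single_gene_auc["mean_auc"]
        with pd.option_context("display.float_format", lambda v: f"{v:.4g}"):
            lines.append(tab.to_string())
        lines.append("")
        lines.append("Best gene subsets by wrapper selection")
        lines.append("-" * 64)
        for crit, bs in self.best_subsets.items():
            lines.append(
                f"{crit:>14}: AUC {bs.mean_auc:.4f}  k={len(bs.genes)}  "
                f"[{', '.join(bs.genes)}]"
            )
        n_over = int((self.gene_tests["direction"] == "over").sum())
        n_under = int((self.gene_tests["direction"] == "under").sum())
        lines.append("")
        lines.append(f"Direction calls: {n_over} overexpressed, {n_under} underexpressed in NTAC")
        return "\n".join(lines)

    def save(self, outdir, matrix_too: bool = False, plots: bool = False) -> dict[str, str]:
        """Write the report bundle; returns {artifact: path}.

        Numeric formats are fixed (P scientific, AUC to 4 decimals) so
        reruns at the same seed are byte-identical.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, str] = {}

        def _put(name: str, fname: str, df: pd.DataFrame, formats: dict | None = None) -> None:
            df = df.copy()
            for col, fmt in (formats or {}).items():
                df[col] = df[col].map(lambda v: fmt % v)
            path = outdir / fname
            df.to_csv(path, sep="\t", lineterminator="\n")
            written[name] = str(path)

        _put(
            "differential", "differential.tsv", self.gene_tests,
            {"rank_sum_W": "%.1f", "z": "%.4f", "p_two_sided": "%.6e",
             "p_adjusted": "%.6e", "mean_difference": "%.4f"},
        )
        _put(
            "single_gene_auc", "single_gene_auc.tsv", self.single_gene_auc,
            {"mean_auc": "%.4f", "sd_auc": "%.4f"},
        )
        for crit, tr in self.traces.items():
            _put(
                f"trace[{crit}]", f"trace_{crit}.tsv",
                tr.to_frame().set_index("k"),
                {"mean_auc": "%.4f", "sd_auc": "%.4f"},
            )
        best = pd.DataFrame(
            [
                {"criterion": c, "k": len(b.genes), "mean_auc": b.mean_auc,
                 "genes": "+".join(b.genes)}
                for c, b in self.best_subsets.items()
            ]
        ).set_index("criterion")
        _put("best_subsets", "best_subsets.tsv", best, {"mean_auc": "%.4f"})

        heat = zscale_for_heatmap(self.model.data).round(4)
        heat.insert(0, "class", self.model.data.class_label)
        heat.insert(0, "tissue", self.model.data.tissue)
        path = outdir / "heatmap_zscores.tsv"
        heat.to_csv(path, sep="\t", float_format="%.4f", lineterminator="\n")
        written["heatmap"] = str(path)

        if matrix_too:
            path = outdir / "score_matrix.tsv"
            write_score_matrix(self.model.data, path)
            written["score_matrix"] = str(path)

        log = {
            "config": self.config(),
            "config_hash": self.config_hash(),
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }
        path = outdir / "run_log.json"
        path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        written["log"] = str(path)

        if plots:
            written.update(self._render_plots(outdir))
        return written

    def _render_plots(self, outdir: Path) -> dict[str, str]:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        written = {}
        fig, axes = plt.subplots(
            1, len(self.traces), figsize=(4 * len(self.traces), 3.2), squeeze=False
        )
        for ax, (crit, tr) in zip(axes[0], self.traces.items()):
            k = range(1, len(tr.mean_auc) + 1)
            ax.errorbar(k, tr.mean_auc, yerr=tr.sd_auc, fmt="o-", ms=3, capsize=2)
            ax.set_title(crit)
            ax.set_xlabel("genes in group")
            ax.set_ylabel("CV AUC")
        fig.tight_layout()
        path = outdir / "selection_traces.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["trace_plot"] = str(path)

        z = zscale_for_heatmap(self.model.data)
        order = self.model.data.class_label.sort_values(kind="stable").index
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(z.loc[order].to_numpy().T, aspect="auto", cmap="RdBu_r",
                       vmin=-3, vmax=3)
        ax.set_yticks(range(len(z.columns)), z.columns, fontsize=6)
        ax.set_xlabel("samples (NTAB then NTAC)")
        fig.colorbar(im, ax=ax, label="z score")
        fig.tight_layout()
        path = outdir / "heatmap.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written["heatmap_plot"] = str(path)
        return written
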