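"""Model/Results front-end over the staged selection pipeline.

:class:`GeneSelectionModel` is constructed from data (matrix + labels, a
DataFrame, or files) together with a :class:`~vewselect.pipeline.PipelineConfig`;
``fit()`` executes the configured number of independent pipeline runs and
returns a :class:`GeneSelectionResults` carrying the selected gene subset,
per-classifier cross-validated metrics with their run-to-run spread, the
optimizer's convergence traces and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, load_expression, preprocess
from .filters import GeneSubset
from .pipeline import (
    PipelineConfig,
    RunRecord,
    metrics_table,
    report,
    run_many,
    select_final_subset,
)


class GeneSelectionModel:
    """Three-stage hybrid gene selection bound to one expression dataset.

    Parameters
    ----------
    data
        An :class:`ExpressionDataset` (raw values are preprocessed —
        mean-imputed and min-max normalized — at construction).
    config
        Pipeline configuration; keyword overrides are applied on top, e.g.
        ``GeneSelectionModel(ds, n_runs=5, seed=7)``.
    """

    def __init__(self, data: ExpressionDataset, config: PipelineConfig | None = None,
                 **overrides):
        cfg = config if config is not None else PipelineConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        self.config = cfg
        self.raw_data = data
        self.data = preprocess(data) if (data.has_missing or _out_of_unit(data)) else data

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_column: str,
                       config: PipelineConfig | None = None, **overrides
                       ) -> "GeneSelectionModel":
        """Build from a samples x genes DataFrame with an embedded label column."""
        labels = frame[label_column].to_numpy()
        matrix = frame.drop(columns=[label_column])
        ds = ExpressionDataset(matrix.to_numpy(dtype=float),
                               [str(c) for c in matrix.columns], labels)
        return cls(ds, config=config, **overrides)

    @classmethod
    def from_files(cls, matrix_path: str | Path, labels: str | Path,
                   orientation: str = "samples-by-genes",
                   config: PipelineConfig | None = None, **overrides
                   ) -> "GeneSelectionModel":
        ds = load_expression(matrix_path, labels, orientation=orientation)
        return cls(ds, config=config, **overrides)

    # -- estimation -------------------------------------------------------
    def fit(self, n_runs: int | None = None, seed: int | None = None
            ) -> "GeneSelectionResults":
        """Run the pipeline ``n_runs`` times and resolve the final subset."""
        cfg = self.config
        updates = {}
        if n_runs is not None:
            updates["n_runs"] = n_runs
        if seed is not None:
            updates["seed"] = seed
        if updates:
            cfg = dataclasses.replace(cfg, **updates)
        records = run_many(self.data, cfg)
        final = select_final_subset(records)
        return GeneSelectionResults(self, cfg, records, final)


def _out_of_unit(ds: ExpressionDataset) -> bool:
    return bool(np.nanmin(ds.values) < 0 or np.nanmax(ds.values) > 1)


class GeneSelectionResults:
    """Fitted selection: the chosen genes plus evaluation diagnostics."""

    def __init__(self, model: GeneSelectionModel, config: PipelineConfig,
                 records: list[RunRecord], final_subset: GeneSubset):
        self.model = model
        self.config = config
        self.records = records
        self.subset_ = final_subset

    @property
    def selected_genes(self) -> tuple[str, ...]:
        return self.subset_.gene_ids

    @property
    def n_selected(self) -> int:
        return len(self.subset_)

    @property
    def metrics(self) -> pd.DataFrame:
        """Classifier x measure table of cross-run mean and SD."""
        return metrics_table(self.records)

    @property
    def traces(self) -> list[tuple[float, ...]]:
        return [r.trace for r in self.records]

    @property
    def mean_acc(self) -> float:
        m = self.metrics
        return float(m.loc[m["measure"] == "acc", "mean"].mean())

    def stage_sizes(self) -> dict:
        """Median genes-in/out per stage across runs (the narrowing funnel)."""
        sizes: dict[str, list[int]] = {}
        for r in self.records:
            for label, n in r.stage_sizes().items():
                sizes.setdefault(label, []).append(n)
        return {label: int(np.median(v)) for label, v in sizes.items()}

    def save(self, out_dir: str | Path) -> dict:
        """Write metric tables, final subset, traces and the parameter manifest."""
        return report(self.records, self.subset_, out_dir, cfg=self.config)

    def plot_convergence(self, ax=None):
        """Best-fitness trace per run (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for r in self.records:
            if r.trace:
                ax.plot(r.trace, alpha=0.6, label=f"seed {r.seed}")
        ax.set_xlabel("iteration")
        ax.set_ylabel("best fitness")
        ax.set_title("whale-optimizer convergence")
        return ax

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels-style."""
        cfg = self.config
        lines = []
        lines.append("Hybrid gene selection (%s) results" % cfg.ablation_tag)
        lines.append("=" * 54)
        lines.append(f"samples: {self.model.data.n_samples:>6}    "
                     f"genes: {self.model.data.n_genes:>6}    runs: {cfg.n_runs}")
        lines.append(f"variance threshold: {cfg.variance_threshold}    "
                     f"alpha: {cfg.alpha}    seed: {cfg.seed}")
        lines.append("-" * 54)
        lines.append("stage funnel (median genes out per stage):")
        for label, n in self.stage_sizes().items():
            lines.append(f"  {label:<10} {n:>8}")
        lines.append(f"final subset: {self.n_selected} gene(s)")
        shown = ", ".join(self.selected_genes[:8])
        if self.n_selected > 8:
            shown += ", ..."
        lines.append(f"  [{shown}]")
        lines.append("-" * 54)
        lines.append(f"{'classifier':<12}{'Acc':>10}{'Pre':>10}{'Recall':>10}{'F1':>10}")
        table = self.metrics
        for tag in table["classifier"].unique():
            sub = table[table["classifier"] == tag].set_index("measure")
            lines.append(
                f"{tag:<12}"
                + "".join(f"{sub.loc[m, 'mean']:>10.4f}"
                          for m in ("acc", "precision", "recall", "f1"))
            )
            lines.append(
                f"{'  (SD)':<12}"
                + "".join(f"{sub.loc[m, 'sd']:>10.4f}"
                          for m in ("acc", "precision", "recall", "f1"))
            )
        lines.append("=" * 54)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<GeneSelectionResults: {self.n_selected} genes, "
                f"mean Acc {self.mean_acc:.3f}>")
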