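"""Three-stage selection pipeline, repeated runs and reporting.

The full pipeline is: preprocess (mean-impute, min-max normalize) ->
variance filter -> extremely-randomized-tree importance filter -> binary
whale-optimization wrapper -> external cross-validated evaluation with
DT/SVM/LR. Two-stage ablations fall out of the ``stages`` tuple: drop
"variance" for an ERT+WOA run, drop "ert" for variance+WOA, drop "woa" for
the pure filter pair.

Because the wrapper stage is stochastic, repeated independent runs (default
10, differing only by spawned seeds) can return different subsets with the
same performance. ``select_final_subset`` resolves this with three ordered
principles: highest mean accuracy across the configured classifiers; among
ties, the smallest subset; among remaining ties, the subset composition
recurring most often across runs (residual ties: lowest run seed).

Two selection protocols are exposed. ``global`` (default) selects genes once
on ALL samples and then cross-validates the chosen subset — the customary
protocol in the comparative gene-selection literature, but note the selected
genes have seen the evaluation data, so CV scores are optimistically biased.
``nested`` reselects genes inside each training fold and predicts the
held-out fold for an honest (and much slower) estimate.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, preprocess
from .errors import EmptySelectionError, VewError
from .evaluation import (
    CVReport,
    METRIC_NAMES,
    aggregate_runs,
    compute_metrics,
    confusion_counts,
    crossval_evaluate,
    make_classifier,
)
from .filters import (
    DEFAULT_VARIANCE_THRESHOLD,
    ERTConfig,
    GeneSubset,
    ert_filter,
    ert_importance,
    variance_filter,
)
from .woa import FitnessContext, WOAParams, run_woa

ALL_STAGES = ("variance", "ert", "woa")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the three-stage pipeline in one place."""

    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    ert: ERTConfig = field(default_factory=ERTConfig)
    woa: WOAParams = field(default_factory=WOAParams)
    alpha: float = 0.99
    knn_k: int = 5
    inner_folds: int = 5
    classifiers: tuple[str, ...] = ("dt", "svm", "lr")
    eval_folds: int = 10
    n_runs: int = 10
    seed: int = 42
    selection_mode: str = "global"
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.selection_mode not in ("global", "nested"):
            raise ValueError("selection_mode must be 'global' or 'nested'")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not self.stages:
            raise ValueError("at least one stage required")

    @property
    def ablation_tag(self) -> str:
        """Short tag naming the stage composition (e.g. 'VEW', 'VW', 'EW', 'VE')."""
        letters = {"variance": "V", "ert": "E", "woa": "W"}
        return "".join(letters[s] for s in ALL_STAGES if s in self.stages)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunRecord:
    """Everything one pipeline run produced."""

    seed: int
    subsets: dict  # stage label -> GeneSubset, in execution order
    final_subset: GeneSubset
    best_fitness: float | None
    trace: tuple[float, ...]
    cv_reports: dict  # classifier tag -> CVReport
    stage_seconds: dict

    @property
    def mean_acc(self) -> float:
        """Mean accuracy across the evaluated classifiers (subset-choice principle 1)."""
        return float(np.mean([r.metric_means["acc"] for r in self.cv_reports.values()]))

    def stage_sizes(self) -> dict:
        return {label: len(sub) for label, sub in self.subsets.items()}


def _ensure_preprocessed(ds: ExpressionDataset) -> ExpressionDataset:
    vals = ds.values
    if ds.has_missing or np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        return preprocess(ds)
    return ds


def select_genes(
    ds: ExpressionDataset,
    cfg: PipelineConfig,
    seed: int,
) -> tuple[dict, GeneSubset, float | None, tuple[float, ...], dict]:
    """Run the configured stages once; returns (subsets, final, fitness, trace, timings)."""
    ds = _ensure_preprocessed(ds)
    subsets: dict = {}
    timings: dict = {}
    current = GeneSubset.full(ds)
    best_fitness: float | None = None
    trace: tuple[float, ...] = ()
    stage = cfg.stages[0]
    try:
        if "variance" in cfg.stages:
            stage = "variance"
            t0 = time.perf_counter()
            current = variance_filter(ds, cfg.variance_threshold)
            timings["variance"] = time.perf_counter() - t0
            subsets["variance"] = current
        if "ert" in cfg.stages:
            stage = "ert"
            t0 = time.perf_counter()
            ert_cfg = dataclasses.replace(cfg.ert, seed=seed)
            scores = ert_importance(ds, current, ert_cfg)
            current = ert_filter(scores, current, ert_cfg.zero_tolerance)
            timings["ert"] = time.perf_counter() - t0
            subsets["ert"] = current
        if "woa" in cfg.stages:
            stage = "woa"
            t0 = time.perf_counter()
            ctx = FitnessContext.from_dataset(
                ds, current, alpha=cfg.alpha, knn_k=cfg.knn_k,
                inner_folds=cfg.inner_folds, fold_seed=seed,
            )
            result = run_woa(ctx, dataclasses.replace(cfg.woa, seed=seed))
            current = result.selected(current)
            best_fitness, trace = result.fitness, result.trace
            timings["woa"] = time.perf_counter() - t0
            subsets["woa"] = current
    except EmptySelectionError as err:
        raise EmptySelectionError(f"stage {stage!r} left no genes: {err}") from err
    return subsets, current, best_fitness, trace, timings


def _nested_cv_report(
    ds: ExpressionDataset,
    cfg: PipelineConfig,
    classifier: str,
    seed: int,
) -> CVReport:
    """Honest protocol: reselect genes inside each training fold."""
    from sklearn.model_selection import StratifiedKFold

    ds = _ensure_preprocessed(ds)
    y = ds.labels
    _, counts = np.unique(y, return_counts=True)
    folds = min(cfg.eval_folds, max(2, int(counts.min())))
    if folds < cfg.eval_folds:
        warnings.warn(f"outer folds reduced {cfg.eval_folds} -> {folds}", stacklevel=2)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = tuple(np.unique(y).tolist())
    fold_metrics = []
    for k, (train, test) in enumerate(splitter.split(ds.values, y)):
        train_ds = ExpressionDataset(
            ds.values[train], list(ds.gene_ids), y[train], ds.missing_mask[train]
        )
        _, subset, _, _, _ = select_genes(train_ds, cfg, seed + 1000 * (k + 1))
        clf = make_classifier(classifier, seed=seed)
        clf.fit(subset.restrict(ds.values[train]), y[train])
        pred = clf.predict(subset.restrict(ds.values[test]))
        fold_metrics.append(
            compute_metrics(confusion_counts(y[test], pred, classes=classes),
                            classifier=classifier)
        )
    means = {m: float(np.mean([fm.as_dict()[m] for fm in fold_metrics]))
             for m in METRIC_NAMES}
    return CVReport(classifier, folds, tuple(fold_metrics), means,
                    {m: 0.0 for m in METRIC_NAMES})


def run_vew(ds: ExpressionDataset, cfg: PipelineConfig, seed: int | None = None) -> RunRecord:
    """One pipeline run: staged selection plus per-classifier evaluation.

    The containment chain (each stage's subset contained in the previous
    stage's) is asserted before returning.
    """
    seed = cfg.seed if seed is None else seed
    ds = _ensure_preprocessed(ds)
    subsets, final, best_fitness, trace, timings = select_genes(ds, cfg, seed)

    chain = list(subsets.values())
    for later, earlier in zip(chain[1:], chain[:-1]):
        if not later.issubset(earlier):
            raise VewError("stage containment chain violated")  # pragma: no cover

    cv_reports = {}
    t0 = time.perf_counter()
    for tag in cfg.classifiers:
        if cfg.selection_mode == "nested":
            cv_reports[tag] = _nested_cv_report(ds, cfg, tag, seed)
        else:
            cv_reports[tag] = crossval_evaluate(
                ds, final, classifier=tag, folds=cfg.eval_folds, seed=seed
            )
    timings["evaluation"] = time.perf_counter() - t0
    return RunRecord(
        seed=seed,
        subsets=subsets,
        final_subset=final,
        best_fitness=best_fitness,
        trace=trace,
        cv_reports=cv_reports,
        stage_seconds=timings,
    )


def run_many(ds: ExpressionDataset, cfg: PipelineConfig) -> list[RunRecord]:
    """``cfg.n_runs`` independent repetitions differing only by spawned seeds."""
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_runs) % (2**31)
    return [run_vew(ds, cfg, seed=int(s)) for s in child_seeds]


def select_final_subset(records: list[RunRecord]) -> GeneSubset:
    """Resolve repeated runs into one subset by the three ordered principles.

    (1) highest mean accuracy over the configured classifiers, (2) smallest
    subset among ties, (3) most frequently recurring gene composition among
    remaining ties; residual ties go to the lowest run seed.
    """
    if not records:
        raise ValueError("no run records")
    freq: dict[tuple, int] = {}
    for r in records:
        freq[r.final_subset.gene_ids] = freq.get(r.final_subset.gene_ids, 0) + 1
    best = min(
        records,
        key=lambda r: (
            -r.mean_acc,
            len(r.final_subset),
            -freq[r.final_subset.gene_ids],
            r.seed,
        ),
    )
    return best.final_subset


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def metrics_table(records: list[RunRecord]) -> pd.DataFrame:
    """Long-form table: one row per classifier x metric with cross-run mean and SD."""
    rows = []
    classifiers = records[0].cv_reports.keys()
    for tag in classifiers:
        agg = aggregate_runs([r.cv_reports[tag] for r in records])
        for m in METRIC_NAMES:
            rows.append({
                "classifier": tag.upper(),
                "measure": m,
                "mean": agg.metric_means[m],
                "sd": agg.metric_sds[m],
            })
    return pd.DataFrame(rows)


def report(records: list[RunRecord], final: GeneSubset, out_dir: str | Path,
           cfg: PipelineConfig | None = None) -> dict:
    """Write metric tables, the final subset, traces and a parameter manifest.

    Output content is fully determined by (data, config, seed): no
    timestamps, so byte-identical re-runs are checkable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    table = metrics_table(records)
    table.to_csv(out / "metrics.csv", index=False)
    written["metrics"] = out / "metrics.csv"

    lines = ["gene_id\tgene_index"]
    for gid, idx in zip(final.gene_ids, final.indices.tolist()):
        lines.append(f"{gid}\t{idx}")
    (out / "final_subset.tsv").write_text("\n".join(lines) + "\n")
    written["final_subset"] = out / "final_subset.tsv"

    trace_rows = []
    for r in records:
        for it, fit in enumerate(r.trace):
            trace_rows.append({"seed": r.seed, "iteration": it, "best_fitness": fit})
    pd.DataFrame(trace_rows).to_csv(out / "traces.csv", index=False)
    written["traces"] = out / "traces.csv"

    manifest = {
        "config": cfg.to_dict() if cfg is not None else None,
        "runs": [
            {
                "seed": r.seed,
                "stage_sizes": r.stage_sizes(),
                "best_fitness": r.best_fitness,
                "mean_acc": r.mean_acc,
                "n_selected": len(r.final_subset),
            }
            for r in records
        ],
        "final_subset_size": len(final),
        "final_gene_ids": list(final.gene_ids),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = out / "manifest.json"
    return written
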