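"""Filter stages: variance threshold and extremely-randomized-tree importance.

Stage 1 removes genes whose per-gene (population) variance on the
normalized [0, 1] scale does not exceed a threshold (default 0.05). Stage 2
fits an ensemble of extremely randomized trees on all samples — no
bootstrap, randomized split thresholds — and eliminates genes whose
impurity-based importance is (numerically) zero. Both stages emit a
:class:`GeneSubset` expressed in the ORIGINAL gene coordinates so that
subsets from successive stages form a containment chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .datasets import ExpressionDataset
from .errors import DegenerateTargetError, EmptySelectionError, StructuralError

DEFAULT_VARIANCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class GeneSubset:
    """An ordered set of retained gene columns, in original coordinates.

    ``indices`` are strictly increasing positions into the original gene
    space; ``gene_ids`` are the matching identifiers; ``stage_label`` records
    which stage produced the subset ("variance", "ert", "woa", ...).
    """

    indices: np.ndarray
    gene_ids: tuple[str, ...]
    stage_label: str = "custom"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if idx.ndim != 1:
            raise StructuralError("subset indices must be 1-D")
        if idx.size and (np.diff(idx) <= 0).any():
            raise StructuralError("subset indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise StructuralError("subset indices must be non-negative")
        if len(self.gene_ids) != idx.size:
            raise StructuralError("gene_ids misaligned with indices")

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset, indices, stage_label: str) -> "GeneSubset":
        idx = np.asarray(sorted(int(i) for i in indices), dtype=int)
        if idx.size and idx[-1] >= ds.n_genes:
            raise StructuralError("subset index beyond gene count")
        return cls(idx, tuple(ds.gene_ids[i] for i in idx), stage_label)

    @classmethod
    def full(cls, ds: ExpressionDataset, stage_label: str = "all") -> "GeneSubset":
        return cls(np.arange(ds.n_genes), tuple(ds.gene_ids), stage_label)

    def __len__(self) -> int:
        return int(self.indices.size)

    def __contains__(self, index: int) -> bool:
        return bool(np.isin(index, self.indices))

    def issubset(self, other: "GeneSubset") -> bool:
        return bool(np.isin(self.indices, other.indices).all())

    def restrict(self, values: np.ndarray) -> np.ndarray:
        """View of a samples x genes matrix restricted to this subset's columns."""
        return values[:, self.indices]


@dataclass(frozen=True)
class ERTConfig:
    """Extremely-randomized-trees ensemble settings.

    ``n_trees`` is the ensemble size M. ``max_features`` is the number of
    candidate genes examined per split; ``None`` means ceil(sqrt(D)) for D
    candidate genes. ``zero_tolerance`` is the numeric floor below which an
    importance counts as zero.
    """

    n_trees: int = 100
    max_depth: int | None = None
    max_features: int | None = None
    seed: int = 0
    zero_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.zero_tolerance < 0:
            raise ValueError("zero_tolerance must be >= 0")


@dataclass(frozen=True)
class ImportanceScores:
    """Per-candidate-gene importances; non-negative, summing to 1 when any is positive."""

    scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", arr)
        if (arr < 0).any():
            raise ValueError("importance scores must be non-negative")

    def __len__(self) -> int:
        return int(self.scores.size)


def variance_filter(
    ds: ExpressionDataset,
    threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> GeneSubset:
    """Retain genes whose population variance is strictly above ``threshold``.

    Intended for preprocessed data on the [0, 1] scale, where the variance
    can be at most 0.25 and the default 0.05 threshold is meaningful.
    """
    if threshold < 0:
        raise ValueError("variance threshold must be non-negative")
    variances = ds.values.var(axis=0)  # population variance (divide by m)
    keep = np.flatnonzero(variances > threshold)
    if keep.size == 0:
        raise EmptySelectionError(
            f"no gene has variance > {threshold}; lower the threshold"
        )
    return GeneSubset.from_dataset(ds, keep, "variance")


def gene_variances(ds: ExpressionDataset, subset: GeneSubset | None = None) -> np.ndarray:
    """Population variance per gene (optionally restricted to a subset)."""
    values = ds.values if subset is None else subset.restrict(ds.values)
    return values.var(axis=0)


def _resolve_max_features(cfg: ERTConfig, n_candidates: int) -> int:
    if cfg.max_features is not None:
        return min(cfg.max_features, n_candidates)
    return min(n_candidates, math.ceil(math.sqrt(n_candidates)))


def ert_importance(
    ds: ExpressionDataset,
    subset: GeneSubset,
    cfg: ERTConfig = ERTConfig(),
) -> ImportanceScores:
    """Impurity-based importances from an extremely-randomized-trees ensemble.

    The ensemble is fit on ALL samples (no bootstrap) over the candidate
    genes. Returned scores sum to 1 whenever any split produced impurity
    gain; an all-constant candidate matrix yields all-zero scores.
    """
    if len(subset) == 0:
        raise EmptySelectionError("candidate subset is empty")
    if np.unique(ds.labels).size < 2:
        raise DegenerateTargetError("labels contain a single class")
    X = subset.restrict(ds.values)
    forest = ExtraTreesClassifier(
        n_estimators=cfg.n_trees,
        bootstrap=False,
        max_depth=cfg.max_depth,
        max_features=_resolve_max_features(cfg, len(subset)),
        random_state=cfg.seed,
    )
    forest.fit(X, ds.labels)
    return ImportanceScores(forest.feature_importances_)


def ert_filter(
    scores: ImportanceScores,
    subset: GeneSubset,
    zero_tolerance: float = 1e-12,
) -> GeneSubset:
    """Drop genes whose importance is numerically zero.

    Keeps genes with score strictly above ``zero_tolerance`` and re-expresses
    the result in original gene coordinates.
    """
    if len(scores) != len(subset):
        raise StructuralError("scores not aligned with subset")
    keep_local = np.flatnonzero(scores.scores > zero_tolerance)
    if keep_local.size == 0:
        raise EmptySelectionError("every importance score is (numerically) zero")
    return GeneSubset(
        subset.indices[keep_local],
        tuple(subset.gene_ids[i] for i in keep_local),
        "ert",
    )
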