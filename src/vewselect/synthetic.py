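"""Synthetic microarray-like fixtures with known ground truth.

Emulates the statistical shape of public microarray classification data —
a huge gene dimension against a tiny, class-imbalanced sample count, a
handful of class-informative genes, many pure-noise genes, some degenerate
near-constant genes and a small fraction of missing cells — so every
selection stage is testable without downloading anything.

Model: noise genes are i.i.d. Gaussian(0, noise_sd^2) per sample;
informative genes get a per-class mean shift of ``effect_size * noise_sd``
between adjacent classes (a standardized effect); near-constant genes are
exactly constant columns (dead/saturated probes — min-max normalization is
scale-invariant, so any nonzero jitter would be stretched to order-one
variance, which is not what a dead probe looks like after preprocessing);
missing cells are injected uniformly at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import ExpressionDataset, write_expression
from .filters import GeneSubset


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; the defaults emulate a small two-class microarray study."""

    n_samples: int = 60
    n_genes: int = 1000
    n_informative: int = 10
    n_near_constant: int = 50
    effect_size: float = 2.5
    class_proportions: tuple[float, ...] = (0.6, 0.4)
    missing_rate: float = 0.02
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_near_constant > self.n_genes:
            raise ValueError("informative + near-constant genes exceed n_genes")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if len(self.class_proportions) < 2:
            raise ValueError("at least 2 classes required")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 2 * len(self.class_proportions):
            raise ValueError("need at least 2 samples per class")


@dataclass(frozen=True)
class SyntheticDataset:
    """An ExpressionDataset plus its planted ground truth."""

    dataset: ExpressionDataset
    informative_indices: np.ndarray
    near_constant_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    spec: SyntheticSpec | None = None

    @property
    def n_informative(self) -> int:
        return int(self.informative_indices.size)


def _class_counts(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic per-class counts matching the proportions within +-1."""
    raw = np.array(spec.class_proportions) * spec.n_samples
    counts = np.floor(raw).astype(int)
    remainder = spec.n_samples - counts.sum()
    order = np.argsort(-(raw - counts))  # largest fractional parts first
    counts[order[:remainder]] += 1
    return counts


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a dataset fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    m, n, K = spec.n_samples, spec.n_genes, len(spec.class_proportions)

    counts = _class_counts(spec)
    class_idx = rng.permutation(np.repeat(np.arange(K), counts))
    labels = np.array([f"class{k}" for k in class_idx], dtype=object)

    values = rng.normal(0.0, spec.noise_sd, size=(m, n))

    special = rng.choice(n, size=spec.n_informative + spec.n_near_constant,
                         replace=False)
    informative = np.sort(special[: spec.n_informative])
    near_constant = np.sort(special[spec.n_informative:])

    # adjacent classes separated by effect_size * noise_sd on informative genes
    class_means = np.arange(K) * spec.effect_size * spec.noise_sd
    values[:, informative] += class_means[class_idx][:, None]

    base = rng.uniform(0.5, 5.0, size=near_constant.size)
    values[:, near_constant] = base[None, :]

    if spec.missing_rate > 0:
        missing = rng.random((m, n)) < spec.missing_rate
        fully_missing = np.flatnonzero(missing.all(axis=0))
        for j in fully_missing:  # every gene keeps >= 1 observed value
            missing[rng.integers(m), j] = False
        values = np.where(missing, np.nan, values)

    gene_ids = [f"G{j:05d}" for j in range(n)]
    ds = ExpressionDataset(values, gene_ids, labels)
    return SyntheticDataset(ds, informative, near_constant, spec)


def recovery_score(selected: GeneSubset, truth: SyntheticDataset) -> tuple[float, float]:
    """(precision, recall) of a selected subset against the planted informative genes."""
    informative = set(truth.informative_indices.tolist())
    chosen = set(selected.indices.tolist())
    hits = len(chosen & informative)
    precision = hits / len(chosen) if chosen else 0.0
    recall = hits / len(informative) if informative else 0.0
    return precision, recall


def write_dataset(
    truth: SyntheticDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Emit the matrix + labels in the layout the loaders read, plus a truth sidecar."""
    write_expression(truth.dataset, matrix_path, labels_path=labels_path)
    if truth_path is not None:
        lines = ["gene_index\tgene_id\trole"]
        for j in truth.informative_indices.tolist():
            lines.append(f"{j}\t{truth.dataset.gene_ids[j]}\tinformative")
        for j in truth.near_constant_indices.tolist():
            lines.append(f"{j}\t{truth.dataset.gene_ids[j]}\tnear_constant")
        Path(truth_path).write_text("\n".join(lines) + "\n")
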