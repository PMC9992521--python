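"""Expression-matrix container, readers/writers and preprocessing.

The central object is :class:`ExpressionDataset`: a samples x genes real
matrix with gene identifiers, per-sample class labels and a mask of the
originally-missing cells. Preprocessing follows the standard microarray
recipe for this kind of pipeline: per-gene mean imputation of missing
values followed by per-gene min-max normalization onto [0, 1].

Missing cells are represented as ``numpy.nan`` inside ``values``;
``missing_mask`` permanently records which cells were missing in the raw
input even after imputation fills them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeneError,
    OrderingError,
    ParseError,
    StructuralError,
)

#: Tokens accepted as "missing" in delimited text dumps.
NA_TOKENS = frozenset({"", "NA", "NaN", "nan", "?"})

SAMPLES_BY_GENES = "samples-by-genes"
GENES_BY_SAMPLES = "genes-by-samples"


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with labels.

    Parameters
    ----------
    values
        Real matrix, shape ``(n_samples, n_genes)``. Missing cells hold NaN.
    gene_ids
        Unique gene identifiers, positionally aligned with columns.
    labels
        One class label per sample (2 or more distinct classes expected for
        supervised stages).
    missing_mask
        Boolean matrix marking originally-missing cells. Defaults to the
        NaN pattern of ``values``.
    """

    values: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = np.asarray(self.labels)
        m, n = self.values.shape
        if len(self.gene_ids) != n:
            raise StructuralError(
                f"{len(self.gene_ids)} gene IDs for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise StructuralError(f"duplicate gene IDs: {dupes[:5]}")
        if self.labels.shape != (m,):
            raise StructuralError(
                f"{self.labels.size} labels for {m} sample rows"
            )
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise StructuralError("missing_mask shape differs from values")

    # -- basic views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct class labels in sorted order."""
        return np.unique(self.labels)

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(),
            list(self.gene_ids),
            self.labels.copy(),
            self.missing_mask.copy(),
        )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _detect_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_numeric(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Parse a string frame into floats + missing mask, with coordinates on failure."""
    raw = frame.to_numpy(dtype=object)
    tokens = np.char.strip(raw.astype(str))
    missing = np.isin(tokens, list(NA_TOKENS))
    cleaned = np.where(missing, "nan", tokens)
    try:
        values = cleaned.astype(float)
    except ValueError:
        for (r, c), tok in np.ndenumerate(cleaned):
            try:
                float(tok)
            except ValueError:
                raise ParseError(
                    f"non-numeric token {tokens[r, c]!r} at row {r}, column {c}",
                    row=int(r),
                    column=int(c),
                ) from None
        raise  # pragma: no cover - unreachable
    values[missing] = np.nan
    return values, missing


def _read_labels_file(path: Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return np.array([ln for ln in lines if ln != ""], dtype=object)


def load_expression(
    matrix_path: str | Path,
    labels: str | Path,
    orientation: str = SAMPLES_BY_GENES,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus class labels.

    Parameters
    ----------
    matrix_path
        CSV/TSV file. For ``samples-by-genes`` the single header line holds
        the gene IDs and each following row is one sample. For
        ``genes-by-samples`` the first column holds gene IDs and each row is
        one gene (the header line holds sample names, which are ignored).
    labels
        Either a path to a one-token-per-sample label file, or (for
        samples-by-genes layouts) the name of a label column embedded in the
        matrix file.
    orientation
        ``"samples-by-genes"`` (default) or ``"genes-by-samples"``. Never
        guessed: transposed microarray dumps are common and silent guessing
        corrupts every downstream stage.
    sep
        Field delimiter; by default ``\\t`` for .tsv/.tab/.txt and ``,``
        otherwise.
    """
    matrix_path = Path(matrix_path)
    if orientation not in (SAMPLES_BY_GENES, GENES_BY_SAMPLES):
        raise StructuralError(f"unknown orientation {orientation!r}")
    delim = _detect_sep(matrix_path, sep)
    with open(matrix_path) as fh:
        header = [tok.strip() for tok in fh.readline().rstrip("\n").split(delim)]
    dupes = sorted({t for t in header if header.count(t) > 1})
    if dupes and orientation == SAMPLES_BY_GENES:
        # pandas silently renames duplicate columns, so check the raw header
        raise StructuralError(f"duplicate gene IDs in header: {dupes[:5]}")
    frame = pd.read_csv(matrix_path, sep=delim, header=0, dtype=str,
                        keep_default_na=False)

    label_values: np.ndarray | None = None
    if orientation == SAMPLES_BY_GENES:
        if not Path(str(labels)).exists() and str(labels) in frame.columns:
            label_values = frame[str(labels)].to_numpy(dtype=object)
            frame = frame.drop(columns=[str(labels)])
        gene_ids = [str(c) for c in frame.columns]
        values, missing = _parse_numeric(frame)
    else:
        gene_col = frame.columns[0]
        gene_ids = [str(g) for g in frame[gene_col]]
        values, missing = _parse_numeric(frame.drop(columns=[gene_col]))
        values, missing = values.T, missing.T

    if label_values is None:
        label_path = Path(str(labels))
        if not label_path.exists():
            raise StructuralError(
                f"labels {labels!r} is neither a file nor an embedded column"
            )
        label_values = _read_labels_file(label_path)

    if len(label_values) != values.shape[0]:
        raise StructuralError(
            f"{len(label_values)} labels for {values.shape[0]} samples"
        )
    return ExpressionDataset(values, gene_ids, label_values, missing)


def write_expression(
    ds: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    label_column: str | None = None,
    sep: str | None = None,
) -> None:
    """Round-trip writer emitting the same delimited layout ``load_expression`` reads.

    Missing cells are written as ``NA``. Labels go either to a sidecar file
    (``labels_path``) or into an embedded column (``label_column``).
    """
    matrix_path = Path(matrix_path)
    delim = _detect_sep(matrix_path, sep)
    frame = pd.DataFrame(ds.values, columns=ds.gene_ids)
    if label_column is not None:
        frame[label_column] = ds.labels
    frame.to_csv(matrix_path, sep=delim, index=False, na_rep="NA")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(str(l) for l in ds.labels) + "\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def impute_missing_mean(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace each missing cell by the mean of its gene's observed values.

    Observed cells are untouched. A gene with zero observed values has no
    defined mean and raises :class:`DegenerateGeneError`.
    """
    values = ds.values.copy()
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = [ds.gene_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise DegenerateGeneError(
            f"gene(s) with no observed values cannot be mean-imputed: {bad[:5]}"
        )
    if not observed.all():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_means = np.nanmean(values, axis=0)
            # the mean of identical observed values is that value exactly;
            # summation rounding must not create a spurious second level
            # that min-max normalization would stretch to the full [0,1] span
            col_min, col_max = np.nanmin(values, axis=0), np.nanmax(values, axis=0)
        col_means = np.where(col_min == col_max, col_min, col_means)
        rows, cols = np.nonzero(~observed)
        values[rows, cols] = col_means[cols]
    return replace(ds, values=values, gene_ids=list(ds.gene_ids),
                   labels=ds.labels.copy(), missing_mask=ds.missing_mask.copy())


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Map each gene affinely onto [0, 1]: ``x -> (x - min) / (max - min)``.

    Constant genes (max == min) are mapped to all-zeros with a warning:
    they carry no class information and are guaranteed casualties of the
    variance filter anyway. Must run after imputation.
    """
    if ds.has_missing:
        raise OrderingError("missing values present; run impute_missing_mean first")
    values = ds.values
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) normalized to all-zeros",
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    normalized = (values - lo) / safe_span
    normalized[:, constant] = 0.0
    return replace(ds, values=normalized, gene_ids=list(ds.gene_ids),
                   labels=ds.labels.copy(), missing_mask=ds.missing_mask.copy())


def preprocess(ds: ExpressionDataset) -> ExpressionDataset:
    """Mean imputation followed by min-max normalization."""
    return minmax_normalize(impute_missing_mean(ds))
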