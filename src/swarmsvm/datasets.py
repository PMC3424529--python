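"""Expression-matrix I/O and synthetic two-class data generation.

The package operates on a continuous samples x genes expression matrix with a
binary phenotype per sample (encoded +1/-1, e.g. tumor vs healthy).  Real data
arrives as delimited text, either with samples as rows and a label column
(default) or in the transposed orientation common to public microarray exports
(genes as rows, one label row).  Label encodings must be declared explicitly --
nothing is inferred from alphabetic order, so the sign of per-class error
reports is never ambiguous.

A seeded synthetic generator plants a small set of informative genes whose
class-conditional means are shifted by a chosen effect size (in units of the
within-class standard deviation) among many pure-noise genes.  Because the
planted indices are known, the generator provides ground truth for
selection-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "ExpressionDataset",
    "SyntheticGroundTruth",
    "read_expression_dataset",
    "write_expression_dataset",
    "generate_synthetic_dataset",
    "parse_label_mapping",
]

#: strings treated as missing expression values / labels on load
_NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "NULL", "null", "None"}


class DataValidationError(ValueError):
    """Raised when a dataset violates the expression-matrix contract."""


@dataclass
class ExpressionDataset:
    """A samples x genes matrix with binary labels and unique identifiers.

    Parameters
    ----------
    matrix
        Real-valued array of shape ``(n_samples, n_genes)``; no missing values.
    labels
        Per-sample class in ``{+1, -1}``.
    gene_ids
        One unique string per column.
    sample_ids
        One unique string per row.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: list
    sample_ids: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.matrix.ndim != 2:
            raise DataValidationError("expression matrix must be 2-dimensional")
        n, d = self.matrix.shape
        if self.labels.shape != (n,):
            raise DataValidationError(
                f"expected {n} labels (one per sample), got {self.labels.shape}"
            )
        if not np.all(np.isin(self.labels, (-1, 1))):
            bad = sorted(set(self.labels) - {-1, 1})
            raise DataValidationError(f"labels must be +1/-1, found {bad}")
        if len(self.gene_ids) != d:
            raise DataValidationError(
                f"expected {d} gene identifiers, got {len(self.gene_ids)}"
            )
        if len(set(self.gene_ids)) != d:
            raise DataValidationError("gene identifiers must be unique")
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise DataValidationError("sample identifiers must be unique, one per row")
        if not np.all(np.isfinite(self.matrix)):
            raise DataValidationError("expression matrix contains missing/non-finite values")
        if np.unique(self.labels).size < 2:
            warnings.warn(
                "dataset contains a single class; training will fail", UserWarning,
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, indices) -> "ExpressionDataset":
        """Column subset (preserving order of *indices*)."""
        idx = np.asarray(list(indices), dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[:, idx],
            labels=self.labels.copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, indices) -> "ExpressionDataset":
        """Row subset (preserving order of *indices*)."""
        idx = np.asarray(list(indices), dtype=int)
        with warnings.catch_warnings():
            # single-class subsets are legitimate intermediates (e.g. CV folds
            # under inspection); training still rejects them.
            warnings.simplefilter("ignore", UserWarning)
            return ExpressionDataset(
                matrix=self.matrix[idx],
                labels=self.labels[idx],
                gene_ids=list(self.gene_ids),
                sample_ids=[self.sample_ids[i] for i in idx],
            )

    def zscore_genes(self) -> "ExpressionDataset":
        """Per-gene standardisation (optional preprocessing; off by default)."""
        mu = self.matrix.mean(axis=0)
        sd = self.matrix.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return replace(self, matrix=(self.matrix - mu) / sd)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Which genes were planted as informative, and under what conditions."""

    informative_gene_indices: frozenset
    effect_size: float
    seed: int


def parse_label_mapping(text: str) -> dict:
    """Parse a CLI-style label mapping such as ``"ALL=1,AML=-1"``."""
    mapping = {}
    for part in text.split(","):
        if "=" not in part:
            raise ValueError(f"bad label mapping entry {part!r}; expected NAME=+1|-1")
        name, _, value = part.partition("=")
        mapping[name.strip()] = int(value)
    return mapping


def _delimiter_for(path, delimiter):
    if delimiter is not None:
        return delimiter
    return "\t" if Path(path).suffix.lower() in {".tsv", ".txt"} else ","


def _encode_labels(raw, sample_ids, label_mapping):
    missing = [sid for sid, v in zip(sample_ids, raw) if str(v).strip() in _NA_TOKENS]
    if missing:
        raise DataValidationError(f"missing class label for samples: {missing}")
    labels = []
    for sid, v in zip(sample_ids, raw):
        v = str(v).strip()
        if label_mapping is not None:
            if v not in label_mapping:
                raise DataValidationError(
                    f"label {v!r} of sample {sid!r} is not covered by the declared "
                    f"mapping {label_mapping}"
                )
            labels.append(int(label_mapping[v]))
        else:
            try:
                labels.append(int(float(v)))
            except ValueError:
                raise DataValidationError(
                    f"label {v!r} of sample {sid!r} is not numeric; declare an "
                    "explicit label mapping (e.g. ALL=1,AML=-1)"
                ) from None
    return np.asarray(labels, dtype=int)


def read_expression_dataset(
    path,
    orientation: str = "samples-as-rows",
    label_name: str = "label",
    label_mapping: dict | None = None,
    delimiter: str | None = None,
    sample_id_column: str | None = None,
    on_missing: str = "error",
) -> ExpressionDataset:
    """Load a delimited expression table into an :class:`ExpressionDataset`.

    Parameters
    ----------
    orientation
        ``"samples-as-rows"`` (default): header of gene ids plus a label
        column named *label_name*.  ``"genes-as-rows"``: first column holds
        gene ids, header holds sample ids, one row named *label_name* carries
        the labels.  Both orientations yield an identical dataset for the same
        underlying table.
    label_mapping
        Explicit mapping from label strings to +1/-1.  Without it, labels must
        already be numeric +1/-1.
    on_missing
        ``"error"`` (default) rejects missing expression cells, reporting their
        coordinates; ``"impute-mean"`` replaces them with the per-gene mean.
    """
    if orientation not in {"samples-as-rows", "genes-as-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if on_missing not in {"error", "impute-mean"}:
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    sep = _delimiter_for(path, delimiter)

    if orientation == "samples-as-rows":
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if sample_id_column is not None and sample_id_column in df.columns:
            sample_ids = [str(s) for s in df.pop(sample_id_column)]
        else:
            sample_ids = [f"s{i + 1}" for i in range(len(df))]
        if label_name not in df.columns:
            raise DataValidationError(f"no label column named {label_name!r}")
        raw_labels = list(df.pop(label_name))
        gene_ids = [str(c) for c in df.columns]
        expr = df
    else:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
        if label_name not in df.index:
            raise DataValidationError(f"no label row named {label_name!r}")
        raw_labels = list(df.loc[label_name])
        expr = df.drop(index=label_name).T  # -> samples as rows
        sample_ids = [str(s) for s in expr.index]
        gene_ids = [str(g) for g in expr.columns]

    labels = _encode_labels(raw_labels, sample_ids, label_mapping)

    matrix = np.empty((len(sample_ids), len(gene_ids)), dtype=float)
    for j, gene in enumerate(gene_ids):
        col = expr.iloc[:, j]
        # cell-exact strtod (pandas' fast to_numeric parser is not round-trip safe)
        values = np.full(len(col), np.nan)
        for i, cell in enumerate(col):
            cell = str(cell).strip()
            if cell in _NA_TOKENS:
                continue
            try:
                values[i] = float(cell)
            except ValueError:
                raise DataValidationError(
                    f"non-numeric expression value {cell!r} at sample "
                    f"{sample_ids[i]!r}, gene {gene!r}"
                ) from None
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size and on_missing == "error":
            coords = [(sample_ids[i], gene) for i in bad]
            raise DataValidationError(f"missing expression values at {coords}")
        if bad.size:  # impute-mean
            good = np.isfinite(values)
            if not good.any():
                raise DataValidationError(f"gene {gene!r} has no observed values")
            values[~good] = values[good].mean()
        matrix[:, j] = values

    return ExpressionDataset(matrix, labels, gene_ids, sample_ids)


def write_expression_dataset(
    dataset: ExpressionDataset,
    path,
    orientation: str = "samples-as-rows",
    label_name: str = "label",
    delimiter: str | None = None,
) -> None:
    """Write a dataset as delimited text; values keep full float precision.

    ``write`` followed by :func:`read_expression_dataset` in either orientation
    reproduces the matrix, labels and identifiers exactly.
    """
    sep = _delimiter_for(path, delimiter)
    frame = pd.DataFrame(
        dataset.matrix, index=pd.Index(dataset.sample_ids, name="sample_id"),
        columns=dataset.gene_ids,
    )
    frame[label_name] = dataset.labels
    if orientation == "samples-as-rows":
        frame.to_csv(path, sep=sep)
    elif orientation == "genes-as-rows":
        frame.T.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")


def generate_synthetic_dataset(
    n_samples: int,
    n_genes: int,
    n_informative: int,
    effect_size: float,
    seed: int,
) -> tuple[ExpressionDataset, SyntheticGroundTruth]:
    """Generate a two-class matrix with planted mean-shifted informative genes.

    Each gene is unit-variance Gaussian within class.  Noise genes share the
    same distribution in both classes; the ``n_informative`` planted genes have
    class means at ``+/- effect_size / 2`` (a between-class separation of
    ``effect_size`` within-class standard deviations, symmetric around zero).
    Labels alternate +1/-1 so the classes are balanced to within one sample.

    Returns the dataset together with a :class:`SyntheticGroundTruth` naming
    the planted gene columns.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4 (at least 2 per class)")
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not 0 < n_informative <= n_genes:
        raise ValueError("need 0 < n_informative <= n_genes")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")

    rng = np.random.default_rng(seed)
    labels = np.where(np.arange(n_samples) % 2 == 0, 1, -1)
    matrix = rng.standard_normal((n_samples, n_genes))
    informative = np.sort(rng.choice(n_genes, size=n_informative, replace=False))
    shift = effect_size / 2.0
    matrix[np.ix_(labels == 1, informative)] += shift
    matrix[np.ix_(labels == -1, informative)] -= shift

    dataset = ExpressionDataset(
        matrix=matrix,
        labels=labels,
        gene_ids=[f"g{j + 1}" for j in range(n_genes)],
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
    )
    truth = SyntheticGroundTruth(
        informative_gene_indices=frozenset(int(i) for i in informative),
        effect_size=float(effect_size),
        seed=int(seed),
    )
    return dataset, truth
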