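"""Reading, validation, normalization and filtering of expression data.

The central container is :class:`ExpressionMatrix`: a feature-by-sample
table of log2 intensities with a per-feature biotype tag (``mRNA`` or
``lncRNA``).  Class labels are a plain :class:`pandas.Series` mapping
sample id to ``case``/``control``; annotation collections hold GMT-style
gene sets over a declared universe.

All on-disk formats are plain text: tab-separated matrices with a header
row of sample ids, two-column TSV for labels and biotypes, and GMT for
annotations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

VALID_BIOTYPES = frozenset({"mRNA", "lncRNA"})
VALID_CLASSES = frozenset({"case", "control"})


class ValidationError(ValueError):
    """Raised when an input file or container violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Feature-by-sample log2 expression with per-feature biotypes.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
    biotype
        Series mapping every feature id to ``"mRNA"`` or ``"lncRNA"``.
    """

    values: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_f = idx[idx.duplicated()].unique()
        if len(dup_f):
            raise ValidationError(f"duplicate feature id(s): {list(dup_f)}")
        dup_s = cols[cols.duplicated()].unique()
        if len(dup_s):
            raise ValidationError(f"duplicate sample id(s): {list(dup_s)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        missing = idx.difference(self.biotype.index)
        if len(missing):
            raise ValidationError(f"feature(s) without biotype: {list(missing[:5])}")
        self.biotype = self.biotype.reindex(idx)
        bad = set(self.biotype.unique()) - VALID_BIOTYPES
        if bad:
            raise ValidationError(f"unknown biotype(s): {sorted(bad)}")

    # -- convenience ----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_biotype(self, biotype: str) -> "ExpressionMatrix":
        keep = self.biotype[self.biotype == biotype].index
        return ExpressionMatrix(self.values.loc[keep], self.biotype.loc[keep])


@dataclass
class AnnotationCollection:
    """GMT-style gene-set collection over a declared feature universe."""

    categories: dict[str, tuple[str, frozenset]]
    universe: frozenset

    def __post_init__(self) -> None:
        for cid, (_, members) in self.categories.items():
            if not members:
                raise ValidationError(f"empty category: {cid!r}")
            stray = members - self.universe
            if stray:
                raise ValidationError(
                    f"category {cid!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.categories)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, biotype_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus a two-column biotype table.

    The matrix file has a header row of sample ids and feature ids in the
    first column.  Duplicated ids, missing biotypes and non-numeric cells
    are hard errors that name the offending id or cell.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows[0]) < 2:
        raise ValidationError(f"{path}: not a feature-by-sample TSV matrix")
    header = rows[0][1:]
    feature_ids, data = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header) + 1:
            raise ValidationError(f"{path}: line {r} has {len(row)} fields, "
                                  f"expected {len(header) + 1}")
        feature_ids.append(row[0])
        vals = []
        for c, cell in enumerate(row[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{row[0]!r}, sample {header[c]!r}"
                ) from None
        data.append(vals)
    values = pd.DataFrame(data, index=pd.Index(feature_ids, name="feature_id"),
                          columns=header, dtype=float)
    biotype = read_biotypes(biotype_path)
    return ExpressionMatrix(values, biotype)


def write_matrix(matrix: ExpressionMatrix, path: str | Path,
                 biotype_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id",
                         float_format="%.10g")
    if biotype_path is not None:
        write_biotypes(matrix.biotype, biotype_path)


def read_biotypes(path: str | Path) -> pd.Series:
    tbl = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "biotype"],
                      dtype=str)
    dup = tbl.feature_id[tbl.feature_id.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate biotype entries: {list(dup.unique())}")
    return tbl.set_index("feature_id")["biotype"]


def write_biotypes(biotype: pd.Series, path: str | Path) -> None:
    biotype.to_csv(path, sep="\t", header=False)


def read_labels(path: str | Path,
                matrix: ExpressionMatrix | None = None) -> pd.Series:
    """Read a two-column (sample_id, class) TSV; classes are case/control."""
    tbl = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "klass"],
                      dtype=str)
    dup = tbl.sample_id[tbl.sample_id.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate label entries: {list(dup.unique())}")
    labels = tbl.set_index("sample_id")["klass"]
    validate_labels(labels, matrix)
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", header=False)


def validate_labels(labels: pd.Series,
                    matrix: ExpressionMatrix | None = None) -> None:
    bad = set(labels.unique()) - VALID_CLASSES
    if bad:
        raise ValidationError(f"unknown class label(s): {sorted(bad)}")
    if len(set(labels.unique())) < 2:
        raise ValidationError("both classes (case, control) must be non-empty")
    if matrix is not None:
        missing = matrix.sample_ids.difference(labels.index)
        if len(missing):
            raise ValidationError(f"sample(s) without label: {list(missing)}")


def read_gmt(path: str | Path, universe: set | None = None) -> AnnotationCollection:
    """Read a GMT file (category, description, tab-separated member ids).

    If *universe* is omitted it defaults to the union of all members.
    """
    categories: dict[str, tuple[str, frozenset]] = {}
    with open(path, newline="") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            cid, desc, members = parts[0], parts[1], frozenset(p for p in parts[2:] if p)
            if cid in categories:
                raise ValidationError(f"duplicate category id: {cid!r}")
            categories[cid] = (desc, members)
    if universe is None:
        universe = set().union(*(m for _, m in categories.values())) if categories else set()
    return AnnotationCollection(categories, frozenset(universe))


def write_gmt(annotations: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, (desc, members) in annotations.categories.items():
            fh.write("\t".join([cid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so every column shares one distribution.

    Each sample's values are replaced by the mean across samples of the
    sorted value vectors, re-ordered by the sample's own ranks.  Ties get
    the average of the reference values at the tied ranks.  Idempotent.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValidationError("quantile normalization requires >= 2 samples")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(1, arr.shape[0] + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")
        # average ranks (x.5) interpolate between adjacent reference values
        out[:, j] = np.interp(ranks, grid, reference)
    values = pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(values, matrix.biotype)


def filter_features(matrix: ExpressionMatrix, min_variance: float = 0.0,
                    max_features: int | None = None) -> ExpressionMatrix:
    """Keep features with variance >= *min_variance*, then the top
    *max_features* by variance, ordered by descending variance.

    Sample variance (ddof=1).  Raises if every feature is filtered out.
    """
    if min_variance < 0:
        raise ValidationError("min_variance must be >= 0")
    var = matrix.values.var(axis=1, ddof=1)
    keep = var[var >= min_variance]
    # stable sort keeps input order among exact variance ties
    keep = keep.sort_values(ascending=False, kind="stable")
    if max_features is not None:
        keep = keep.iloc[:max_features]
    if keep.empty:
        raise ValidationError("all features removed by variance filter")
    return ExpressionMatrix(matrix.values.loc[keep.index],
                            matrix.biotype.loc[keep.index])
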