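"""Two-group summaries, hierarchical clustering, and qPCR ddCt arithmetic.

Fold changes are differences of group means on the log2 scale, reported
alongside the linear fold 2^|log2FC| and an up/down/flat direction call.
Clustering for heatmap ordering uses correlation distance (1 - Pearson r)
with average linkage, the common microarray convention.  qPCR validation
follows the 2^-ddCt method: per-sample dCt = Ct_target - Ct_reference,
ddCt = mean(dCt, case) - mean(dCt, control), fold = 2^-ddCt, so a fold
above 1 means higher expression in cases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, ValidationError


@dataclass
class Dendrogram:
    """Agglomerative merge tree: (node_a, node_b, height) triples plus
    the resulting leaf order.  Node numbering is SciPy-style: leaves are
    0..n-1 in input order (``ids``); merge k creates node n+k."""

    merges: list[tuple[int, int, float]]
    ids: list
    leaf_order: list
    axis: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "axis": self.axis,
            "ids": list(map(str, self.ids)),
            "merges": [[int(a), int(b), float(h)] for a, b, h in self.merges],
            "leaf_order": list(map(str, self.leaf_order)),
        }, indent=2))

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch heights."""
        n = len(self.ids)
        nodes: dict[int, str] = {i: str(self.ids[i]) for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            la, lb = h - heights[a], h - heights[b]
            nodes[n + k] = f"({nodes[a]}:{la:g},{nodes[b]}:{lb:g})"
            heights[n + k] = h
        return nodes[max(nodes)] + ";"


@dataclass
class CtTable:
    """qPCR cycle-threshold table: genes x samples plus a reference gene."""

    ct: pd.DataFrame
    reference_gene: str
    classes: pd.Series

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.index:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} not in the table")
        arr = self.ct.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValidationError("all Ct values must be finite and > 0")
        aligned = self.classes.reindex(self.ct.columns)
        if aligned.isna().any():
            raise ValidationError("every sample needs a class label")
        for klass in ("case", "control"):
            if not (aligned == klass).any():
                raise ValidationError(f"no samples in class {klass!r}")
        self.classes = aligned


def fold_change(matrix: ExpressionMatrix, labels: pd.Series,
                log2fc_threshold: float = 1.0) -> pd.DataFrame:
    """Per-feature case-vs-control fold change on the log2 scale.

    Columns: mean_case, mean_control, log2_fold_change (their exact
    difference), linear_fold = 2^|log2FC|, and direction (up/down/flat by
    |log2FC| >= threshold).
    """
    aligned = labels.reindex(matrix.sample_ids)
    if aligned.isna().any():
        raise ValidationError("every sample needs a class label")
    case_cols = matrix.sample_ids[(aligned == "case").to_numpy()]
    ctrl_cols = matrix.sample_ids[(aligned == "control").to_numpy()]
    if len(case_cols) == 0 or len(ctrl_cols) == 0:
        raise ValidationError("both classes must have >= 1 sample")
    mean_case = matrix.values[case_cols].mean(axis=1)
    mean_control = matrix.values[ctrl_cols].mean(axis=1)
    lfc = mean_case - mean_control
    direction = np.where(lfc >= log2fc_threshold, "up",
                         np.where(lfc <= -log2fc_threshold, "down", "flat"))
    return pd.DataFrame({
        "mean_case": mean_case,
        "mean_control": mean_control,
        "log2_fold_change": lfc,
        "linear_fold": np.power(2.0, np.abs(lfc)),
        "direction": direction,
    }, index=matrix.feature_ids)


def correlation_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; constant rows get distance 1 to all
    others (correlation undefined), with a warning."""
    sd = data.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant vector(s): correlation "
                      "undefined, treated as distance 1 to all others")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    return np.clip(d, 0.0, None)


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "features",
                         ) -> Dendrogram:
    """Average-linkage agglomerative clustering with correlation distance.

    ``axis`` chooses whether features (rows) or samples (columns) are
    clustered; the returned leaf order is what a heatmap would use.
    """
    if axis == "features":
        data = matrix.values.to_numpy(dtype=float)
        ids = list(matrix.feature_ids)
    elif axis == "samples":
        data = matrix.values.to_numpy(dtype=float).T
        ids = list(matrix.sample_ids)
    else:
        raise ValidationError(f"axis must be 'features' or 'samples', got {axis!r}")
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    d = correlation_distance(data)
    z = linkage(squareform(d, checks=False), method="average")
    order = leaves_list(z)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(merges=merges, ids=ids,
                      leaf_order=[ids[i] for i in order], axis=axis)


def ddct_fold_change(ct: CtTable) -> pd.DataFrame:
    """2^-ddCt relative quantification of every target gene.

    Columns: delta_delta_ct and fold (2^-ddCt; > 1 means up in cases).
    """
    ref = ct.ct.loc[ct.reference_gene]
    case_cols = ct.classes[ct.classes == "case"].index
    ctrl_cols = ct.classes[ct.classes == "control"].index
    rows = []
    for gene in ct.ct.index:
        if gene == ct.reference_gene:
            continue
        dct = ct.ct.loc[gene] - ref
        ddct = float(dct[case_cols].mean() - dct[ctrl_cols].mean())
        rows.append((gene, ddct, float(2.0 ** -ddct)))
    return pd.DataFrame(rows, columns=["gene", "delta_delta_ct", "fold"]
                        ).set_index("gene")


def read_ct_table(path: str | Path, reference_gene: str,
                  labels: pd.Series) -> CtTable:
    """Read a genes-by-samples Ct TSV (header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CtTable(df, reference_gene, labels)
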