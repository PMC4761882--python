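"""Thresholded Pearson lncRNA-mRNA co-expression networks.

Every (lncRNA, mRNA) pair is scored by the sample Pearson correlation of
its expression profiles; pairs at or above the threshold (|r| in the
default absolute mode, signed r otherwise) become edges of a bipartite
graph.  The boundary is inclusive: r exactly equal to the threshold
yields an edge.  Within-biotype pairs are never tested.  Graphs export
to Cytoscape-readable SIF and GraphML, and to a lossless edge TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

_BOUNDARY_EPS = 1e-12  # keeps r == threshold inclusive despite float round-off


@dataclass
class CoexpressionNetwork:
    """Bipartite lncRNA-mRNA graph with Pearson edge weights.

    ``edges`` columns: lnc_id, mrna_id, r.  Nodes are the features
    incident to at least one edge, partitioned by biotype.
    """

    edges: pd.DataFrame
    threshold: float
    mode: str

    def __post_init__(self) -> None:
        if self.edges.empty:
            self.edges = pd.DataFrame(columns=["lnc_id", "mrna_id", "r"])
        elif self.edges.duplicated(["lnc_id", "mrna_id"]).any():
            raise ValidationError("duplicate edges")

    @property
    def lnc_nodes(self) -> list:
        return sorted(set(self.edges["lnc_id"]))

    @property
    def mrna_nodes(self) -> list:
        return sorted(set(self.edges["mrna_id"]))

    @property
    def n_nodes(self) -> int:
        return len(self.lnc_nodes) + len(self.mrna_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class DegreeSummary:
    """Per-node degrees plus per-partition min/max/mean and totals."""

    lnc_degree: dict
    mrna_degree: dict
    n_nodes: int
    n_edges: int

    @staticmethod
    def _stats(deg: dict) -> dict:
        if not deg:
            return {"min": 0, "max": 0, "mean": 0.0}
        vals = list(deg.values())
        return {"min": min(vals), "max": max(vals),
                "mean": float(np.mean(vals))}

    @property
    def lnc_stats(self) -> dict:
        return self._stats(self.lnc_degree)

    @property
    def mrna_stats(self) -> dict:
        return self._stats(self.mrna_degree)


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if x.size < 3:
        raise ValidationError("need >= 3 observations for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def build_network(matrix: ExpressionMatrix, threshold: float = 0.8,
                  mode: str = "absolute") -> CoexpressionNetwork:
    """Correlate every lncRNA against every mRNA and keep strong pairs.

    ``mode="absolute"`` keeps |r| >= threshold; ``mode="signed"`` keeps
    r >= threshold only.  Constant features have no defined correlation
    and are skipped with a warning.
    """
    if mode not in ("absolute", "signed"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    biotype = matrix.biotype
    lnc_ids = biotype.index[biotype == "lncRNA"]
    mrna_ids = biotype.index[biotype == "mRNA"]
    if len(lnc_ids) == 0 or len(mrna_ids) == 0:
        raise ValidationError("matrix must contain both lncRNA and mRNA features")

    def standardized(ids):
        arr = matrix.values.loc[ids].to_numpy(dtype=float)
        sd = arr.std(axis=1)
        const = sd == 0
        if const.any():
            warnings.warn(f"{const.sum()} constant feature(s) skipped: "
                          "correlation undefined")
        arr = arr - arr.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            arr = arr / np.sqrt((arr ** 2).sum(axis=1, keepdims=True))
        arr[const] = np.nan
        return arr

    lnc = standardized(lnc_ids)
    mrna = standardized(mrna_ids)
    r = lnc @ mrna.T  # (n_lnc, n_mrna) correlation block
    crit = np.abs(r) if mode == "absolute" else r
    with np.errstate(invalid="ignore"):
        keep = crit >= threshold - _BOUNDARY_EPS
    keep &= np.isfinite(r)
    li, mi = np.nonzero(keep)
    edges = pd.DataFrame({
        "lnc_id": lnc_ids[li],
        "mrna_id": mrna_ids[mi],
        "r": r[li, mi],
    })
    return CoexpressionNetwork(edges=edges, threshold=threshold, mode=mode)


def degree_summary(network: CoexpressionNetwork) -> DegreeSummary:
    """Exact degree tallies; lnc-side and mRNA-side degrees each sum to
    the edge count."""
    lnc_deg = network.edges["lnc_id"].value_counts().to_dict()
    mrna_deg = network.edges["mrna_id"].value_counts().to_dict()
    return DegreeSummary(lnc_degree=lnc_deg, mrna_degree=mrna_deg,
                         n_nodes=network.n_nodes, n_edges=network.n_edges)


def pathway_subnetwork(network: CoexpressionNetwork,
                       gene_set) -> CoexpressionNetwork:
    """Restrict to mRNA nodes in *gene_set*, their incident edges, and
    the lncRNA endpoints of those edges."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValidationError("gene set is empty")
    keep = network.edges["mrna_id"].isin(gene_set)
    if not keep.any():
        warnings.warn("gene set shares no mRNA with the network; "
                      "subnetwork is empty")
    return CoexpressionNetwork(edges=network.edges[keep].reset_index(drop=True),
                               threshold=network.threshold, mode=network.mode)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_graph(network: CoexpressionNetwork, path: str | Path,
                 format: str = "sif") -> None:
    """Write the network as Cytoscape-readable SIF or GraphML, or as a
    lossless edge TSV (lnc_id, mrna_id, r)."""
    fmt = format.lower()
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in network.edges.itertuples(index=False):
                fh.write(f"{e.lnc_id}\tcoexp\t{e.mrna_id}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for node in network.lnc_nodes:
            g.add_node(node, biotype="lncRNA")
        for node in network.mrna_nodes:
            g.add_node(node, biotype="mRNA")
        for e in network.edges.itertuples(index=False):
            g.add_edge(e.lnc_id, e.mrna_id, r=float(e.r))
        nx.write_graphml(g, path)
    elif fmt in ("tsv", "edge-tsv"):
        network.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValidationError(f"unknown format {format!r}; "
                              "use sif, graphml or edge-tsv")


def read_edge_tsv(path: str | Path, threshold: float,
                  mode: str = "absolute") -> CoexpressionNetwork:
    """Read back an edge TSV written by :func:`export_graph`."""
    edges = pd.read_csv(path, sep="\t",
                        dtype={"lnc_id": str, "mrna_id": str, "r": float})
    return CoexpressionNetwork(edges=edges, threshold=threshold, mode=mode)
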