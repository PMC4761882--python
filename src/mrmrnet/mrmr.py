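"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

The pipeline's core statistic.  Expression values are discretized into
three states around each feature's mean (below mu - t*sigma, within,
above mu + t*sigma).  Dependence between discrete vectors is the plug-in
mutual information

    I(x; y) = sum_xy p(x,y) * log2[ p(x,y) / (p(x) p(y)) ]

with empirical cell frequencies and 0*log0 = 0.  A feature's relevance is
D = I(feature; class); its redundancy against an already-selected set Vs
of m features is R = (1/m) * sum_{s in Vs} I(feature; s).  Greedy
selection picks argmax D in round 1 and thereafter argmax of the mRMR
score: D - R (MID, the default) or D / (R + eps) (MIQ).  Ties always go
to the earliest feature in input order, so rankings are deterministic.

The selection round h of each feature is recorded: smaller h means the
feature offered a better relevance/redundancy trade-off earlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

STATES = (-1, 0, 1)
MIQ_EPS = 1e-12  # division guard for the quotient scheme
_NEG_TOL = 1e-12  # clamp tiny negative MI from float round-off


@dataclass
class DiscretizedMatrix:
    """Three-state (-1/0/+1) version of an expression matrix."""

    states: pd.DataFrame          # int8, features x samples
    bin_edges: pd.DataFrame       # columns (low, high) per feature
    biotype: pd.Series

    @property
    def feature_ids(self) -> pd.Index:
        return self.states.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.states.columns


@dataclass
class MRMRSelection:
    """Ordered mRMR selection with per-round diagnostics.

    ``table`` columns: h (selection round, 1-based), feature_id, biotype,
    relevance D, redundancy R, and the scheme's score at selection time.
    """

    table: pd.DataFrame
    scheme: str
    total_features: int

    @property
    def selected_ids(self) -> list:
        return list(self.table["feature_id"])

    @property
    def selected_count(self) -> int:
        return len(self.table)

    @property
    def remaining_count(self) -> int:
        return self.total_features - len(self.table)


def discretize(matrix: ExpressionMatrix, t: float = 0.5) -> DiscretizedMatrix:
    """Discretize each feature to {-1, 0, +1} around mu +/- t*sigma.

    sigma is the sample standard deviation (ddof=1); constant features
    (sigma = 0) map entirely to state 0.
    """
    if t <= 0:
        raise ValidationError("threshold multiplier t must be > 0")
    arr = matrix.values.to_numpy(dtype=float)
    mu = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(arr.shape[0])
    low = mu - t * sd
    high = mu + t * sd
    states = np.zeros(arr.shape, dtype=np.int8)
    nonconst = sd > 0
    states[nonconst] = (arr[nonconst] > high[nonconst, None]).astype(np.int8) \
        - (arr[nonconst] < low[nonconst, None]).astype(np.int8)
    return DiscretizedMatrix(
        states=pd.DataFrame(states, index=matrix.feature_ids,
                            columns=matrix.sample_ids),
        bin_edges=pd.DataFrame({"low": low, "high": high},
                               index=matrix.feature_ids),
        biotype=matrix.biotype,
    )


def mutual_information(x, y) -> float:
    """Plug-in mutual information of two discrete vectors, in bits.

    Symmetric, >= 0 (tiny negative round-off is clamped to 0), and equal
    to the empirical entropy H(x) when y = x.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if x.size == 0:
        raise ValidationError("vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky)
    return _mi_from_counts(joint)


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
    if mi < 0:
        if mi < -_NEG_TOL:
            warnings.warn(f"MI round-off beyond tolerance: {mi}")
        mi = 0.0
    return mi


def entropy(x) -> float:
    """Empirical Shannon entropy in bits; equals I(x; x)."""
    x = np.asarray(x).ravel()
    _, counts = np.unique(x, return_counts=True)
    p = counts / x.size
    return float(-np.sum(p * np.log2(p)))


def _encode_labels(labels: pd.Series, sample_ids) -> np.ndarray:
    aligned = labels.reindex(sample_ids)
    if aligned.isna().any():
        missing = list(aligned.index[aligned.isna()])
        raise ValidationError(f"sample(s) without class label: {missing}")
    return (aligned.to_numpy() == "case").astype(np.int8)


def _mi_vector_vs_matrix(v: np.ndarray, states: np.ndarray) -> np.ndarray:
    """MI of one discrete vector against every row of a state matrix.

    Vectorized over features: builds each feature's joint table from
    boolean reductions, so selection over thousands of candidates stays
    fast.
    """
    v_states = np.unique(v)
    m_states = np.unique(states)
    nf, ns = states.shape
    joint = np.zeros((nf, len(v_states), len(m_states)))
    for a, va in enumerate(v_states):
        mask = v == va
        sub = states[:, mask]
        for b, mb in enumerate(m_states):
            joint[:, a, b] = (sub == mb).sum(axis=1)
    p = joint / ns
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    denom = px * py
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / denom), 0.0)
    mi = terms.sum(axis=(1, 2))
    return np.maximum(mi, 0.0)


def relevance(feature, labels_vector) -> float:
    """Relevance D of one discretized feature: its MI with the class."""
    return mutual_information(feature, labels_vector)


def redundancy(candidate, selected_set) -> float:
    """Redundancy R: mean MI of the candidate with each selected feature.

    Zero by convention when nothing has been selected yet.
    """
    selected_set = list(selected_set)
    if not selected_set:
        return 0.0
    return float(np.mean([mutual_information(candidate, s) for s in selected_set]))


def relevance_all(matrix: DiscretizedMatrix, labels: pd.Series) -> np.ndarray:
    """Relevance D of every feature, in the matrix's row order."""
    c = _encode_labels(labels, matrix.sample_ids)
    return _mi_vector_vs_matrix(c, matrix.states.to_numpy())


def maxrel_table(matrix: DiscretizedMatrix, labels: pd.Series) -> pd.DataFrame:
    """All features ranked by relevance D, descending; ties keep input order."""
    d = relevance_all(matrix, labels)
    tbl = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "biotype": matrix.biotype.reindex(matrix.feature_ids).to_numpy(),
        "D": d,
    })
    tbl = tbl.sort_values("D", ascending=False, kind="stable").reset_index(drop=True)
    tbl.insert(0, "rank", np.arange(1, len(tbl) + 1))
    return tbl


def mrmr_select(matrix: DiscretizedMatrix, labels: pd.Series, k: int,
                scheme: str = "MID") -> MRMRSelection:
    """Greedy mRMR selection of k features.

    Round 1 takes the maximum-relevance feature; each later round takes
    the remaining feature maximizing D - R (MID) or D / (R + eps) (MIQ).
    Deterministic: score ties go to the earliest feature in input order.
    """
    if scheme not in ("MID", "MIQ"):
        raise ValidationError(f"unknown scheme {scheme!r}; use MID or MIQ")
    states = matrix.states.to_numpy()
    nf = states.shape[0]
    if not 1 <= k <= nf:
        raise ValidationError(f"k must be in 1..{nf}, got {k}")
    d = relevance_all(matrix, labels)

    remaining = np.ones(nf, dtype=bool)
    mi_sum = np.zeros(nf)  # running sum of MI(candidate, each selected)
    rows = []
    for h in range(1, k + 1):
        m = h - 1
        r = mi_sum / m if m else np.zeros(nf)
        if scheme == "MID":
            score = d - r
        else:
            score = d / (r + MIQ_EPS)
        masked = np.where(remaining, score, -np.inf)
        pick = int(np.argmax(masked))  # argmax returns the first max: stable ties
        rows.append((h, matrix.feature_ids[pick],
                     matrix.biotype.iloc[pick], d[pick], r[pick], score[pick]))
        remaining[pick] = False
        mi_sum += _mi_vector_vs_matrix(states[pick], states)

    table = pd.DataFrame(rows, columns=["h", "feature_id", "biotype",
                                        "D", "R", "score"])
    return MRMRSelection(table=table, scheme=scheme, total_features=nf)
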