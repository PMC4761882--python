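"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exact rational arithmetic,
exhaustive enumeration, per-round rescans.  None of it shares code with
the package.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from fractions import Fraction


def exact_mi_bits(x, y) -> float:
    """Plug-in mutual information via exact rational cell frequencies.

    Returns sum p*log2(p/(px*py)) with the log taken only at the end, so
    all probability ratios are exact Fractions.
    """
    n = len(x)
    assert len(y) == n and n > 0
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p = Fraction(c, n)
        ratio = Fraction(c * n, px[a] * py[b])
        total += float(p) * math.log2(ratio)
    return max(total, 0.0)


def exact_entropy_bits(x) -> float:
    n = len(x)
    return -sum(float(Fraction(c, n)) * math.log2(Fraction(c, n))
                for c in Counter(x).values())


def mrmr_round_scores(features: dict, labels, selected, remaining,
                      scheme: str) -> dict:
    """One round of the mRMR rescan: score every remaining candidate
    against the already-selected set, from scratch."""
    eps = 1e-12
    scores = {}
    for f in remaining:
        d = exact_mi_bits(features[f], labels)
        if selected:
            r = sum(exact_mi_bits(features[f], features[s])
                    for s in selected) / len(selected)
        else:
            r = 0.0
        scores[f] = d - r if scheme == "MID" else d / (r + eps)
    return scores


def mrmr_greedy_rescan(features: dict, labels, k: int, scheme: str):
    """Greedy mRMR by full per-round rescan of every remaining candidate.

    ``features`` maps feature id -> discrete vector; iteration order of
    the dict defines tie-breaking (first strictly-best wins).  Returns
    the ordered list of selected ids.
    """
    selected: list = []
    remaining = list(features)
    for _ in range(k):
        scores = mrmr_round_scores(features, labels, selected, remaining,
                                   scheme)
        best = max(remaining, key=lambda f: scores[f])
        selected.append(best)
        remaining.remove(best)
    return selected


def hypergeom_upper_tail_enumeration(overlap, list_size, category_size,
                                     universe_size) -> float:
    """P(X >= overlap) by enumerating every possible draw (small universes)."""
    universe = range(universe_size)
    category = set(range(category_size))
    hits = total = 0
    for draw in itertools.combinations(universe, list_size):
        total += 1
        if len(category.intersection(draw)) >= overlap:
            hits += 1
    return float(Fraction(hits, total))


def pearson_naive(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def network_brute_force(matrix, threshold: float, mode: str):
    """All-pairs lncRNA x mRNA correlation with inclusive threshold."""
    lnc = [f for f in matrix.feature_ids if matrix.biotype[f] == "lncRNA"]
    mrna = [f for f in matrix.feature_ids if matrix.biotype[f] == "mRNA"]
    edges = set()
    for a in lnc:
        x = matrix.values.loc[a].tolist()
        if len(set(x)) == 1:
            continue
        for b in mrna:
            y = matrix.values.loc[b].tolist()
            if len(set(y)) == 1:
                continue
            r = pearson_naive(x, y)
            crit = abs(r) if mode == "absolute" else r
            if crit >= threshold - 1e-12:
                edges.add((a, b))
    return edges


def average_linkage_oracle(dist):
    """Naive agglomerative average linkage on a full distance matrix.

    Returns the list of merge heights in order (cluster identity is
    checked separately via leaf-order permutation tests).
    """
    n = len(dist)
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = sum(dist[i][j] for i in clusters[a] for j in clusters[b]) \
                / (len(clusters[a]) * len(clusters[b]))
            if best is None or h < best[0] - 1e-12:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        new_id = max(clusters) + 1
        clusters[new_id] = clusters.pop(a) + clusters.pop(b)
    return heights
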