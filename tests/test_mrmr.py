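import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmrnet import (SyntheticConfig, ValidationError, discretize, entropy,
                     generate_expression, maxrel_table, mrmr_select,
                     mutual_information, redundancy, relevance, relevance_all)
from mrmrnet.mrmr import DiscretizedMatrix

from ._oracles import (exact_entropy_bits, exact_mi_bits, mrmr_greedy_rescan,
                       mrmr_round_scores)
from .conftest import make_matrix

discrete_vectors = st.lists(st.integers(-1, 1), min_size=2, max_size=12)


def make_discretized(states, labels=None):
    """DiscretizedMatrix from an integer array (features x samples)."""
    states = np.asarray(states, dtype=np.int8)
    nf, ns = states.shape
    fids = [f"F{i + 1}" for i in range(nf)]
    sids = [f"S{j + 1}" for j in range(ns)]
    disc = DiscretizedMatrix(
        states=pd.DataFrame(states, index=pd.Index(fids, name="feature_id"),
                            columns=sids),
        bin_edges=pd.DataFrame({"low": np.zeros(nf), "high": np.zeros(nf)},
                               index=fids),
        biotype=pd.Series(["mRNA"] * nf, index=fids),
    )
    lab = None
    if labels is not None:
        lab = pd.Series(np.where(np.asarray(labels) == 1, "case", "control"),
                        index=sids)
    return disc, lab


class TestDiscretize:
    def test_constant_feature_all_zero(self):
        m = make_matrix([[5.0] * 6])
        assert (discretize(m).states.to_numpy() == 0).all()

    def test_two_level_feature_split(self):
        m = make_matrix([[0, 0, 0, 10, 10, 10]])
        states = discretize(m, t=0.5).states.to_numpy()[0]
        np.testing.assert_array_equal(states, [-1, -1, -1, 1, 1, 1])

    def test_huge_t_maps_all_to_zero(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(5, 10)))
        assert (discretize(m, t=100.0).states.to_numpy() == 0).all()

    def test_bin_edges_ordered(self):
        rng = np.random.default_rng(1)
        edges = discretize(make_matrix(rng.normal(size=(5, 10)))).bin_edges
        assert (edges["low"] <= edges["high"]).all()

    def test_invalid_t_rejected(self, small_matrix):
        with pytest.raises(ValidationError):
            discretize(small_matrix, t=0.0)


class TestMutualInformation:
    def test_identical_fair_binary_is_one_bit(self):
        x = [-1, -1, 1, 1]
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_empirically_independent_is_zero(self):
        assert mutual_information([-1, -1, 1, 1], [-1, 1, -1, 1]) == 0.0

    def test_plug_in_matches_enumerated_cells(self):
        # joint counts (0,0)x2 (0,1)x1 (1,0)x1 (1,1)x2 over six samples
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert mutual_information(x, y) == pytest.approx(exact_mi_bits(x, y),
                                                         abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information([0, 1], [0, 1, 1])

    @settings(derandomize=True, max_examples=200)
    @given(discrete_vectors, discrete_vectors)
    def test_symmetry_nonneg_and_oracle(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        mi = mutual_information(x, y)
        assert mi >= 0.0
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert mi == pytest.approx(exact_mi_bits(x, y), abs=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(discrete_vectors)
    def test_self_information_is_entropy(self, x):
        assert mutual_information(x, x) == pytest.approx(entropy(x), abs=1e-12)
        assert entropy(x) == pytest.approx(exact_entropy_bits(x), abs=1e-10)


class TestRelevanceRedundancy:
    def test_class_indicator_has_unit_relevance(self):
        c = np.array([0, 0, 1, 1])
        assert relevance(c, c) == pytest.approx(1.0)

    def test_independent_feature_zero_relevance(self):
        assert relevance([0, 1, 0, 1], [0, 0, 1, 1]) == 0.0

    def test_empty_selected_set_zero_redundancy(self):
        assert redundancy([0, 1, 0], []) == 0.0

    def test_self_redundancy_is_entropy(self):
        x = [-1, 0, 1, 1, 0, -1]
        assert redundancy(x, [x]) == pytest.approx(entropy(x))

    def test_redundancy_is_mean_pairwise_mi(self):
        x = [0, 0, 1, 1, 1, 0]
        s1 = [0, 1, 1, 1, 0, 0]
        s2 = [1, 1, 0, 0, 1, 1]
        expected = (mutual_information(x, s1) + mutual_information(x, s2)) / 2
        assert redundancy(x, [s1, s2]) == pytest.approx(expected, abs=1e-12)

    def test_relevance_all_matches_scalar_relevance(self):
        rng = np.random.default_rng(3)
        states = rng.integers(-1, 2, size=(10, 16))
        labels = rng.integers(0, 2, size=16)
        disc, lab = make_discretized(states, labels)
        d = relevance_all(disc, lab)
        c = (lab == "case").astype(int).to_numpy()
        for i in range(10):
            assert d[i] == pytest.approx(exact_mi_bits(list(states[i]), list(c)),
                                         abs=1e-10)


class TestMaxRel:
    def test_sorted_by_relevance_with_stable_ties(self):
        labels = [0, 0, 1, 1]
        # F1 and F2 are relabelings of each other: identical D; F3 is noise
        states = [[0, 0, 1, 1], [1, 1, 0, 0], [0, 1, 0, 1]]
        disc, lab = make_discretized(states, labels)
        tbl = maxrel_table(disc, lab)
        assert list(tbl["feature_id"]) == ["F1", "F2", "F3"]
        assert list(tbl["rank"]) == [1, 2, 3]

    def test_head_agrees_with_k1_selection(self):
        rng = np.random.default_rng(5)
        states = rng.integers(-1, 2, size=(8, 12))
        labels = rng.integers(0, 2, size=12)
        disc, lab = make_discretized(states, labels)
        tbl = maxrel_table(disc, lab)
        sel = mrmr_select(disc, lab, k=1)
        assert sel.selected_ids[0] == tbl["feature_id"].iloc[0]

    def test_planted_informative_rank_ahead_of_noise(self):
        hits = trials = 0
        for seed in range(10):
            cfg = SyntheticConfig(n_informative=5, n_redundant=0, n_noise=100,
                                  n_coexpressed=0, effect_size=2.0,
                                  noise_sd=0.5, seed=seed)
            m, labels, truth = generate_expression(cfg)
            tbl = maxrel_table(discretize(m), labels)
            top5 = set(tbl["feature_id"].head(5))
            trials += 1
            hits += top5 == truth.informative_ids
        assert hits / trials >= 0.9


class TestMRMRSelect:
    def test_duplicate_penalized_behind_weaker_feature(self):
        # f2 copies f1; MID must defer the copy behind the weaker, less
        # redundant f3: selection order (F1, F3, F2)
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        f1 = [0, 0, 0, 1, 1, 1, 1, 1]
        f3 = [0, 0, 1, 1, 0, 0, 1, 1]
        disc, lab = make_discretized([f1, f1, f3], labels)
        sel = mrmr_select(disc, lab, k=3, scheme="MID")
        assert sel.selected_ids == ["F1", "F3", "F2"]
        assert list(sel.table["h"]) == [1, 2, 3]
        assert sel.table["R"].iloc[0] == 0.0

    @pytest.mark.parametrize("scheme", ["MID", "MIQ"])
    def test_matches_brute_force_rescan(self, scheme):
        """Greedy selection agrees with an independent exact-arithmetic
        per-round rescan: every pick attains the round's best score, and
        picks are identical whenever the best is unique."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            nf = int(rng.integers(3, 12))
            ns = int(rng.integers(6, 20))
            states = rng.integers(-1, 2, size=(nf, ns))
            labels = rng.integers(0, 2, size=ns)
            disc, lab = make_discretized(states, labels)
            k = int(rng.integers(1, nf + 1))
            sel = mrmr_select(disc, lab, k=k, scheme=scheme)
            features = {f"F{i + 1}": list(states[i]) for i in range(nf)}
            oracle_ids = mrmr_greedy_rescan(features, list(labels), k, scheme)

            selected, remaining, any_tie = [], list(features), False
            for pick in sel.selected_ids:
                scores = mrmr_round_scores(features, list(labels), selected,
                                           remaining, scheme)
                best = max(scores.values())
                tol = 1e-9 * max(1.0, abs(best))
                assert scores[pick] >= best - tol
                near_best = [f for f in remaining if scores[f] >= best - tol]
                any_tie |= len(near_best) > 1
                selected.append(pick)
                remaining.remove(pick)
            if not any_tie:  # unique greedy path: ids must agree exactly
                assert sel.selected_ids == oracle_ids

    def test_equal_redundancy_reduces_to_maxrel(self):
        # orthogonal-ish features with all pairwise MI equal (here 0):
        # MID order must equal the MaxRel order
        labels = [0, 0, 1, 1, 0, 0, 1, 1]
        states = [
            [0, 0, 1, 1, 0, 0, 1, 1],   # D = 1
            [0, 1, 0, 1, 0, 1, 0, 1],   # independent of others
            [0, 0, 0, 0, 1, 1, 1, 1],   # independent of labels here? no
        ]
        disc, lab = make_discretized(states, labels)
        tbl = maxrel_table(disc, lab)
        sel = mrmr_select(disc, lab, k=3, scheme="MID")
        pairwise = {mutual_information(states[i], states[j])
                    for i in range(3) for j in range(i + 1, 3)}
        if len(pairwise) == 1:  # precondition of the property
            assert sel.selected_ids == list(tbl["feature_id"])

    def test_selection_partitions_candidates(self):
        rng = np.random.default_rng(23)
        states = rng.integers(-1, 2, size=(9, 14))
        labels = rng.integers(0, 2, size=14)
        disc, lab = make_discretized(states, labels)
        sel = mrmr_select(disc, lab, k=4)
        assert sel.selected_count == 4
        assert sel.remaining_count == 5
        assert sel.total_features == 9
        assert len(set(sel.selected_ids)) == 4

    def test_k_out_of_range_rejected(self, small_matrix, balanced_labels):
        disc = discretize(small_matrix)
        with pytest.raises(ValidationError):
            mrmr_select(disc, balanced_labels, k=7)
        with pytest.raises(ValidationError):
            mrmr_select(disc, balanced_labels, k=0)

    def test_planted_signal_enrichment_in_top_selection(self):
        cfg = SyntheticConfig(n_informative=10, n_redundant=0, n_noise=300,
                              n_coexpressed=0, effect_size=2.0, noise_sd=0.5,
                              seed=31)
        m, labels, truth = generate_expression(cfg)
        sel = mrmr_select(discretize(m), labels, k=15)
        assert len(set(sel.selected_ids) & truth.informative_ids) >= 9
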