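"""Frustration enumeration, contributions, analytic nulls and WBR."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import frustnet as fn
from frustnet.frustration import FORMATION_TYPES, HEMISPHERE_STATES

from helpers import (
    brute_force_edge_counts,
    brute_force_formation_counts,
    brute_force_frustrations,
    brute_force_hemisphere_counts,
    brute_force_node_counts,
)


# ---------------------------------------------------------------------------
# triad classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("signs", list(itertools.product((-1, 1), repeat=3)))
def test_classification_matches_odd_negative_parity(signs):
    """Sign-product rule equals odd-negative-count rule on all 8 triples."""
    n_neg = signs.count(-1)
    expected = "frustrated" if n_neg % 2 == 1 else "balanced"
    assert fn.classify_triad(*signs) == expected


def test_zero_sign_rejected():
    with pytest.raises(ValueError, match="zero"):
        fn.classify_triad(1, 0, -1)


# ---------------------------------------------------------------------------
# enumeration vs brute force
# ---------------------------------------------------------------------------

def test_all_positive_network_has_no_frustrations():
    net = fn.generate_signed_graph(10, p_neg=0.0, seed=0)
    assert fn.enumerate_frustrations(net).n_frust == 0


def test_k4_single_negative_edge(k4_one_negative):
    """One negative edge frustrates exactly the two triangles containing it."""
    fs = fn.enumerate_frustrations(k4_one_negative)
    assert fs.n_frust == 2
    assert fs.triads.tolist() == [[0, 1, 2], [0, 1, 3]]
    assert fn.node_contributions(fs).tolist() == [2, 2, 1, 1]
    edges = fn.edge_contributions(fs)
    assert edges[0, 1] == 2  # the negative edge itself


def test_all_negative_k4_fully_frustrated():
    net = fn.generate_signed_graph(4, p_neg=1.0, seed=0)
    assert fn.enumerate_frustrations(net).n_frust == 4


def test_enumeration_matches_brute_force_on_random_graphs(rng):
    for _ in range(50):
        n = int(rng.integers(3, 16))
        net = fn.generate_signed_graph(n, float(rng.uniform(0, 1)), seed=int(rng.integers(2**31)))
        fs = fn.enumerate_frustrations(net)
        expected = brute_force_frustrations(net.signs)
        assert [tuple(t) for t in fs.triads] == expected


def test_enumeration_rejects_asymmetric_input():
    signs = np.ones((4, 4), dtype=np.int8)
    np.fill_diagonal(signs, 0)
    signs[0, 1] = -1  # not mirrored
    with pytest.raises(ValueError, match="symmetric"):
        fn.SignedNetwork(signs)


def test_sign_flip_maps_parity_classes(rng):
    """Negating all links swaps 0<->3 and 1<->2 negative-link triads."""
    net = fn.generate_signed_graph(12, 0.4, seed=9)
    flipped = fn.SignedNetwork(-net.signs)
    n = net.n
    by_neg = {c: 0 for c in range(4)}
    for i, j, k in itertools.combinations(range(n), 3):
        neg = sum(s == -1 for s in (net.signs[i, j], net.signs[j, k], net.signs[i, k]))
        by_neg[neg] += 1
    expected_flip = by_neg[0] + by_neg[2]  # become 3-neg and 1-neg: frustrated
    assert fn.enumerate_frustrations(flipped).n_frust == expected_flip


# ---------------------------------------------------------------------------
# contributions and conservation
# ---------------------------------------------------------------------------

def test_conservation_sums(rng):
    """Node and edge contributions each sum to 3 N_frust."""
    for seed in range(5):
        net = fn.generate_signed_graph(15, 0.35, seed=seed)
        fs = fn.enumerate_frustrations(net)
        nodes = fn.node_contributions(fs)
        edges = fn.edge_contributions(fs)
        iu = np.triu_indices(15, k=1)
        assert nodes.sum() == 3 * fs.n_frust
        assert edges[iu].sum() == 3 * fs.n_frust


def test_contributions_match_brute_force(rng):
    net = fn.generate_signed_graph(14, 0.5, seed=77)
    fs = fn.enumerate_frustrations(net)
    triads = brute_force_frustrations(net.signs)
    assert fn.node_contributions(fs).tolist() == brute_force_node_counts(triads, 14).tolist()
    bf_edges = brute_force_edge_counts(triads, 14)
    edges = fn.edge_contributions(fs)
    for (a, b), cnt in bf_edges.items():
        assert edges[a, b] == cnt


# ---------------------------------------------------------------------------
# analytic nulls
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_roi, n_frust, expected",
    [(268, 268, 3.0), (10, 5, 1.5)],
)
def test_null_node_formula(n_roi, n_frust, expected):
    assert fn.null_node_contribution(n_roi, n_frust) == pytest.approx(expected)


@pytest.mark.parametrize(
    "n_roi, n_frust, expected",
    [(4, 2, 1.0), (268, 35778, 3.0)],
)
def test_null_edge_formula(n_roi, n_frust, expected):
    # C(268, 2) = 35778 by direct product: 268*267/2
    assert 268 * 267 // 2 == 35778
    assert fn.null_edge_contribution(n_roi, n_frust) == pytest.approx(expected)


def test_null_network_formation_two_equal_networks():
    """Two networks of 4 in N=8 with N_frust = C(8,3) = 56."""
    part = fn.generate_partition(8, [4, 4], (4, 4), seed=0)
    nulls = fn.null_network_formation(part, 56)
    t = part.networks[0]
    assert nulls.loc[t, "within"] == pytest.approx(comb(4, 3))
    assert nulls.loc[t, "between_I"] == pytest.approx(comb(4, 2) * 4)
    assert nulls.loc[t, "between_II"] == pytest.approx(4 * comb(4, 2))
    assert nulls.loc[t, "between_III"] == pytest.approx(0.0)


def test_null_network_formation_single_network():
    part = fn.generate_partition(9, [9], (4, 5), seed=0)
    nulls = fn.null_network_formation(part, 17)
    row = nulls.iloc[0]
    assert row["within"] == pytest.approx(17.0)
    assert row[["between_I", "between_II", "between_III"]].sum() == pytest.approx(0.0)


def test_null_hemisphere_degenerate_and_sum():
    all_left = fn.null_hemisphere_states(12, 0, 7)
    assert all_left["all_L"] == pytest.approx(7.0)
    assert all_left[["all_R", "two_R", "two_L"]].sum() == pytest.approx(0.0)
    # C(a,3) + C(b,3) + C(a,2) b + C(b,2) a = C(a+b,3): nulls always sum to N_frust
    for a, b in [(133, 135), (5, 7), (3, 0)]:
        nulls = fn.null_hemisphere_states(a, b, 11)
        assert nulls.sum() == pytest.approx(11.0)


def test_formation_and_hemisphere_counts_match_brute_force(four_net_partition):
    part = four_net_partition
    net = fn.generate_signed_graph(part.n, 0.3, seed=5, partition=part)
    fs = fn.enumerate_frustrations(net)
    triads = brute_force_frustrations(net.signs)
    labels = list(part.network_labels)
    bf = brute_force_formation_counts(triads, labels, list(part.networks))
    ours = fn.network_formation_counts(fs, part)
    for t in part.networks:
        for ftype in FORMATION_TYPES:
            assert ours.loc[t, ftype] == bf[t][ftype]
    bf_h = brute_force_hemisphere_counts(triads, list(part.hemisphere_labels))
    ours_h = fn.hemisphere_state_counts(fs, part)
    for state in HEMISPHERE_STATES:
        assert ours_h[state] == bf_h[state]
    assert ours_h.sum() == fs.n_frust


def test_formation_counts_partition_frustrations_touching_network(small_partition):
    """For each network the 4 types sum to frustrations touching it."""
    part = small_partition
    net = fn.generate_signed_graph(part.n, 0.4, seed=11, partition=part)
    fs = fn.enumerate_frustrations(net)
    counts = fn.network_formation_counts(fs, part)
    codes = part.network_codes[fs.triads]
    for t in range(len(part.networks)):
        touching = int((codes == t).any(axis=1).sum())
        assert counts.iloc[t].sum() == touching


def test_combinatorial_identity_random_partitions(rng):
    """sum_T C(N_T,3) + sum_T C(N_T,2)(N-N_T) + sum_{i<j<k} N_i N_j N_k = C(N,3)."""
    for _ in range(30):
        k = int(rng.integers(2, 8))
        sizes = rng.multinomial(int(rng.integers(k * 2, 60)), np.ones(k) / k)
        sizes = [int(s) for s in sizes if s > 0]
        n = sum(sizes)
        if n < 3:
            continue
        total = (
            sum(comb(s, 3) for s in sizes)
            + sum(comb(s, 2) * (n - s) for s in sizes)
            + sum(
                sizes[a] * sizes[b] * sizes[c]
                for a in range(len(sizes))
                for b in range(a + 1, len(sizes))
                for c in range(b + 1, len(sizes))
            )
        )
        assert total == comb(n, 3)


def test_nulls_match_monte_carlo_relabeling(four_net_partition, rng):
    """Analytic nulls equal MC means over uniform node relabelings (3 SE)."""
    part = four_net_partition
    net = fn.generate_signed_graph(part.n, 0.3, seed=13, partition=part)
    fs = fn.enumerate_frustrations(net)
    n_rel = 400
    node_samples, form_samples, hemi_samples = [], [], []
    codes = part.network_codes
    right = part.hemisphere_is_right
    for _ in range(n_rel):
        perm = rng.permutation(part.n)
        relabeled = perm[fs.triads]
        node_samples.append(np.bincount(relabeled.ravel(), minlength=part.n))
        c = codes[relabeled]
        neq = (c[:, 0] != c[:, 1]).astype(int) + (c[:, 1] != c[:, 2]) + (c[:, 0] != c[:, 2])
        cnt0 = (c == 0).sum(axis=1)
        form_samples.append(
            [
                (cnt0 == 3).sum(),
                (cnt0 == 2).sum(),
                ((cnt0 == 1) & (neq == 2)).sum(),
                ((cnt0 == 1) & (neq == 3)).sum(),
            ]
        )
        r = right[relabeled].sum(axis=1)
        hemi_samples.append([(r == 3).sum(), (r == 0).sum(), (r == 2).sum(), (r == 1).sum()])

    node_mc = np.array(node_samples, dtype=float)
    expect = fn.null_node_contribution(part.n, fs.n_frust)
    mean, se = node_mc.mean(axis=0), node_mc.std(axis=0, ddof=1) / np.sqrt(n_rel)
    assert np.all(np.abs(mean - expect) <= 3 * np.maximum(se, 1e-12))

    form_mc = np.array(form_samples, dtype=float)
    expect_form = fn.null_network_formation(part, fs.n_frust).iloc[0].values
    mean, se = form_mc.mean(axis=0), form_mc.std(axis=0, ddof=1) / np.sqrt(n_rel)
    assert np.all(np.abs(mean - expect_form) <= 3 * np.maximum(se, 1e-12))

    hemi_mc = np.array(hemi_samples, dtype=float)
    expect_hemi = fn.null_hemisphere_states(part.n_left, part.n_right, fs.n_frust).values
    mean, se = hemi_mc.mean(axis=0), hemi_mc.std(axis=0, ddof=1) / np.sqrt(n_rel)
    assert np.all(np.abs(mean - expect_hemi) <= 3 * np.maximum(se, 1e-12))


# ---------------------------------------------------------------------------
# WBR
# ---------------------------------------------------------------------------

def test_wbr_two_networks_of_three():
    part = fn.generate_partition(6, [3, 3], (3, 3), seed=0)
    # 3 within edges + 3 between edges -> (3/3)/(6/9) = 1.5
    edges = [(0, 1), (0, 2), (3, 4), (0, 3), (1, 4), (2, 5)]
    res = fn.wbr(edges, part)
    assert (res.wc0, res.bc0) == (6, 9)
    assert res.value == pytest.approx(1.5)


def test_wbr_extremes():
    part = fn.generate_partition(6, [3, 3], (3, 3), seed=0)
    assert fn.wbr([(0, 3), (1, 4)], part).value == pytest.approx(0.0)
    # proportional to (WC0, BC0): WBR = 1 (all possible edges)
    all_edges = list(itertools.combinations(range(6), 2))
    assert fn.wbr(all_edges, part).value == pytest.approx(1.0)
    # all-within edge set: BC = 0 -> flagged infinite, counts kept
    res = fn.wbr([(0, 1), (3, 4)], part)
    assert np.isinf(res.value) and not res.defined
    assert (res.wc, res.bc) == (2, 0)
    # empty edge set: undefined
    assert not fn.wbr([], part).defined


def test_wbr_accepts_boolean_mask(small_partition):
    part = small_partition
    mask = np.zeros((part.n, part.n), dtype=bool)
    mask[0, 1] = mask[1, 0] = True  # same network (contiguous blocks)
    res = fn.wbr(mask, part)
    assert (res.wc, res.bc) == (1, 0)


# ---------------------------------------------------------------------------
# property-based checks
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(3, 12), st.floats(0, 1), st.integers(0, 2**20))
def test_enumeration_always_matches_brute_force(n, p_neg, seed):
    net = fn.generate_signed_graph(n, p_neg, seed=seed)
    fs = fn.enumerate_frustrations(net)
    assert fs.n_frust == len(brute_force_frustrations(net.signs))
    assert fn.node_contributions(fs).sum() == 3 * fs.n_frust
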