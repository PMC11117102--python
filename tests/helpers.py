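"""Independent oracles shared across test modules.

Everything here is deliberately naive — brute-force triple loops, full 2^n
enumeration, Monte-Carlo relabelings — and never calls the code paths it
checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_frustrations(signs: np.ndarray) -> list[tuple[int, int, int]]:
    """All frustrated triples by an explicit triple loop over sign products."""
    n = signs.shape[0]
    out = []
    for i, j, k in itertools.combinations(range(n), 3):
        if signs[i, j] * signs[j, k] * signs[i, k] == -1:
            out.append((i, j, k))
    return out


def brute_force_node_counts(triads: list[tuple[int, int, int]], n: int) -> np.ndarray:
    counts = np.zeros(n, dtype=int)
    for t in triads:
        for node in t:
            counts[node] += 1
    return counts


def brute_force_edge_counts(
    triads: list[tuple[int, int, int]], n: int
) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for i, j, k in triads:
        for a, b in ((i, j), (j, k), (i, k)):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def brute_force_formation_counts(
    triads: list[tuple[int, int, int]], labels: list, networks: list
) -> dict:
    """Per-network within / between-I / between-II / between-III counts."""
    out = {t: {"within": 0, "between_I": 0, "between_II": 0, "between_III": 0}
           for t in networks}
    for i, j, k in triads:
        labs = [labels[i], labels[j], labels[k]]
        for t in networks:
            c = labs.count(t)
            if c == 3:
                out[t]["within"] += 1
            elif c == 2:
                out[t]["between_I"] += 1
            elif c == 1:
                others = [l for l in labs if l != t]
                if others[0] == others[1]:
                    out[t]["between_II"] += 1
                else:
                    out[t]["between_III"] += 1
    return out


def brute_force_hemisphere_counts(
    triads: list[tuple[int, int, int]], hemis: list
) -> dict:
    out = {"all_R": 0, "all_L": 0, "two_R": 0, "two_L": 0}
    for i, j, k in triads:
        r = [hemis[i], hemis[j], hemis[k]].count("R")
        key = {3: "all_R", 0: "all_L", 2: "two_R", 1: "two_L"}[r]
        out[key] += 1
    return out


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by full 2^n enumeration (no ties, n <= ~16)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    w_values = []
    for signs in itertools.product((0, 1), repeat=n):
        w_values.append(sum(r for r, s in zip(ranks, signs) if s))
    w_values = np.array(w_values)
    lo = (w_values <= w_obs).mean()
    hi = (w_values >= w_obs).mean()
    return min(1.0, 2 * min(lo, hi))


def mc_relabeled_means(
    triads: np.ndarray,
    n: int,
    n_rel: int,
    rng: np.random.Generator,
    reducer,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo mean and SE of ``reducer(permuted node order)``.

    ``reducer(perm)`` must return a 1-D float vector of element counts for
    the relabeling where original node v gets new identity ``perm[v]``.
    """
    samples = []
    for _ in range(n_rel):
        perm = rng.permutation(n)
        samples.append(np.asarray(reducer(perm), dtype=float))
    samples = np.stack(samples)
    return samples.mean(axis=0), samples.std(axis=0, ddof=1) / np.sqrt(n_rel)
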