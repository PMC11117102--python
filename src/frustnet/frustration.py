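"""Triadic frustration enumeration and combinatorial null contributions.

A triad (i, j, k) of a complete signed graph is *frustrated* when it
carries an odd number of negative links — equivalently when the product of
its three link signs is -1 (Heider/Cartwright–Harary structural balance).
This module enumerates all frustrated triads of a network and measures how
much each element contributes to them:

* regions — number of frustrated triads containing the region;
* connections — number of frustrated triads containing the edge;
* canonical networks — counts of four formation types relative to a target
  network T: *within* (all 3 nodes in T), *between-I* (2 in T), *between-II*
  (1 in T, other 2 together in one other network), *between-III* (1 in T,
  other 2 in two distinct other networks);
* hemispheres — all-right / all-left / exactly-2-right / exactly-2-left.

For every count an analytic null gives the expected value under uniform
placement of the observed N_frust frustrations over all C(N, 3) triads,
a pure counting argument over the partition sizes.  The WBR statistic
(within/between connection ratio, normalized by the maximum possible
counts) summarizes whether an edge set is predominantly within-network
(WBR > 1) or between-network (WBR < 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import SignedNetwork
from .partition import RegionPartition

__all__ = [
    "FrustrationSet",
    "WBRResult",
    "classify_triad",
    "enumerate_frustrations",
    "node_contributions",
    "null_node_contribution",
    "edge_contributions",
    "null_edge_contribution",
    "FORMATION_TYPES",
    "network_formation_counts",
    "null_network_formation",
    "HEMISPHERE_STATES",
    "hemisphere_state_counts",
    "null_hemisphere_states",
    "wbr",
]

FORMATION_TYPES = ("within", "between_I", "between_II", "between_III")
HEMISPHERE_STATES = ("all_R", "all_L", "two_R", "two_L")


def classify_triad(s_ij: int, s_jk: int, s_ik: int) -> str:
    """Classify one sign triple as ``"balanced"`` or ``"frustrated"``."""
    for s in (s_ij, s_jk, s_ik):
        if s not in (-1, 1):
            raise ValueError(
                f"link sign must be +1 or -1, got {s!r}; resolve zero "
                "signs with a zero policy before classification"
            )
    return "frustrated" if s_ij * s_jk * s_ik == -1 else "balanced"


@dataclass(frozen=True)
class FrustrationSet:
    """All frustrated triads of one signed network.

    ``triads`` is an (M, 3) integer array of node indices i < j < k in
    lexicographic order; ``signs`` the matching (M, 3) array of
    (s_ij, s_jk, s_ik).
    """

    triads: np.ndarray
    signs: np.ndarray
    n_regions: int
    partition: RegionPartition | None = None
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        triads = np.asarray(self.triads, dtype=np.int64).reshape(-1, 3)
        signs = np.asarray(self.signs, dtype=np.int8).reshape(-1, 3)
        object.__setattr__(self, "triads", triads)
        object.__setattr__(self, "signs", signs)
        if triads.shape != signs.shape:
            raise ValueError("triads and signs must have matching shapes")
        if triads.size and not (
            (triads[:, 0] < triads[:, 1]) & (triads[:, 1] < triads[:, 2])
        ).all():
            raise ValueError("triads must be strictly increasing triples")

    @property
    def n_frust(self) -> int:
        return self.triads.shape[0]

    @property
    def n_triads_total(self) -> int:
        return comb(self.n_regions, 3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": self.triads[:, 0],
                "j": self.triads[:, 1],
                "k": self.triads[:, 2],
                "s_ij": self.signs[:, 0],
                "s_jk": self.signs[:, 1],
                "s_ik": self.signs[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def enumerate_frustrations(net: SignedNetwork) -> FrustrationSet:
    """Enumerate every frustrated triad of a complete signed network.

    Sign products are accumulated in lexicographic triple order with a
    vectorized sweep over the smallest node index; triads containing a
    dropped (0) link are skipped.
    """
    S = net.signs
    n = net.n
    if n < 3:
        raise ValueError(f"need at least 3 nodes for triads, got {n}")

    tri_chunks: list[np.ndarray] = []
    sign_chunks: list[np.ndarray] = []
    for i in range(n - 2):
        si = S[i, i + 1 :].astype(np.int32)
        sub = S[i + 1 :, i + 1 :]
        ju, ku = np.triu_indices(n - 1 - i, k=1)
        s_ij = si[ju]
        s_ik = si[ku]
        s_jk = sub[ju, ku].astype(np.int32)
        prod = s_ij * s_jk * s_ik
        mask = prod == -1  # a zero link yields product 0: skipped
        if not mask.any():
            continue
        j = ju[mask] + i + 1
        k = ku[mask] + i + 1
        tri = np.column_stack([np.full(j.size, i, dtype=np.int64), j, k])
        sgn = np.column_stack([s_ij[mask], s_jk[mask], s_ik[mask]]).astype(np.int8)
        tri_chunks.append(tri)
        sign_chunks.append(sgn)

    if tri_chunks:
        triads = np.concatenate(tri_chunks)
        signs = np.concatenate(sign_chunks)
    else:
        triads = np.empty((0, 3), dtype=np.int64)
        signs = np.empty((0, 3), dtype=np.int8)
    return FrustrationSet(
        triads, signs, n_regions=n, partition=net.partition, subject_id=net.subject_id
    )


# ---------------------------------------------------------------------------
# element contributions and analytic nulls
# ---------------------------------------------------------------------------

def node_contributions(frustset: FrustrationSet) -> np.ndarray:
    """Per-region count of frustrated triads containing the region.

    Sums to ``3 * n_frust`` (each triad has three nodes).
    """
    return np.bincount(frustset.triads.ravel(), minlength=frustset.n_regions)


def null_node_contribution(n_roi: int, n_frust: int) -> float:
    """Expected regional contribution under uniform placement: 3 N_frust / N.

    The factor 3 appears because every frustration involves three regions.
    """
    if n_roi < 3:
        raise ValueError(f"need at least 3 regions, got {n_roi}")
    if n_frust < 0:
        raise ValueError("n_frust must be non-negative")
    return 3.0 * n_frust / n_roi


def edge_contributions(frustset: FrustrationSet) -> np.ndarray:
    """Symmetric matrix of per-connection frustrated-triad counts.

    Entry (a, b) counts frustrated triads containing the unordered edge
    {a, b}; the upper triangle sums to ``3 * n_frust``.
    """
    n = frustset.n_regions
    tri = frustset.triads
    flat = np.concatenate(
        [
            tri[:, 0] * n + tri[:, 1],
            tri[:, 1] * n + tri[:, 2],
            tri[:, 0] * n + tri[:, 2],
        ]
    )
    counts = np.bincount(flat, minlength=n * n).reshape(n, n)
    return counts + counts.T


def null_edge_contribution(n_roi: int, n_frust: int) -> float:
    """Expected connection contribution: 3 N_frust / C(N, 2).

    The factor 3 appears because every frustration engages three
    connections; C(N, 2) is the link count of the complete graph.
    """
    if n_roi < 3:
        raise ValueError(f"need at least 3 regions, got {n_roi}")
    return 3.0 * n_frust / comb(n_roi, 2)


def network_formation_counts(
    frustset: FrustrationSet, partition: RegionPartition
) -> pd.DataFrame:
    """Count the four formation types for every canonical network.

    Returns a DataFrame indexed by network with columns
    ``within, between_I, between_II, between_III``.  For each network T the
    four counts partition the frustrations that touch T.
    """
    if partition.n != frustset.n_regions:
        raise ValueError(
            f"partition covers {partition.n} regions but frustration set "
            f"has {frustset.n_regions}"
        )
    codes = partition.network_codes[frustset.triads]  # (M, 3)
    # number of distinct network codes per triad (1, 2 or 3)
    neq = (
        (codes[:, 0] != codes[:, 1]).astype(np.int8)
        + (codes[:, 1] != codes[:, 2])
        + (codes[:, 0] != codes[:, 2])
    )
    distinct = np.where(neq == 0, 1, np.where(neq == 2, 2, 3))

    rows = []
    for t, name in enumerate(partition.networks):
        cnt = (codes == t).sum(axis=1)
        rows.append(
            {
                "within": int((cnt == 3).sum()),
                "between_I": int((cnt == 2).sum()),
                "between_II": int(((cnt == 1) & (distinct == 2)).sum()),
                "between_III": int(((cnt == 1) & (distinct == 3)).sum()),
            }
        )
    return pd.DataFrame(rows, index=list(partition.networks))[list(FORMATION_TYPES)]


def null_network_formation(
    partition: RegionPartition, n_frust: int
) -> pd.DataFrame:
    """Analytic expected formation-type counts under uniform placement.

    For target network T of size N_T in an N-region graph::

        within      = C(N_T, 3) / C(N, 3) * N_frust
        between-I   = C(N_T, 2) (N - N_T) / C(N, 3) * N_frust
        between-II  = sum_{i != T} N_T C(N_i, 2) / C(N, 3) * N_frust
        between-III = sum_{i < j, both != T} N_T N_i N_j / C(N, 3) * N_frust

    Numerators are exact integer binomials; division happens last.
    """
    sizes = list(partition.network_sizes.values())
    names = list(partition.networks)
    n = partition.n
    total = comb(n, 3)
    rows = []
    for t, n_t in enumerate(sizes):
        others = [s for u, s in enumerate(sizes) if u != t]
        within = comb(n_t, 3)
        between_i = comb(n_t, 2) * (n - n_t)
        between_ii = n_t * sum(comb(s, 2) for s in others)
        between_iii = n_t * sum(
            others[a] * others[b]
            for a in range(len(others))
            for b in range(a + 1, len(others))
        )
        rows.append(
            {
                "within": within * n_frust / total,
                "between_I": between_i * n_frust / total,
                "between_II": between_ii * n_frust / total,
                "between_III": between_iii * n_frust / total,
            }
        )
    return pd.DataFrame(rows, index=names)[list(FORMATION_TYPES)]


def hemisphere_state_counts(
    frustset: FrustrationSet, partition: RegionPartition
) -> pd.Series:
    """Count frustrations in the four hemisphere states.

    States: all three regions right (``all_R``), all left (``all_L``),
    exactly two right (``two_R``), exactly two left (``two_L``); the four
    counts sum to ``n_frust``.
    """
    if partition.n != frustset.n_regions:
        raise ValueError("partition does not cover the frustration set")
    n_right = partition.hemisphere_is_right[frustset.triads].sum(axis=1)
    return pd.Series(
        {
            "all_R": int((n_right == 3).sum()),
            "all_L": int((n_right == 0).sum()),
            "two_R": int((n_right == 2).sum()),
            "two_L": int((n_right == 1).sum()),
        }
    )[list(HEMISPHERE_STATES)]


def null_hemisphere_states(n_lh: int, n_rh: int, n_frust: int) -> pd.Series:
    """Analytic expected hemisphere-state counts under uniform placement.

    Homogeneous states use C(N_H, 3)/C(N, 3) * N_frust and mixed states
    C(N_H, 2)(N - N_H)/C(N, 3) * N_frust, keyed by hemisphere label; the
    four nulls sum to N_frust for any split.
    """
    n = n_lh + n_rh
    if n < 3:
        raise ValueError("need at least 3 regions in total")
    total = comb(n, 3)
    return pd.Series(
        {
            "all_R": comb(n_rh, 3) * n_frust / total,
            "all_L": comb(n_lh, 3) * n_frust / total,
            "two_R": comb(n_rh, 2) * n_lh * n_frust / total,
            "two_L": comb(n_lh, 2) * n_rh * n_frust / total,
        }
    )[list(HEMISPHERE_STATES)]


# ---------------------------------------------------------------------------
# WBR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WBRResult:
    """Within/between connection ratio of an edge set.

    ``value = (WC/BC) / (WC0/BC0)`` with WC, BC the observed within- and
    between-network edge counts and WC0, BC0 the maximum possible counts
    given the partition.  ``value`` is ``inf`` when BC = 0 and ``nan`` for
    an empty edge set (both flagged via :attr:`defined`).
    """

    wc: int
    bc: int
    wc0: int
    bc0: int
    value: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


def wbr(
    edge_set: Iterable[tuple[int, int]] | np.ndarray,
    partition: RegionPartition,
) -> WBRResult:
    """Within-to-between ratio of an edge set over a network partition.

    ``edge_set`` may be an iterable of region-index pairs or a boolean
    N × N matrix (upper triangle used).  WBR > 1 indicates predominantly
    within-network edges, WBR < 1 predominantly between-network edges.
    """
    codes = partition.network_codes
    n = partition.n
    if isinstance(edge_set, np.ndarray) and edge_set.ndim == 2:
        if edge_set.shape != (n, n):
            raise ValueError("edge mask shape does not match partition")
        iu = np.triu_indices(n, k=1)
        mask = np.asarray(edge_set, dtype=bool)[iu]
        a, b = iu[0][mask], iu[1][mask]
    else:
        pairs = {(min(i, j), max(i, j)) for i, j in edge_set}
        for i, j in pairs:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid edge ({i}, {j})")
        a = np.array([p[0] for p in pairs], dtype=int)
        b = np.array([p[1] for p in pairs], dtype=int)

    wc0 = sum(comb(s, 2) for s in partition.network_sizes.values())
    bc0 = comb(n, 2) - wc0
    if wc0 == 0 or bc0 == 0:
        raise ValueError("partition admits no within- or no between-network edges")

    within = codes[a] == codes[b]
    wc = int(within.sum())
    bc = int(a.size - wc)
    if a.size == 0:
        value = float("nan")
    elif bc == 0:
        value = float("inf")
    else:
        value = (wc / bc) / (wc0 / bc0)
    return WBRResult(wc=wc, bc=bc, wc0=wc0, bc0=bc0, value=value)
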