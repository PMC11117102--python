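"""Group-level inference for contribution tables.

Two comparison families drive the analysis: a paired Wilcoxon signed-rank
test of actual vs analytic-null contributions across subjects (effect size
r = Z/sqrt(n)), and a Kruskal–Wallis test across life-span stages (effect
size the rank eta-squared (H - k + 1)/(n - k)).  Raw p values are corrected
by Benjamini–Hochberg FDR within one analysis level × stage; effects are
banded small/medium/large (paired r: 0.1/0.4/0.6; eta²: 0.01/0.06/0.14)
and an element is called significant only when adjusted p < alpha *and*
its band reaches the required band.

The spatial randomness of a significance pattern is tested with a
bin-normalized Shannon entropy over canonical-network states against a
uniform-shuffle null (one-sided: clustered patterns have *low* entropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, log
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .partition import RegionPartition

__all__ = [
    "PairedResult",
    "EffectBands",
    "EntropyTestResult",
    "paired_wilcoxon_r",
    "kruskal_eta2",
    "fdr_bh",
    "effect_band",
    "BAND_ORDER",
    "significant_elements",
    "pattern_entropy",
    "entropy_shuffle_test",
    "paired_contribution_stats",
]

BAND_ORDER = ("negligible", "small", "medium", "large")


@dataclass(frozen=True)
class EffectBands:
    """Small/medium/large lower bounds per test kind."""

    paired: tuple[float, float, float] = (0.1, 0.4, 0.6)
    multigroup: tuple[float, float, float] = (0.01, 0.06, 0.14)

    def __post_init__(self) -> None:
        for th in (self.paired, self.multigroup):
            if not (th[0] < th[1] < th[2]):
                raise ValueError(f"band thresholds must increase: {th}")


DEFAULT_BANDS = EffectBands()


@dataclass(frozen=True)
class PairedResult:
    """Wilcoxon matched-pairs signed-rank outcome for one element."""

    statistic: float
    p_value: float
    r: float
    n: int
    degenerate: bool = False


def paired_wilcoxon_r(
    actual: Sequence[float] | np.ndarray,
    null: Sequence[float] | np.ndarray,
) -> PairedResult:
    """Two-sided Wilcoxon signed-rank test with signed r = Z/sqrt(n).

    Zero differences are dropped (signed-rank convention).  p is exact for
    n <= 25 without tied |differences| and a tie-corrected normal
    approximation with continuity correction otherwise.  r is positive
    when the actual values tend to exceed the null values.
    """
    actual = np.asarray(actual, dtype=float)
    null = np.asarray(null, dtype=float)
    if actual.shape != null.shape or actual.ndim != 1:
        raise ValueError("actual and null must be 1-D arrays of equal length")
    d = actual - null
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedResult(0.0, 1.0, 0.0, 0, degenerate=True)
    if n < 5:
        # too few informative pairs for a meaningful two-sided p at alpha 0.05
        raise ValueError(f"need >=5 non-zero differences, got {n}")

    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    diff = w_pos - mu
    if sigma2 <= 0 or diff == 0:
        z = 0.0
    else:
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    r = z / np.sqrt(n)

    has_ties = (tie_counts > 1).any()
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        d,
        zero_method="wilcox",
        correction=True,
        alternative="two-sided",
        method=method,
    )
    return PairedResult(float(res.statistic), float(res.pvalue), float(r), n)


def kruskal_eta2(
    groups: Sequence[Sequence[float] | np.ndarray],
) -> tuple[float, float, float]:
    """Tie-corrected Kruskal–Wallis H with rank eta² = (H - k + 1)/(n - k)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    k = len(groups)
    n = sum(g.size for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    eta2 = (h - k + 1) / (n - k)
    return float(h), float(p), float(eta2)


def fdr_bh(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effect_band(
    value: float, test_kind: str, bands: EffectBands = DEFAULT_BANDS
) -> str:
    """Band an effect size by magnitude: negligible/small/medium/large."""
    if test_kind == "paired":
        small, medium, large = bands.paired
    elif test_kind == "multigroup":
        small, medium, large = bands.multigroup
    else:
        raise ValueError(f"test_kind must be 'paired' or 'multigroup', got {test_kind!r}")
    v = abs(value)
    if v >= large:
        return "large"
    if v >= medium:
        return "medium"
    if v >= small:
        return "small"
    return "negligible"


def significant_elements(
    results: pd.DataFrame,
    alpha: float = 0.05,
    band: str = "large",
) -> pd.DataFrame:
    """Flag elements with adjusted p < alpha and at least the required band.

    ``results`` must carry columns ``p_fdr``, ``effect`` and ``band``.
    Adds boolean ``significant`` and ``direction`` in
    {"greater", "lower", "none"} from the sign of the effect.
    """
    if band not in BAND_ORDER:
        raise ValueError(f"band must be one of {BAND_ORDER}")
    rank = {b: i for i, b in enumerate(BAND_ORDER)}
    need = rank[band]
    out = results.copy()
    out["significant"] = (out["p_fdr"] < alpha) & (
        out["band"].map(rank).fillna(-1) >= need
    )
    out["direction"] = np.where(
        ~out["significant"], "none", np.where(out["effect"] > 0, "greater", "lower")
    )
    return out


# ---------------------------------------------------------------------------
# pattern entropy
# ---------------------------------------------------------------------------

def _entropy_states(
    flags: np.ndarray, partition: RegionPartition, state_mode: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (element state codes, state bin sizes, n_states)."""
    codes = partition.network_codes
    k = len(partition.networks)
    if state_mode == "regions-by-network":
        flags = np.asarray(flags, dtype=bool).ravel()
        if flags.size != partition.n:
            raise ValueError("region flags must have one entry per region")
        sizes = np.bincount(codes, minlength=k).astype(float)
        return flags, codes, sizes
    if state_mode == "edges-by-network-pair":
        flags2 = np.asarray(flags, dtype=bool)
        if flags2.shape != (partition.n, partition.n):
            raise ValueError("edge flags must be an N × N boolean matrix")
        iu = np.triu_indices(partition.n, k=1)
        a, b = codes[iu[0]], codes[iu[1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        state = lo * k + hi  # unordered pair (lo, hi) incl. within-pairs
        sizes_net = np.bincount(codes, minlength=k)
        n_states = k * k
        sizes = np.zeros(n_states, dtype=float)
        for t in range(k):
            sizes[t * k + t] = comb(int(sizes_net[t]), 2)
            for u in range(t + 1, k):
                sizes[t * k + u] = sizes_net[t] * sizes_net[u]
        return flags2[iu], state, sizes
    raise ValueError(
        "state_mode must be 'regions-by-network' or 'edges-by-network-pair'"
    )


def _entropy_from_counts(counts: np.ndarray, sizes: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sizes > 0, counts / sizes, 0.0)
    total = w.sum()
    p = w[w > 0] / total
    return float(-(p * np.log(p)).sum())


def pattern_entropy(
    flags: np.ndarray, partition: RegionPartition, state_mode: str = "regions-by-network"
) -> float:
    """Bin-normalized Shannon entropy (nats) of a significance pattern.

    States are canonical networks (regions mode) or unordered network
    pairs (edges mode).  Flag counts are normalized by the state's bin
    size (number of elements in the state) and then renormalized to
    probabilities; empty states contribute 0 (0·ln 0 := 0).  Maximal
    ``ln(#non-empty states)`` when bin-normalized weights are equal, 0
    when all flags share one state.
    """
    elem_flags, state, sizes = _entropy_states(flags, partition, state_mode)
    if not elem_flags.any():
        raise ValueError("pattern entropy is undefined with zero flagged elements")
    counts = np.bincount(state[elem_flags], minlength=sizes.size).astype(float)
    return _entropy_from_counts(counts, sizes)


@dataclass(frozen=True)
class EntropyTestResult:
    """Shuffle-null entropy test for one significance pattern."""

    entropy: float
    null_entropies: np.ndarray
    p_value: float
    degenerate: bool = False


def entropy_shuffle_test(
    flags: np.ndarray,
    partition: RegionPartition,
    state_mode: str = "regions-by-network",
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EntropyTestResult:
    """Compare actual pattern entropy to uniformly shuffled patterns.

    Shuffles permute the flag vector over all elements (flag count
    preserved).  One-sided lower-tail p with the +1 permutation
    correction: ``p = (1 + #{H_null <= H_actual}) / (1 + n_shuffles)``;
    small p means the pattern is more clustered than chance.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    elem_flags, state, sizes = _entropy_states(flags, partition, state_mode)
    m = int(elem_flags.sum())
    if m == 0:
        raise ValueError("entropy test undefined with zero flagged elements")
    h_actual = pattern_entropy(flags, partition, state_mode)
    n_elem = elem_flags.size
    if m == n_elem:
        return EntropyTestResult(
            h_actual, np.full(n_shuffles, h_actual), 1.0, degenerate=True
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = sizes.size
    null_h = np.empty(n_shuffles)
    # vectorized: sample m flagged positions per shuffle via random argsort
    order = np.argsort(rng.random((n_shuffles, n_elem)), axis=1)[:, :m]
    picked_states = state[order]  # (n_shuffles, m)
    counts = np.zeros((n_shuffles, k))
    np.add.at(counts, (np.repeat(np.arange(n_shuffles), m), picked_states.ravel()), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sizes > 0, counts / sizes, 0.0)
    totals = w.sum(axis=1, keepdims=True)
    p = np.divide(w, totals, out=np.zeros_like(w), where=totals > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    null_h = -(p * logp).sum(axis=1)

    p_value = (1 + int((null_h <= h_actual + 1e-12).sum())) / (1 + n_shuffles)
    return EntropyTestResult(h_actual, null_h, float(p_value))


# ---------------------------------------------------------------------------
# table-level convenience
# ---------------------------------------------------------------------------

def paired_contribution_stats(
    table: pd.DataFrame,
    alpha: float = 0.05,
    required_band: str = "large",
    bands: EffectBands = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Paired actual-vs-null tests for every element of one analysis level.

    ``table`` is long-format with columns (subject_id, element_id, actual,
    null).  One Wilcoxon signed-rank test per element; BH-FDR across the
    elements of the table (one family = one level × stage); banding,
    significance flag and direction appended.
    """
    rows = []
    for element_id, sub in table.groupby("element_id", sort=True):
        try:
            res = paired_wilcoxon_r(sub["actual"].values, sub["null"].values)
        except ValueError:
            # fewer than 5 informative pairs: no test possible for this element
            n_nz = int((sub["actual"].values != sub["null"].values).sum())
            res = PairedResult(0.0, 1.0, 0.0, n_nz, degenerate=True)
        rows.append(
            {
                "element_id": element_id,
                "n": res.n,
                "statistic": res.statistic,
                "p": res.p_value,
                "effect": res.r,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].values)
    out["band"] = [effect_band(v, "paired", bands) for v in out["effect"]]
    return significant_elements(out, alpha=alpha, band=required_band)
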