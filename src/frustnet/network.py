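"""Signed functional network construction from regional time series.

The construction mirrors the resting-state connectivity recipe the analysis
is built on: truncate every subject's regional time series to a common
length, correlate every pair of regions (Pearson), and keep only the *sign*
of each correlation.  The result is a complete signed graph — no
thresholding, positive links for synchronous coactivation, negative links
for antisynchronous coactivation.  Global-signal regression is available as
an optional preprocessing step (off by default; it is known to inflate the
number of negative correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .partition import RegionPartition

__all__ = [
    "RegionalTimeSeries",
    "ConnectivityMatrix",
    "SignedNetwork",
    "truncate_timeseries",
    "global_signal_regress",
    "pearson_connectivity",
    "to_signed_network",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionalTimeSeries:
    """Regions × time-points activity matrix with region metadata."""

    data: np.ndarray
    partition: RegionPartition | None = None
    subject_id: str = "subject"
    stage: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("time series must be a 2-D (regions × time) array")
        if data.shape[1] < 3:
            raise ValueError(
                f"subject {self.subject_id!r}: need at least 3 time points, "
                f"got {data.shape[1]}"
            )
        if not np.isfinite(data).all():
            raise ValueError(f"subject {self.subject_id!r}: non-finite values")
        if self.partition is not None and self.partition.n != data.shape[0]:
            raise ValueError(
                f"subject {self.subject_id!r}: {data.shape[0]} rows but "
                f"partition has {self.partition.n} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    partition: RegionPartition | None = None
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n, m = values.shape
        if n != m:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(values).max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(values), 1.0):
            raise ValueError("diagonal must be 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SignedNetwork:
    """Complete signed graph: link signs in {+1, -1}, zero diagonal.

    With ``zero_policy="drop"`` exactly-zero correlations are stored as 0
    and triads containing them are excluded from enumeration.
    """

    signs: np.ndarray
    partition: RegionPartition | None = None
    subject_id: str = "subject"
    n_zero_links: int = 0

    def __post_init__(self) -> None:
        signs = np.asarray(self.signs)
        if signs.dtype != np.int8:
            signs = signs.astype(np.int8)
        object.__setattr__(self, "signs", signs)
        n, m = signs.shape
        if n != m:
            raise ValueError("sign matrix must be square")
        if not np.array_equal(signs, signs.T):
            raise ValueError("sign matrix must be symmetric")
        if np.any(np.diag(signs) != 0):
            raise ValueError("diagonal (self-links) must be zero")
        off = signs[~np.eye(n, dtype=bool)]
        if not np.isin(off, (-1, 0, 1)).all():
            raise ValueError("link signs must be -1, 0 (dropped) or +1")

    @property
    def n(self) -> int:
        return self.signs.shape[0]

    @property
    def negative_fraction(self) -> float:
        """Fraction of (upper-triangle) links that are negative."""
        iu = np.triu_indices(self.n, k=1)
        s = self.signs[iu]
        return float((s == -1).sum() / s.size)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def truncate_timeseries(ts: RegionalTimeSeries, n_timepoints: int) -> RegionalTimeSeries:
    """Keep the first ``n_timepoints`` columns of a subject's time series.

    Truncating all subjects to one common length (147 points in the
    reference setup, the shortest acquisition) equalizes effective scan
    duration before correlation.
    """
    if n_timepoints < 1:
        raise ValueError(f"n_timepoints must be positive, got {n_timepoints}")
    if ts.n_timepoints < n_timepoints:
        raise ValueError(
            f"subject {ts.subject_id!r} has only {ts.n_timepoints} time "
            f"points, cannot truncate to {n_timepoints}"
        )
    return replace(ts, data=ts.data[:, :n_timepoints].copy())


def global_signal_regress(ts: RegionalTimeSeries) -> RegionalTimeSeries:
    """Regress the across-region mean series out of every region.

    Each regional series is replaced by its ordinary-least-squares residual
    against ``[intercept, global mean]``; residuals are exactly orthogonal
    to the global mean.  A zero-variance global signal degenerates to
    intercept-only regression (demeaning) with a logged warning.
    """
    if ts.n_regions < 2:
        raise ValueError("global signal regression needs at least 2 regions")
    data = ts.data
    g = data.mean(axis=0)
    if np.ptp(g) == 0:
        logger.warning(
            "subject %s: constant global signal; intercept-only regression",
            ts.subject_id,
        )
        resid = data - data.mean(axis=1, keepdims=True)
        return replace(ts, data=resid)
    X = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    resid = data - (X @ beta).T
    return replace(ts, data=resid)


def pearson_connectivity(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Pearson product-moment correlation between every pair of regions."""
    data = ts.data
    sd = data.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        ids = (
            [ts.partition.region_ids[i] for i in flat]
            if ts.partition is not None
            else flat.tolist()
        )
        raise ValueError(
            f"subject {ts.subject_id!r}: zero-variance regions {ids}"
        )
    corr = np.corrcoef(data)
    corr = (corr + corr.T) / 2.0  # enforce symmetry before sign-taking
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(corr, partition=ts.partition, subject_id=ts.subject_id)


def to_signed_network(
    conn: ConnectivityMatrix, zero_policy: str = "positive"
) -> SignedNetwork:
    """Map correlations to link signs; policy decides exact zeros.

    ``zero_policy``:

    * ``"positive"`` (default) — zeros become +1 (conservative: a positive
      link alone can never create a frustration);
    * ``"negative"`` — zeros become -1;
    * ``"drop"`` — zeros stay 0 and triads containing them are skipped by
      the enumerator.

    Empirical correlations are almost surely nonzero, so the policy is
    essentially inert on real data; the count of affected links is logged.
    """
    if zero_policy not in ("positive", "negative", "drop"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    signs = np.sign(conn.values).astype(np.int8)
    np.fill_diagonal(signs, 0)
    zero_mask = (conn.values == 0) & ~np.eye(conn.n, dtype=bool)
    n_zero = int(zero_mask.sum() // 2)
    if n_zero:
        logger.warning(
            "subject %s: %d exactly-zero correlations handled by policy %r",
            conn.subject_id,
            n_zero,
            zero_policy,
        )
        if zero_policy == "positive":
            signs[zero_mask] = 1
        elif zero_policy == "negative":
            signs[zero_mask] = -1
        # "drop": leave zeros in place
    return SignedNetwork(
        signs,
        partition=conn.partition,
        subject_id=conn.subject_id,
        n_zero_links=n_zero,
    )
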