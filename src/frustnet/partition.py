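"""Region metadata: partition of regions into canonical networks and hemispheres.

A :class:`RegionPartition` is the bookkeeping object every stage of the
pipeline shares.  It records, for each region of a parcellation, which
canonical functional network it belongs to (visual, somatomotor, default
mode, ..., subcortical structures, brain stem, cerebellum) and which
hemisphere hosts it.  All analytic null formulas depend only on the group
sizes stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RegionPartition", "generate_partition", "shen268_partition"]


@dataclass(frozen=True)
class RegionPartition:
    """Assignment of each region to exactly one network and one hemisphere.

    Parameters
    ----------
    region_ids
        Ordered region identifiers (strings); order defines row/column
        order of every matrix downstream.
    network_labels
        Canonical-network label per region, aligned with ``region_ids``.
    hemisphere_labels
        ``"L"`` or ``"R"`` per region.
    """

    region_ids: tuple[str, ...]
    network_labels: tuple[str, ...]
    hemisphere_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if len(self.network_labels) != n or len(self.hemisphere_labels) != n:
            raise ValueError(
                f"label lengths ({len(self.network_labels)}, "
                f"{len(self.hemisphere_labels)}) do not match "
                f"{n} region ids"
            )
        if len(set(self.region_ids)) != n:
            raise ValueError("region ids must be unique")
        bad = sorted(set(self.hemisphere_labels) - {"L", "R"})
        if bad:
            raise ValueError(f"hemisphere labels must be 'L' or 'R', got {bad}")

    # -- derived views ----------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of regions."""
        return len(self.region_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        """Network names in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.network_labels:
            seen.setdefault(lab)
        return tuple(seen)

    @property
    def network_sizes(self) -> dict[str, int]:
        sizes = {name: 0 for name in self.networks}
        for lab in self.network_labels:
            sizes[lab] += 1
        return sizes

    @property
    def network_codes(self) -> np.ndarray:
        """Integer network code per region (order of :attr:`networks`)."""
        index = {name: i for i, name in enumerate(self.networks)}
        return np.array([index[lab] for lab in self.network_labels], dtype=np.int64)

    @property
    def hemisphere_is_right(self) -> np.ndarray:
        return np.array([h == "R" for h in self.hemisphere_labels], dtype=bool)

    @property
    def n_left(self) -> int:
        return sum(h == "L" for h in self.hemisphere_labels)

    @property
    def n_right(self) -> int:
        return sum(h == "R" for h in self.hemisphere_labels)

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "network": self.network_labels,
                "hemisphere": self.hemisphere_labels,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionPartition":
        return cls(
            tuple(frame["region_id"].astype(str)),
            tuple(frame["network"].astype(str)),
            tuple(frame["hemisphere"].astype(str)),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionPartition":
        return cls.from_frame(pd.read_csv(path))


def generate_partition(
    n_regions: int,
    network_sizes: dict[str, int] | list[int] | tuple[int, ...],
    hemisphere_split: tuple[int, int],
    seed: int = 0,
) -> RegionPartition:
    """Build a deterministic region partition.

    Networks are assigned in contiguous blocks (matching the block structure
    of the synthetic covariance); hemisphere labels are a seeded random
    interleaving with the requested left/right counts.

    Parameters
    ----------
    n_regions
        Total number of regions.
    network_sizes
        Sizes per network, either a mapping ``name -> size`` or a sequence
        of sizes (auto-named ``net01``, ``net02``, ...).
    hemisphere_split
        ``(n_left, n_right)`` region counts.
    seed
        Seed for the hemisphere interleaving.
    """
    if not isinstance(network_sizes, dict):
        network_sizes = {
            f"net{i + 1:02d}": int(s) for i, s in enumerate(network_sizes)
        }
    total = sum(network_sizes.values())
    if total != n_regions:
        raise ValueError(
            f"network sizes sum to {total}, expected n_regions={n_regions}"
        )
    n_left, n_right = hemisphere_split
    if n_left + n_right != n_regions:
        raise ValueError(
            f"hemisphere split sums to {n_left + n_right}, "
            f"expected n_regions={n_regions}"
        )
    if min(n_left, n_right) < 0:
        raise ValueError("hemisphere counts must be non-negative")

    region_ids = tuple(f"roi{i + 1:03d}" for i in range(n_regions))
    network_labels: list[str] = []
    for name, size in network_sizes.items():
        if size < 0:
            raise ValueError(f"network {name!r} has negative size {size}")
        network_labels.extend([name] * size)

    rng = np.random.default_rng(seed)
    hemis = np.array(["L"] * n_left + ["R"] * n_right)
    rng.shuffle(hemis)
    return RegionPartition(region_ids, tuple(network_labels), tuple(hemis))


#: plausible canonical-network sizes for a 268-region whole-brain atlas
_SHEN268_SIZES = {
    "VIS": 30,
    "SM": 32,
    "DA": 22,
    "VA": 24,
    "LIM": 20,
    "FP": 30,
    "DM": 40,
    "SCS": 30,
    "BS": 10,
    "CB": 30,
}


def shen268_partition(seed: int = 0) -> RegionPartition:
    """268-region preset: 10 canonical networks, 135 left / 133 right."""
    return generate_partition(268, dict(_SHEN268_SIZES), (135, 133), seed=seed)
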