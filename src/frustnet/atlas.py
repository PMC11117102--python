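"""Projection of a fine parcellation onto canonical networks via Dice overlap.

Canonical-network atlases and region parcellations rarely share boundaries,
so each parcel i is assigned to the network j maximizing the Dice
coefficient ``C_ij = 2 h_ij / (a_i + b_j)`` where ``a_i`` and ``b_j`` are
the voxel counts of parcel and network and ``h_ij`` their overlap.
Parcels outside the canonical atlas's coverage (e.g., subcortical
structures, brain stem, cerebellum when the network atlas is cortical-only)
are handled by explicit anatomical overrides.

Volumes are integer label grids on a shared voxel grid; resampling between
spaces is delegated to external neuroimaging tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DiceMatrix",
    "AssignmentResult",
    "dice_matrix",
    "assign_parcels",
    "read_label_volume",
    "write_label_volume",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiceMatrix:
    """Dice coefficients between fine parcels (rows) and networks (columns)."""

    dice: pd.DataFrame
    a: pd.Series  # voxel count per parcel
    b: pd.Series  # voxel count per network
    h: pd.DataFrame  # overlap voxel counts

    def __post_init__(self) -> None:
        if (self.h.values > np.minimum.outer(self.a.values, self.b.values)).any():
            raise ValueError("overlap exceeds min(a_i, b_j)")


def dice_matrix(
    fine_volume: np.ndarray,
    coarse_volume: np.ndarray,
    parcel_ids: list[int] | None = None,
    network_ids: list[int] | None = None,
) -> DiceMatrix:
    """Exact voxel-count Dice for every (parcel, network) label pair.

    Label 0 is background and never participates.  Parcels listed in
    ``parcel_ids`` but absent from the volume get a zero row with a warning.
    """
    fine = np.asarray(fine_volume)
    coarse = np.asarray(coarse_volume)
    if fine.shape != coarse.shape:
        raise ValueError(
            f"volumes must share one grid: {fine.shape} vs {coarse.shape}"
        )
    if (fine < 0).any() or (coarse < 0).any():
        raise ValueError("labels must be non-negative integers")

    present_p = [int(v) for v in np.unique(fine) if v > 0]
    present_n = [int(v) for v in np.unique(coarse) if v > 0]
    parcels = parcel_ids if parcel_ids is not None else present_p
    networks = network_ids if network_ids is not None else present_n

    a = pd.Series(
        {p: int((fine == p).sum()) for p in parcels}, dtype=int, name="a"
    )
    for p in parcels:
        if a[p] == 0:
            logger.warning("parcel %s is empty; Dice row set to zero", p)
    b = pd.Series(
        {q: int((coarse == q).sum()) for q in networks}, dtype=int, name="b"
    )

    # joint histogram over (fine, coarse) labels
    pmax = max(parcels, default=0)
    nmax = max(networks, default=0)
    joint = np.zeros((pmax + 1, nmax + 1), dtype=np.int64)
    mask = (fine > 0) & (coarse > 0)
    np.add.at(joint, (fine[mask], coarse[mask]), 1)

    h = pd.DataFrame(
        [[int(joint[p, q]) if p <= pmax and q <= nmax else 0 for q in networks]
         for p in parcels],
        index=parcels,
        columns=networks,
    )
    denom = a.values[:, None] + b.values[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        dice = np.where(denom > 0, 2.0 * h.values / denom, 0.0)
    return DiceMatrix(
        dice=pd.DataFrame(dice, index=parcels, columns=networks),
        a=a,
        b=b,
        h=h,
    )


@dataclass(frozen=True)
class AssignmentResult:
    """Parcel→network assignment with tie and coverage diagnostics."""

    table: pd.DataFrame  # parcel_id, network_label, dice, overridden
    ties: list[int]
    unassigned: list[int]

    def mapping(self) -> dict[int, object]:
        return dict(zip(self.table["parcel_id"], self.table["network_label"]))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def assign_parcels(
    dice: DiceMatrix,
    overrides: dict[int, object] | None = None,
) -> AssignmentResult:
    """Assign each parcel to the network with the largest Dice coefficient.

    ``overrides`` (parcel id → label) take precedence regardless of Dice,
    covering parcels outside the canonical atlas.  Exact argmax ties
    resolve to the lowest column index and are logged; all-zero rows
    without an override are flagged unassigned.
    """
    overrides = overrides or {}
    rows = []
    ties: list[int] = []
    unassigned: list[int] = []
    cols = list(dice.dice.columns)
    for p in dice.dice.index:
        row = dice.dice.loc[p].values
        if p in overrides:
            rows.append((p, overrides[p], float(row.max(initial=0.0)), True))
            continue
        if not (row > 0).any():
            unassigned.append(int(p))
            rows.append((p, None, 0.0, False))
            continue
        best = int(np.argmax(row))
        if (row == row[best]).sum() > 1:
            ties.append(int(p))
            logger.warning(
                "parcel %s: Dice tie at %.4f; resolved to first network %r",
                p,
                row[best],
                cols[best],
            )
        rows.append((p, cols[best], float(row[best]), False))
    if unassigned:
        logger.warning("unassigned parcels (zero overlap, no override): %s", unassigned)
    table = pd.DataFrame(
        rows, columns=["parcel_id", "network_label", "dice", "overridden"]
    )
    return AssignmentResult(table=table, ties=ties, unassigned=unassigned)


def read_label_volume(path: str | Path) -> np.ndarray:
    """Read an integer label volume from NIfTI (via nibabel) or ``.npy``."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    import nibabel as nib

    img = nib.load(str(path))
    return np.rint(np.asanyarray(img.dataobj)).astype(np.int32)


def write_label_volume(
    volume: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> None:
    """Write an integer label volume to NIfTI or ``.npy``."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(volume, dtype=np.int32))
        return
    import nibabel as nib

    img = nib.Nifti1Image(
        np.asarray(volume, dtype=np.int32),
        affine if affine is not None else np.eye(4),
    )
    nib.save(img, str(path))
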