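"""Plain-text I/O contracts shared by all pipeline stages.

Time series travel as TSV (regions × time points, header row of time
indices, first column the region id); region metadata and cohort manifests
as headered CSV; matrices (connectivity, signs, edge significance) as TSV
with region-id headers.  Everything round-trips losslessly enough for the
sign-based analysis (full float repr for correlations).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import ConnectivityMatrix, RegionalTimeSeries, SignedNetwork
from .partition import RegionPartition

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_signed_network_tsv",
    "read_signed_network_tsv",
    "write_cohort",
    "read_cohort",
]


def _region_ids(n: int, partition: RegionPartition | None) -> list[str]:
    if partition is not None:
        return list(partition.region_ids)
    return [f"roi{i + 1:03d}" for i in range(n)]


def write_timeseries_tsv(ts: RegionalTimeSeries, path: str | Path) -> None:
    frame = pd.DataFrame(
        ts.data,
        index=pd.Index(_region_ids(ts.n_regions, ts.partition), name="region_id"),
        columns=[f"t{j}" for j in range(ts.n_timepoints)],
    )
    frame.to_csv(path, sep="\t")


def read_timeseries_tsv(
    path: str | Path,
    partition: RegionPartition | None = None,
    subject_id: str | None = None,
    stage: str | None = None,
    age: float | None = None,
) -> RegionalTimeSeries:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if partition is not None:
        if list(frame.index) != list(partition.region_ids):
            raise ValueError(
                f"{path}: region order does not match the partition"
            )
    return RegionalTimeSeries(
        frame.values,
        partition=partition,
        subject_id=subject_id or Path(path).stem,
        stage=stage,
        age=age,
    )


def write_matrix_tsv(
    values: np.ndarray,
    path: str | Path,
    partition: RegionPartition | None = None,
) -> None:
    ids = _region_ids(values.shape[0], partition)
    pd.DataFrame(values, index=pd.Index(ids, name="region_id"), columns=ids).to_csv(
        path, sep="\t"
    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_signed_network_tsv(net: SignedNetwork, path: str | Path) -> None:
    write_matrix_tsv(net.signs.astype(int), path, net.partition)


def read_signed_network_tsv(
    path: str | Path, partition: RegionPartition | None = None
) -> SignedNetwork:
    frame = read_matrix_tsv(path)
    return SignedNetwork(
        frame.values.astype(np.int8), partition=partition, subject_id=Path(path).stem
    )


def write_cohort(
    subjects: list[RegionalTimeSeries],
    outdir: str | Path,
    partition: RegionPartition | None = None,
) -> Path:
    """Write per-subject TSVs, the region-metadata CSV and a manifest CSV.

    Returns the manifest path.  The manifest records subject_id, stage,
    age and the relative time-series path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    part = partition or (subjects[0].partition if subjects else None)
    if part is not None:
        part.to_csv(outdir / "regions.csv")
    records = []
    for ts in subjects:
        rel = f"{ts.subject_id}.tsv"
        write_timeseries_tsv(ts, outdir / rel)
        records.append(
            {
                "subject_id": ts.subject_id,
                "stage": ts.stage,
                "age": ts.age,
                "path": rel,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[RegionalTimeSeries]:
    """Load a cohort from a manifest CSV written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    regions = base / "regions.csv"
    partition = RegionPartition.from_csv(regions) if regions.exists() else None
    subjects = []
    for rec in manifest.itertuples():
        subjects.append(
            read_timeseries_tsv(
                base / rec.path,
                partition=partition,
                subject_id=str(rec.subject_id),
                stage=None if pd.isna(rec.stage) else str(rec.stage),
                age=None if pd.isna(rec.age) else float(rec.age),
            )
        )
    return subjects
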