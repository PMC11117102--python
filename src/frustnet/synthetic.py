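"""Synthetic cohorts with the statistical structure the analysis assumes.

Real inputs to this kind of study are parcellated resting-state fMRI time
series; those are deliberately out of scope.  Instead this module draws
regional time series from a zero-mean multivariate normal with a
block-constant (compound-symmetry per network) correlation matrix:
``rho_within`` inside each canonical network, ``rho_between`` across
networks.  With ``rho_within > 0 > rho_between`` the sample-correlation
signs reproduce the qualitative geography the analysis rests on — within-
network links essentially all positive, negative links almost exclusively
between networks.

Also provided: random complete signed graphs (direct fixtures for the
frustration kernel), life-span cohorts with stage labels, and paired
fine/coarse label volumes with known ground truth for the atlas-projection
Dice machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import RegionalTimeSeries, SignedNetwork
from .partition import RegionPartition

__all__ = [
    "LIFESPAN_STAGES",
    "CohortSpec",
    "pair_coupling_matrix",
    "generate_timeseries",
    "generate_signed_graph",
    "generate_cohort",
    "generate_label_volumes",
]

logger = logging.getLogger(__name__)

#: life-span stages with (min, max) ages, Erikson-style banding
LIFESPAN_STAGES: dict[str, tuple[float, float]] = {
    "childhood": (6, 12),
    "adolescence": (12, 18),
    "early_adulthood": (18, 40),
    "middle_adulthood": (40, 65),
    "late_adulthood": (65, 80),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    Defaults reflect the reference setup scaled to desk size: 147 time
    points per subject, modular positive coupling with a slightly negative
    between-network coupling.
    """

    stage_counts: dict[str, int]
    T: int = 147
    rho_within: float = 0.4
    rho_between: float = -0.05
    rho_between_pos: float = 0.15
    n_systems: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stage_counts) - set(LIFESPAN_STAGES)
        if unknown:
            raise ValueError(
                f"unknown stages {sorted(unknown)}; choose from "
                f"{sorted(LIFESPAN_STAGES)}"
            )
        if self.T < 3:
            raise ValueError("T must be at least 3")
        for rho in (self.rho_within, self.rho_between):
            if not -1 < rho < 1:
                raise ValueError(f"coupling {rho} must satisfy |rho| < 1")
        if not -1 < self.rho_between_pos < 1:
            raise ValueError("rho_between_pos must satisfy |rho| < 1")
        if all(c <= 0 for c in self.stage_counts.values()):
            raise ValueError("cohort must contain at least one subject")

    @property
    def n_subjects(self) -> int:
        return sum(max(c, 0) for c in self.stage_counts.values())


def _block_correlation(
    partition: RegionPartition,
    rho_within: float,
    rho_between: float | np.ndarray,
) -> np.ndarray:
    """Block-constant correlation matrix.

    ``rho_between`` is a scalar (compound symmetry across all network
    pairs) or a symmetric K × K matrix of per-network-pair couplings
    (diagonal ignored: within-network coupling is ``rho_within``).
    """
    codes = partition.network_codes
    same = codes[:, None] == codes[None, :]
    if np.ndim(rho_between) == 0:
        C = np.where(same, rho_within, float(rho_between))
    else:
        pair = np.asarray(rho_between, dtype=float)
        k = len(partition.networks)
        if pair.shape != (k, k) or not np.allclose(pair, pair.T):
            raise ValueError(
                f"per-pair coupling must be a symmetric {k}×{k} matrix"
            )
        if np.abs(pair).max() >= 1:
            raise ValueError("couplings must satisfy |rho| < 1")
        C = pair[np.ix_(codes, codes)]
        C[same] = rho_within
    C = C.astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def pair_coupling_matrix(
    n_networks: int,
    rho_between: float,
    rho_between_pos: float = 0.15,
    n_systems: int = 3,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Symmetric per-network-pair coupling matrix with system structure.

    Canonical networks are grouped into ``n_systems`` super-systems (a
    seeded random balanced grouping); network pairs within one system
    couple at ``rho_between_pos`` (weakly synchronous, like the
    sensory/attention cluster), pairs across systems at ``rho_between``
    (anticorrelated, like task-positive vs default-mode).  This is the
    sign heterogeneity real large-scale connectivity shows and it keeps
    the implied block correlation matrix comfortably positive definite.
    """
    if n_systems < 1 or n_systems > n_networks:
        raise ValueError("n_systems must lie in [1, n_networks]")
    rng = np.random.default_rng(seed)
    systems = np.arange(n_networks) % n_systems
    rng.shuffle(systems)
    same = np.equal.outer(systems, systems)
    pair = np.where(same, rho_between_pos, rho_between).astype(float)
    np.fill_diagonal(pair, 0.0)
    return pair


def generate_timeseries(
    partition: RegionPartition,
    T: int = 147,
    rho_within: float = 0.4,
    rho_between: float | np.ndarray = -0.02,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "subject",
    stage: str | None = None,
    age: float | None = None,
    allow_shrinkage: bool = True,
) -> RegionalTimeSeries:
    """Draw one subject's regions × time matrix from the block model.

    The requested block correlation matrix is validated for positive
    semi-definiteness; an infeasible combination is repaired by convex
    shrinkage toward the identity (weight logged) or rejected when
    ``allow_shrinkage`` is off.  ``noise_sd`` adds independent white noise,
    attenuating all correlations by ``1/(1 + noise_sd**2)``.
    """
    if T < 3:
        raise ValueError("T must be at least 3")
    C = _block_correlation(partition, rho_within, rho_between)
    min_eig = float(np.linalg.eigvalsh(C)[0])
    if min_eig < -1e-10:
        if not allow_shrinkage:
            raise ValueError(
                f"requested block covariance is not PSD (min eigenvalue "
                f"{min_eig:.3g}) and shrinkage is disabled"
            )
        lam = (-min_eig) / (1.0 - min_eig) + 1e-9
        logger.warning(
            "block covariance not PSD (min eig %.3g); shrinking toward "
            "identity with weight %.4f",
            min_eig,
            lam,
        )
        C = (1 - lam) * C + lam * np.eye(partition.n)
    if noise_sd:
        C = C + noise_sd**2 * np.eye(partition.n)

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(partition.n))
    data = L @ rng.standard_normal((partition.n, T))
    return RegionalTimeSeries(
        data, partition=partition, subject_id=subject_id, stage=stage, age=age
    )


def generate_signed_graph(
    n: int,
    p_neg: float,
    seed: int | np.random.SeedSequence = 0,
    partition: RegionPartition | None = None,
) -> SignedNetwork:
    """Complete signed graph with i.i.d. negative links of probability ``p_neg``."""
    if n < 3:
        raise ValueError(f"need at least 3 nodes to form triads, got {n}")
    if not 0 <= p_neg <= 1:
        raise ValueError(f"p_neg must lie in [0, 1], got {p_neg}")
    rng = np.random.default_rng(seed)
    signs = np.ones((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)
    neg = rng.random(iu[0].size) < p_neg
    signs[iu] = np.where(neg, -1, 1)
    signs.T[iu] = signs[iu]
    np.fill_diagonal(signs, 0)
    return SignedNetwork(signs, partition=partition)


def generate_cohort(
    spec: CohortSpec, partition: RegionPartition
) -> list[RegionalTimeSeries]:
    """Generate a life-span cohort; per-subject seeds spawn from the master seed.

    Subjects are returned in declared stage order with deterministic ids
    ``sub-<stage>-<index>`` and ages drawn uniformly within the stage's
    band, so cohorts are reproducible and extendable.
    """
    if spec.n_systems > 1:
        coupling: float | np.ndarray = pair_coupling_matrix(
            len(partition.networks),
            spec.rho_between,
            rho_between_pos=spec.rho_between_pos,
            n_systems=spec.n_systems,
            seed=np.random.SeedSequence(spec.seed, spawn_key=(0xC0FFEE,)),
        )
    else:
        coupling = spec.rho_between
    subjects: list[RegionalTimeSeries] = []
    idx = 0
    for stage, count in spec.stage_counts.items():
        lo, hi = LIFESPAN_STAGES[stage]
        for s in range(max(count, 0)):
            child = np.random.SeedSequence(spec.seed, spawn_key=(idx,))
            age_rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(idx, 1))
            )
            subjects.append(
                generate_timeseries(
                    partition,
                    T=spec.T,
                    rho_within=spec.rho_within,
                    rho_between=coupling,
                    noise_sd=spec.noise_sd,
                    seed=child,
                    subject_id=f"sub-{stage}-{s + 1:03d}",
                    stage=stage,
                    age=float(np.round(age_rng.uniform(lo, hi), 1)),
                )
            )
            idx += 1
    return subjects


def generate_label_volumes(
    grid_shape: tuple[int, int, int],
    partition: RegionPartition,
    parcels_per_network: int,
    seed: int = 0,
    jitter: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """Paired fine/coarse label volumes with known parcel→network truth.

    The grid is sliced into one slab per canonical network along axis 0
    (the coarse volume) and each slab into ``parcels_per_network`` fine
    parcels along axis 1.  With ``jitter > 0`` a fraction of each parcel's
    voxels is swapped with a parcel of a different network, degrading the
    Dice overlap while leaving ground truth defined.

    Returns ``(fine_volume, coarse_volume, mapping)`` with 0 as background
    (absent here: parcels tile the grid) and fine labels numbered from 1.
    """
    networks = partition.networks
    k = len(networks)
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must lie in [0, 0.5)")
    if grid_shape[0] < k or grid_shape[1] < parcels_per_network:
        raise ValueError(
            f"grid {grid_shape} cannot pack {k} networks × "
            f"{parcels_per_network} parcels with at least one voxel each"
        )
    coarse = np.zeros(grid_shape, dtype=np.int32)
    fine = np.zeros(grid_shape, dtype=np.int32)
    mapping: dict[int, str] = {}
    slabs = np.array_split(np.arange(grid_shape[0]), k)
    cols = np.array_split(np.arange(grid_shape[1]), parcels_per_network)
    pid = 0
    for t, slab in enumerate(slabs):
        coarse[slab, :, :] = t + 1
        for c in cols:
            pid += 1
            fine[np.ix_(slab, c, np.arange(grid_shape[2]))] = pid
            mapping[pid] = networks[t]

    if jitter > 0:
        rng = np.random.default_rng(seed)
        flat = fine.ravel()
        coarse_codes = coarse.ravel()
        parcel_net = {p: np.flatnonzero(flat == p) for p in mapping}
        for p, voxels in parcel_net.items():
            m = int(round(jitter * voxels.size))
            if m == 0:
                continue
            # swap with a parcel from a different network
            others = [
                q for q, net in mapping.items() if net != mapping[p] and q != p
            ]
            q = int(rng.choice(others))
            q_voxels = np.flatnonzero(flat == q)
            take_p = rng.choice(voxels, size=min(m, voxels.size), replace=False)
            take_q = rng.choice(q_voxels, size=take_p.size, replace=False)
            flat[take_p] = q
            flat[take_q] = p
        fine = flat.reshape(grid_shape)
        _ = coarse_codes
    return fine, coarse, mapping
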