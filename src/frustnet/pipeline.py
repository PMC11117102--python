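"""End-to-end orchestration: cohort → signed networks → frustrations → stats.

``run_subject`` takes one subject from time series to contribution rows at
all four analysis levels (regions, connections, network formation types,
hemisphere states), each paired with its analytic null.  ``run_group``
aggregates subjects per life-span stage (plus the pooled "all" group),
runs the paired actual-vs-null statistics with FDR and effect banding,
computes WBR on the significantly low/high-contributed edge sets, runs
between-stage Kruskal–Wallis comparisons, and entropy shuffle tests on the
pooled significance patterns.

Defaults reproduce the reference analysis choices: truncation to 147 time
points, no global-signal regression, sign-only complete networks, alpha
0.05 with a large effect band, 1,000 entropy shuffles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as gstats
from .frustration import (
    FORMATION_TYPES,
    HEMISPHERE_STATES,
    FrustrationSet,
    WBRResult,
    edge_contributions,
    enumerate_frustrations,
    hemisphere_state_counts,
    network_formation_counts,
    node_contributions,
    null_edge_contribution,
    null_hemisphere_states,
    null_network_formation,
    null_node_contribution,
    wbr,
)
from .network import (
    RegionalTimeSeries,
    SignedNetwork,
    global_signal_regress,
    pearson_connectivity,
    to_signed_network,
    truncate_timeseries,
)
from .partition import RegionPartition

__all__ = ["PipelineConfig", "run_subject", "run_group", "GroupReport"]

logger = logging.getLogger(__name__)

ELEMENT_LEVELS = ("region", "edge", "network_formation", "hemisphere_state")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one study run; defaults match the main analysis."""

    n_timepoints: int = 147
    gsr: bool = False
    zero_policy: str = "positive"
    alpha: float = 0.05
    required_band: str = "large"
    n_shuffles: int = 1000
    seed: int = 0
    min_subjects: int = 5
    pool_all: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _edge_ids(partition: RegionPartition) -> list[str]:
    ids = partition.region_ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    return [f"{ids[a]}--{ids[b]}" for a, b in zip(iu[0], iu[1])]


def run_subject(
    ts: RegionalTimeSeries, config: PipelineConfig = PipelineConfig()
) -> tuple[SignedNetwork, FrustrationSet, pd.DataFrame]:
    """Process one subject: signed network, frustrations, contribution rows.

    The returned DataFrame is long-format with columns (subject_id, stage,
    element_type, element_id, actual, null).
    """
    if ts.partition is None:
        raise ValueError(f"subject {ts.subject_id!r} has no region partition")
    part = ts.partition
    work = truncate_timeseries(ts, config.n_timepoints)
    if config.gsr:
        work = global_signal_regress(work)
    conn = pearson_connectivity(work)
    net = to_signed_network(conn, zero_policy=config.zero_policy)
    fs = enumerate_frustrations(net)
    logger.info(
        "subject %s: N_frust=%d, negative link fraction=%.4f",
        ts.subject_id,
        fs.n_frust,
        net.negative_fraction,
    )

    rows: list[dict] = []
    base = {"subject_id": ts.subject_id, "stage": ts.stage}

    node_act = node_contributions(fs)
    node_null = null_node_contribution(part.n, fs.n_frust)
    for rid, act in zip(part.region_ids, node_act):
        rows.append(
            base
            | {
                "element_type": "region",
                "element_id": rid,
                "actual": int(act),
                "null": node_null,
            }
        )

    edge_act = edge_contributions(fs)
    edge_null = null_edge_contribution(part.n, fs.n_frust)
    iu = np.triu_indices(part.n, k=1)
    for eid, act in zip(_edge_ids(part), edge_act[iu]):
        rows.append(
            base
            | {
                "element_type": "edge",
                "element_id": eid,
                "actual": int(act),
                "null": edge_null,
            }
        )

    form_act = network_formation_counts(fs, part)
    form_null = null_network_formation(part, fs.n_frust)
    for net_name in part.networks:
        for ftype in FORMATION_TYPES:
            rows.append(
                base
                | {
                    "element_type": "network_formation",
                    "element_id": f"{net_name}:{ftype}",
                    "actual": int(form_act.loc[net_name, ftype]),
                    "null": float(form_null.loc[net_name, ftype]),
                }
            )

    hemi_act = hemisphere_state_counts(fs, part)
    hemi_null = null_hemisphere_states(part.n_left, part.n_right, fs.n_frust)
    for state in HEMISPHERE_STATES:
        rows.append(
            base
            | {
                "element_type": "hemisphere_state",
                "element_id": state,
                "actual": int(hemi_act[state]),
                "null": float(hemi_null[state]),
            }
        )

    return net, fs, pd.DataFrame(rows)


@dataclass
class GroupReport:
    """Outputs of one group-level run."""

    contributions: pd.DataFrame
    paired: pd.DataFrame  # per (stage, level, element): stats + flags
    stagewise: pd.DataFrame  # Kruskal–Wallis between stages per element
    wbr_results: pd.DataFrame  # per stage: WBR of low/high-contributed edges
    entropy: pd.DataFrame  # entropy shuffle tests on pooled patterns
    manifest: dict

    def digest(self) -> str:
        hasher = hashlib.sha256()
        for frame in (
            self.contributions,
            self.paired,
            self.stagewise,
            self.wbr_results,
            self.entropy,
        ):
            hasher.update(frame.round(12).to_csv(index=False).encode())
        return hasher.hexdigest()[:16]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.contributions.to_csv(outdir / "contributions.csv", index=False)
        self.paired.to_csv(outdir / "paired_stats.csv", index=False)
        self.stagewise.to_csv(outdir / "stagewise_stats.csv", index=False)
        self.wbr_results.to_csv(outdir / "wbr.csv", index=False)
        self.entropy.to_csv(outdir / "entropy_tests.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _edge_flag_matrix(
    paired: pd.DataFrame, partition: RegionPartition, direction: str
) -> np.ndarray:
    """Boolean N × N matrix of significantly greater/lower edges."""
    n = partition.n
    index = {rid: i for i, rid in enumerate(partition.region_ids)}
    mask = np.zeros((n, n), dtype=bool)
    sel = paired[(paired["direction"] == direction)]
    for eid in sel["element_id"]:
        a, b = eid.split("--")
        mask[index[a], index[b]] = mask[index[b], index[a]] = True
    return mask


def run_group(
    subjects: list[RegionalTimeSeries],
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> GroupReport:
    """Run the full group-level study over a cohort.

    Stages with fewer than ``config.min_subjects`` subjects are skipped
    with a warning (the signed-rank minimum).  The pooled ``"all"`` group
    is analyzed when ``config.pool_all`` is set.  Entropy shuffle tests run
    on the pooled regional and connectional significance patterns, for the
    greater- and lower-contributed directions separately.
    """
    if not subjects:
        raise ValueError("empty cohort")
    part = subjects[0].partition
    if part is None:
        raise ValueError("subjects must carry a region partition")

    all_rows = []
    for ts in subjects:
        _, _, rows = run_subject(ts, config)
        all_rows.append(rows)
    contributions = pd.concat(all_rows, ignore_index=True)

    stage_groups: dict[str, pd.DataFrame] = {}
    for stage, sub in contributions.groupby("stage", dropna=False):
        name = "unstaged" if pd.isna(stage) else str(stage)
        n_sub = sub["subject_id"].nunique()
        if n_sub < config.min_subjects:
            logger.warning(
                "stage %s skipped: %d subjects < minimum %d",
                name,
                n_sub,
                config.min_subjects,
            )
            continue
        stage_groups[name] = sub
    if config.pool_all and contributions["subject_id"].nunique() >= config.min_subjects:
        stage_groups["all"] = contributions

    # paired actual-vs-null per stage × level (one FDR family each)
    paired_frames = []
    for stage, sub in stage_groups.items():
        for level, lvl in sub.groupby("element_type"):
            res = gstats.paired_contribution_stats(
                lvl,
                alpha=config.alpha,
                required_band=config.required_band,
            )
            res.insert(0, "element_type", level)
            res.insert(0, "stage", stage)
            paired_frames.append(res)
    paired = pd.concat(paired_frames, ignore_index=True)

    # between-stage Kruskal–Wallis per element (true stages only)
    true_stages = [s for s in stage_groups if s not in ("all", "unstaged")]
    kw_rows = []
    if len(true_stages) >= 2:
        per_stage = {s: stage_groups[s] for s in true_stages}
        for level in ELEMENT_LEVELS:
            elements = contributions.loc[
                contributions["element_type"] == level, "element_id"
            ].unique()
            stats_rows = []
            for element in elements:
                groups = [
                    per_stage[s]
                    .loc[
                        (per_stage[s]["element_type"] == level)
                        & (per_stage[s]["element_id"] == element),
                        "actual",
                    ]
                    .values
                    for s in true_stages
                ]
                h, p, eta2 = gstats.kruskal_eta2(groups)
                stats_rows.append(
                    {
                        "element_type": level,
                        "element_id": element,
                        "statistic": h,
                        "p": p,
                        "effect": eta2,
                    }
                )
            frame = pd.DataFrame(stats_rows)
            frame["p_fdr"] = gstats.fdr_bh(frame["p"].values)
            frame["band"] = [
                gstats.effect_band(v, "multigroup") for v in frame["effect"]
            ]
            frame = gstats.significant_elements(
                frame, alpha=config.alpha, band=config.required_band
            )
            kw_rows.append(frame)
    stagewise = (
        pd.concat(kw_rows, ignore_index=True)
        if kw_rows
        else pd.DataFrame(
            columns=[
                "element_type",
                "element_id",
                "statistic",
                "p",
                "effect",
                "p_fdr",
                "band",
                "significant",
                "direction",
            ]
        )
    )

    # WBR of significantly low/high-contributed edge sets per stage
    wbr_rows = []
    for stage in stage_groups:
        edges = paired[
            (paired["stage"] == stage) & (paired["element_type"] == "edge")
        ]
        for direction, label in (("lower", "low_contributed"), ("greater", "high_contributed")):
            mask = _edge_flag_matrix(edges, part, direction)
            res: WBRResult = wbr(mask, part)
            wbr_rows.append(
                {
                    "stage": stage,
                    "edge_set": label,
                    "n_edges": res.wc + res.bc,
                    "wc": res.wc,
                    "bc": res.bc,
                    "wc0": res.wc0,
                    "bc0": res.bc0,
                    "wbr": res.value,
                }
            )
    wbr_results = pd.DataFrame(wbr_rows)

    # entropy shuffle tests on the pooled significance patterns
    rng = np.random.default_rng(config.seed)
    entropy_rows = []
    pooled_name = "all" if "all" in stage_groups else None
    if pooled_name:
        pooled = paired[paired["stage"] == pooled_name]
        region_tbl = pooled[pooled["element_type"] == "region"]
        region_index = {rid: i for i, rid in enumerate(part.region_ids)}
        for direction in ("greater", "lower"):
            flags = np.zeros(part.n, dtype=bool)
            for rid in region_tbl.loc[
                region_tbl["direction"] == direction, "element_id"
            ]:
                flags[region_index[rid]] = True
            entropy_rows.append(
                _entropy_row(
                    "region", direction, flags, part,
                    "regions-by-network", config, rng,
                )
            )
        edge_tbl = pooled[pooled["element_type"] == "edge"]
        for direction in ("greater", "lower"):
            mask = _edge_flag_matrix(edge_tbl, part, direction)
            entropy_rows.append(
                _entropy_row(
                    "edge", direction, mask, part,
                    "edges-by-network-pair", config, rng,
                )
            )
    entropy = pd.DataFrame(
        entropy_rows,
        columns=["element_type", "direction", "n_flagged", "entropy", "p"],
    )

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "n_subjects": contributions["subject_id"].nunique(),
        "stages": {
            s: int(g["subject_id"].nunique()) for s, g in stage_groups.items()
        },
        "partition_networks": dict(part.network_sizes),
    }
    report = GroupReport(
        contributions=contributions,
        paired=paired,
        stagewise=stagewise,
        wbr_results=wbr_results,
        entropy=entropy,
        manifest=manifest,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def _entropy_row(
    level: str,
    direction: str,
    flags: np.ndarray,
    part: RegionPartition,
    state_mode: str,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> dict:
    n_flagged = int(np.asarray(flags).sum()) if flags.ndim == 1 else int(
        flags[np.triu_indices(part.n, k=1)].sum()
    )
    if n_flagged == 0:
        return {
            "element_type": level,
            "direction": direction,
            "n_flagged": 0,
            "entropy": np.nan,
            "p": np.nan,
        }
    res = gstats.entropy_shuffle_test(
        flags, part, state_mode, n_shuffles=config.n_shuffles, seed=rng
    )
    return {
        "element_type": level,
        "direction": direction,
        "n_flagged": n_flagged,
        "entropy": res.entropy,
        "p": res.p_value,
    }


def export_edge_heatmap(
    paired: pd.DataFrame,
    partition: RegionPartition,
    stage: str,
    csv_path: str | Path,
    image_path: str | Path | None = None,
) -> np.ndarray:
    """Export the connection significance map (+1 greater, -1 lower, 0 none).

    Writes a region × region CSV and optionally a PNG heat map with
    network-block boundaries.
    """
    edges = paired[
        (paired["stage"] == stage) & (paired["element_type"] == "edge")
    ]
    greater = _edge_flag_matrix(edges, partition, "greater")
    lower = _edge_flag_matrix(edges, partition, "lower")
    signed = greater.astype(int) - lower.astype(int)
    ids = list(partition.region_ids)
    pd.DataFrame(signed, index=ids, columns=ids).to_csv(csv_path)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(signed, cmap="bwr", vmin=-1, vmax=1, interpolation="nearest")
        bounds = np.cumsum(list(partition.network_sizes.values()))[:-1]
        for b in bounds:
            ax.axhline(b - 0.5, color="k", lw=0.5)
            ax.axvline(b - 0.5, color="k", lw=0.5)
        ax.set_title(f"edge contribution significance — {stage}")
        fig.savefig(image_path, dpi=120)
        plt.close(fig)
    return signed
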