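"""End-to-end orchestration of the analysis stages on a cohort of event
matrices: QC -> logicle transform -> viability/doublet exclusion ->
downsampling -> SOM metaclustering -> frequencies and group statistics ->
median profiles -> ligand-receptor screen within the disease group.

This is a thin convenience layer over the stage modules; every step can be
run individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventMatrix
from .preprocess import (
    LogicleTransform,
    QCParams,
    TransformParams,
    downsample_cohort,
    log_z_scale,
    remove_anomalous_segments,
    transform_events,
)
from .metacluster import (
    assign_cells,
    mc_frequencies,
    metacluster_nodes,
    select_k_elbow,
    train_som,
)
from .communication import lr_screen, median_profile
from .stats_report import compare_populations

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    markers: list[str]
    transform: TransformParams = field(default_factory=TransformParams)
    qc: QCParams = field(default_factory=QCParams)
    downsample_to: int = 1500
    grid: tuple[int, int] = (10, 10)
    k: int | None = None            # None -> elbow-selected
    k_range: tuple[int, int] = (2, 12)
    scale_before_som: bool = True
    epochs: int = 10
    screen_group: str | None = None  # restrict the LR screen to one group
    alpha: float = 0.05
    n_perm: int = 9_999
    profile_scale: str = "raw"       # MFIs for correlation: raw medians
    min_cells_profile: int = 1


@dataclass
class PipelineResult:
    som: object
    k: int
    k_elbow: int
    node_labels: np.ndarray
    metaclusters: np.ndarray
    sample_ids: np.ndarray
    truth: np.ndarray | None
    frequencies: pd.DataFrame
    comparisons: pd.DataFrame
    profiles: pd.DataFrame
    lr_table: pd.DataFrame | None
    qc_reports: dict
    cluster_truth_match: pd.Series | None


def run_pipeline(
    events_by_sample: dict[str, EventMatrix],
    sample_sheet: pd.DataFrame,
    config: PipelineConfig,
    catalogue: pd.DataFrame | None = None,
    sender_truth: str | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on raw event matrices.

    Cells flagged as doublet/dead in ``labels`` (when present) are excluded
    after QC, standing in for manual pre-gating.  When ``sender_truth`` is
    given and truth labels exist, the LR screen uses the metacluster whose
    majority truth label matches it as the sender population.
    """
    rng = np.random.default_rng(seed)
    tr = LogicleTransform(config.transform)

    clean: dict[str, EventMatrix] = {}
    qc_reports = {}
    for sid, em in events_by_sample.items():
        em = em.sorted_by_time()
        em = transform_events(em, config.transform)
        em, report = remove_anomalous_segments(em, config.qc)
        qc_reports[sid] = report
        if em.labels is not None and {"doublet", "dead"} <= set(em.labels.columns):
            keep = ~(em.labels["doublet"] | em.labels["dead"]).to_numpy()
            em = em.with_values(em.values[keep], row_mask=keep)
        clean[sid] = em

    ds = downsample_cohort(
        clean, config.downsample_to, seed=int(rng.integers(0, 2**31 - 1))
    )

    X_parts, sid_parts, truth_parts = [], [], []
    for sid, em in ds.items():
        cols = [em.channel_index(m) for m in config.markers]
        X_parts.append(em.values[:, cols])
        sid_parts.append(np.repeat(sid, em.n_events))
        if em.labels is not None and "metacluster" in em.labels.columns:
            truth_parts.append(em.labels["metacluster"].to_numpy())
    X = np.vstack(X_parts)
    sample_ids = np.concatenate(sid_parts)
    truth = np.concatenate(truth_parts) if len(truth_parts) == len(ds) else None

    Xs = log_z_scale(X.T).T if config.scale_before_som else X
    som_seed = int(rng.integers(0, 2**31 - 1))
    som = train_som(
        Xs, markers=config.markers, grid=config.grid,
        epochs=config.epochs, seed=som_seed,
    )
    nodes = assign_cells(som, Xs)
    k_elbow, _ = select_k_elbow(
        som, range(config.k_range[0], config.k_range[1] + 1), seed=som_seed
    )
    k = config.k if config.k is not None else k_elbow
    node_labels = metacluster_nodes(som, k, seed=som_seed)
    metaclusters = node_labels[nodes]

    freq = mc_frequencies(metaclusters, sample_ids)
    comparisons = compare_populations(freq, sample_sheet, design="two-group")

    match = None
    if truth is not None:
        match = pd.crosstab(metaclusters, truth).idxmax(axis=1)

    # raw-scale median profiles (transform inverted before the medians)
    prof_events, assignments = {}, {}
    pos = 0
    group_of = sample_sheet.set_index("sample_id")["group"]
    for sid, em in ds.items():
        n = em.n_events
        if config.screen_group is None or group_of[sid] == config.screen_group:
            vals = em.values.copy()
            mcols = [em.channel_index(m) for m in em.marker_channels]
            if config.profile_scale == "raw":
                vals[:, mcols] = tr.inverse(vals[:, mcols])
            prof_events[sid] = em.with_values(vals)
            assignments[sid] = metaclusters[pos : pos + n]
        pos += n
    profiles = median_profile(
        prof_events, assignments, min_cells=config.min_cells_profile
    )

    lr_table = None
    if catalogue is not None:
        if sender_truth is not None and match is not None:
            senders = [c for c in freq.columns if match.get(c) == sender_truth]
        else:
            senders = list(freq.columns)
        receivers = [c for c in freq.columns if c not in senders]
        if senders:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lr_table = lr_screen(
                    profiles, catalogue, senders, receivers,
                    alpha=config.alpha, n_perm=config.n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )

    return PipelineResult(
        som=som,
        k=k,
        k_elbow=k_elbow,
        node_labels=node_labels,
        metaclusters=metaclusters,
        sample_ids=sample_ids,
        truth=truth,
        frequencies=freq,
        comparisons=comparisons,
        profiles=profiles,
        lr_table=lr_table,
        qc_reports=qc_reports,
        cluster_truth_match=match,
    )
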