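"""FlowSOM-style clustering: online self-organising map, bootstrap consensus
metaclustering of the SOM codebook, elbow-guided choice of k, and per-sample
metacluster frequencies.

The SOM is trained online with Euclidean distance and a Gaussian
neighbourhood whose radius and learning rate decay linearly over the run
(published FlowSOM-style defaults: 10 epochs, initial radius from a quantile
of node-grid distances).  Nodes are grouped into metaclusters by
average-linkage hierarchical clustering of a bootstrap consensus matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "SOMModel",
    "train_som",
    "assign_cells",
    "metacluster_nodes",
    "consensus_matrix",
    "select_k_elbow",
    "mc_frequencies",
]


@dataclass
class SOMModel:
    rows: int
    cols: int
    codebook: np.ndarray  # nodes x markers
    markers: list[str]
    epochs: int
    seed: int
    initial_radius: float
    alpha: tuple[float, float]

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def grid_positions(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c]).astype(float)


def train_som(
    X,
    markers: Sequence[str] | None = None,
    grid: tuple[int, int] = (10, 10),
    epochs: int = 10,
    alpha: tuple[float, float] = (0.05, 0.01),
    radius_quantile: float = 0.67,
    seed: int = 0,
) -> SOMModel:
    """Train an online SOM on cells x markers data (transformed and scaled).

    Deterministic under ``seed``; the codebook is initialised from random
    data rows and updated one cell at a time with a Gaussian neighbourhood,
    radius decaying linearly from the ``radius_quantile`` of node-grid
    distances to 0 and the learning rate from ``alpha[0]`` to ``alpha[1]``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be cells x markers")
    if np.isnan(X).any():
        raise ValueError("NaN in SOM training data")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 markers to train a SOM")
    rows, cols = grid
    n_nodes = rows * cols
    n = X.shape[0]
    if n < 5 * n_nodes:
        warnings.warn(
            f"only {n} cells for {n_nodes} nodes; "
            "recommend at least 5 cells per node",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    codebook = X[rng.integers(0, n, size=n_nodes)].copy()

    pos = np.column_stack(np.divmod(np.arange(n_nodes), cols)).astype(float)
    grid_d2 = squareform(pdist(pos, "sqeuclidean"))
    radius0 = float(np.quantile(np.sqrt(grid_d2[grid_d2 > 0]), radius_quantile))

    total = epochs * n
    step = 0
    a0, a1 = alpha
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total - 1, 1)
            lr = a0 + (a1 - a0) * frac
            radius = radius0 * (1.0 - frac)
            x = X[i]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            if radius > 1e-12:
                h = np.exp(-grid_d2[bmu] / (2.0 * radius * radius))
            else:
                h = np.zeros(n_nodes)
                h[bmu] = 1.0
            codebook += (lr * h)[:, None] * (x - codebook)
            step += 1
    return SOMModel(
        rows=rows,
        cols=cols,
        codebook=codebook,
        markers=list(markers) if markers is not None else
        [f"m{j}" for j in range(X.shape[1])],
        epochs=epochs,
        seed=seed,
        initial_radius=radius0,
        alpha=(a0, a1),
    )


def assign_cells(som: SOMModel, X, markers: Sequence[str] | None = None) -> np.ndarray:
    """Best-matching-unit indices: argmin Euclidean distance to the codebook,
    ties broken by the lowest node index."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != som.codebook.shape[1]:
        raise ValueError(
            f"{X.shape[1]} columns do not match the {som.codebook.shape[1]} "
            "training markers"
        )
    if markers is not None and list(markers) != som.markers:
        raise ValueError("marker names do not match the training markers")
    d = cdist(X, som.codebook, "sqeuclidean")
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) index


def consensus_matrix(
    codebook: np.ndarray, k: int, B: int = 100, seed: int = 0
) -> np.ndarray:
    """Bootstrap consensus of average-linkage k-clusterings of the codebook.

    For each of ``B`` bootstrap resamples of the nodes, the resampled
    codebook is average-linkage clustered and cut at ``k``; the consensus
    entry (i, j) is the fraction of resamples containing both nodes in which
    they co-clustered.
    """
    n = codebook.shape[0]
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    both = np.zeros((n, n))
    for _ in range(B):
        idx = np.unique(rng.integers(0, n, size=n))
        if len(idx) <= k:
            continue
        Z = average(pdist(codebook[idx]))
        lab = fcluster(Z, t=k, criterion="maxclust")
        inb = np.zeros(n, dtype=bool)
        inb[idx] = True
        pair_in = np.outer(inb, inb)
        full_lab = np.full(n, -1)
        full_lab[idx] = lab
        same = (full_lab[:, None] == full_lab[None, :]) & pair_in
        both += pair_in
        together += same
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(both > 0, together / np.maximum(both, 1), 0.0)
    np.fill_diagonal(cons, 1.0)
    return cons


def metacluster_nodes(
    som: SOMModel, k: int, seed: int = 0, B: int = 100
) -> np.ndarray:
    """Map each SOM node to one of ``k`` metaclusters (labels 0..k-1) by
    cutting an average-linkage tree on the bootstrap consensus matrix."""
    n = som.n_nodes
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    if k == n:
        return np.arange(n)
    cons = consensus_matrix(som.codebook, k, B=B, seed=seed)
    dist = 1.0 - cons
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return _relabel_by_first_occurrence(labels)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Stable relabelling: clusters numbered by first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def select_k_elbow(
    som: SOMModel,
    k_range: Sequence[int] = range(2, 21),
    seed: int = 0,
    B: int = 100,
) -> tuple[int, pd.DataFrame]:
    """Elbow-guided k: within-metacluster sum of squares of the codebook per
    candidate k; returns the k maximising the discrete second difference
    (curvature) of the WSS curve, plus the full curve for inspection.

    On featureless (near-linear) curves the smallest k is returned with a
    warning.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 3:
        raise ValueError("k range must contain at least 3 values")
    if ks[0] < 2 or ks[-1] > som.n_nodes:
        raise ValueError(f"k range outside [2, {som.n_nodes}]")
    wss = []
    for k in ks:
        labels = metacluster_nodes(som, k, seed=seed, B=B)
        total = 0.0
        for lab in np.unique(labels):
            pts = som.codebook[labels == lab]
            total += float(((pts - pts.mean(axis=0)) ** 2).sum())
        wss.append(total)
    curve = pd.DataFrame({"k": ks, "wss": wss})
    w = np.asarray(wss)
    curv = w[:-2] - 2 * w[1:-1] + w[2:]  # second difference at interior ks
    span = max(w.max() - w.min(), 1e-300)
    if w.max() <= 0 or curv.max() <= 1e-6 * span:
        warnings.warn(
            "no elbow detected (featureless WSS curve); returning smallest k",
            stacklevel=2,
        )
        return ks[0], curve
    k_star = ks[1:-1][int(np.argmax(curv))]
    return k_star, curve


def mc_frequencies(
    metacluster_labels,
    sample_ids,
    parent_counts: Mapping[str, int] | None = None,
    populations: Sequence | None = None,
) -> pd.DataFrame:
    """Per-sample metacluster percentages of the parent population.

    Returns a samples x populations table of ``100 * cells-in-MC / parent``.
    By default the parent count is the number of assigned cells in the
    sample, so rows sum to 100.  Samples with zero parent count get NaN rows
    and a warning rather than a division.
    """
    labels = np.asarray(metacluster_labels)
    sids = np.asarray(sample_ids)
    if labels.shape[0] != sids.shape[0]:
        raise ValueError("labels and sample ids differ in length")
    df = pd.DataFrame({"sample_id": sids, "population": labels})
    counts = (
        df.groupby(["sample_id", "population"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    if populations is not None:
        counts = counts.reindex(columns=list(populations), fill_value=0)
    if parent_counts is None:
        parents = counts.sum(axis=1)
    else:
        parents = pd.Series(
            {s: parent_counts.get(s, 0) for s in counts.index}, dtype=float
        )
    freq = 100.0 * counts.div(parents.replace(0, np.nan), axis=0)
    zero = parents[parents == 0].index.tolist()
    if zero:
        warnings.warn(
            f"samples with zero parent count flagged (NaN rows): {zero}",
            stacklevel=2,
        )
    freq.columns.name = "population"
    return freq
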