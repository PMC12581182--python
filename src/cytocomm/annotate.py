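"""Metacluster annotation: marker enrichment modelling (MEM) scores and
transparent axis-aligned gates fit by greedy F1 coordinate ascent, with
per-marker importance measured as the F1 deterioration when a marker's
constraints are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEMLabel",
    "mem_scores",
    "mem_table",
    "GateSpec",
    "fit_gate",
    "gate_mask",
    "gate_f1",
    "marker_importance",
]

_EPS_IQR = 1e-9


@dataclass
class MEMLabel:
    """Signed per-marker enrichment scores scaled to [-10, +10]."""

    scores: pd.Series
    reference: str = "all other cells"

    def __str__(self) -> str:
        up = self.scores[self.scores > 0].sort_values(ascending=False)
        dn = self.scores[self.scores < 0].sort_values()
        pos = " ".join(f"{m}+{v:.0f}" for m, v in up.items())
        neg = " ".join(f"{m}{v:.0f}" for m, v in dn.items())
        return (pos + (" " if pos and neg else "") + neg) or "(no enrichment)"


def mem_scores(
    population: np.ndarray,
    reference: np.ndarray,
    markers: Sequence[str],
) -> MEMLabel:
    """MEM enrichment of a population against a reference.

    Per marker: ``raw = |median_pop - median_ref| + IQR_ref/IQR_pop - 1``
    floored at 0, signed by ``sign(median_pop - median_ref)``, then rescaled
    so the largest magnitude across markers is 10.  Zero IQRs are floored at
    a small epsilon.
    """
    pop = np.asarray(population, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pop.size == 0 or ref.size == 0:
        raise ValueError("population and reference must both be non-empty")
    if pop.ndim != 2 or ref.ndim != 2 or pop.shape[1] != ref.shape[1]:
        raise ValueError("population and reference must share the marker axis")
    if pop.shape[1] != len(markers):
        raise ValueError("marker names do not match the matrix width")

    med_p = np.median(pop, axis=0)
    med_r = np.median(ref, axis=0)
    iqr_p = np.maximum(
        np.percentile(pop, 75, axis=0) - np.percentile(pop, 25, axis=0),
        _EPS_IQR,
    )
    iqr_r = np.maximum(
        np.percentile(ref, 75, axis=0) - np.percentile(ref, 25, axis=0),
        _EPS_IQR,
    )
    raw = np.abs(med_p - med_r) + iqr_r / iqr_p - 1.0
    raw = np.maximum(raw, 0.0)
    signed = raw * np.sign(med_p - med_r)
    top = np.max(np.abs(signed))
    scaled = signed * (10.0 / top) if top > 0 else signed
    return MEMLabel(scores=pd.Series(scaled, index=list(markers)))


def mem_table(
    X: np.ndarray, labels: np.ndarray, markers: Sequence[str]
) -> pd.DataFrame:
    """MEM scores for every population, reference = all other cells."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rows = {}
    for pop in pd.unique(labels):
        mask = labels == pop
        if mask.all():
            rows[pop] = pd.Series(0.0, index=list(markers))
            continue
        rows[pop] = mem_scores(X[mask], X[~mask], markers).scores
    out = pd.DataFrame(rows).T
    out.index.name = "population"
    return out


# ---------------------------------------------------------------------------
# Axis-aligned auto-gating
# ---------------------------------------------------------------------------

@dataclass
class GateSpec:
    """An ordered set of axis-aligned bounds reproducing a population."""

    constraints: list[tuple[str, float, float]]  # (marker, lower, upper)
    f1: float
    importance: pd.Series | None = None
    history: list[float] = field(default_factory=list)

    @property
    def markers(self) -> list[str]:
        return [m for m, _, _ in self.constraints]

    def describe(self) -> str:
        if not self.constraints:
            return f"(no constraints; F1={self.f1:.3f})"
        parts = []
        for m, lo, hi in self.constraints:
            if np.isfinite(lo) and np.isfinite(hi):
                parts.append(f"{lo:.3g} <= {m} <= {hi:.3g}")
            elif np.isfinite(lo):
                parts.append(f"{m} >= {lo:.3g}")
            else:
                parts.append(f"{m} <= {hi:.3g}")
        return " AND ".join(parts) + f"  (F1={self.f1:.3f})"


def _f1(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def gate_mask(gate: GateSpec, X: np.ndarray, markers: Sequence[str]) -> np.ndarray:
    """Boolean in-gate indicator for every cell."""
    X = np.asarray(X, dtype=float)
    idx = {m: j for j, m in enumerate(markers)}
    mask = np.ones(X.shape[0], dtype=bool)
    for m, lo, hi in gate.constraints:
        v = X[:, idx[m]]
        if np.isfinite(lo):
            mask &= v >= lo
        if np.isfinite(hi):
            mask &= v <= hi
    return mask


def gate_f1(gate: GateSpec, X, markers, target) -> float:
    target = np.asarray(target, dtype=bool)
    mask = gate_mask(gate, X, markers)
    tp = float((mask & target).sum())
    return _f1(tp, float((mask & ~target).sum()), float((~mask & target).sum()))


def _best_bound(values, target, rest_mask, candidates, side):
    """Best threshold for one side of one marker, rest of the gate fixed.

    Counts via sorted positives/negatives + searchsorted, so all candidate
    thresholds are scored in O(n log n).
    """
    pos_v = np.sort(values[rest_mask & target])
    neg_v = np.sort(values[rest_mask & ~target])
    p_total = float(target.sum())
    if side == "lower":
        tp = len(pos_v) - np.searchsorted(pos_v, candidates, side="left")
        fp = len(neg_v) - np.searchsorted(neg_v, candidates, side="left")
    else:
        tp = np.searchsorted(pos_v, candidates, side="right")
        fp = np.searchsorted(neg_v, candidates, side="right")
    fn = p_total - tp
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    best = int(np.argmax(f1))
    return float(f1[best]), float(candidates[best])


def fit_gate(
    X,
    target,
    markers: Sequence[str],
    max_constraints: int = 20,
    tol: float = 1e-4,
    n_candidates: int = 99,
    min_positives: int = 10,
) -> GateSpec:
    """Fit an axis-aligned gate reproducing a binary target population.

    Greedy coordinate ascent over candidate thresholds (percentile grid per
    marker): repeatedly apply the single (marker, bound) change that
    maximally increases F1 = 2TP/(2TP+FP+FN); stop when the improvement
    falls below ``tol`` or ``max_constraints`` bounds are in place.
    Deterministic: ties go to the first (marker, side) in scan order.
    """
    X = np.asarray(X, dtype=float)
    target = np.asarray(target, dtype=bool)
    markers = list(markers)
    if target.sum() == 0:
        raise ValueError("no positive cells to gate")
    if target.sum() < min_positives:
        raise ValueError(
            f"only {int(target.sum())} positive cells; need >= {min_positives}"
        )
    qs = np.linspace(1, 99, n_candidates)
    cand = {m: np.percentile(X[:, j], qs) for j, m in enumerate(markers)}
    bounds: dict[str, list[float]] = {}
    order: list[str] = []

    def current_mask(exclude: str | None = None, keep_side: str | None = None):
        mask = np.ones(X.shape[0], dtype=bool)
        for m, (lo, hi) in bounds.items():
            v = X[:, markers.index(m)]
            lo_eff, hi_eff = lo, hi
            if m == exclude:
                if keep_side == "lower":
                    hi_eff = np.inf
                else:
                    lo_eff = -np.inf
            if np.isfinite(lo_eff):
                mask &= v >= lo_eff
            if np.isfinite(hi_eff):
                mask &= v <= hi_eff
        return mask

    def n_bounds() -> int:
        return sum(np.isfinite(b).sum() for b in bounds.values())

    full = current_mask()
    tp = float((full & target).sum())
    f1_now = _f1(tp, float((full & ~target).sum()), float((~full & target).sum()))
    history = [f1_now]

    for _ in range(200):
        if n_bounds() >= max_constraints:
            break
        best = (f1_now, None, None, None)
        for j, m in enumerate(markers):
            v = X[:, j]
            for side in ("lower", "upper"):
                # rest of the gate = all bounds except this (marker, side)
                rest = current_mask(exclude=m,
                                    keep_side="upper" if side == "lower" else "lower")
                f1_c, thr = _best_bound(v, target, rest, cand[m], side)
                if f1_c > best[0] + 1e-15:
                    best = (f1_c, m, side, thr)
        f1_new, m, side, thr = best
        if m is None or f1_new - f1_now < tol:
            break
        lo, hi = bounds.get(m, [-np.inf, np.inf])
        adding_new = not np.isfinite(lo if side == "lower" else hi)
        if adding_new and n_bounds() >= max_constraints:
            break
        if side == "lower":
            lo = thr
        else:
            hi = thr
        bounds[m] = [lo, hi]
        if m not in order:
            order.append(m)
        f1_now = f1_new
        history.append(f1_now)

    constraints = [(m, bounds[m][0], bounds[m][1]) for m in order]
    gate = GateSpec(constraints=constraints, f1=f1_now, history=history)
    gate.importance = marker_importance(gate, X, markers, target)
    return gate


def marker_importance(
    gate: GateSpec, X, markers: Sequence[str], target
) -> pd.Series:
    """F1 drop when each gated marker's constraints are removed (no re-fit),
    sorted descending.  Markers absent from the gate score 0."""
    target = np.asarray(target, dtype=bool)
    full_f1 = gate_f1(gate, X, markers, target)
    imp = {}
    for m in markers:
        if m not in gate.markers:
            imp[m] = 0.0
            continue
        reduced = GateSpec(
            constraints=[c for c in gate.constraints if c[0] != m],
            f1=np.nan,
        )
        imp[m] = full_f1 - gate_f1(reduced, X, markers, target)
    return pd.Series(imp).sort_values(ascending=False)
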