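"""Pre-processing: logicle transformation, flow-anomaly QC, downsampling,
per-feature log-z scaling and low-count sample exclusion.

The logicle transform is the Parks-Roeder-Moore biexponential display scale:
near-linear around zero (width ``w`` decades) and logarithmic at high
intensity, with the top of scale ``t`` mapping to display value 1 (GatingML
convention).  The forward transform is the numerical inverse of the exact
biexponential, solved to 1e-8.

The QC stage is a segment-deviation filter emulating automated removal of
clogs and other acquisition anomalies: consecutive time segments whose
per-channel mean profile deviates from the run's typical profile (in robust
MAD units) are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import EventMatrix

__all__ = [
    "TransformParams",
    "LogicleTransform",
    "logicle",
    "logicle_inverse",
    "transform_events",
    "QCParams",
    "QCReport",
    "remove_anomalous_segments",
    "downsample",
    "downsample_cohort",
    "log_z_scale",
    "exclude_low_count_samples",
]


@dataclass(frozen=True)
class TransformParams:
    """Logicle parameters: ``w`` linearisation width (decades), ``t`` top of
    scale, ``m`` total decades, ``a`` additional negative decades."""

    w: float = 0.5
    t: float = 10_000.0
    m: float = 2.0
    a: float = 0.0

    def __post_init__(self):
        if not (self.t > 0 and self.m > 0):
            raise ValueError("t and m must be positive")
        if not (0 <= self.w <= self.m / 2):
            raise ValueError("w must satisfy 0 <= w <= m/2")
        if self.a < 0:
            raise ValueError("a must be non-negative")


class LogicleTransform:
    """Logicle display transform with output scaled so that x = t maps to 1.

    The inverse (display -> intensity) is the exact biexponential
    ``B(y) = p_a e^{b y} - p_c e^{-d y} + p_f``; the forward transform solves
    ``B(y) = x`` by vectorised safeguarded Newton iteration.
    """

    def __init__(self, params: TransformParams = TransformParams()):
        self.params = params
        T, W, M, A = params.t, params.w, params.m, params.a
        w = W / (M + A)
        x2 = A / (M + A)
        x1 = x2 + w
        x0 = x2 + 2 * w
        b = (M + A) * np.log(10.0)
        if w > 0:
            # d solves 2 (ln d - ln b) + w (b + d) = 0 on (0, b)
            d = brentq(lambda dd: 2 * (np.log(dd) - np.log(b)) + w * (b + dd),
                       1e-12, b, xtol=1e-14, rtol=1e-15)
        else:
            d = b
        c_a = np.exp(x0 * (b + d))
        mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
        p_a = T / ((np.exp(b) - mf_a) - c_a / np.exp(d))
        self._a, self._b = p_a, b
        self._c, self._d = c_a * p_a, d
        self._f = -mf_a * p_a
        self._x1 = x1  # display value of intensity 0

    # -- inverse: display value -> raw intensity ---------------------------
    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("non-finite input to logicle inverse")
        return self._a * np.exp(self._b * y) - self._c * np.exp(-self._d * y) + self._f

    def _slope(self, y):
        return (self._a * self._b * np.exp(self._b * y)
                + self._c * self._d * np.exp(-self._d * y))

    # -- forward: raw intensity -> display value ---------------------------
    def forward(self, x, tol: float = 1e-8, max_iter: int = 60):
        x = np.asarray(x, dtype=float)
        if not np.isfinite(x).all():
            raise ValueError("non-finite input to logicle transform")
        scalar = x.ndim == 0
        x = np.atleast_1d(x).astype(float)
        lo = np.full_like(x, -0.5)
        hi = np.full_like(x, 1.5)
        # widen brackets until B(lo) <= x <= B(hi)
        for _ in range(200):
            bad = self.inverse(lo) > x
            if not bad.any():
                break
            lo[bad] -= 0.5
        for _ in range(200):
            bad = self.inverse(hi) < x
            if not bad.any():
                break
            hi[bad] += 0.5
        y = np.clip(self._x1 + x / max(self._slope(self._x1), 1e-300), lo, hi)
        scale = np.maximum(np.abs(x), self.params.t)
        for _ in range(max_iter):
            fx = self.inverse(y) - x
            done = np.abs(fx) <= tol * scale
            if done.all():
                break
            step = fx / self._slope(y)
            y_new = y - step
            # bisect where Newton leaves the bracket
            outside = (y_new <= lo) | (y_new >= hi)
            y_new[outside] = 0.5 * (lo[outside] + hi[outside])
            below = self.inverse(y_new) < x
            lo = np.where(below, y_new, lo)
            hi = np.where(below, hi, y_new)
            y = y_new
        return float(y[0]) if scalar else y

    __call__ = forward


def logicle(x, params: TransformParams = TransformParams()):
    """Logicle-transform raw intensities (top of scale -> 1)."""
    return LogicleTransform(params).forward(x)


def logicle_inverse(y, params: TransformParams = TransformParams()):
    """Exact biexponential: display values back to raw intensities."""
    return LogicleTransform(params).inverse(y)


def transform_events(events: EventMatrix,
                     params: TransformParams = TransformParams(),
                     channels: Sequence[str] | None = None) -> EventMatrix:
    """Apply the logicle transform to all (or the given) non-time channels."""
    tr = LogicleTransform(params)
    values = events.values.copy()
    targets = set(channels) if channels is not None else set(events.marker_channels)
    for j, ch in enumerate(events.channels):
        if ch in targets and ch != events.time_channel:
            values[:, j] = tr.forward(values[:, j])
    out = events.with_values(values)
    out.metadata["transform"] = (
        f"logicle(w={params.w},t={params.t},m={params.m},a={params.a})"
    )
    return out


# ---------------------------------------------------------------------------
# Flow-anomaly QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCParams:
    """Segment-deviation QC: events are cut into consecutive time segments of
    ``segment_size``; a segment whose summed absolute channel-mean z-score
    exceeds ``median + c * MAD`` is removed."""

    segment_size: int = 200
    c: float = 5.0
    channels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.segment_size < 50:
            raise ValueError("segment_size must be >= 50")
        if self.c <= 0:
            raise ValueError("deviation threshold c must be positive")


@dataclass
class QCReport:
    removed_fraction: float
    removed_segments: list[int]
    removed_windows: list[tuple[float, float]]
    segment_scores: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": np.arange(len(self.segment_scores)),
                "score": self.segment_scores,
                "removed": np.isin(
                    np.arange(len(self.segment_scores)), self.removed_segments
                ),
            }
        )


def remove_anomalous_segments(
    events: EventMatrix, q: QCParams = QCParams()
) -> tuple[EventMatrix, QCReport]:
    """Drop time segments with anomalous mean channel profiles.

    Events must be sorted by the time channel.  Per-segment per-channel means
    are z-scored against all segments; the segment score is the sum of
    absolute z over monitored channels, thresholded at median + c * MAD
    (MAD scaled by 1.4826 for normal consistency).
    """
    n = events.n_events
    if n < q.segment_size:
        raise ValueError(
            f"{n} events is fewer than one segment of {q.segment_size}"
        )
    if events.time_channel in events.channels:
        t = events.channel(events.time_channel)
        if np.any(np.diff(t) < 0):
            raise ValueError("events must be sorted by the time channel")
    else:
        t = np.arange(n, dtype=float)

    monitored = list(q.channels) if q.channels else events.marker_channels
    cols = [events.channel_index(c) for c in monitored]
    n_seg = n // q.segment_size
    used = n_seg * q.segment_size
    seg_means = (
        events.values[:used, cols]
        .reshape(n_seg, q.segment_size, len(cols))
        .mean(axis=1)
    )
    mu = seg_means.mean(axis=0)
    sd = seg_means.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (seg_means - mu) / sd
    scores = np.abs(z).sum(axis=1)
    med = float(np.median(scores))
    mad = 1.4826 * float(np.median(np.abs(scores - med)))
    threshold = med + q.c * max(mad, 1e-12)
    bad = np.where(scores > threshold)[0]

    keep = np.ones(n, dtype=bool)
    windows = []
    for s in bad:
        i0, i1 = s * q.segment_size, (s + 1) * q.segment_size
        keep[i0:i1] = False
        windows.append((float(t[i0]), float(t[i1 - 1])))
    out = events.with_values(events.values[keep], row_mask=keep)
    report = QCReport(
        removed_fraction=float((~keep).sum()) / n,
        removed_segments=bad.tolist(),
        removed_windows=windows,
        segment_scores=scores,
        threshold=threshold,
    )
    return out, report


# ---------------------------------------------------------------------------
# Downsampling and scaling
# ---------------------------------------------------------------------------

def downsample(events: EventMatrix, n_per_sample: int, seed: int) -> EventMatrix:
    """Uniform subsample without replacement; smaller samples pass through."""
    if n_per_sample < 1:
        raise ValueError("n_per_sample must be >= 1")
    if events.n_events <= n_per_sample:
        return events
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(events.n_events, size=n_per_sample, replace=False))
    keep = np.zeros(events.n_events, dtype=bool)
    keep[idx] = True
    return events.with_values(events.values[idx], row_mask=keep)


def downsample_cohort(
    events_by_sample: Mapping[str, EventMatrix], n_per_sample: int, seed: int
) -> dict[str, EventMatrix]:
    """Downsample every sample, deriving a per-sample stream from ``seed``."""
    root = np.random.default_rng(seed)
    out = {}
    for sid in events_by_sample:
        sub_seed = int(root.integers(0, 2**31 - 1))
        out[sid] = downsample(events_by_sample[sid], n_per_sample, sub_seed)
    return out


def log_z_scale(matrix, axis: int = 1):
    """Natural log then per-feature standardisation (mean 0, sd 1).

    ``matrix`` is features x observations (``axis=1`` = observations).
    Features containing non-positive values are shifted by ``1 - min`` before
    the log; constant features map to all-zeros.
    """
    df_in = isinstance(matrix, pd.DataFrame)
    X = np.asarray(matrix, dtype=float).copy()
    if X.ndim == 1:
        X = X[None, :]
        squeeze = True
    else:
        squeeze = False
    if axis == 0:
        X = X.T
    mins = X.min(axis=1, keepdims=True)
    shift = np.where(mins <= 0, 1.0 - mins, 0.0)
    X = np.log(X + shift)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if axis == 0:
        out = out.T
    if squeeze:
        out = out[0]
    if df_in:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def exclude_low_count_samples(
    counts: Mapping[str, int], threshold: int = 100
) -> tuple[list[str], dict[str, str]]:
    """Drop samples with fewer than ``threshold`` cells of the target
    population (strict less-than); returns (retained ids, reasons for drops).
    """
    retained, reasons = [], {}
    for sid, cnt in counts.items():
        if cnt < threshold:
            reasons[sid] = (
                f"excluded: {cnt} target cells < {threshold} required"
            )
            warnings.warn(f"sample {sid} {reasons[sid]}", stacklevel=2)
        else:
            retained.append(sid)
    if not retained:
        raise ValueError(
            f"all samples fall below the {threshold}-cell threshold; "
            "nothing left to analyse"
        )
    return retained, reasons
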