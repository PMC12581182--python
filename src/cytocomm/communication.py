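"""Signed distance-correlation inference of cell-cell communication.

Across-sample dependence between a sender population's ligand MFI and a
receiver population's receptor MFI is measured with Szekely's sample
distance correlation, which detects linear and nonlinear association alike;
the sign is borrowed from the Pearson correlation of the same pair.
Significance comes from a permutation test (exact enumeration for small n,
Monte-Carlo otherwise), with Benjamini-Hochberg correction across each
screening family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .io import EventMatrix, normalize_marker
from .preprocess import log_z_scale

__all__ = [
    "median_profile",
    "distance_correlation",
    "signed_dcor",
    "SignedDcor",
    "dcor_pvalue",
    "lr_screen",
    "frequency_screen",
    "bh_adjust",
    "significant_rows",
]

EXACT_N_MAX = 7  # n! <= 5040: enumerate all permutations


# ---------------------------------------------------------------------------
# Median-intensity profiles
# ---------------------------------------------------------------------------

def median_profile(
    events_by_sample: Mapping[str, EventMatrix],
    assignments: Mapping[str, np.ndarray],
    markers: Sequence[str] | None = None,
    min_cells: int = 1,
) -> pd.DataFrame:
    """Per sample x population x marker median fluorescence intensity.

    ``assignments`` maps sample id -> per-cell population label.  Populations
    with fewer than ``min_cells`` cells in a sample are reported as missing
    entries (never silent zeros); cell counts are recorded per row.
    Returns a long table (sample_id, population, marker, mfi, n_cells).
    """
    rows = []
    for sid, em in events_by_sample.items():
        labels = np.asarray(assignments[sid])
        if labels.shape[0] != em.n_events:
            raise ValueError(f"assignments for {sid} do not cover all events")
        use = markers if markers is not None else em.marker_channels
        cols = [em.channel_index(m) for m in use]
        for pop in pd.unique(labels):
            mask = labels == pop
            cnt = int(mask.sum())
            if cnt < min_cells:
                continue
            med = np.median(em.values[np.ix_(mask, cols)], axis=0)
            for m, v in zip(use, med):
                rows.append(
                    {
                        "sample_id": sid,
                        "population": pop,
                        "marker": normalize_marker(m),
                        "mfi": float(v),
                        "n_cells": cnt,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distance correlation
# ---------------------------------------------------------------------------

def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def _centered_dist(v: np.ndarray) -> np.ndarray:
    """Double-centered absolute-difference matrix (U = V-statistic kernel)."""
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def _dcor_from_centered(A: np.ndarray, B: np.ndarray) -> float:
    dcov2 = (A * B).mean()
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


def _dcor_blocked(x: np.ndarray, y: np.ndarray, block: int) -> float:
    """Memory-light O(n^2) dcor for large n: accumulate the double-centered
    products in row blocks instead of materialising n x n matrices."""
    n = x.size
    rx = np.empty(n)
    ry = np.empty(n)
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        rx[i0:i1] = np.abs(x[i0:i1, None] - x[None, :]).mean(axis=1)
        ry[i0:i1] = np.abs(y[i0:i1, None] - y[None, :]).mean(axis=1)
    gx, gy = rx.mean(), ry.mean()
    s_ab = s_aa = s_bb = 0.0
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        A = np.abs(x[i0:i1, None] - x[None, :]) - rx[i0:i1, None] - rx[None, :] + gx
        B = np.abs(y[i0:i1, None] - y[None, :]) - ry[i0:i1, None] - ry[None, :] + gy
        s_ab += (A * B).sum()
        s_aa += (A * A).sum()
        s_bb += (B * B).sum()
    if s_aa <= 0 or s_bb <= 0:
        return 0.0
    return float(np.sqrt(max(s_ab, 0.0) / np.sqrt(s_aa * s_bb)))


def distance_correlation(x, y, block_threshold: int = 3000) -> float:
    """Szekely's sample distance correlation in [0, 1].

    Pairwise absolute-difference matrices are double-centered (row mean,
    column mean, grand mean) and the statistic is
    ``dCov / sqrt(dVar_x * dVar_y)``; 0 when either distance variance
    vanishes.  Above ``block_threshold`` points the same statistic is
    accumulated in row blocks to bound memory.
    """
    x, y = _check_pair(x, y)
    if x.size > block_threshold:
        return _dcor_blocked(x, y, block_threshold)
    return _dcor_from_centered(_centered_dist(x), _centered_dist(y))


@dataclass(frozen=True)
class SignedDcor:
    value: float
    dcor: float
    pearson: float
    zero_sign: bool  # Pearson was exactly 0; sign defaulted to +1


def signed_dcor(x, y) -> SignedDcor:
    """Distance correlation with the sign of the Pearson correlation.

    Pearson exactly 0 (or undefined on constant input) defaults the sign to
    +1 with ``zero_sign=True`` recorded.
    """
    x, y = _check_pair(x, y)
    d = distance_correlation(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(pearsonr(x, y).statistic)
    # a mathematically-zero Pearson (e.g. symmetric quadratic) comes out as
    # rounding noise; snap it so the zero-sign rule fires
    if abs(r) <= 1e-12:
        r = 0.0
    zero = r == 0.0
    sign = 1.0 if zero else math.copysign(1.0, r)
    return SignedDcor(value=sign * d, dcor=d, pearson=r, zero_sign=zero)


def dcor_pvalue(
    x,
    y,
    method: str = "auto",
    n_perm: int = 9_999,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the distance correlation.

    ``method='exact'`` enumerates all n! permutations of y (identity
    included): p = #{dcor_perm >= dcor_obs} / n!.  ``method='monte-carlo'``
    draws ``n_perm`` random permutations: p = (1 + #{>=}) / (1 + n_perm).
    ``'auto'`` picks exact for n <= 7.
    """
    x, y = _check_pair(x, y)
    n = x.size
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "monte-carlo"
    if method not in ("exact", "monte-carlo"):
        raise ValueError(f"invalid method {method!r}")

    A = _centered_dist(x)
    B = _centered_dist(y)
    obs = _dcor_from_centered(A, B)

    if method == "exact":
        count = 0
        total = 0
        for perm in permutations(range(n)):
            idx = np.asarray(perm)
            # permuting y permutes B's rows and columns simultaneously
            d = _dcor_from_centered(A, B[np.ix_(idx, idx)])
            count += d >= obs - 1e-12
            total += 1
        return count / total

    rng = np.random.default_rng(seed)
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        return 1.0
    count = 0
    chunk = max(1, min(n_perm, int(2e6 / (n * n)) + 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(m)])
        # permuting y permutes B's rows and columns simultaneously
        Bp = B[perms[:, :, None], perms[:, None, :]]  # (m, n, n)
        dcov2 = (A[None, :, :] * Bp).mean(axis=(1, 2))
        d_perm = np.sqrt(np.maximum(dcov2, 0.0) / np.sqrt(dvx * dvy))
        count += int((d_perm >= obs - 1e-12).sum())
        done += m
    return (1 + count) / (1 + n_perm)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    monotone, adjusted >= raw elementwise)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_rows(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rows retained by the raw-p screening rule p < alpha."""
    return table[table["p"] < alpha].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def _profile_vector(
    profiles: pd.DataFrame, population: str, marker: str
) -> pd.Series:
    sub = profiles[
        (profiles["population"] == population)
        & (profiles["marker"] == marker)
    ]
    return sub.set_index("sample_id")["mfi"]


def _screen_pair(x: pd.Series, y: pd.Series, min_n: int, scale: bool,
                 n_perm: int, seed, perm_method: str):
    common = x.index.intersection(y.index)
    if len(common) < min_n:
        return None
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    if scale:
        xv = log_z_scale(xv)
        yv = log_z_scale(yv)
    sd = signed_dcor(xv, yv)
    n = len(common)
    method = perm_method
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "monte-carlo"
    p = dcor_pvalue(xv, yv, method=method, n_perm=n_perm, seed=seed)
    return n, sd, p, method


def lr_screen(
    profiles: pd.DataFrame,
    catalogue: pd.DataFrame,
    sender_populations: Sequence[str],
    receiver_populations: Sequence[str],
    alpha: float = 0.05,
    min_n: int = 4,
    scale: bool = True,
    n_perm: int = 9_999,
    seed: int | None = None,
    perm_method: str = "auto",
) -> pd.DataFrame:
    """Screen every catalogued ligand-receptor axis between the populations
    of interest and the TME populations.

    For each catalogue pair, both orientations present on the panels are
    tested: ligand on the sender vs. receptor on the receiver, and the
    reverse.  MFI vectors are log-transformed and z-normalised across
    samples before the signed distance correlation; pairs lacking a marker
    or with fewer than ``min_n`` complete samples are skipped (and logged by
    warning).  The full table is returned with BH-adjusted p-values and a
    ``significant`` flag for the raw-p < alpha screening rule.
    """
    rows = []
    rng = np.random.default_rng(seed)
    have = {
        (pop, mk)
        for pop, mk in profiles.groupby(["population", "marker"]).groups
    }
    for _, cat in catalogue.iterrows():
        lig = normalize_marker(cat["ligand"])
        rec = normalize_marker(cat["receptor"])
        for poi in sender_populations:
            for tme in receiver_populations:
                if poi == tme:
                    continue
                orientations = [
                    # receptor on the population of interest, ligand on TME
                    (tme, lig, poi, rec),
                    # ligand on the population of interest, receptor on TME
                    (poi, lig, tme, rec),
                ]
                for sender, lmk, receiver, rmk in orientations:
                    if (sender, lmk) not in have or (receiver, rmk) not in have:
                        warnings.warn(
                            f"skipping {lmk}->{rmk} for {sender}->{receiver}: "
                            "marker absent from panel profiles",
                            stacklevel=2,
                        )
                        continue
                    res = _screen_pair(
                        _profile_vector(profiles, sender, lmk),
                        _profile_vector(profiles, receiver, rmk),
                        min_n, scale, n_perm,
                        int(rng.integers(0, 2**31 - 1)),
                        perm_method,
                    )
                    if res is None:
                        continue
                    n, sd, p, method = res
                    rows.append(
                        {
                            "sender": sender,
                            "ligand": lmk,
                            "receiver": receiver,
                            "receptor": rmk,
                            "n": n,
                            "dcor": sd.dcor,
                            "pearson": sd.pearson,
                            "signed": sd.value,
                            "zero_sign": sd.zero_sign,
                            "p": p,
                            "method": method,
                        }
                    )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        raise ValueError("no complete ligand-receptor pairs to screen")
    table = table.drop_duplicates(
        subset=["sender", "ligand", "receiver", "receptor"]
    ).reset_index(drop=True)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p"] < alpha
    return table.sort_values(
        ["p", "dcor"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


def frequency_screen(
    freq: pd.DataFrame,
    populations_of_interest: Sequence,
    tme_populations: Sequence,
    alpha: float = 0.05,
    min_n: int = 4,
    scale: bool = True,
    n_perm: int = 9_999,
    seed: int | None = None,
    perm_method: str = "auto",
) -> pd.DataFrame:
    """Signed distance correlation between population frequencies across
    samples (samples x populations table); self-pairings are excluded.
    Same scaling, permutation and BH conventions as :func:`lr_screen`."""
    rows = []
    rng = np.random.default_rng(seed)
    for poi in populations_of_interest:
        for tme in tme_populations:
            if poi == tme:
                continue
            x = freq[poi].dropna()
            y = freq[tme].dropna()
            res = _screen_pair(
                x, y, min_n, scale, n_perm,
                int(rng.integers(0, 2**31 - 1)), perm_method,
            )
            if res is None:
                continue
            n, sd, p, method = res
            rows.append(
                {
                    "population_a": poi,
                    "population_b": tme,
                    "n": n,
                    "dcor": sd.dcor,
                    "pearson": sd.pearson,
                    "signed": sd.value,
                    "zero_sign": sd.zero_sign,
                    "p": p,
                    "method": method,
                }
            )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        raise ValueError("no complete frequency pairs to screen")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p"] < alpha
    return table.sort_values(
        ["p", "dcor"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
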