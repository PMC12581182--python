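"""Group-level statistics and report assembly: PCA of population
frequencies, exact/asymptotic Mann-Whitney, Kruskal-Wallis with Dunn's post
hoc, per-population comparison tables with BH correction and significance
tiers, and a CSV report bundle with a manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu, norm, rankdata

from .communication import bh_adjust

__all__ = [
    "PCAResult",
    "pca_frequencies",
    "mann_whitney",
    "kruskal_wallis_dunn",
    "KWDunnResult",
    "compare_populations",
    "significance_tier",
    "build_report",
]

EXACT_MW_MAX_N = 12


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # populations x components (orthonormal)
    explained_variance_ratio: np.ndarray
    top_contributors: pd.DataFrame
    dropped: list[str]


def pca_frequencies(freq: pd.DataFrame, n_top: int = 5) -> PCAResult:
    """PCA of a samples x populations frequency table.

    Each population is centred and scaled to unit variance before SVD.
    Missing values are refused (no silent imputation); constant populations
    are dropped with a warning.  Contributors are ranked by squared loading
    on the first two components.
    """
    if freq.isna().any().any():
        raise ValueError(
            "frequency table contains missing values; PCA refuses to impute"
        )
    if len(freq) < 3:
        raise ValueError("need at least 3 samples for PCA")
    sd = freq.std(axis=0, ddof=1)
    dropped = sd[sd == 0].index.tolist()
    if dropped:
        warnings.warn(f"dropping constant populations: {dropped}", stacklevel=2)
    X = freq.drop(columns=dropped)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    ncomp = S.size
    comps = [f"PC{i + 1}" for i in range(ncomp)]
    scores = pd.DataFrame(U * S, index=X.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comps)
    evr = S**2 / (S**2).sum()
    contrib = (
        (loadings[comps[: min(2, ncomp)]] ** 2)
        .sum(axis=1)
        .sort_values(ascending=False)
        .head(n_top)
    )
    top = pd.DataFrame(
        {"population": contrib.index, "squared_loading_pc12": contrib.to_numpy()}
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        top_contributors=top,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of the first group (ties count half)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U of the first group, p).

    Combined n <= 12: exact two-tailed p by full enumeration of all
    group-label assignments, p = 2 * min(P(U <= u), P(U >= u)) capped at 1
    (ties handled by the enumeration itself).  Larger samples use the
    normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _mw_u(a, b)
    n = a.size + b.size
    if n <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        us = np.array(
            [
                _mw_u(pooled[list(idx)],
                      pooled[[i for i in range(n) if i not in idx]])
                for idx in combinations(range(n), a.size)
            ]
        )
        lo = float((us <= u_obs + 1e-12).mean())
        hi = float((us >= u_obs - 1e-12).mean())
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        p = float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return u_obs, p


@dataclass
class KWDunnResult:
    h: float
    p: float
    dunn: pd.DataFrame  # group_a, group_b, z, p, p_adj


def kruskal_wallis_dunn(groups: dict[str, np.ndarray]) -> KWDunnResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post hoc.

    Dunn's pairwise z uses pooled mid-ranks with the tie correction
    ``sum(t^3 - t) / (12 (N - 1))``; two-sided normal p-values are BH
    adjusted across the pairwise family.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("need at least 3 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size < 2:
            warnings.warn(f"group {g} has fewer than 2 values", stacklevel=2)
    if all(np.all(arr == arrays[0][0]) for arr in arrays):
        h, p_kw = 0.0, 1.0
    else:
        h, p_kw = kruskal(*arrays)
    pooled = np.concatenate(arrays)
    ranks = rankdata(pooled)
    N = pooled.size
    sizes = [arr.size for arr in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean()
        for i, g in enumerate(names)
    }
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for ga, gb in combinations(names, 2):
        na, nb = groups[ga].__len__(), groups[gb].__len__()
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[ga] - mean_ranks[gb]) / se if se > 0 else 0.0
        p = 2 * norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p": max(p, 1e-300)})
    dunn = pd.DataFrame(rows)
    dunn["p_adj"] = bh_adjust(dunn["p"].to_numpy())
    return KWDunnResult(h=float(h), p=float(p_kw), dunn=dunn)


def significance_tier(p_adj: float) -> str:
    """ns / * / ** / *** tiers matching the usual figure-legend cutoffs."""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def compare_populations(
    freq: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    design: str = "two-group",
) -> pd.DataFrame:
    """Per-population group comparison of a samples x populations table.

    ``design='two-group'`` runs Mann-Whitney per population;
    ``'multi-group'`` runs Kruskal-Wallis (Dunn pairwise p available via
    :func:`kruskal_wallis_dunn`).  BH correction is applied across
    populations; mean +/- sem and median/IQR summaries are both reported.
    """
    if design not in ("two-group", "multi-group"):
        raise ValueError(f"unknown design {design!r}")
    sheet = sample_sheet.set_index("sample_id")
    groups = sheet.loc[freq.index, "group"]
    names = list(pd.unique(groups))
    if design == "two-group" and len(names) != 2:
        raise ValueError(f"two-group design needs 2 groups, got {names}")
    if design == "multi-group" and len(names) < 3:
        raise ValueError("multi-group design needs >= 3 groups")
    rows = []
    for pop in freq.columns:
        vals = {g: freq.loc[groups == g, pop].dropna().to_numpy() for g in names}
        summary = {}
        for g in names:
            v = vals[g]
            summary[f"mean_{g}"] = float(v.mean()) if v.size else np.nan
            summary[f"sem_{g}"] = (
                float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
            )
            summary[f"median_{g}"] = float(np.median(v)) if v.size else np.nan
            summary[f"iqr_{g}"] = (
                float(np.percentile(v, 75) - np.percentile(v, 25))
                if v.size
                else np.nan
            )
        if design == "two-group":
            stat, p = mann_whitney(vals[names[0]], vals[names[1]])
            test = "mann-whitney"
        else:
            res = kruskal_wallis_dunn(vals)
            stat, p = res.h, res.p
            test = "kruskal-wallis"
        rows.append(
            {"population": pop, "test": test, "statistic": stat, "p": p,
             **summary}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["tier"] = out["p_adj"].map(significance_tier)
    return out


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def build_report(
    tables: dict[str, pd.DataFrame],
    outdir,
    params: dict | None = None,
    seed: int | None = None,
    expected_stages: list[str] | None = None,
) -> dict:
    """Write every table as CSV plus a manifest and run log.

    ``expected_stages`` not present in ``tables`` are marked absent in the
    manifest rather than failing.  Returns the manifest dict.
    """
    from .io import TOOL_VERSION

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": TOOL_VERSION,
        "seed": seed,
        "params": params or {},
        "tables": {},
    }
    for name, df in sorted(tables.items()):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=isinstance(df.index, pd.MultiIndex)
                  or df.index.name is not None)
        manifest["tables"][name] = {
            "file": path.name,
            "rows": int(len(df)),
            "present": True,
        }
    for stage in expected_stages or []:
        if stage not in manifest["tables"]:
            manifest["tables"][stage] = {"file": None, "rows": 0, "present": False}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"tool: {TOOL_VERSION}\nseed: {seed}\n")
        for k, v in (params or {}).items():
            fh.write(f"{k}: {v}\n")
        for name in sorted(manifest["tables"]):
            entry = manifest["tables"][name]
            fh.write(f"table {name}: {'ok' if entry['present'] else 'ABSENT'}\n")
    return manifest
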