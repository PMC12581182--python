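"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately written as plain-Python
brute force (explicit loops, enumeration, per-point root finding) so they
share no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import brentq

import cytocomm as cc


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def dcor_bruteforce(x, y) -> float:
    """Explicit-loop O(n^2) double-centering distance correlation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        rm = [sum(r) / n for r in m]
        cm = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        gm = sum(sum(r) for r in m) / n**2
        return [
            [m[i][j] - rm[i] - cm[j] + gm for j in range(n)] for i in range(n)
        ]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(v * v for r in A for v in r) / n**2
    dvy = sum(v * v for r in B for v in r) / n**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return (max(dcov2, 0.0) / (dvx * dvy) ** 0.5) ** 0.5


def logicle_bruteforce(value: float, w=0.5, t=10_000.0, m=2.0, a=0.0) -> float:
    """Independent logicle: biexponential constants derived step by step from
    the reference parameterisation, inverted per point with brentq."""
    wn = w / (m + a)
    x2 = a / (m + a)
    x1 = x2 + wn
    x0 = x2 + 2 * wn
    b = (m + a) * np.log(10.0)
    if wn > 0:
        d = brentq(
            lambda dd: 2 * (np.log(dd) - np.log(b)) + wn * (b + dd), 1e-12, b,
            xtol=1e-15,
        )
    else:
        d = b
    c_a = np.exp(x0 * (b + d))
    mf_a = np.exp(b * x1) - c_a / np.exp(d * x1)
    amp = t / ((np.exp(b) - mf_a) - c_a / np.exp(d))

    def biexp(yy):
        return amp * (np.exp(b * yy) - c_a * np.exp(-d * yy) - mf_a)

    return brentq(lambda yy: biexp(yy) - value, -10.0, 10.0, xtol=1e-12)


def mann_whitney_enumeration(a, b) -> float:
    """Two-tailed exact Mann-Whitney p by brute enumeration of label
    assignments, U computed by direct pairwise comparison counting."""
    a, b = list(a), list(b)
    pooled = a + b
    n, na = len(pooled), len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for va in group_a:
            for vb in group_b:
                if va > vb:
                    u += 1.0
                elif va == vb:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(n), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_stat(ga, gb))
    lo = sum(u <= u_obs + 1e-12 for u in us) / len(us)
    hi = sum(u >= u_obs - 1e-12 for u in us) / len(us)
    return min(1.0, 2.0 * min(lo, hi))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_817)


@pytest.fixture(scope="session")
def blob_data():
    """Three well-separated Gaussian blobs in 3-D (sd 0.3, centres 5 apart)."""
    r = np.random.default_rng(7)
    centers = np.array([[0, 0, 0], [5, 5, 0], [0, 5, 5.0]])
    X = np.vstack([c + 0.3 * r.standard_normal((2000, 3)) for c in centers])
    labels = np.repeat([0, 1, 2], 2000)
    return X, labels, centers


@pytest.fixture(scope="session")
def small_cohort():
    """Default study-shaped cohort at reduced size (shared, read-only)."""
    spec = cc.default_cohort_spec(seed=11, cells_per_sample=1200)
    return cc.simulate_cohort(spec)
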