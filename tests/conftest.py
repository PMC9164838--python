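"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by the slowest, most
literal route (triple loops, textbook formulas) so they stay independent of
the vectorised implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import dmrnetwork as dn


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def pcc_textbook(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation by the literal sum formula."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def tom_triple_loop(a: np.ndarray) -> np.ndarray:
    """Topological overlap by the definition, one entry at a time."""
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a0[i, u] * a0[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + a0[i, j]) / (min(k[i], k[j]) + 1.0 - a0[i, j])
    return out


def dmr_avg_nested_loops(tom: np.ndarray, probe_ids, dmrs) -> np.ndarray:
    """Cross-block average TOM by explicit nested loops over probe pairs."""
    idx = {p: i for i, p in enumerate(probe_ids)}
    n = len(dmrs.dmrs)
    out = np.eye(n)
    for i, d1 in enumerate(dmrs):
        for j, d2 in enumerate(dmrs):
            if i == j:
                continue
            vals = [tom[idx[p], idx[q]] for p in d1.probe_ids for q in d2.probe_ids]
            out[i, j] = sum(vals) / len(vals)
    return out


def hotelling_two_sample_oracle(x1: np.ndarray, x2: np.ndarray):
    """Step-by-step two-sample T^2: means, pooled covariance, inverse."""
    from scipy.stats import f as fdist

    n1, n2 = x1.shape[0], x2.shape[0]
    p = x1.shape[1]
    d = x1.mean(axis=0) - x2.mean(axis=0)
    s1 = np.cov(x1, rowvar=False, ddof=1)
    s2 = np.cov(x2, rowvar=False, ddof=1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    sp = np.atleast_2d(sp)
    if p == 2:  # explicit 2x2 inverse
        det = sp[0, 0] * sp[1, 1] - sp[0, 1] * sp[1, 0]
        inv = np.array([[sp[1, 1], -sp[0, 1]], [-sp[1, 0], sp[0, 0]]]) / det
    else:
        inv = np.linalg.inv(sp)
    t2 = (n1 * n2 / (n1 + n2)) * d @ inv @ d
    f = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2)) * t2
    pval = fdist.sf(f, p, n1 + n2 - p - 1)
    return t2, f, pval


def hotelling_paired_oracle(diffs: np.ndarray):
    from scipy.stats import f as fdist

    n, p = diffs.shape
    dbar = diffs.mean(axis=0)
    s = np.cov(diffs, rowvar=False, ddof=1)
    t2 = n * dbar @ np.linalg.inv(np.atleast_2d(s)) @ dbar
    f = (n - p) / (p * (n - 1)) * t2
    return t2, f, fdist.sf(f, p, n - p)


def random_adjacency(rng: np.random.Generator, n: int) -> dn.AdjacencyMatrix:
    m = rng.random((n, n))
    a = (m + m.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return dn.AdjacencyMatrix([f"p{i}" for i in range(n)], a, beta=1.0)


# ---------------------------------------------------------------------------
# Dataset fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny():
    return dn.make_fixture("tiny")


@pytest.fixture(scope="session")
def blocks():
    return dn.make_fixture("blocks")


@pytest.fixture(scope="session")
def blocks_tom(blocks):
    matrix, dmrs, _, _ = blocks
    corr = dn.compute_correlation(matrix)
    beta, _ = dn.select_soft_threshold(corr, dn.NetworkParams())
    return dn.compute_tom(dn.adjacency(corr, beta))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
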