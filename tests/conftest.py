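"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive — exhaustive enumeration, power
iteration, textbook formulas — and never call the code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import eigenalign as ea


# ---------------------------------------------------------------- oracles


def brute_triples(adj: np.ndarray) -> tuple[int, int]:
    """Clustered/spanning triple counts by enumerating every (centre, pair)."""
    adj = (np.asarray(adj) != 0).astype(int)
    n = adj.shape[0]
    clustered = spanning = 0
    for c in range(n):
        neigh = [j for j in range(n) if adj[c, j]]
        for a, b in itertools.combinations(neigh, 2):
            if adj[a, b]:
                clustered += 1
            else:
                spanning += 1
    return clustered, spanning


def brute_cst(weights: np.ndarray):
    """Exhaustive CST scan with the enumeration counter.

    Same selection rule as the library states — minimal normalized
    imbalance over candidates up to the first clustered-to-spanning
    majority crossing, smallest cutoff on ties — but computed with an
    independent triple counter and an independent loop.
    """
    n = weights.shape[0]
    vals = sorted({weights[i, j] for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0})
    best = None
    seen_majority = False
    for t in vals:
        clu, spa = brute_triples(weights >= t)
        total = clu + spa
        if total == 0:
            continue
        obj = abs(clu - spa) / total
        if best is None or obj < best[0]:
            best = (obj, t, clu, spa)
        if clu > spa:
            seen_majority = True
        elif seen_majority:
            break
    return best  # (objective, threshold, clustered, spanning) or None


def oracle_angles(weights: np.ndarray, k: int = 3, cdi_scale: bool = False) -> np.ndarray:
    """Angles via a from-scratch eigendecomposition + arccos loop."""
    evals, evecs = np.linalg.eigh(np.asarray(weights, dtype=float))
    mag = np.abs(evals)
    scale = max(mag.max(), 1.0)
    keys = [(-round(m / scale, 12), -v, i) for i, (m, v) in enumerate(zip(mag, evals))]
    order = [i for _, _, i in sorted((k_[0], k_[1], k_[2]) for k_ in keys)]
    order = sorted(range(len(evals)), key=lambda i: (-round(mag[i] / scale, 12), -evals[i], i))
    V = evecs[:, order[:k]].copy()
    for j in range(k):
        col = V[:, j]
        if col[int(np.argmax(np.abs(col)))] < 0:
            V[:, j] = -col
    if cdi_scale:
        V[:, 0] *= np.abs(V[:, 1:]).max() / V[:, 0].max()
    n = V.shape[0]
    theta = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ri, rj = V[i], V[j]
            ni, nj = math.sqrt(ri @ ri), math.sqrt(rj @ rj)
            if ni == 0 or nj == 0:
                raise ValueError("oracle hit a zero position")
            theta[i, j] = math.acos(max(-1.0, min(1.0, float(ri @ rj) / (ni * nj))))
    return theta


def welch_oracle(a, b) -> tuple[float, float, float]:
    """Textbook Welch statistic, Welch-Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p


def random_weighted_matrix(rng: np.random.Generator, n: int) -> ea.ConnectivityMatrix:
    """Random symmetric weighted matrix with some zero and negative entries."""
    w = rng.uniform(-0.2, 1.0, (n, n))
    w[rng.random((n, n)) < 0.3] = 0.0
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ea.ConnectivityMatrix("rand", w)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def p3_matrix() -> ea.ConnectivityMatrix:
    """Path graph on 3 nodes, unit weights."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return ea.ConnectivityMatrix("p3", w)


@pytest.fixture(scope="session")
def weighted4_matrix() -> ea.ConnectivityMatrix:
    """The 4-node weighted reference graph used across modules."""
    w = np.array(
        [
            [0.0, 0.8, 0.3, 0.0],
            [0.8, 0.0, 0.5, 0.3],
            [0.3, 0.5, 0.0, 0.9],
            [0.0, 0.3, 0.9, 0.0],
        ]
    )
    return ea.ConnectivityMatrix("w4", w)


@pytest.fixture(scope="session")
def study_cohorts() -> tuple[ea.SubjectGroup, ea.SubjectGroup]:
    """One healthy and one degraded bilateral cohort (fixed seeds)."""
    healthy = ea.generate_cohort(ea.synthetic.bilateral_study_spec(0.0, seed=11))
    degraded = ea.generate_cohort(ea.synthetic.bilateral_study_spec(0.8, seed=22))
    return healthy, degraded


@pytest.fixture(scope="session")
def study_results(study_cohorts):
    """Pipeline outputs for both study cohorts under default config."""
    cfg = ea.PipelineConfig()
    healthy, degraded = study_cohorts
    return ea.run_group(healthy, cfg), ea.run_group(degraded, cfg)
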