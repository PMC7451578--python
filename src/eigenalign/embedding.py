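"""Spectral embedding: dominant eigenpairs, scaling, and eigenvector centrality.

Nodes are embedded in the Euclidean space spanned by the k most dominant
eigenvectors of the (thresholded, symmetric) connectivity matrix —
"dominant" meaning largest eigenvalue magnitude. Node i's position vector
is row i of the n-by-k eigenvector block. Two scaling conventions:

* ``unit``: each eigenvector at unit 2-norm, untouched.
* ``cdi``: the first eigenvector is stretched so its largest entry equals
  the largest absolute entry across the remaining k-1 eigenvectors (times
  an optional multiplier), tying the frame's first axis to global rather
  than local influence. This is the frame used for community detection
  and, by default, for alignment angles.

Eigenvector centrality (EC) is the unit-norm, sign-fixed dominant
eigenvector itself — non-negative on a connected non-negative matrix by
Perron-Frobenius — and is independent of the scaling convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import connected_components

from .cst import ThresholdedMatrix

__all__ = [
    "EmbeddingSpace",
    "PositionSet",
    "DegenerateSpectrumError",
    "dominant_eigenpairs",
    "scale_embedding",
    "eigenvector_centrality",
    "position_vectors",
]

#: zero-length position vectors are nudged by this much on the first axis
ZERO_REPAIR = 1e-12

#: |lambda_k| - |lambda_{k+1}| gaps below this flag a basis-dependent embedding
DEGENERACY_TOL = 1e-10


class DegenerateSpectrumError(ValueError):
    """The dominant eigenvector is identically zero (empty matrix)."""


@dataclass(frozen=True)
class EmbeddingSpace:
    """k dominant eigenpairs of a symmetric matrix plus scaling state.

    ``vectors[:, j]`` is the eigenvector of ``eigenvalues[j]``; columns are
    ordered by descending |eigenvalue| and unit-norm before scaling. The
    sign convention makes each column's largest-magnitude entry positive,
    so the first column is the non-negative Perron vector whenever the
    input is connected and non-negative.
    """

    eigenvalues: np.ndarray  # (k,)
    vectors: np.ndarray  # (n, k)
    scaling_mode: str = "unit"
    scale_multiplier: float = 1.0
    disconnected: bool = False
    degenerate: bool = False

    @property
    def k(self) -> int:
        return int(self.eigenvalues.shape[0])

    @property
    def n(self) -> int:
        return int(self.vectors.shape[0])


@dataclass(frozen=True)
class PositionSet:
    """Per-node coordinates in the scaled eigenvector frame.

    ``positions[i]`` is node i's k-vector; nodes with no connections have
    an exact-zero row repaired to ``(1e-12, 0, ..., 0)`` and are flagged.
    """

    positions: np.ndarray  # (n, k)
    isolated: np.ndarray  # (n,) bool

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    @property
    def k(self) -> int:
        return int(self.positions.shape[1])


def _as_symmetric_array(matrix) -> np.ndarray:
    w = matrix.weights if hasattr(matrix, "weights") else np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrix must be square")
    if np.abs(w - w.T).max(initial=0.0) > 1e-10:
        raise ValueError("matrix must be symmetric")
    return np.asarray(w, dtype=float)


def dominant_eigenpairs(matrix: ThresholdedMatrix | np.ndarray, k: int = 3) -> EmbeddingSpace:
    """Full symmetric eigendecomposition, keeping the k most dominant pairs.

    Ordering is by descending |lambda|; ties break toward the larger
    algebraic eigenvalue, then the smaller original index, so results are
    deterministic. Each kept column is sign-fixed (largest-|entry|
    positive). A disconnected topology sets ``disconnected``; a
    near-degenerate gap between |lambda_k| and |lambda_{k+1}| sets
    ``degenerate`` (the embedding is then basis-dependent).
    """
    w = _as_symmetric_array(matrix)
    n = w.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    evals, evecs = np.linalg.eigh(w)
    idx = np.arange(n)
    # |lambda| compared with a relative tolerance: bipartite-like spectra
    # have +lambda/-lambda pairs equal only up to float error, and the
    # positive (Perron) member must sort first deterministically
    mag = np.abs(evals)
    scale = max(mag.max(), 1.0)
    mag_key = np.round(mag / scale, 12)
    order = np.lexsort((idx, -evals, -mag_key))
    evals, evecs = evals[order], evecs[:, order]
    for j in range(n):
        col = evecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, j] = -col
    degenerate = bool(k < n and abs(abs(evals[k - 1]) - abs(evals[k])) < DEGENERACY_TOL)
    n_comp, _ = connected_components((w != 0).astype(np.int8), directed=False)
    return EmbeddingSpace(
        eigenvalues=evals[:k].copy(),
        vectors=evecs[:, :k].copy(),
        scaling_mode="unit",
        disconnected=bool(n_comp > 1),
        degenerate=degenerate,
    )


def scale_embedding(
    space: EmbeddingSpace, mode: str = "cdi", multiplier: float = 1.0
) -> EmbeddingSpace:
    """Apply a scaling convention to an embedding.

    ``unit`` returns the space unchanged. ``cdi`` multiplies the first
    eigenvector by ``multiplier * max|v_2..k| / max(v_1)``, equalizing the
    largest first-eigenvector entry with the largest entry (in absolute
    value) of the other frame axes; ``multiplier`` != 1 supports
    sensitivity analyses around that convention.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if mode == "unit":
        return replace(space, scaling_mode="unit", scale_multiplier=1.0)
    if mode != "cdi":
        raise ValueError(f"unknown scaling mode {mode!r}")
    if space.k < 2:
        raise ValueError("cdi scaling needs k >= 2")
    v = space.vectors.copy()
    peak1 = v[:, 0].max()
    if peak1 <= 0:
        raise DegenerateSpectrumError("first eigenvector has no positive entry to scale")
    s = multiplier * np.abs(v[:, 1:]).max() / peak1
    v[:, 0] *= s
    return replace(space, vectors=v, scaling_mode="cdi", scale_multiplier=float(multiplier))


def eigenvector_centrality(space: EmbeddingSpace) -> np.ndarray:
    """Eigenvector centrality: the unit-norm, sign-fixed dominant eigenvector.

    Computed from the unscaled column, so EC does not depend on the
    scaling convention. On a connected non-negative matrix this is the
    Perron vector; entries more negative than -1e-10 indicate an internal
    inconsistency and raise.
    """
    # any positive rescaling of v1 cancels in the normalization below
    v1 = space.vectors[:, 0]
    nrm = np.linalg.norm(v1)
    if nrm == 0:
        raise DegenerateSpectrumError("dominant eigenvector is zero")
    v1 = v1 / nrm
    if not space.disconnected and v1.min() < -1e-10:
        raise RuntimeError(
            f"dominant eigenvector of a connected matrix has negative entry {v1.min():.3g}"
        )
    return np.clip(v1, 0.0, None) if not space.disconnected else v1


def position_vectors(space: EmbeddingSpace) -> PositionSet:
    """Node coordinates in the (scaled) eigenvector frame.

    Exact-zero rows — nodes with no surviving connections — are given the
    small value 1e-12 on the first coordinate so every node has a
    direction, and flagged as isolated.
    """
    pos = space.vectors.copy()
    # tolerance catches denormal eigh noise (~1e-300) on degree-0 nodes,
    # whose squared norm underflows to an exact 0 downstream
    isolated = np.linalg.norm(pos, axis=1) < 1e-100
    pos[isolated] = 0.0
    pos[isolated, 0] = ZERO_REPAIR
    return PositionSet(positions=pos, isolated=isolated)
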