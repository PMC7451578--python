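"""Eigenvector alignment: angles between node position vectors.

The alignment between two nodes is the angle

    theta = arccos( r . s / (|r| |s|) )        theta in [0, pi]

between their position vectors r, s in the dominant-eigenvector frame.
Small angles mean the two nodes occupy similar positions relative to the
network's principal modes of information flow — a holistic notion of
functional relationship that responds to every connectivity change in the
network, not just the direct edge between the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import PositionSet

__all__ = [
    "AlignmentMatrix",
    "GroupAlignmentSummary",
    "alignment_angle",
    "alignment_matrix",
    "group_alignment_summary",
]


@dataclass(frozen=True)
class AlignmentMatrix:
    """All-pairs alignment angles (radians) for one subject."""

    subject_id: str
    angles: np.ndarray  # (n, n), symmetric, zero diagonal, values in [0, pi]

    @property
    def n(self) -> int:
        return int(self.angles.shape[0])


@dataclass(frozen=True)
class GroupAlignmentSummary:
    """Element-wise mean/SD of subject angle matrices plus per-node consistency.

    ``consistency[i]`` is the standard deviation over j != i of the mean
    angle matrix row i: nodes with consistently tight (or consistently
    loose) alignments across partners have high sigma, while a node whose
    mean alignments are all similar — no partner stands out — has low
    sigma and will rarely show significant alignment change.
    """

    mean_angles: np.ndarray
    sd_angles: np.ndarray
    consistency: np.ndarray
    n_subjects: int


def alignment_angle(r: np.ndarray, s: np.ndarray) -> float:
    """Angle in radians between two position vectors.

    The cosine is clamped to [-1, 1] before arccos: floating-point dot
    products of parallel vectors can overshoot by ~1e-16 and would
    otherwise yield NaN.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError(f"position vectors must share one length, got {r.shape} vs {s.shape}")
    denom = np.linalg.norm(r) * np.linalg.norm(s)
    if denom == 0:
        raise ValueError("zero-length position vector (zero-repair missing upstream)")
    return float(np.arccos(np.clip(r @ s / denom, -1.0, 1.0)))


def alignment_matrix(positions: PositionSet, subject_id: str = "") -> AlignmentMatrix:
    """All-pairs alignment angles from a node embedding."""
    p = positions.positions
    norms = np.linalg.norm(p, axis=1)
    cos = (p @ p.T) / np.outer(norms, norms)
    theta = np.arccos(np.clip(cos, -1.0, 1.0))
    theta = (theta + theta.T) / 2.0
    np.fill_diagonal(theta, 0.0)
    return AlignmentMatrix(subject_id=subject_id, angles=theta)


def group_alignment_summary(matrices: list[AlignmentMatrix]) -> GroupAlignmentSummary:
    """Aggregate subject angle matrices into group mean, SD and consistency.

    Means are plain arithmetic means (angles live in [0, pi]; no circular
    statistics needed). SDs are sample SDs (ddof=1) when there are at
    least two subjects, zero otherwise. Consistency excludes the diagonal
    so the trivial self-alignment of 0 does not deflate it.
    """
    if not matrices:
        raise ValueError("need at least one subject")
    n = matrices[0].n
    if any(m.n != n for m in matrices):
        raise ValueError("subjects have inconsistent node counts")
    stack = np.stack([m.angles for m in matrices])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(matrices) > 1 else np.zeros_like(mean)
    off = ~np.eye(n, dtype=bool)
    consistency = np.array([mean[i][off[i]].std(ddof=1) for i in range(n)])
    return GroupAlignmentSummary(
        mean_angles=mean, sd_angles=sd, consistency=consistency, n_subjects=len(matrices)
    )
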