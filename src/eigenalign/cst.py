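"""Cluster-Span Threshold (CST) selection and application.

A weighted network is binarized at a candidate cutoff t by keeping edges
with weight >= t. For the resulting topology, a *triple* is a centre node
with two distinct neighbours; a triple is *clustered* when the two
neighbours are themselves adjacent (each triangle contributes three
clustered triples) and *spanning* otherwise. The CST is the cutoff whose
topology best balances clustered against spanning triples — an unbiased
alternative to arbitrary fixed thresholds for correlation networks.

Exact equality of the two integer counts is rarely attainable, so the
selected threshold minimizes the *normalized* imbalance
|clustered - spanning| / total over all admissible candidates
(candidates whose topology has at least one triple), breaking ties
toward the smallest cutoff, i.e. the densest admissible graph. The
normalization matters: the raw count difference is trivially small for
near-empty topologies (a lone open triple scores 1), so an absolute
objective would drift to the sparse tail of the weight distribution,
while the normalized objective finds the density at which half of all
triples close — the balance the criterion intends. On iid U(0,1)
weights it sits at a cutoff of ~0.5, where triangle closure probability
is one half.

The scan runs over ascending candidate cutoffs and stops once a
clustered-triple majority has given way to a spanning majority: that
sign change is the balance crossing, and the sparse topologies beyond
it can match the objective only by small-count luck (three clustered
and three spanning triples on six surviving edges says nothing about
the network's balance). Thresholding preserves surviving edge weights;
only the selection step binarizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ConnectivityMatrix

__all__ = [
    "TripleCounts",
    "ThresholdResult",
    "ThresholdedMatrix",
    "DegenerateTopologyError",
    "count_triples",
    "cluster_span_threshold",
    "apply_threshold",
]


class DegenerateTopologyError(ValueError):
    """No admissible threshold: every candidate topology is triple-free."""


@dataclass(frozen=True)
class TripleCounts:
    """Exact triple census of a binary topology."""

    clustered: int
    spanning: int

    @property
    def total(self) -> int:
        return self.clustered + self.spanning

    @property
    def imbalance(self) -> int:
        return abs(self.clustered - self.spanning)

    @property
    def normalized_imbalance(self) -> float:
        """|clustered - spanning| / total; the CST selection objective."""
        if self.total == 0:
            raise ZeroDivisionError("no triples: normalized imbalance undefined")
        return self.imbalance / self.total


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a CST scan."""

    threshold: float
    counts: TripleCounts
    candidates_examined: int

    @property
    def imbalance(self) -> int:
        return self.counts.imbalance

    @property
    def normalized_imbalance(self) -> float:
        return self.counts.normalized_imbalance


@dataclass(frozen=True)
class ThresholdedMatrix:
    """Weighted matrix with sub-threshold edges removed (weights retained)."""

    subject_id: str
    weights: np.ndarray
    threshold: float

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def topology(self) -> np.ndarray:
        """Binary (0/1 int) adjacency of the surviving edges."""
        return (self.weights != 0).astype(np.int64)


def count_triples(topology: np.ndarray) -> TripleCounts:
    """Count clustered and spanning triples of a binary undirected topology.

    ``total = sum_c C(deg(c), 2)`` and ``clustered = 3 * #triangles
    = trace(A^3) / 2``; both are exact integer identities.
    """
    a = np.asarray(topology)
    a = (a != 0).astype(np.int64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("topology must be square")
    if np.any(a != a.T) or np.any(np.diag(a)):
        raise ValueError("topology must be symmetric with zero diagonal")
    deg = a.sum(axis=0)
    total = int((deg * (deg - 1) // 2).sum())
    clustered = int(np.trace(a @ a @ a)) // 2
    return TripleCounts(clustered=clustered, spanning=total - clustered)


def cluster_span_threshold(matrix: ConnectivityMatrix) -> ThresholdResult:
    """Select the CST for a weighted connectivity matrix.

    Scans every distinct strictly-positive weight as a candidate cutoff
    (keep rule ``w >= t``), discards candidates with no triples, and
    returns the candidate minimizing |clustered - spanning| / total;
    ties go to the smallest cutoff. Negative weights are scanned as-is
    and never survive a positive threshold.

    Raises
    ------
    DegenerateTopologyError
        If no candidate produces a topology with at least one triple.
    """
    w = matrix.weights
    iu = np.triu_indices(matrix.n, k=1)
    vals = w[iu]
    candidates = np.unique(vals[vals > 0])
    if candidates.size == 0:
        raise DegenerateTopologyError("no strictly positive weights to threshold")
    best: tuple[float, float, TripleCounts] | None = None
    seen_clustered_majority = False
    for t in candidates:  # ascending: strict '<' keeps the smallest tied cutoff
        counts = count_triples(w >= t)
        if counts.total == 0:
            continue
        objective = counts.imbalance / counts.total
        if best is None or objective < best[0]:
            best = (objective, float(t), counts)
        if counts.clustered > counts.spanning:
            seen_clustered_majority = True
        elif seen_clustered_majority:
            # the clustered majority just gave way to spanning: this is the
            # balance crossing; sparser topologies beyond it are noise
            break
    if best is None:
        raise DegenerateTopologyError(
            "every candidate threshold yields a triple-free topology"
        )
    return ThresholdResult(
        threshold=best[1], counts=best[2], candidates_examined=int(candidates.size)
    )


def apply_threshold(matrix: ConnectivityMatrix, t: float) -> ThresholdedMatrix:
    """Zero out entries below ``t``, keeping surviving weights unchanged."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    w = matrix.weights.copy()
    w[w < t] = 0.0
    np.fill_diagonal(w, 0.0)
    return ThresholdedMatrix(subject_id=matrix.subject_id, weights=w, threshold=float(t))


def cst_threshold_and_apply(matrix: ConnectivityMatrix) -> tuple[ThresholdResult, ThresholdedMatrix]:
    """Convenience: select the CST and apply it in one call."""
    res = cluster_span_threshold(matrix)
    return res, apply_threshold(matrix, res.threshold)
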