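"""Communities of dynamical influence (CDI).

A deterministic community detection keyed to influence rather than edge
density. In the dominant-eigenvector frame:

1. **Leaders** are nodes strictly farther from the origin than every one
   of their topological neighbours.
2. Every other node joins the leader, reachable within its own connected
   component, whose position vector has the largest dot product with its
   own — i.e. the most closely aligned reachable leader.
3. Communities are **ranked** by the largest eigenvector-centrality value
   among their members; rank 1 is the most influential.

On highly symmetric graphs the strict-distance rule can leave a component
leaderless; that component's farthest node (lowest index on ties) is then
promoted and the partition flagged as degenerate. All tie-breaks are
deterministic, so identical inputs always give identical partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import connected_components

from .cst import DegenerateTopologyError, ThresholdedMatrix
from .embedding import PositionSet

__all__ = [
    "CommunityPartition",
    "find_leaders",
    "assign_communities",
    "rank_communities",
    "community_size_profile",
    "SizeProfile",
]


@dataclass(frozen=True)
class CommunityPartition:
    """A total, disjoint node partition with leaders and influence ranks.

    ``membership[i]`` is the community index of node i; community c has
    leader ``leaders[c]``. ``ranks`` (if ranked) maps community index to
    its influence rank, a permutation of ``1..n_communities``.
    """

    leaders: tuple[int, ...]
    membership: np.ndarray  # (n,) int community index
    ranks: tuple[int, ...] | None = None
    degenerate_leaders: bool = False

    @property
    def n_communities(self) -> int:
        return len(self.leaders)

    def members(self, community: int) -> np.ndarray:
        return np.flatnonzero(self.membership == community)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.membership, minlength=self.n_communities)

    def community_by_rank(self, rank: int) -> int:
        if self.ranks is None:
            raise ValueError("partition is not ranked")
        return self.ranks.index(rank)


@dataclass(frozen=True)
class SizeProfile:
    """Community sizes at either end of the influence spectrum."""

    most_influential: int
    least_influential: int
    mean_two_most: float
    mean_two_least: float
    n_communities: int
    single_community: bool = False


def find_leaders(positions: PositionSet, topology: ThresholdedMatrix) -> tuple[tuple[int, ...], bool]:
    """Identify community leaders: nodes farther out than all neighbours.

    Returns ``(leaders, degenerate)`` where ``degenerate`` is True if any
    connected component had no strict-distance leader and its maximum-
    distance node (lowest index on ties) was promoted instead. Isolated
    nodes lead their own singleton communities vacuously.

    Raises
    ------
    DegenerateTopologyError
        If the graph has no edges at all.
    """
    adj = topology.topology()
    n = adj.shape[0]
    if positions.n != n:
        raise ValueError("positions and topology node counts differ")
    if adj.sum() == 0:
        raise DegenerateTopologyError("graph has no edges; CDI is undefined")
    dist = np.linalg.norm(positions.positions, axis=1)
    # strictly farther means beyond float noise: embeddings of symmetric
    # graphs put nodes at distances equal up to ~1e-16, and those ties must
    # fall through to the per-component fallback, not be decided by rounding
    tol = 1e-12 * max(1.0, dist.max())
    leaders = [
        i for i in range(n) if all(dist[i] > dist[j] + tol for j in np.flatnonzero(adj[i]))
    ]
    leader_set = set(leaders)
    _, comp = connected_components(adj, directed=False)
    degenerate = False
    for c in range(comp.max() + 1):
        nodes = np.flatnonzero(comp == c)
        if leader_set.isdisjoint(nodes):
            promoted = int(nodes[np.argmax(dist[nodes])])  # argmax keeps lowest index on ties
            leader_set.add(promoted)
            degenerate = True
    return tuple(sorted(leader_set)), degenerate


def assign_communities(
    positions: PositionSet,
    topology: ThresholdedMatrix,
    leaders: tuple[int, ...],
    ec: np.ndarray | None = None,
    degenerate_leaders: bool = False,
) -> CommunityPartition:
    """Assign every node to the most-aligned leader reachable from it.

    A node only considers leaders in its own connected component (the
    path condition), and among those joins the leader maximizing the dot
    product of position vectors. Dot-product ties break toward the leader
    with the higher eigenvector centrality (if ``ec`` is given), then the
    lower leader index.
    """
    adj = topology.topology()
    n = adj.shape[0]
    if not leaders:
        raise ValueError("at least one leader required")
    if any(not 0 <= l < n for l in leaders):
        raise ValueError("leader index out of range")
    _, comp = connected_components(adj, directed=False)
    p = positions.positions
    membership = np.full(n, -1, dtype=int)
    leader_list = list(leaders)
    for node in range(n):
        if node in leaders:
            membership[node] = leader_list.index(node)
            continue
        reachable = [c for c, l in enumerate(leader_list) if comp[l] == comp[node]]
        if not reachable:  # cannot occur after find_leaders' per-component fallback
            raise RuntimeError(f"node {node} has no reachable leader")
        dots = np.array([p[node] @ p[leader_list[c]] for c in reachable])
        best = np.flatnonzero(dots == dots.max())
        if len(best) > 1 and ec is not None:
            ecs = np.array([ec[leader_list[reachable[b]]] for b in best])
            best = best[np.flatnonzero(ecs == ecs.max())]
        membership[node] = reachable[int(best[0])]  # lowest leader index last resort
    return CommunityPartition(
        leaders=tuple(leader_list),
        membership=membership,
        degenerate_leaders=degenerate_leaders,
    )


def rank_communities(partition: CommunityPartition, ec: np.ndarray) -> CommunityPartition:
    """Rank communities by their maximum member EC (rank 1 = most influential).

    Ties break toward the lower leader index.
    """
    if ec.shape[0] != partition.membership.shape[0]:
        raise ValueError("EC vector and partition node counts differ")
    ncom = partition.n_communities
    max_ec = np.array([ec[partition.members(c)].max() for c in range(ncom)])
    order = sorted(range(ncom), key=lambda c: (-max_ec[c], partition.leaders[c]))
    ranks = [0] * ncom
    for r, c in enumerate(order, start=1):
        ranks[c] = r
    return replace(partition, ranks=tuple(ranks))


def detect_communities(
    positions: PositionSet, topology: ThresholdedMatrix, ec: np.ndarray
) -> CommunityPartition:
    """Full CDI: leaders, assignment, ranking."""
    leaders, degenerate = find_leaders(positions, topology)
    part = assign_communities(positions, topology, leaders, ec=ec, degenerate_leaders=degenerate)
    return rank_communities(part, ec)


def community_size_profile(partition: CommunityPartition) -> SizeProfile:
    """Sizes of the most/least influential communities and two-community means.

    With a single community all four size statistics collapse to that
    community's size and the profile is flagged.
    """
    if partition.ranks is None:
        raise ValueError("partition must be ranked first")
    sizes = partition.sizes()
    by_rank = [int(sizes[partition.community_by_rank(r)]) for r in range(1, partition.n_communities + 1)]
    if len(by_rank) == 1:
        s = by_rank[0]
        return SizeProfile(s, s, float(s), float(s), 1, single_community=True)
    return SizeProfile(
        most_influential=by_rank[0],
        least_influential=by_rank[-1],
        mean_two_most=(by_rank[0] + by_rank[1]) / 2.0,
        mean_two_least=(by_rank[-1] + by_rank[-2]) / 2.0,
        n_communities=len(by_rank),
    )
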