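"""Seeded generators for null matrices, structured cohorts and demo networks.

Three generators cover every testing need without external data:

* :func:`random_uniform_matrix` — the null model: symmetric matrices of
  iid U(0,1) weights, the reference distribution against which observed
  alignments are screened for significance.
* :func:`generate_cohort` — cohorts of connectivity matrices with the
  gross structure of real resting-state correlation data: bilateral
  (homotopic) ROI pairs with strong coupling, block community structure,
  additive noise, and a tunable "disease" degradation that weakens the
  homotopic couplings by a fractional amount delta.
* :func:`toy_network` — a fixed 4-node weighted network demonstrating how
  a single edge-weight change repositions nodes across the whole
  embedding, not just the directly connected pair.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ConnectivityMatrix, SubjectGroup

__all__ = [
    "CohortSpec",
    "random_uniform_matrix",
    "generate_cohort",
    "bilateral_study_spec",
    "toy_network",
    "TOY_BASE_WEIGHTS",
]


def random_uniform_matrix(n: int, seed: int | np.random.Generator) -> ConnectivityMatrix:
    """Symmetric matrix of iid U(0,1) off-diagonal weights, zero diagonal."""
    if n < 3:
        raise ValueError("need n >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w[iu] = rng.uniform(0.0, 1.0, size=len(iu[0]))
    w = w + w.T
    return ConnectivityMatrix("null", w)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort of connectivity matrices.

    Parameters
    ----------
    n_roi, n_subjects
        Cohort dimensions.
    homotopic_pairs
        Disjoint (i, j) index pairs standing in for left/right instances
        of the same cortical area, coupled at ``homotopic_coupling``.
    degraded_pairs
        The subset of homotopic pairs the "disease" affects: their
        coupling becomes ``rho * (1 - degradation)``. ``None`` (default)
        degrades every homotopic pair; an explicit empty tuple degrades
        none (a healthy cohort regardless of ``degradation``).
    homotopic_coupling
        Healthy homotopic edge weight rho (Fisher-z units).
    community_blocks
        ROI index sets forming functional modules: within-block weight
        ``mu_in``, everything else ``mu_out``.
    background_jitter
        Half-width of uniform per-edge heterogeneity added to the
        template, drawn once from ``template_seed``. Real connectomes
        have no two regions with identical coupling profiles; without
        this jitter, homotopic partners inside one block would be exact
        graph twins and stay perfectly aligned whatever happens to
        their direct edge.
    noise_sd
        SD of additive Gaussian noise applied per subject before
        symmetrization by averaging.
    template_seed
        Seed for the jitter draw, *separate* from ``seed`` so healthy
        and degraded cohorts built with different subject seeds share
        the same underlying anatomy.
    """

    n_roi: int
    n_subjects: int
    homotopic_pairs: tuple[tuple[int, int], ...] = ()
    homotopic_coupling: float = 0.85
    community_blocks: tuple[tuple[int, ...], ...] = ()
    mu_in: float = 0.45
    mu_out: float = 0.2
    degradation: float = 0.0
    degraded_pairs: tuple[tuple[int, int], ...] | None = None
    background_jitter: float = 0.25
    noise_sd: float = 0.08
    seed: int = 0
    template_seed: int = 1729

    def __post_init__(self) -> None:
        if not 0.0 <= self.degradation <= 1.0:
            raise ValueError("degradation must lie in [0, 1]")
        if not self.mu_in > self.mu_out >= 0.0:
            raise ValueError("need mu_in > mu_out >= 0")
        if self.n_roi < 3:
            raise ValueError("need n_roi >= 3")
        if self.n_subjects < 1:
            raise ValueError("need n_subjects >= 1")
        if self.background_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise_sd must be non-negative")
        seen: set[int] = set()
        for i, j in self.homotopic_pairs:
            if i == j or not (0 <= i < self.n_roi and 0 <= j < self.n_roi):
                raise ValueError(f"bad homotopic pair ({i}, {j})")
            if i in seen or j in seen:
                raise ValueError("homotopic pairs must be disjoint")
            seen.update((i, j))
        if self.degraded_pairs is not None:
            extra = set(self.degraded_pairs) - set(self.homotopic_pairs)
            if extra:
                raise ValueError(f"degraded pairs not homotopic: {sorted(extra)}")

    @property
    def effective_degraded_pairs(self) -> tuple[tuple[int, int], ...]:
        if self.degraded_pairs is None:
            return self.homotopic_pairs
        return self.degraded_pairs

    def template(self) -> np.ndarray:
        """Noise-free mean weight matrix implied by the spec."""
        w = np.full((self.n_roi, self.n_roi), self.mu_out)
        for block in self.community_blocks:
            idx = np.asarray(block)
            w[np.ix_(idx, idx)] = self.mu_in
        if self.background_jitter > 0:
            rng = np.random.default_rng(self.template_seed)
            jit = rng.uniform(-self.background_jitter, self.background_jitter,
                              (self.n_roi, self.n_roi))
            w = w + (jit + jit.T) / 2.0
        degraded = set(self.effective_degraded_pairs)
        for i, j in self.homotopic_pairs:
            d = self.degradation if (i, j) in degraded else 0.0
            w[i, j] = w[j, i] = self.homotopic_coupling * (1.0 - d)
        np.fill_diagonal(w, 0.0)
        return w


def generate_cohort(spec: CohortSpec) -> SubjectGroup:
    """Draw a cohort of subjects from a :class:`CohortSpec`.

    Each subject is the spec template plus iid Gaussian noise,
    symmetrized by averaging with its transpose and clipped to [-1, 1]
    (a plausible Fisher-z range). With ``noise_sd=0`` all subjects equal
    the template exactly.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template()
    members = []
    for s in range(spec.n_subjects):
        noise = rng.normal(0.0, spec.noise_sd, size=template.shape) if spec.noise_sd > 0 else 0.0
        w = template + noise
        w = (w + w.T) / 2.0
        w = np.clip(w, -1.0, 1.0)
        np.fill_diagonal(w, 0.0)
        members.append(ConnectivityMatrix(f"sim-{s + 1:03d}", w))
    label = f"delta={spec.degradation:g}"
    return SubjectGroup(label, tuple(members))


#: bilateral study geometry: four homotopic pairs (i, i+10), three
#: six-node modules each anchored by one pair plus four unpaired regions
STUDY_PAIRS = ((0, 10), (1, 11), (2, 12), (3, 13))
STUDY_BLOCKS = ((0, 10, 4, 5, 14, 15), (1, 11, 6, 7, 16, 17), (2, 12, 8, 9, 18, 19))
STUDY_DEGRADED = ((0, 10),)


def bilateral_study_spec(
    degradation: float = 0.0,
    n_subjects: int = 10,
    seed: int = 0,
    noise_sd: float = 0.08,
) -> CohortSpec:
    """The reference 20-ROI bilateral cohort used throughout the test bench.

    Twenty regions: four homotopic pairs ``(i, i+10)`` and twelve
    unpaired regions, organized into three functional modules of six
    (one pair anchoring each module). Healthy cohorts keep all pairs at
    coupling 0.85; a degraded cohort weakens the first pair by the
    given fraction, emulating a disease hitting part of the bilateral
    (commissural) system while the rest of the anatomy is untouched.
    Cohorts built with different ``seed`` values share the same
    underlying template, differing only in subject noise.
    """
    return CohortSpec(
        n_roi=20,
        n_subjects=n_subjects,
        homotopic_pairs=STUDY_PAIRS,
        community_blocks=STUDY_BLOCKS,
        degradation=degradation,
        degraded_pairs=STUDY_DEGRADED if degradation > 0 else (),
        noise_sd=noise_sd,
        seed=seed,
    )


#: Fixed toy weights: nodes A, B, C, D = indices 0-3. At the baseline
#: B-D weight of 0.3, A and D have identical coupling profiles (0.3 to
#: B, 0.7 to C), making them near-fully aligned despite sharing no edge.
TOY_BASE_WEIGHTS: dict[tuple[int, int], float] = {
    (0, 1): 0.3,  # A-B
    (0, 2): 0.7,  # A-C
    (2, 3): 0.7,  # C-D
    (1, 3): 0.3,  # B-D, the edge the demo perturbs
}


def toy_network(boost: float = 0.3) -> ConnectivityMatrix:
    """The 4-node demo network with the B-D edge set to ``boost``.

    At ``boost=0.3`` nodes A and D have identical connectivity profiles
    and are near-fully aligned (theta ~ 0) although no edge joins them.
    Raising the B-D weight to 1 pulls D toward B: the B-D angle shrinks
    (direct effect) while the A-D angle opens from ~0 to above 1 radian
    — an alignment change at a pair whose own edge never changed. Angles
    for this network are conventionally computed in the ``unit`` scaling
    frame.
    """
    if not 0.3 <= boost <= 1.0:
        raise ValueError("boost must lie in [0.3, 1.0]")
    w = np.zeros((4, 4))
    for (i, j), v in TOY_BASE_WEIGHTS.items():
        w[i, j] = w[j, i] = v
    w[1, 3] = w[3, 1] = boost
    return ConnectivityMatrix(f"toy-boost={boost:g}", w)
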