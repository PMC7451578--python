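"""Group comparisons: Welch tests, random-model filtering, ROI substitution.

Group differences in alignment, centrality, raw connectivity and
community size are assessed with Welch's unequal-variance t test — the
natural choice here because the compared samples are small and of
different sizes (about ten subjects against hundreds of null matrices).

False-positive control uses a *random-model filter* instead of multiple
-testing correction: a ROI pair is only eligible for a group-vs-group
alignment test if at least one of the two groups differs significantly
from matrices of iid U(0,1) weights, and does so consistently across
several independently generated null sets. Pairs whose alignment is
indistinguishable from noise never reach the group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import stats as sps

from .cst import DegenerateTopologyError
from .data_model import ConnectivityMatrix, SubjectGroup, ValidationError
from .pipeline import PipelineConfig, SubjectResult, run_subject
from .synthetic import random_uniform_matrix

__all__ = [
    "TestResult",
    "PairEligibilityMask",
    "ComparisonResult",
    "welch_t_test",
    "angle_stack",
    "ec_stack",
    "random_model_null",
    "eligible_pairs",
    "compare_alignment",
    "compare_centrality",
    "compare_connectivity",
    "compare_community_sizes",
    "substitute_roi",
]


class DegenerateSampleError(ValueError):
    """Both samples have zero variance; the t statistic is undefined."""


@dataclass(frozen=True)
class TestResult:
    """One Welch test: statistic, Welch-Satterthwaite df, two-sided p."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float

    @property
    def mean_diff(self) -> float:
        return self.mean_a - self.mean_b


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Welch's two-sample t test (two-sided, unequal variances)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            # identical constant samples: no evidence of difference
            return TestResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0,
                              mean_a=float(a.mean()), mean_b=float(b.mean()))
        raise DegenerateSampleError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def _welch_grid(stack_a: np.ndarray, stack_b: np.ndarray):
    """Vectorized Welch test along axis 0 of two stacks of grids."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(stack_a, stack_b, axis=0, equal_var=False)
        t = np.array(res.statistic, dtype=float, copy=True)
        p = np.array(res.pvalue, dtype=float, copy=True)
        df = np.array(np.broadcast_to(res.df, t.shape), dtype=float, copy=True)
    return t, df, p


@dataclass(frozen=True)
class PairEligibilityMask:
    """ROI pairs that survive the random-model screen.

    ``mask[i, j]`` is True when the pair differed from every null set
    (Welch p <= alpha for at least one of the two compared groups, in all
    sets). Carries the provenance needed to reproduce the screen.
    """

    mask: np.ndarray  # (n, n) bool, symmetric, diagonal False
    n_sets: int
    models_per_set: int
    alpha: float
    seed: int

    @property
    def n_eligible_pairs(self) -> int:
        return int(self.mask[np.triu_indices(self.mask.shape[0], k=1)].sum())


@dataclass(frozen=True)
class ComparisonResult:
    """Per-pair (or per-ROI) Welch results for one group-vs-group contrast.

    For ``metric="alignment"`` entries are mean angles and *increase in
    alignment* means a smaller mean angle in the first group. For
    centrality and connectivity the direction follows the plain mean
    difference. Grids hold NaN where no test was run.
    """

    metric: str  # "alignment" | "centrality" | "connectivity"
    mean_a: np.ndarray
    mean_b: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    eligible: np.ndarray  # bool, same shape
    alpha: float

    @property
    def pairwise(self) -> bool:
        return self.mean_a.ndim == 2

    @property
    def delta(self) -> np.ndarray:
        return self.mean_a - self.mean_b

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.eligible & (self.p <= self.alpha)

    def increased(self) -> np.ndarray:
        """Where the metric moved up in group 1 (for alignment: angle down)."""
        if self.metric == "alignment":
            return self.mean_a < self.mean_b
        return self.mean_a > self.mean_b

    def direction_label(self, i: int, j: int | None = None) -> str:
        inc = self.increased()
        flag = inc[i, j] if j is not None and self.pairwise else inc[i]
        return "increase" if flag else "decrease"

    def tested_pairs(self) -> Iterator[tuple[int, int]]:
        """Upper-triangle (i, j) pairs where a test was run, i < j ascending."""
        if not self.pairwise:
            raise ValueError("not a pairwise result")
        n = self.mean_a.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if self.eligible[i, j] and np.isfinite(self.p[i, j]):
                    yield i, j

    def pair(self, i: int, j: int) -> TestResult:
        return TestResult(
            t=float(self.t[i, j]),
            df=float(self.df[i, j]),
            p=float(self.p[i, j]),
            mean_a=float(self.mean_a[i, j]),
            mean_b=float(self.mean_b[i, j]),
        )

    def roi_change_counts(self) -> np.ndarray:
        """Per-ROI count of significant pairwise changes (row sums).

        Each significant pair increments both of its endpoints, so the
        vector sums to twice the number of significant pairs.
        """
        if not self.pairwise:
            raise ValueError("not a pairwise result")
        return self.significant.sum(axis=1)


def angle_stack(results: Sequence[SubjectResult]) -> np.ndarray:
    """(m, n, n) stack of subject alignment-angle matrices."""
    return np.stack([r.angles.angles for r in results])


def ec_stack(results: Sequence[SubjectResult]) -> np.ndarray:
    """(m, n) stack of subject eigenvector-centrality vectors."""
    return np.stack([r.ec for r in results])


def random_model_null(
    n: int,
    models_per_set: int,
    n_sets: int = 3,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
) -> list[np.ndarray]:
    """Null alignment distributions from random U(0,1) connectivity matrices.

    Each set holds ``models_per_set`` matrices of iid uniform weights
    pushed through the *same* pipeline as real subjects (CST, embedding,
    scaling, angles), yielding per-pair angle samples. Set seeds are
    derived deterministically from ``seed``; the rare random matrix with
    no admissible threshold is redrawn (never silently skipped).
    """
    if models_per_set < 2:
        raise ValueError("need at least two models per set")
    sets = []
    for child in np.random.SeedSequence(seed).spawn(n_sets):
        rng = np.random.default_rng(child)
        angles = np.empty((models_per_set, n, n))
        for m in range(models_per_set):
            while True:
                try:
                    matrix = random_uniform_matrix(n, rng)
                    angles[m] = run_subject(matrix, config).angles.angles
                    break
                except DegenerateTopologyError:
                    continue  # redraw from the same stream
        sets.append(angles)
    return sets


def eligible_pairs(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    nulls: Sequence[np.ndarray],
    alpha: float = 0.05,
    seed: int = 0,
) -> PairEligibilityMask:
    """Screen ROI pairs against the random-model null sets.

    In one set a pair is flagged when Welch p <= alpha for group A vs
    null *or* group B vs null; the final mask keeps pairs flagged in
    every set. The diagonal is never eligible.
    """
    if not nulls:
        raise ValueError("need at least one null set")
    n = stack_a.shape[1]
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    for null in nulls:
        _, _, p_a = _welch_grid(stack_a, null)
        _, _, p_b = _welch_grid(stack_b, null)
        with np.errstate(invalid="ignore"):
            hit = (p_a <= alpha) | (p_b <= alpha)
        mask &= hit
    np.fill_diagonal(mask, False)
    return PairEligibilityMask(
        mask=mask,
        n_sets=len(nulls),
        models_per_set=int(nulls[0].shape[0]),
        alpha=alpha,
        seed=seed,
    )


def compare_alignment(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    mask: PairEligibilityMask | None = None,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Welch tests on subject-level alignment angles for every eligible pair."""
    if stack_a.shape[0] < 2 or stack_b.shape[0] < 2:
        raise ValueError("each group needs at least two subjects")
    n = stack_a.shape[1]
    eligible = mask.mask.copy() if mask is not None else ~np.eye(n, dtype=bool)
    t, df, p = _welch_grid(stack_a, stack_b)
    for arr in (t, df, p):
        arr[~eligible] = np.nan
    return ComparisonResult(
        metric="alignment",
        mean_a=stack_a.mean(axis=0),
        mean_b=stack_b.mean(axis=0),
        t=t,
        df=df,
        p=p,
        eligible=eligible,
        alpha=alpha,
    )


def compare_centrality(
    ec_a: np.ndarray, ec_b: np.ndarray, alpha: float = 0.05
) -> ComparisonResult:
    """Per-ROI Welch tests on eigenvector-centrality values."""
    if ec_a.shape[0] < 2 or ec_b.shape[0] < 2:
        raise ValueError("each group needs at least two subjects")
    t, df, p = _welch_grid(ec_a, ec_b)
    eligible = np.ones(ec_a.shape[1], dtype=bool)
    return ComparisonResult(
        metric="centrality",
        mean_a=ec_a.mean(axis=0),
        mean_b=ec_b.mean(axis=0),
        t=t,
        df=df,
        p=p,
        eligible=eligible,
        alpha=alpha,
    )


def compare_connectivity(
    group_a: SubjectGroup, group_b: SubjectGroup, alpha: float = 0.05
) -> ComparisonResult:
    """Per-pair Welch tests on raw (pre-threshold) edge weights."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two subjects")
    wa, wb = group_a.weight_stack(), group_b.weight_stack()
    n = wa.shape[1]
    eligible = ~np.eye(n, dtype=bool)
    t, df, p = _welch_grid(wa, wb)
    for arr in (t, df, p):
        arr[~eligible] = np.nan
    return ComparisonResult(
        metric="connectivity",
        mean_a=wa.mean(axis=0),
        mean_b=wb.mean(axis=0),
        t=t,
        df=df,
        p=p,
        eligible=eligible,
        alpha=alpha,
    )


#: size statistics compared between groups
_SIZE_FIELDS = ("most_influential", "least_influential", "mean_two_most", "mean_two_least")


def compare_community_sizes(
    results_a: Sequence[SubjectResult], results_b: Sequence[SubjectResult]
) -> dict[str, TestResult]:
    """Welch tests on community sizes at both ends of the influence spectrum.

    Two constant samples with different values — every subject in each
    group showing exactly the same size — have no sampling variability
    and are reported as an exact difference (p = 0, infinite t) rather
    than an error.
    """
    out = {}
    for name in _SIZE_FIELDS:
        sa = [float(getattr(r.sizes, name)) for r in results_a]
        sb = [float(getattr(r.sizes, name)) for r in results_b]
        try:
            out[name] = welch_t_test(sa, sb)
        except DegenerateSampleError:
            diff = float(np.mean(sa) - np.mean(sb))
            out[name] = TestResult(
                t=float(np.inf) * np.sign(diff),
                df=float(len(sa) + len(sb) - 2),
                p=0.0,
                mean_a=float(np.mean(sa)),
                mean_b=float(np.mean(sb)),
            )
    return out


def substitute_roi(
    host: SubjectGroup,
    donor: SubjectGroup,
    roi_id: int,
    pairing: Sequence[tuple[int, int]] | None = None,
) -> SubjectGroup:
    """Transplant one ROI's connectivity from donor subjects into hosts.

    For each (host, donor) pair the host's row *and* column for the ROI
    are replaced by the donor's, preserving symmetry and the zero
    diagonal; every other entry is untouched. The default pairing matches
    subjects by manifest order, truncated to the smaller group. Useful
    for asking whether one region's connectivity changes, in isolation,
    would alter its alignments.
    """
    if host.members[0].roi_ids != donor.members[0].roi_ids:
        raise ValidationError("host and donor groups must share the ROI ordering")
    roi_ids = host.members[0].roi_ids
    if roi_id not in roi_ids:
        raise ValueError(f"ROI id {roi_id} not present (ids {roi_ids[0]}..{roi_ids[-1]})")
    idx = roi_ids.index(roi_id)
    if pairing is None:
        m = min(len(host), len(donor))
        pairing = [(i, i) for i in range(m)]
    members = []
    for hi, di in pairing:
        w = host.members[hi].weights.copy()
        row = donor.members[di].weights[idx].copy()
        w[idx, :] = row
        w[:, idx] = row
        w[idx, idx] = 0.0
        members.append(
            ConnectivityMatrix(
                f"{host.members[hi].subject_id}+roi{roi_id}from{donor.members[di].subject_id}",
                w,
                roi_ids,
            )
        )
    return SubjectGroup(f"{host.label}+roi{roi_id}", tuple(members))
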