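"""Core domain types and file I/O for connectivity-network analysis.

The central object is the :class:`ConnectivityMatrix`: one subject's
ROI-by-ROI weighted functional network, typically Fisher z-transformed
correlation coefficients. Matrices are square, symmetric, zero-diagonal;
weights may be negative before thresholding. Cohorts of subjects are held
in :class:`SubjectGroup` objects, and ROI identities in an
:class:`ROITable` whose ids are 1-based and contiguous (user-facing I/O is
1-based; all in-memory arrays are 0-based).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "ROITable",
    "ConnectivityMatrix",
    "SubjectGroup",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
    "read_roi_table",
    "read_group_manifest",
    "write_pair_results",
    "read_pair_results",
]

#: largest tolerated |A - A.T| entry; anything bigger is a corrupt file
ASYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """Input parsed but violates a structural invariant."""


class FormatError(ValueError):
    """Input could not be parsed into the expected shape."""


@dataclass(frozen=True)
class ROITable:
    """Atlas table mapping 1-based ROI ids to region names.

    Ids must be contiguous ``1..n`` and names unique, so a table is fully
    determined by the ordered name list.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValidationError(f"duplicate ROI names: {dupes}")
        if self.hemispheres is not None and len(self.hemispheres) != len(self.names):
            raise ValidationError("hemisphere column length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.names) + 1))

    def name_of(self, roi_id: int) -> str:
        """Region name for a 1-based ROI id."""
        if not 1 <= roi_id <= len(self.names):
            raise KeyError(f"ROI id {roi_id} out of range 1..{len(self.names)}")
        return self.names[roi_id - 1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's weighted ROI-to-ROI network.

    ``weights`` is square, symmetric (to 1e-10), zero-diagonal; entries are
    connectivity values in Fisher-z units and may be negative before
    thresholding. ``roi_ids`` are the 1-based atlas ids of the rows/columns.
    """

    subject_id: str
    weights: np.ndarray
    roi_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 3:
            raise ValidationError(f"need at least 3 ROIs, got {n}")
        if not np.all(np.isfinite(w)):
            bad = np.argwhere(~np.isfinite(w))[0]
            raise ValidationError(f"non-finite entry at {tuple(bad)}")
        asym = np.abs(w - w.T)
        if asym.max() > 1e-10:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"matrix not symmetric: |A[{i},{j}] - A[{j},{i}]| = {asym[i, j]:.3g}"
            )
        if np.any(np.diag(w) != 0):
            raise ValidationError("diagonal must be exactly zero")
        if not self.roi_ids:
            object.__setattr__(self, "roi_ids", tuple(range(1, n + 1)))
        elif len(self.roi_ids) != n:
            raise ValidationError("roi_ids length does not match matrix dimension")
        w.setflags(write=False)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray) -> "ConnectivityMatrix":
        """Same subject and ROI ordering, new weight matrix."""
        return ConnectivityMatrix(self.subject_id, np.array(weights), self.roi_ids)


@dataclass(frozen=True)
class SubjectGroup:
    """An ordered cohort of subjects sharing one ROI ordering."""

    label: str
    members: tuple[ConnectivityMatrix, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"group {self.label!r} is empty")
        ref = self.members[0].roi_ids
        for m in self.members[1:]:
            if m.roi_ids != ref:
                raise ValidationError(
                    f"subject {m.subject_id!r} has a different ROI ordering"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    @property
    def n_roi(self) -> int:
        return self.members[0].n

    def weight_stack(self) -> np.ndarray:
        """(n_subjects, n, n) array of raw weight matrices."""
        return np.stack([m.weights for m in self.members])


def _sanitize(raw: np.ndarray, subject_id: str, roi_ids=()) -> ConnectivityMatrix:
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise FormatError(f"expected a square matrix, got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        bad = np.argwhere(~np.isfinite(raw))[0]
        raise ValidationError(f"non-finite entry at {tuple(bad)}")
    asym = np.abs(raw - raw.T)
    worst = asym.max() if asym.size else 0.0
    if worst > ASYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"asymmetry {worst:.3g} at cell ({i + 1},{j + 1}) exceeds "
            f"tolerance {ASYMMETRY_TOL:g}; refusing to symmetrize"
        )
    w = (raw + raw.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(subject_id, w, tuple(roi_ids))


def read_connectivity_matrix(
    path: str | os.PathLike, dialect: str = "delimited", subject_id: str | None = None
) -> ConnectivityMatrix:
    """Load and validate one subject's connectivity matrix.

    Parameters
    ----------
    path
        A dense text matrix (whitespace- or comma-delimited) or, with
        ``dialect="mat"``, a MAT-container holding a single 2-D array.
    dialect
        ``"delimited"`` (default) or ``"mat"``.
    subject_id
        Defaults to the file stem.

    Tiny asymmetries (≤ 1e-8, i.e. decimal round-off) are repaired by
    averaging the matrix with its transpose; anything larger raises
    :class:`ValidationError` naming the worst cell. The diagonal is forced
    to zero.
    """
    path = os.fspath(path)
    sid = subject_id if subject_id is not None else os.path.splitext(os.path.basename(path))[0]
    if dialect == "delimited":
        with open(path) as fh:
            text = fh.read()
        delim = "," if "," in text.splitlines()[0] else None
        try:
            raw = np.loadtxt(io.StringIO(text), delimiter=delim, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: could not parse as a numeric matrix: {exc}") from exc
    elif dialect == "mat":
        from scipy.io import loadmat

        contents = {k: v for k, v in loadmat(path).items() if not k.startswith("__")}
        arrays = [v for v in contents.values() if isinstance(v, np.ndarray) and v.ndim == 2]
        if len(arrays) != 1:
            raise FormatError(
                f"{path}: expected exactly one 2-D array in MAT container, "
                f"found {len(arrays)} (variables: {sorted(contents)})"
            )
        raw = arrays[0]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _sanitize(raw, sid)


def write_connectivity_matrix(matrix: ConnectivityMatrix, path: str | os.PathLike) -> None:
    """Write the weight matrix as tab-delimited text at 12 significant digits."""
    np.savetxt(path, matrix.weights, fmt="%.12g", delimiter="\t")


def read_roi_table(path: str | os.PathLike) -> ROITable:
    """Read a delimited ROI table with columns ``id, name[, hemisphere]``.

    Ids must be unique and contiguous from 1; names must be unique.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("ROI table needs at least two columns: id, name")
    ids = df.iloc[:, 0].to_numpy()
    names = [str(x) for x in df.iloc[:, 1]]
    if len(set(ids.tolist())) != len(ids):
        raise ValidationError("duplicate ROI ids")
    order = np.argsort(ids)
    ids, names = ids[order], [names[i] for i in order]
    expected = np.arange(1, len(ids) + 1)
    if not np.array_equal(ids, expected):
        missing = sorted(set(expected.tolist()) - set(ids.tolist()))
        raise ValidationError(f"ROI ids not contiguous from 1: missing {missing}")
    hemis = None
    if df.shape[1] >= 3:
        hemis = tuple(str(x) for x in df.iloc[:, 2].to_numpy()[order])
    return ROITable(tuple(names), hemis)


def read_group_manifest(path: str | os.PathLike) -> dict[str, SubjectGroup]:
    """Read a cohort manifest (``subject_id, group, path``) and load all matrices.

    Relative matrix paths are resolved against the manifest's directory.
    Returns one :class:`SubjectGroup` per group label, members in manifest
    order.
    """
    path = os.fspath(path)
    df = pd.read_csv(path)
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}")
    base = os.path.dirname(os.path.abspath(path))
    groups: dict[str, list[ConnectivityMatrix]] = {}
    for row in df.itertuples(index=False):
        mpath = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        m = read_connectivity_matrix(mpath, subject_id=str(row.subject_id))
        groups.setdefault(str(row.group), []).append(m)
    return {label: SubjectGroup(label, tuple(ms)) for label, ms in groups.items()}


_PAIR_COLUMNS = [
    "roi_i",
    "roi_j",
    "mean_angle_group1",
    "mean_angle_group2",
    "delta",
    "t",
    "df",
    "p",
    "direction",
    "passed_filter",
]


def write_pair_results(result, path: str | os.PathLike) -> None:
    """Serialize a pairwise :class:`~eigenalign.stats.ComparisonResult`.

    Long-format TSV with one row per tested ROI pair (i < j, ascending,
    1-based ids), 12 significant digits on all floats. Pairs excluded by
    the eligibility filter are not listed.
    """
    rows = []
    for i, j in result.tested_pairs():
        r = result.pair(i, j)
        rows.append(
            [
                i + 1,
                j + 1,
                f"{r.mean_a:.12g}",
                f"{r.mean_b:.12g}",
                f"{r.mean_diff:.12g}",
                f"{r.t:.12g}",
                f"{r.df:.12g}",
                f"{r.p:.12g}",
                result.direction_label(i, j),
                "yes",
            ]
        )
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pair_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a pair-results TSV written by :func:`write_pair_results`."""
    return pd.read_csv(path, sep="\t")
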