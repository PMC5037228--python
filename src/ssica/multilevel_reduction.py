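"""Three-level PCA/whitening reduction for multi-group spatial ICA.

Multi-subject spatial ICA operates on time-by-voxel matrices. Before the
unmixing step the data pass through three linear reduction levels:

1. *subject* level -- each subject's demeaned series is projected onto its
   top principal temporal directions (PCA only, no whitening; the projection
   ``F`` keeps the level well-conditioned and mirrors common group-ICA
   practice),
2. *group* level -- the temporally concatenated subject-reduced data of each
   group is PCA-reduced **and whitened** by ``H_j``,
3. *aggregate* level -- the two groups' whitened matrices are stacked
   row-wise and whitened again by ``G`` down to the number of components
   ``N`` to extract.

Every level stores both the forward projector and its Moore-Penrose inverse
so that group-level results can be propagated back to single subjects.
Covariances are estimated across voxels (rows = time/PC dimensions,
columns = voxels, divisor ``M - 1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

_RANK_RTOL = 1e-10  # relative eigenvalue cutoff defining numerical rank


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SubjectSeries:
    """One subject's (optionally run-concatenated) time-by-voxel matrix.

    ``data`` has shape ``(T, M)``: ``T`` time points by ``M`` in-mask voxels.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str
    group_id: str
    run_id: str = "run1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (T x M), got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("a series needs at least 2 time points")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class ReductionLevel:
    """One linear reduction step: ``forward`` projector and its pseudo-inverse."""

    forward: np.ndarray        # (out_dim, in_dim)
    backward: np.ndarray       # (in_dim, out_dim), Moore-Penrose inverse of forward
    explained_variance_fraction: float
    whitened: bool

    @property
    def out_dim(self) -> int:
        return self.forward.shape[0]

    @property
    def in_dim(self) -> int:
        return self.forward.shape[1]


@dataclass
class ReducedDataset:
    """The full three-level reduction plus the bookkeeping needed to invert it.

    ``row_index`` maps each subject id to ``(group_id, slice)`` where the
    slice addresses that subject's row block inside its group's stacked
    level-2 *input* matrix. ``X_subject`` keeps each subject's level-1
    output (the input to level 2), which back-reconstruction consumes.
    """

    subject_levels: dict[str, ReductionLevel]
    group_levels: dict[str, ReductionLevel]
    aggregate_level: ReductionLevel
    X: np.ndarray                       # (N, M) final whitened data
    X_group: dict[str, np.ndarray]      # group -> (Ng_j, M) level-2 output
    X_subject: dict[str, np.ndarray]    # subject -> (T_j, M) level-1 output
    row_index: dict[str, tuple[str, slice]]
    dims: dict[str, int]                # N, Ng per group, T_j per subject
    group_ids: tuple[str, str]
    series: list[SubjectSeries] = field(default_factory=list)  # demeaned input

    @property
    def n_components_space(self) -> int:
        return self.X.shape[0]

    def group_block_slices(self) -> dict[str, slice]:
        """Row blocks of each group inside the stacked level-3 input."""
        g1, g2 = self.group_ids
        ng1 = self.X_group[g1].shape[0]
        ng2 = self.X_group[g2].shape[0]
        return {g1: slice(0, ng1), g2: slice(ng1, ng1 + ng2)}

    def subjects_of(self, group_id: str) -> list[str]:
        return [s for s, (g, _) in self.row_index.items() if g == group_id]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def demean_series(series: SubjectSeries) -> SubjectSeries:
    """Remove the temporal mean of every voxel time course."""
    if not np.all(np.isfinite(series.data)):
        raise ValueError(
            f"series {series.subject_id!r} contains non-finite values; "
            "clean the input before reduction"
        )
    return replace(series, data=series.data - series.data.mean(axis=0, keepdims=True))


def _fix_eigvec_signs(vecs: np.ndarray) -> np.ndarray:
    # PCA sign ambiguity: make the largest-magnitude entry of each eigenvector
    # positive so repeated fits are bit-identical.
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _pca_over_voxels(data: np.ndarray, n_keep: int):
    """Eigendecomposition of the row-space covariance ``data @ data.T / (M-1)``.

    Returns (eigvals_desc, eigvecs_desc, total_variance, numerical_rank).
    """
    m = data.shape[1]
    cov = data @ data.T / (m - 1)
    vals, vecs = np.linalg.eigh(cov)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    vals = np.clip(vals, 0.0, None)
    total = float(vals.sum())
    if total <= 0:
        raise ValueError("data has zero variance; cannot fit a reduction")
    rank = int(np.sum(vals > _RANK_RTOL * vals[0]))
    vecs = _fix_eigvec_signs(vecs)
    return vals, vecs, total, rank


def fit_subject_reduction(series: SubjectSeries, target_dim: int) -> ReductionLevel:
    """Level-1 PCA of one subject's series (projection only, no whitening)."""
    t = series.n_timepoints
    if target_dim < 1:
        raise ValueError(f"target_dim must be positive, got {target_dim}")
    if target_dim > t:
        raise ValueError(
            f"target_dim {target_dim} exceeds the series' {t} time points"
        )
    vals, vecs, total, rank = _pca_over_voxels(series.data, target_dim)
    if target_dim > rank:
        logger.warning(
            "subject %s: requested %d dims but numerical rank is %d; truncating",
            series.subject_id, target_dim, rank,
        )
        target_dim = rank
    e = vecs[:, :target_dim]
    forward = e.T                       # (k, T); orthonormal rows
    backward = e                        # pinv of an orthonormal-row matrix
    evf = float(vals[:target_dim].sum() / total)
    return ReductionLevel(forward, backward, evf, whitened=False)


def _fit_whitening(stacked: np.ndarray, n_out: int, what: str) -> ReductionLevel:
    rows = stacked.shape[0]
    if n_out < 1:
        raise ValueError(f"{what}: output dimension must be positive, got {n_out}")
    if n_out > rows:
        raise ValueError(
            f"{what}: requested {n_out} dims from a {rows}-row matrix"
        )
    vals, vecs, total, rank = _pca_over_voxels(stacked, n_out)
    if n_out > rank:
        raise ValueError(
            f"{what}: requested {n_out} dims but the matrix rank is {rank}"
        )
    e = vecs[:, :n_out]
    lam = vals[:n_out]
    forward = (e / np.sqrt(lam)).T      # (n_out, rows)
    backward = e * np.sqrt(lam)         # (rows, n_out); exact pinv of forward
    evf = float(lam.sum() / total)
    return ReductionLevel(forward, backward, evf, whitened=True)


def fit_group_whitening(stacked: np.ndarray, ng: int) -> ReductionLevel:
    """Level-2 PCA + whitening of one group's concatenated subject-reduced data.

    The output ``H_j @ stacked`` has identity covariance across voxels. The
    PCA subspace does not depend on the order of the subject blocks.
    """
    return _fit_whitening(np.asarray(stacked, dtype=float), ng, "group whitening")


def fit_aggregate_whitening(x1: np.ndarray, x2: np.ndarray, n: int) -> ReductionLevel:
    """Level-3 whitening of the row-stacked group matrices down to ``n`` rows."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape[1] != x2.shape[1]:
        raise ValueError(
            f"group matrices disagree on voxel count: {x1.shape[1]} vs {x2.shape[1]}"
        )
    if n > x1.shape[0] + x2.shape[0]:
        raise ValueError(
            f"requested {n} aggregate dims from {x1.shape[0]} + {x2.shape[0]} rows"
        )
    return _fit_whitening(np.vstack([x1, x2]), n, "aggregate whitening")


def build_reduction(
    dataset: list[SubjectSeries],
    dims: tuple[int, int, int, int],
) -> ReducedDataset:
    """Compose the three reduction levels over a two-group dataset.

    ``dims = (subject_dim, ng1, ng2, n)``. Groups are taken in sorted order
    of their ids; within a group, subjects keep their order of appearance.
    """
    subject_dim, ng1, ng2, n = dims
    if n > ng1 + ng2:
        raise ValueError(f"n={n} exceeds ng1+ng2={ng1 + ng2}")
    group_ids = sorted({s.group_id for s in dataset})
    if len(group_ids) != 2:
        raise ValueError(
            f"exactly two groups are required, got {len(group_ids)}: {group_ids}"
        )
    voxel_counts = {s.n_voxels for s in dataset}
    if len(voxel_counts) != 1:
        raise ValueError(f"inconsistent voxel counts across subjects: {voxel_counts}")

    by_group: dict[str, list[SubjectSeries]] = {g: [] for g in group_ids}
    for s in dataset:
        by_group[s.group_id].append(s)
    for g, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has {len(members)} subject(s); need >= 2")

    subject_levels: dict[str, ReductionLevel] = {}
    x_subject: dict[str, np.ndarray] = {}
    row_index: dict[str, tuple[str, slice]] = {}
    demeaned: list[SubjectSeries] = []
    per_subject_t: dict[str, int] = {}

    group_levels: dict[str, ReductionLevel] = {}
    x_group: dict[str, np.ndarray] = {}
    ng_for = {group_ids[0]: ng1, group_ids[1]: ng2}
    for g in group_ids:
        blocks = []
        offset = 0
        for s in by_group[g]:
            ds = demean_series(s)
            demeaned.append(ds)
            lvl = fit_subject_reduction(ds, subject_dim)
            subject_levels[s.subject_id] = lvl
            xs = lvl.forward @ ds.data
            x_subject[s.subject_id] = xs
            row_index[s.subject_id] = (g, slice(offset, offset + lvl.out_dim))
            per_subject_t[s.subject_id] = lvl.out_dim
            offset += lvl.out_dim
            blocks.append(xs)
        stacked = np.vstack(blocks)
        lvl2 = fit_group_whitening(stacked, ng_for[g])
        group_levels[g] = lvl2
        x_group[g] = lvl2.forward @ stacked

    lvl3 = fit_aggregate_whitening(x_group[group_ids[0]], x_group[group_ids[1]], n)
    x = lvl3.forward @ np.vstack([x_group[group_ids[0]], x_group[group_ids[1]]])

    dims_out = {"N": n, f"Ng_{group_ids[0]}": ng_for[group_ids[0]],
                f"Ng_{group_ids[1]}": ng_for[group_ids[1]]}
    dims_out.update({f"T_{k}": v for k, v in per_subject_t.items()})
    return ReducedDataset(
        subject_levels=subject_levels,
        group_levels=group_levels,
        aggregate_level=lvl3,
        X=x,
        X_group=x_group,
        X_subject=x_subject,
        row_index=row_index,
        dims=dims_out,
        group_ids=(group_ids[0], group_ids[1]),
        series=demeaned,
    )


def build_gica_reduction(
    dataset: list[SubjectSeries],
    subject_dim: int,
    n: int,
) -> ReducedDataset:
    """Two-level reduction (subject PCA then aggregate whitening) for the
    unconstrained group-ICA baseline.

    The group level is the identity, so the same back-reconstruction chain
    applies: the aggregate backward operator's subject row blocks play the
    role the group backward operator plays in the three-level reduction.
    """
    group_ids = sorted({s.group_id for s in dataset})
    if len(group_ids) != 2:
        raise ValueError("two groups are required (labels are kept for evaluation)")
    by_group: dict[str, list[SubjectSeries]] = {g: [] for g in group_ids}
    for s in dataset:
        by_group[s.group_id].append(s)

    subject_levels: dict[str, ReductionLevel] = {}
    x_subject: dict[str, np.ndarray] = {}
    row_index: dict[str, tuple[str, slice]] = {}
    demeaned: list[SubjectSeries] = []
    x_group: dict[str, np.ndarray] = {}
    group_levels: dict[str, ReductionLevel] = {}

    for g in group_ids:
        blocks = []
        offset = 0
        for s in by_group[g]:
            ds = demean_series(s)
            demeaned.append(ds)
            lvl = fit_subject_reduction(ds, subject_dim)
            subject_levels[s.subject_id] = lvl
            xs = lvl.forward @ ds.data
            x_subject[s.subject_id] = xs
            row_index[s.subject_id] = (g, slice(offset, offset + lvl.out_dim))
            offset += lvl.out_dim
            blocks.append(xs)
        stacked = np.vstack(blocks)
        ident = np.eye(stacked.shape[0])
        group_levels[g] = ReductionLevel(ident, ident.copy(), 1.0, whitened=False)
        x_group[g] = stacked

    lvl3 = fit_aggregate_whitening(x_group[group_ids[0]], x_group[group_ids[1]], n)
    x = lvl3.forward @ np.vstack([x_group[group_ids[0]], x_group[group_ids[1]]])
    dims_out = {"N": n, f"Ng_{group_ids[0]}": x_group[group_ids[0]].shape[0],
                f"Ng_{group_ids[1]}": x_group[group_ids[1]].shape[0]}
    return ReducedDataset(
        subject_levels=subject_levels,
        group_levels=group_levels,
        aggregate_level=lvl3,
        X=x,
        X_group=x_group,
        X_subject=x_subject,
        row_index=row_index,
        dims=dims_out,
        group_ids=(group_ids[0], group_ids[1]),
        series=demeaned,
    )
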