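"""Back-reconstruction of group components to single subjects, PVAF, and
group-level statistics.

The reduction chain is linear, so the contribution of subject ``i`` (group
``j``) to the group decomposition is obtained by walking the backward
operators: the subject-specific mixing matrix is

    M_ij = B_ij @ D_j @ A

where ``D_j`` is the group-``j`` row block of the aggregate back-projector
``G+``, ``B_ij`` is the subject-``i`` row block of the group back-projector
``H_j+``, and ``A`` is the aggregate mixing matrix. Subject spatial maps are
the least-squares solution ``pinv(M_ij) @ X_ij`` against the subject's
level-1-reduced data, and subject time courses live in the original time
domain through the subject back-projector ``F_ij+``.

PVAF (percent variance accounted for) of component ``c`` in subject ``ij``
is ``(1 - var(Y_ij - Yhat_c) / var(Y_ij)) * 100`` with ``Yhat_c`` the
single-component reconstruction and ``var`` the average over time points of
the across-voxel variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .multilevel_reduction import ReducedDataset, SubjectSeries
from .ssica_engine import SSICAResult

logger = logging.getLogger(__name__)


@dataclass
class SubjectComponent:
    spatial_map: np.ndarray
    timecourse: np.ndarray
    pvaf_percent: float
    component_id: int
    subject_id: str
    group_id: str


@dataclass
class GroupStatMap:
    t_values: np.ndarray
    df: int
    kind: str                       # "one_sample" | "two_sample"
    threshold_applied: float | None = None
    mask_ref: str | None = None


# ---------------------------------------------------------------------------
# back-reconstruction chain
# ---------------------------------------------------------------------------

def subject_mixing(result: SSICAResult, reduction: ReducedDataset, subject_id: str) -> np.ndarray:
    """Subject-specific mixing matrix ``M_ij = B_ij @ D_j @ A`` (``T_j x N``)."""
    if subject_id not in reduction.row_index:
        raise KeyError(f"unknown subject {subject_id!r}")
    group_id, rows = reduction.row_index[subject_id]
    d_j = reduction.aggregate_level.backward[reduction.group_block_slices()[group_id]]
    b_ij = reduction.group_levels[group_id].backward[rows]
    return b_ij @ d_j @ result.mixing


def back_reconstruct_subject(
    result: SSICAResult,
    reduction: ReducedDataset,
    subject_id: str,
    compute_pvaf: bool = True,
) -> list[SubjectComponent]:
    """Per-subject component maps and original-domain time courses."""
    m_ij = subject_mixing(result, reduction, subject_id)
    group_id, _ = reduction.row_index[subject_id]
    x_ij = reduction.X_subject[subject_id]
    rank = np.linalg.matrix_rank(m_ij)
    if rank < min(m_ij.shape):
        logger.warning(
            "subject %s: mixing matrix rank %d < %d; using tolerance pseudo-inverse",
            subject_id, rank, min(m_ij.shape),
        )
    maps = np.linalg.pinv(m_ij) @ x_ij                       # (N, M)
    f_back = reduction.subject_levels[subject_id].backward    # (T_orig, T_j)
    tcs = f_back @ m_ij                                       # (T_orig, N)
    series = {s.subject_id: s for s in reduction.series}.get(subject_id)
    out = []
    for c in range(maps.shape[0]):
        p = float("nan")
        if compute_pvaf and series is not None:
            p = pvaf(series.data, component_projection(result, reduction, subject_id, c))
        out.append(SubjectComponent(maps[c], tcs[:, c], p, c, subject_id, group_id))
    return out


def component_projection(
    result: SSICAResult,
    reduction: ReducedDataset,
    subject_id: str,
    c: int,
) -> np.ndarray:
    """Original-domain reconstruction of subject data from component ``c``
    alone: ``F_ij+ @ B_ij @ D_j @ A_c @ S`` with all other mixing columns
    zeroed (rank-one, computed as an outer product)."""
    n = result.sources.shape[0]
    if not 0 <= c < n:
        raise IndexError(f"component {c} out of range [0, {n})")
    m_ij = subject_mixing(result, reduction, subject_id)
    f_back = reduction.subject_levels[subject_id].backward
    tc = f_back @ m_ij[:, c]                                  # (T_orig,)
    return np.outer(tc, result.sources[c])


def pvaf(y, yhat_c: np.ndarray) -> float:
    """Percent variance accounted for by one component's reconstruction."""
    if isinstance(y, SubjectSeries):
        y = y.data
    y = np.asarray(y, dtype=float)
    yhat_c = np.asarray(yhat_c, dtype=float)
    if y.shape != yhat_c.shape:
        raise ValueError(f"shape mismatch: data {y.shape} vs reconstruction {yhat_c.shape}")

    def _var(a: np.ndarray) -> float:
        # average over time points of the across-voxel variance
        return float(np.mean(np.var(a, axis=1, ddof=1)))

    vy = _var(y)
    if vy == 0.0:
        raise ValueError("data has zero variance; PVAF undefined")
    return (1.0 - _var(y - yhat_c) / vy) * 100.0


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def _zero_variance_guard(t: np.ndarray, where: np.ndarray) -> np.ndarray:
    if where.any():
        warnings.warn(
            f"{int(where.sum())} zero-variance voxel(s); t set to 0 there",
            RuntimeWarning, stacklevel=3,
        )
        t = np.where(where, 0.0, t)
    return t


def one_sample_tmap(maps: list[np.ndarray] | np.ndarray) -> GroupStatMap:
    """Voxel-wise one-sample t statistic ``mean / (sd / sqrt(n))``, df = n-1."""
    a = np.asarray(maps, dtype=float)
    n = a.shape[0]
    if n < 2:
        raise ValueError("one-sample t needs at least 2 maps")
    sd = a.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = a.mean(axis=0) / (sd / np.sqrt(n))
    return GroupStatMap(_zero_variance_guard(t, zero), df=n - 1, kind="one_sample")


def two_sample_tmap(maps_g1, maps_g2) -> GroupStatMap:
    """Voxel-wise pooled-variance two-sample t, df = n1 + n2 - 2."""
    a = np.asarray(maps_g1, dtype=float)
    b = np.asarray(maps_g2, dtype=float)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 maps, got {n1} and {n2}")
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    zero = sp2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return GroupStatMap(_zero_variance_guard(t, zero), df=n1 + n2 - 2, kind="two_sample")


def tmap_pvalues(stat_map: GroupStatMap) -> np.ndarray:
    """Two-sided p-values of a t-map."""
    return 2.0 * stats.t.sf(np.abs(stat_map.t_values), stat_map.df)


# ---------------------------------------------------------------------------
# network time courses and spectral power
# ---------------------------------------------------------------------------

def network_timecourse(series: SubjectSeries, network_map: np.ndarray) -> np.ndarray:
    """Spatial regression of each time point's data on a network map: one
    least-squares coefficient per time point (the network's time course)."""
    m = np.asarray(network_map, dtype=float)
    denom = float(m @ m)
    if denom == 0.0:
        raise ValueError("network map is identically zero")
    return series.data @ m / denom


def band_power(tc: np.ndarray, tr_seconds: float, band: tuple[float, float]) -> float:
    """Hamming-windowed periodogram power inside ``band`` (Hz)."""
    lo, hi = band
    fs = 1.0 / tr_seconds
    nyquist = fs / 2.0
    if hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {nyquist} Hz")
    tc = np.asarray(tc, dtype=float)
    freqs, psd = signal.periodogram(tc, fs=fs, window="hamming", detrend=False)
    sel = (freqs >= lo) & (freqs <= hi)
    df = freqs[1] - freqs[0]
    return float(psd[sel].sum() * df)
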