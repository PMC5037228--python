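"""Scoring of extracted components against planted ground truth.

Spatial maps are compared after Z-scoring (demean / unit-sd over mask
voxels) and thresholding at |Z| > 2.3: RMSE and squared Pearson correlation
r^2 quantify reconstruction, greedy one-to-one matching by descending r^2
pairs truths with components. Two purpose-built ratios diagnose capacity
mismatches:

* similarity ratio r1 / sqrt(r1^2 + r2^2) -- which of two true specific
  patches (strong r1 vs weak r2 correlation) an extracted specific
  component represents, binned low [0, 0.2) / middle / high (0.8, 1];
* splitting factor max_l mean(Z_l,weak) / (mean(Z_l,weak) + mean(Z_l,strong))
  over blobs l -- noise (~0), repetition (~0.5) or split (~1) regime when
  more specific components are allowed than exist.

The shared/specific classification ROC treats *shared* as the positive
class; the optimal operating point minimizes fpr^2 + fnr^2. A reliability
clustering (average-linkage on pairwise spatial correlation) summarizes
specific components recurring across repeated runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .reconstruction_stats import GroupStatMap, tmap_pvalues

Z_THRESHOLD_DEFAULT = 2.3

SIMILARITY_BINS = ((0.0, 0.2), (0.2, 0.8), (0.8, 1.0))  # low / middle / high


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]      # (truth_id, component_id, r2)
    unmatched_truths: list[int]
    method: str = "best_r2"

    def r2_of(self, truth_id: int) -> float:
        for t, _, r2 in self.pairs:
            if t == truth_id:
                return r2
        return 0.0

    def component_of(self, truth_id: int) -> int | None:
        for t, c, _ in self.pairs:
            if t == truth_id:
                return c
        return None


@dataclass
class ROCCurve:
    points: list[tuple[float, float, float]]  # (threshold, fpr, tpr)
    optimal: tuple[float, float, float]       # (fpr, fnr, threshold)
    positive_class: str = "shared"


@dataclass
class ClusterSet:
    clusters: list[list[int]]
    representatives: list[np.ndarray]
    similarity_threshold: float


@dataclass
class EvalRecord:
    """Per-matched-component metrics feeding ROC curves and histograms."""
    truth_id: int
    component_id: int | None
    rmse: float
    r2: float
    true_label: str
    predicted_label: str
    similarity_ratio: float | None = None
    splitting_factor: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# map preprocessing and similarity
# ---------------------------------------------------------------------------

def zscore_threshold(map_vec: np.ndarray, mask: np.ndarray | None = None,
                     z_thr: float = Z_THRESHOLD_DEFAULT) -> np.ndarray:
    """Z-score a masked spatial map and zero sub-threshold voxels.

    ``mask`` is an optional boolean selector over entries (all true by
    default); out-of-mask entries are zeroed in the output.
    """
    v = np.asarray(map_vec, dtype=float)
    m = np.ones_like(v, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    vals = v[m]
    sd = vals.std()
    if sd == 0:
        raise ValueError("map has zero variance within the mask; cannot Z-score")
    z = np.zeros_like(v)
    z[m] = (vals - vals.mean()) / sd
    z[np.abs(z) <= z_thr] = 0.0
    return z


def map_similarity(s_p: np.ndarray, s_tilde: np.ndarray) -> tuple[float, float]:
    """(RMSE, r^2) between two already Z-scored/thresholded maps."""
    a = np.asarray(s_p, dtype=float)
    b = np.asarray(s_tilde, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"maps disagree in size: {a.shape} vs {b.shape}")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if not a.any() or not b.any():
        warnings.warn("all-zero map after thresholding; r2 set to 0", RuntimeWarning,
                      stacklevel=2)
        return rmse, 0.0
    r = np.corrcoef(a, b)[0, 1]
    if np.isnan(r):
        return rmse, 0.0
    return rmse, float(r**2)


def match_to_truth(components: list[np.ndarray], truths: list[np.ndarray],
                   z_thr: float = Z_THRESHOLD_DEFAULT,
                   preprocess: bool = True) -> MatchResult:
    """Greedy one-to-one assignment of components to truths by descending r^2."""
    if len(components) == 0:
        raise ValueError("no components to match")

    def prep(m):
        if not preprocess:
            return np.asarray(m, dtype=float)
        try:
            return zscore_threshold(m, z_thr=z_thr)
        except ValueError:
            return np.zeros_like(np.asarray(m, dtype=float))

    cs = [prep(c) for c in components]
    ts = [prep(t) for t in truths]
    scored = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for ti, t in enumerate(ts):
            for ci, c in enumerate(cs):
                _, r2 = map_similarity(t, c)
                scored.append((r2, ti, ci))
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    pairs = []
    for r2, ti, ci in scored:
        if ti in used_t or ci in used_c:
            continue
        pairs.append((ti, ci, float(r2)))
        used_t.add(ti)
        used_c.add(ci)
    pairs.sort()
    unmatched = [ti for ti in range(len(ts)) if ti not in used_t]
    return MatchResult(pairs=pairs, unmatched_truths=unmatched)


# ---------------------------------------------------------------------------
# capacity-mismatch diagnostics
# ---------------------------------------------------------------------------

def similarity_ratio(r1: float, r2: float) -> float:
    """``r1 / sqrt(r1^2 + r2^2)`` with r1 (r2) the spatial correlation to the
    strong (weak) simulated patch."""
    if r1 < 0 or r2 < 0:
        raise ValueError("correlations must be non-negative (use |r| or r^2-derived r)")
    if r1 == 0 and r2 == 0:
        raise ValueError("similarity ratio undefined when both correlations are 0")
    return float(r1 / np.hypot(r1, r2))


def similarity_ratio_bin(value: float) -> str:
    if value < 0.2:
        return "low"
    if value <= 0.8:
        return "middle"
    return "high"


def splitting_factor(weak_map: np.ndarray, strong_map: np.ndarray,
                     blobs: list[np.ndarray]) -> float:
    """Blob-wise weak/(weak+strong) mean-Z ratio, maximized over blobs.

    ``blobs`` are boolean supports (jitter-free truth geometry) over the same
    masked-voxel vector as the two thresholded Z-maps. Negative blob means
    are floored at zero; blobs with a zero denominator are skipped.
    """
    weak = np.asarray(weak_map, dtype=float)
    strong = np.asarray(strong_map, dtype=float)
    ratios = []
    for sup in blobs:
        sup = np.asarray(sup, dtype=bool)
        mw = max(float(weak[sup].mean()), 0.0) if sup.any() else 0.0
        ms = max(float(strong[sup].mean()), 0.0) if sup.any() else 0.0
        denom = mw + ms
        if denom == 0:
            continue
        ratios.append(mw / denom)
    if not ratios:
        raise ValueError("every blob had a zero denominator; splitting factor undefined")
    return float(max(ratios))


# ---------------------------------------------------------------------------
# classification / ROC
# ---------------------------------------------------------------------------

def gica_label_by_diffmap(tmap: GroupStatMap, alpha: float,
                          voxel_count_threshold: int) -> str:
    """Baseline classifier: a component is called specific when its
    between-group difference t-map has at least ``voxel_count_threshold``
    voxels significant at ``alpha`` (two-sided), the side given by the
    dominant t sign among those voxels; otherwise shared."""
    p = tmap_pvalues(tmap)
    sig = p < alpha
    if int(sig.sum()) < voxel_count_threshold:
        return "shared"
    side_t = tmap.t_values[sig].sum() if sig.any() else 0.0
    return "specific_g1" if side_t >= 0 else "specific_g2"


def roc_and_optimal(runs: list[tuple[float, list[str], list[str]]]) -> ROCCurve:
    """ROC over classification runs at different thresholds.

    Positive class = shared: per threshold, tpr = P(predict shared | true
    shared) and fpr = P(predict shared | true specific); the optimal point
    minimizes fpr^2 + fnr^2.
    """
    points = []
    best = None
    for thr, true_labels, pred_labels in runs:
        true_pos = [p for t, p in zip(true_labels, pred_labels) if t == "shared"]
        true_neg = [p for t, p in zip(true_labels, pred_labels) if t != "shared"]
        if not true_pos:
            raise ValueError("no true-shared (positive) labels in a run")
        if not true_neg:
            raise ValueError("no true-specific (negative) labels in a run")
        tpr = sum(p == "shared" for p in true_pos) / len(true_pos)
        fpr = sum(p == "shared" for p in true_neg) / len(true_neg)
        points.append((float(thr), float(fpr), float(tpr)))
        fnr = 1.0 - tpr
        cost = fpr**2 + fnr**2
        if best is None or cost < best[0]:
            best = (cost, fpr, fnr, float(thr))
    if best is None:
        raise ValueError("no runs supplied")
    return ROCCurve(points=points, optimal=(best[1], best[2], best[3]))


# ---------------------------------------------------------------------------
# reliability clustering
# ---------------------------------------------------------------------------

def cluster_specific_components(maps: list[np.ndarray],
                                sim_threshold: float) -> ClusterSet:
    """Average-linkage agglomerative clustering on pairwise spatial
    correlation, cut at ``sim_threshold``; each cluster's representative is
    the voxel-wise mean of its members, re-Z-scored (unthresholded)."""
    if len(maps) < 2:
        raise ValueError("clustering needs at least 2 maps")
    arr = np.asarray(maps, dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(z, t=1.0 - sim_threshold, criterion="distance")
    clusters = [sorted(np.nonzero(assign == k)[0].tolist())
                for k in sorted(set(assign))]
    reps = []
    for members in clusters:
        mean_map = arr[members].mean(axis=0)
        reps.append(zscore_threshold(mean_map, z_thr=0.0))
    return ClusterSet(clusters=clusters, representatives=reps,
                      similarity_threshold=sim_threshold)
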