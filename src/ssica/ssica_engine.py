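"""Constrained fixed-point ICA with shared / group-specific components.

The engine decomposes the whitened aggregate data ``X`` (``N x M``) into
``N`` spatially independent components while labeling each component as
*shared* (present in both groups) or *specific* to one group. A specific
component's mixing column, expressed in the level-2 (group-stacked)
coordinates via the aggregate back-projector ``G+``, must have (near) zero
energy in the opposite group's row block.

Because the unmixing matrix is orthonormal on white data, the aggregate
mixing column of component ``c`` equals its unmixing row ``w_c``, so the
group constraint is a linear constraint ``C_opp w_c = 0`` with ``C_opp``
the opposite group's row block of ``G+``. The algorithm alternates:

1. one symmetric FastICA fixed-point update (tanh or pow3 contrast),
2. re-labeling — at the first constrained iteration from per-subject PVAF
   t-tests, afterwards from the opposite-block energy fraction of the
   mixing columns,
3. constraint enforcement — each specific row is orthogonally projected
   onto its feasible subspace and the whole matrix is re-orthonormalized in
   an order (specific-g1, specific-g2, shared) that keeps the constraints
   exact.

The feasible subspace for group-1-specific components, ``null(C_g2)``, has
dimension ``N - Ng2``, which is exactly the model's cap ``M1`` on the number
of group-1-specific components (symmetrically ``M2 = N - Ng1``). If a
projection annihilates a row, or the constraint residual is still large at
convergence, the component is demoted to shared — the algorithm may end up
extracting fewer specific components than allowed, down to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .multilevel_reduction import ReducedDataset

logger = logging.getLogger(__name__)

SHARED = "shared"

_DEMOTE_NORM = 1e-8   # projected-row norm below which a specific row is demoted
_FREEZE_FRACTION = 0.9  # labels frozen for the last 10% of iterations
_RELABEL_BURN_IN = 10   # constrained iterations run on the PVAF labels before
                        # mixing-based re-labeling takes over (the first steps
                        # after projection are transient and not informative)
_DEMOTE_FRACTION = 0.45  # hysteresis: an enforced specific component is only
                         # demoted when its post-update opposite fraction rises
                         # near the ~0.5 equilibrium of a shared component;
                         # without the gap labels oscillate around theta and
                         # the fixed point never settles


def _specific_label(group_id: str) -> str:
    return f"specific_{group_id}"


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class SSICAConfig:
    n_components: int
    max_specific: tuple[int, int] = (0, 0)      # (M1, M2)
    classification_threshold: float = 0.1       # theta on the opposite-energy fraction
    pvaf_alpha_base: float = 0.05               # Bonferroni base: alpha = base / N
    nonlinearity: str = "tanh"                  # "tanh" or "pow3"
    convergence_tol: float = 1e-6
    constraint_tol: float = 1e-4
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nonlinearity not in ("tanh", "pow3"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if not 0.0 <= self.classification_threshold <= 1.0:
            raise ValueError("classification_threshold must be in [0, 1]")

    def validate_against(self, reduction: ReducedDataset) -> None:
        g1, g2 = reduction.group_ids
        ng1 = reduction.X_group[g1].shape[0]
        ng2 = reduction.X_group[g2].shape[0]
        n = self.n_components
        m1, m2 = self.max_specific
        if n != reduction.X.shape[0]:
            raise ValueError(
                f"config n_components={n} but reduction produced {reduction.X.shape[0]} rows"
            )
        if m1 > max(n - ng2, 0) or m2 > max(n - ng1, 0):
            raise ValueError(
                f"max_specific {self.max_specific} exceeds the model caps "
                f"(M1 <= N-Ng2 = {n - ng2}, M2 <= N-Ng1 = {n - ng1})"
            )


@dataclass
class SSICAResult:
    unmixing: np.ndarray                 # W, (N, N), orthonormal
    mixing: np.ndarray                   # A = W.T in aggregate space
    mixing_group_blocks: dict[str, np.ndarray]  # group -> (Ng_j, N) level-2 blocks
    sources: np.ndarray                  # S = W @ X, (N, M)
    labels: list[str]
    constraint_residuals: np.ndarray     # per-component opposite-block fraction
    iterations: int
    converged: bool

    def specific_indices(self, group_id: str | None = None) -> list[int]:
        if group_id is None:
            return [i for i, l in enumerate(self.labels) if l != SHARED]
        want = _specific_label(group_id)
        return [i for i, l in enumerate(self.labels) if l == want]


@dataclass
class LabelDecision:
    component_id: int
    pvaf_g1_values: list[float]
    pvaf_g2_values: list[float]
    t_statistic: float
    p_value: float
    assigned: str = SHARED


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def opposite_energy_fraction(
    mixing_column: np.ndarray,
    target_group: str,
    block_slices: dict[str, slice],
) -> float:
    """Squared-energy fraction of a level-2 mixing column in the *opposite*
    group's row block (0 = perfectly specific to ``target_group``)."""
    col = np.asarray(mixing_column, dtype=float)
    total = float(col @ col)
    if total == 0.0:
        raise ValueError("zero mixing column has no defined energy fraction")
    opp = [g for g in block_slices if g != target_group]
    if len(opp) != 1:
        raise ValueError(f"need exactly 2 groups, got {list(block_slices)}")
    e = col[block_slices[opp[0]]]
    return float(e @ e) / total


def classify_by_mixing(
    blocks: dict[str, np.ndarray],
    theta: float,
    caps: dict[str, int],
) -> list[str]:
    """Label each component from its level-2 mixing-column block energies.

    A component is a candidate specific to group g when the opposite block
    holds strictly less than ``theta`` of its column energy. If both groups
    qualify the smaller fraction wins (exact tie -> shared); per-group
    candidates beyond the cap are dropped keeping the smallest fractions.
    ``theta = 0`` labels everything shared.
    """
    groups = list(blocks)
    if len(groups) != 2:
        raise ValueError("classify_by_mixing needs exactly two groups")
    n = blocks[groups[0]].shape[1]
    cols = np.vstack([blocks[groups[0]], blocks[groups[1]]])
    slices = {groups[0]: slice(0, blocks[groups[0]].shape[0]),
              groups[1]: slice(blocks[groups[0]].shape[0], cols.shape[0])}
    labels = [SHARED] * n
    candidates: dict[str, list[tuple[float, int]]] = {g: [] for g in groups}
    for c in range(n):
        col = cols[:, c]
        if not col.any():
            continue
        fr = {g: opposite_energy_fraction(col, g, slices) for g in groups}
        qual = [g for g in groups if fr[g] < theta]
        if not qual:
            continue
        if len(qual) == 2:
            if fr[groups[0]] == fr[groups[1]]:
                continue  # exact tie -> shared
            qual = [min(groups, key=lambda g: fr[g])]
        g = qual[0]
        candidates[g].append((fr[g], c))
    for g in groups:
        keep = sorted(candidates[g])[: caps.get(g, 0)]
        for _, c in keep:
            labels[c] = _specific_label(g)
    return labels


def _relabel_with_hysteresis(
    labels: list[str],
    blocks: dict[str, np.ndarray],
    theta: float,
    caps: dict[str, int],
) -> list[str]:
    """Iterative re-labeling with a promote/demote gap.

    Shared components are promoted when their opposite-block fraction falls
    strictly below ``theta`` (respecting the caps, smallest fractions first);
    specific components are demoted only when their fraction exceeds
    ``_DEMOTE_FRACTION``. The gap keeps the label assignment from
    oscillating when a component's fraction hovers around ``theta``.
    """
    groups = list(blocks)
    cols = np.vstack([blocks[g] for g in groups])
    slices = {groups[0]: slice(0, blocks[groups[0]].shape[0]),
              groups[1]: slice(blocks[groups[0]].shape[0], cols.shape[0])}
    labels = list(labels)
    fractions: list[dict[str, float]] = []
    for c in range(len(labels)):
        col = cols[:, c]
        fractions.append({g: (opposite_energy_fraction(col, g, slices)
                              if col.any() else 1.0) for g in groups})
    for c, lab in enumerate(labels):
        if lab != SHARED:
            g = lab.removeprefix("specific_")
            if fractions[c][g] > _DEMOTE_FRACTION:
                labels[c] = SHARED
    for g in groups:
        room = caps.get(g, 0) - sum(l == _specific_label(g) for l in labels)
        cand = sorted(
            (fractions[c][g], c) for c, l in enumerate(labels)
            if l == SHARED and fractions[c][g] < theta
            and fractions[c][g] <= fractions[c][[h for h in groups if h != g][0]]
        )
        for _, c in cand[:max(room, 0)]:
            labels[c] = _specific_label(g)
    return labels


def initial_pvaf_labeling(
    candidate: SSICAResult,
    reduction: ReducedDataset,
    config: SSICAConfig,
) -> list[LabelDecision]:
    """Label components by comparing per-subject PVAF between groups.

    For every component the percent variance accounted for is computed in
    each subject's original-domain data; a pooled-variance two-sample t-test
    compares the two groups and a component is a specific candidate at
    Bonferroni significance ``alpha = pvaf_alpha_base / N`` on the side with
    the larger mean PVAF. Candidates beyond the caps are dropped keeping the
    lowest p-values.
    """
    from .reconstruction_stats import component_projection, pvaf

    g1, g2 = reduction.group_ids
    subjects = {g: reduction.subjects_of(g) for g in (g1, g2)}
    for g, subj in subjects.items():
        if len(subj) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects; t-test undefined")
    series_by_id = {s.subject_id: s for s in reduction.series}
    n = candidate.sources.shape[0]
    alpha = config.pvaf_alpha_base / n

    decisions: list[LabelDecision] = []
    for c in range(n):
        vals: dict[str, list[float]] = {g1: [], g2: []}
        for g in (g1, g2):
            for sid in subjects[g]:
                y = series_by_id[sid].data
                yhat = component_projection(candidate, reduction, sid, c)
                vals[g].append(pvaf(y, yhat))
        t, p = stats.ttest_ind(vals[g1], vals[g2], equal_var=True)
        decisions.append(LabelDecision(c, vals[g1], vals[g2], float(t), float(p)))

    m1, m2 = config.max_specific
    caps = {g1: m1, g2: m2}
    cands: dict[str, list[tuple[float, int]]] = {g1: [], g2: []}
    for d in decisions:
        if d.p_value < alpha:
            side = g1 if np.mean(d.pvaf_g1_values) > np.mean(d.pvaf_g2_values) else g2
            cands[side].append((d.p_value, d.component_id))
    for g in (g1, g2):
        for _, c in sorted(cands[g])[: caps[g]]:
            decisions[c].assigned = _specific_label(g)
    return decisions


# ---------------------------------------------------------------------------
# fixed-point machinery
# ---------------------------------------------------------------------------

def _sym_orth(w: np.ndarray) -> np.ndarray:
    """Symmetric orthogonalization W <- (W W^T)^(-1/2) W.

    When the update matrix is mildly rank-deficient (fewer non-Gaussian
    directions in the data than rows, so some linear combination of rows
    collapses), the inverse square root is regularized with an eigenvalue
    floor and the result re-orthonormalized by QR; the deficient subspace is
    completed deterministically. Gross collapse (more than half the rows)
    raises, since no meaningful decorrelation exists then.
    """
    k = w @ w.T
    vals, vecs = np.linalg.eigh(k)
    top = max(float(vals[-1]), 1e-300)
    deficient = int(np.sum(vals < 1e-12 * top))
    if deficient > w.shape[0] // 2:
        raise np.linalg.LinAlgError(
            "W W^T is numerically singular; cannot orthogonalize symmetrically"
        )
    if deficient:
        vals = np.maximum(vals, 1e-12 * top)
        w1 = (vecs / np.sqrt(vals)) @ vecs.T @ w
        q, r = np.linalg.qr(w1.T)
        return (q * np.sign(np.diag(r))[None, :]).T
    inv_sqrt = (vecs / np.sqrt(vals)) @ vecs.T
    return inv_sqrt @ w


def fastica_step(w: np.ndarray, x: np.ndarray, nonlinearity: str = "tanh") -> np.ndarray:
    """One symmetric FastICA fixed-point update on white data ``x``."""
    m = x.shape[1]
    u = w @ x
    if nonlinearity == "tanh":
        gu = np.tanh(u)
        g_prime = 1.0 - gu**2
    elif nonlinearity == "pow3":
        gu = u**3
        g_prime = 3.0 * u**2
    else:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    w_new = (gu @ x.T) / m - g_prime.mean(axis=1)[:, None] * w
    # near-Gaussian directions have E[s g(s)] ~ E[g'(s)] and an update that
    # collapses to zero; keep the previous direction for those rows so the
    # symmetric orthogonalization stays well-posed
    norms = np.linalg.norm(w_new, axis=1)
    weak = norms < 1e-8
    if weak.any():
        w_new[weak] = w[weak]
    return _sym_orth(w_new)


def random_orthonormal(n: int, seed: int) -> np.ndarray:
    """Deterministic random orthonormal matrix (QR of a seeded Gaussian)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))[None, :]


def _constraint_blocks(reduction: ReducedDataset) -> dict[str, np.ndarray]:
    """Group row blocks of the aggregate back-projector G+ ((Ng1+Ng2) x N)."""
    g_back = reduction.aggregate_level.backward
    return {g: g_back[sl] for g, sl in reduction.group_block_slices().items()}


def mixing_group_blocks(w: np.ndarray, reduction: ReducedDataset) -> dict[str, np.ndarray]:
    """Level-2 mixing blocks of each component (columns indexed by component)."""
    a = w.T  # aggregate mixing of an orthonormal unmixing matrix
    blocks = _constraint_blocks(reduction)
    return {g: blk @ a for g, blk in blocks.items()}


def feasible_bases(reduction: ReducedDataset) -> dict[str, np.ndarray]:
    """Orthonormal bases of the feasible subspaces for each specific label."""
    g1, g2 = reduction.group_ids
    blocks = _constraint_blocks(reduction)
    return {
        _specific_label(g1): sla.null_space(blocks[g2]),
        _specific_label(g2): sla.null_space(blocks[g1]),
    }


def enforce_specific_constraint(
    w: np.ndarray,
    labels: list[str],
    reduction: ReducedDataset,
    bases: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Project specific rows onto their feasible subspaces and re-orthonormalize.

    Feasibility for a group-1-specific component is ``C_g2 w = 0`` (its
    level-2 mixing column vanishes on the group-2 block), enforced as an
    exact orthogonal projection. Orthonormalization runs in the order
    specific-g1, specific-g2, shared, each stage constrained to the
    null space of the already-fixed constraints, so feasibility survives.
    A row annihilated by its projection is demoted to shared.
    """
    labels = list(labels)
    w = np.array(w, dtype=float)
    n = w.shape[0]

    # feasible-subspace bases: zero opposite block <=> in the null space of
    # the opposite group's rows of G+
    if bases is None:
        bases = feasible_bases(reduction)

    # 1) project every specific row into its feasible subspace (demote rows
    #    the projection annihilates)
    spec: list[int] = []
    for i, l in enumerate(labels):
        if l == SHARED:
            continue
        basis = bases[l]
        v = basis @ (basis.T @ w[i])
        nv = np.linalg.norm(v)
        if basis.shape[1] == 0 or nv < _DEMOTE_NORM:
            logger.info("component %d: constraint annihilated its row; demoted to shared", i)
            labels[i] = SHARED
            continue
        w[i] = v / nv
        spec.append(i)

    # 2) orthonormalize within each group (linear combinations stay inside
    #    the group's feasible subspace) and decorrelate across groups with
    #    feasible-manifold Newton sweeps: each pairwise correction moves a
    #    row only inside its own subspace. When the feasible subspaces are
    #    not orthogonal enough (saturated caps), the step size explodes and
    #    the pair is left to the convergence-time tolerance check.
    by_label: dict[str, list[int]] = {}
    for i in spec:
        by_label.setdefault(labels[i], []).append(i)
    projectors = {lab: bases[lab] @ bases[lab].T for lab in by_label}

    def orthonormalize_within() -> None:
        for lab, idx in by_label.items():
            if len(idx) > 1:
                w[idx] = _sym_orth(w[idx])
            elif idx:
                w[idx[0]] /= np.linalg.norm(w[idx[0]])

    orthonormalize_within()
    labs = list(by_label)
    if len(labs) == 2:
        idx_a, idx_b = by_label[labs[0]], by_label[labs[1]]
        p_a, p_b = projectors[labs[0]], projectors[labs[1]]
        for _ in range(50):
            worst = 0.0
            for i in idx_a:
                for j in idx_b:
                    c = float(w[i] @ w[j])
                    worst = max(worst, abs(c))
                    if abs(c) < 1e-14:
                        continue
                    denom = float(w[j] @ p_a @ w[j] + w[i] @ p_b @ w[i])
                    if denom < 1e-15:   # then c = 0 up to round-off anyway
                        continue
                    alpha = c / denom
                    wi = w[i] - alpha * (p_a @ w[j])
                    wj = w[j] - alpha * (p_b @ w[i])
                    w[i] = wi / np.linalg.norm(wi)
                    w[j] = wj / np.linalg.norm(wj)
            orthonormalize_within()
            cross = w[idx_a] @ w[idx_b].T
            if worst < 1e-14 or (np.abs(cross) < 1e-13).all():
                break
        # orthonormality always holds exactly; any cross-correlation the
        # sweeps could not remove becomes a feasibility residual handled by
        # the convergence-time tolerance check
        if spec:
            w[spec] = _sym_orth(w[spec])

    idx_sh = [i for i, l in enumerate(labels) if l == SHARED]
    if idx_sh:
        w_sp = w[spec] if spec else np.zeros((0, n))
        w_sh = w[idx_sh] - (w[idx_sh] @ w_sp.T) @ w_sp
        w[idx_sh] = _sym_orth(w_sh)
    return w, labels


def constraint_residuals(w: np.ndarray, labels: list[str], reduction: ReducedDataset) -> np.ndarray:
    """Opposite-block energy fraction of every component's level-2 column
    (0 for shared components by convention)."""
    g1, g2 = reduction.group_ids
    blocks = mixing_group_blocks(w, reduction)
    slices = {g1: slice(0, blocks[g1].shape[0]),
              g2: slice(blocks[g1].shape[0], blocks[g1].shape[0] + blocks[g2].shape[0])}
    cols = np.vstack([blocks[g1], blocks[g2]])
    res = np.zeros(w.shape[0])
    for c, lab in enumerate(labels):
        if lab == SHARED:
            continue
        grp = g1 if lab == _specific_label(g1) else g2
        res[c] = opposite_energy_fraction(cols[:, c], grp, slices)
    return res


def _converged(w_new: np.ndarray, w_old: np.ndarray, tol: float) -> bool:
    return float(np.max(np.abs(1.0 - np.abs(np.diag(w_new @ w_old.T))))) < tol


def _unconstrained_fastica(
    x: np.ndarray, config: SSICAConfig
) -> tuple[np.ndarray, int, bool]:
    w = random_orthonormal(x.shape[0], config.seed)
    w = _sym_orth(w)
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        w_new = fastica_step(w, x, config.nonlinearity)
        if _converged(w_new, w, config.convergence_tol):
            w = w_new
            converged = True
            break
        w = w_new
    return w, it, converged


def _order_and_sign(w: np.ndarray, reduction: ReducedDataset, labels: list[str]):
    """Order components by explained group-data variance; positive-skew maps."""
    g_back = reduction.aggregate_level.backward
    energy = np.sum((g_back @ w.T) ** 2, axis=0)
    order = np.argsort(-energy, kind="stable")
    w = w[order]
    labels = [labels[i] for i in order]
    s = w @ reduction.X
    signs = np.sign(stats.skew(s, axis=1))
    signs[signs == 0] = 1.0
    w = w * signs[:, None]
    return w, labels


def _build_result(
    w: np.ndarray,
    reduction: ReducedDataset,
    labels: list[str],
    iterations: int,
    converged: bool,
) -> SSICAResult:
    w, labels = _order_and_sign(w, reduction, labels)
    res = constraint_residuals(w, labels, reduction)
    return SSICAResult(
        unmixing=w,
        mixing=w.T,
        mixing_group_blocks=mixing_group_blocks(w, reduction),
        sources=w @ reduction.X,
        labels=labels,
        constraint_residuals=res,
        iterations=iterations,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def fit_ssica(reduction: ReducedDataset, config: SSICAConfig) -> SSICAResult:
    """Fit the constrained decomposition.

    Runs an unconstrained symmetric FastICA pass first; its components are
    labeled by PVAF group comparison, then the constrained loop alternates
    fixed-point updates, mixing-based re-labeling and constraint projection.
    Labels freeze over the last 10% of the iteration budget to let the
    fixed point settle. Specific components whose residual still exceeds
    ``constraint_tol`` at the end are demoted to shared.
    """
    config.validate_against(reduction)
    g1, g2 = reduction.group_ids
    m1, m2 = config.max_specific
    x = reduction.X
    n = config.n_components

    w, it0, conv0 = _unconstrained_fastica(x, config)
    if m1 == 0 and m2 == 0:
        return _build_result(w, reduction, [SHARED] * n, it0, conv0)

    candidate = _build_result(w, reduction, [SHARED] * n, it0, conv0)
    decisions = initial_pvaf_labeling(candidate, reduction, config)
    # _build_result reordered components; map labels back onto candidate's W
    labels = [d.assigned for d in decisions]
    w = candidate.unmixing

    caps = {g1: m1, g2: m2}
    theta = config.classification_threshold
    freeze_after = int(np.ceil(_FREEZE_FRACTION * config.max_iterations))
    converged = False
    it = 0
    bases = feasible_bases(reduction)
    w, labels = enforce_specific_constraint(w, labels, reduction, bases)
    for it in range(1, config.max_iterations + 1):
        w_step = fastica_step(w, x, config.nonlinearity)
        if _RELABEL_BURN_IN < it <= freeze_after:
            labels = _relabel_with_hysteresis(
                labels, mixing_group_blocks(w_step, reduction), theta, caps)
        w_new, labels = enforce_specific_constraint(w_step, labels, reduction, bases)
        # no convergence break before mixing-based re-labeling has pruned the
        # initial label set at least once
        if it > _RELABEL_BURN_IN + 1 and _converged(w_new, w, config.convergence_tol):
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        logger.warning("constrained loop did not converge in %d iterations", it)

    # tolerance check: demote the worst-violating specific component and
    # re-enforce until every retained one satisfies the constraint — the
    # specific count shrinks (possibly to zero) rather than the whole set
    # being discarded when one component makes the constraints unsatisfiable
    while True:
        res = constraint_residuals(w, labels, reduction)
        bad = [c for c in range(n)
               if labels[c] != SHARED and res[c] >= config.constraint_tol]
        if not bad:
            break
        worst = max(bad, key=lambda c: res[c])
        logger.info(
            "component %d residual %.2e >= %.0e at convergence; demoted to shared",
            worst, res[worst], config.constraint_tol,
        )
        labels[worst] = SHARED
        w, labels = enforce_specific_constraint(w, labels, reduction, bases)
    return _build_result(w, reduction, labels, it0 + it, converged)


def fit_gica_baseline(reduction: ReducedDataset, config: SSICAConfig) -> SSICAResult:
    """Unconstrained symmetric FastICA on identically reduced data; all
    components labeled shared. Comparison arm for the constrained fit."""
    x = reduction.X
    if config.n_components != x.shape[0]:
        raise ValueError(
            f"config n_components={config.n_components} but reduction has {x.shape[0]} rows"
        )
    w, it, conv = _unconstrained_fastica(x, config)
    return _build_result(w, reduction, [SHARED] * x.shape[0], it, conv)
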