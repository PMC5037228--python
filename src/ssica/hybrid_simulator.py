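"""Synthetic multi-group fMRI-like datasets with planted activation patches.

Each dataset is a structured background plus *patches*: clusters of 2-3
blobs of neighbouring voxels sharing (up to within-component variability) a
band-limited time course. The background emulates resting-state noise as
spatially smoothed, temporally AR(1)-correlated Gaussian fields; its mean
voxel variance is the reference against which patch power is defined.

Patch semantics:

* ``shared`` -- planted with the configured ``snr`` (power) in every subject
  of both groups,
* ``specific_g1`` / ``specific_g2`` -- planted only in the named group; the
  contribution to the opposite group's series is exactly zero,
* ``partial_g1`` / ``partial_g2`` -- planted at power ``snr`` in the named
  (matching) group and at power ``snr * power_ratio`` in the opposite group.

*Power* of a patch is the ratio of its time-course variance to the mean
background voxel variance; time-course amplitudes are scaled by the square
root of the requested power so the realized variance ratio equals ``snr``.
Anatomical variability is emulated by a per-subject integer translation of
the patch in the axial plane (uniform on {-floor(n/2), ..., floor(n/2)}^2).
The ``unbalance_ratio`` multiplies the power of the first-listed specific
patch of each group, making it the designated "strong" patch.

Everything is deterministic given ``SimDesign.seed``: every random draw uses
an rng keyed on (seed, subject, patch, run, purpose).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .multilevel_reduction import SubjectSeries

MEMBERSHIPS = ("shared", "specific_g1", "specific_g2", "partial_g1", "partial_g2")
GROUP_IDS = ("g1", "g2")


# ---------------------------------------------------------------------------
# mask geometry (x-fastest flattening convention shared with file I/O)
# ---------------------------------------------------------------------------

class MaskGeometry:
    """A boolean 3-D mask with a fixed voxel order: x varies fastest."""

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask).astype(bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {mask.shape}")
        self.mask = mask
        xi, yi, zi = np.nonzero(mask)
        order = np.lexsort((xi, yi, zi))  # z-major, x-fastest
        self._xi, self._yi, self._zi = xi[order], yi[order], zi[order]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return self._xi.size

    def flatten(self, vol: np.ndarray) -> np.ndarray:
        """3-D volume (or 4-D t,x,y,z series) -> in-mask vector (or T x M)."""
        if vol.ndim == 3:
            return vol[self._xi, self._yi, self._zi]
        if vol.ndim == 4:
            return vol[:, self._xi, self._yi, self._zi]
        raise ValueError(f"expected 3-D or 4-D input, got shape {vol.shape}")

    def unflatten(self, vec: np.ndarray) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=float)
        vol[self._xi, self._yi, self._zi] = vec
        return vol

    @property
    def voxel_coords(self) -> np.ndarray:
        """(M, 3) integer voxel coordinates in flattening order."""
        return np.column_stack([self._xi, self._yi, self._zi])


def ellipsoid_mask(grid_shape: tuple[int, int, int], margin: float = 0.5) -> MaskGeometry:
    """Ellipsoidal brain-like mask inscribed in the grid (minus a margin)."""
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = cx - margin, cy - margin, cz - margin
    x, y, z = np.ogrid[:nx, :ny, :nz]
    mask = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    return MaskGeometry(mask)


# ---------------------------------------------------------------------------
# design types
# ---------------------------------------------------------------------------

@dataclass
class BlobSpec:
    center: tuple[int, int, int]
    radius_voxels: float
    shape: str = "sphere"           # "sphere" | "box"

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "box"):
            raise ValueError(f"unknown blob shape {self.shape!r}")
        if self.radius_voxels <= 0:
            raise ValueError("blob radius must be positive")


@dataclass
class PatchSpec:
    blobs: list[BlobSpec]
    membership: str
    snr: float = 1.0
    power_ratio: float = 1.0        # used by partial memberships only
    within_component_variability: float = 0.0   # k

    def __post_init__(self) -> None:
        if self.membership not in MEMBERSHIPS:
            raise ValueError(f"unknown membership {self.membership!r}")
        if not 1 <= len(self.blobs) <= 3:
            raise ValueError("a patch needs 1-3 blobs (the field convention is 2-3)")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not 0.0 < self.power_ratio <= 1.0:
            raise ValueError("power_ratio must be in (0, 1]")
        if self.within_component_variability < 0:
            raise ValueError("within-component variability k must be >= 0")

    @property
    def matching_group(self) -> str | None:
        if self.membership == "shared":
            return None
        return "g1" if self.membership.endswith("g1") else "g2"


@dataclass
class SimDesign:
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    subjects_per_group: int = 6
    runs_per_subject: int = 2
    T: int = 100
    tr_seconds: float = 2.0
    patches: list[PatchSpec] = field(default_factory=list)
    anatomical_noise: int = 0       # n: axial jitter range in voxels
    unbalance_ratio: float = 1.0    # m: power multiplier of the strong specific patch
    background_fwhm_voxels: float = 1.5
    background_ar1: float = 0.3
    background_variance: float = 1.0
    n_background_networks: int = 6  # shared resting-state-network stand-ins
    network_fwhm_voxels: float = 1.5
    network_energy_fraction: float = 0.1  # per-network spatial energy / brain energy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anatomical_noise < 0:
            raise ValueError("anatomical_noise must be >= 0")
        if self.unbalance_ratio < 1:
            raise ValueError("unbalance_ratio must be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2")

    def mask(self) -> MaskGeometry:
        return ellipsoid_mask(self.grid_shape)


@dataclass
class HybridDataset:
    series: list[SubjectSeries]
    truth_maps: dict[int, dict[str, np.ndarray]]     # patch -> subject -> masked map
    truth_base_maps: dict[int, np.ndarray]           # patch -> jitter-free masked map
    truth_labels: dict[int, str]                     # patch -> membership
    truth_timecourses: dict[int, dict[str, np.ndarray]]
    truth_blob_supports: dict[int, list[np.ndarray]]  # jitter-free in-mask boolean supports
    mask: MaskGeometry
    provenance: dict

    def group_series(self, group_id: str) -> list[SubjectSeries]:
        return [s for s in self.series if s.group_id == group_id]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])


def background_network_maps(design: SimDesign, mask: MaskGeometry) -> np.ndarray:
    """Common spatial modes of the background — stand-ins for the resting
    state networks that real brains share across groups. Smooth seeded
    Gaussian fields, identical for every subject, each rescaled to a fixed
    fraction of the total brain spatial energy. Shape (n_networks, M)."""
    sigma = design.network_fwhm_voxels / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    maps = np.empty((design.n_background_networks, mask.n_voxels))
    target = design.network_energy_fraction * mask.n_voxels
    for j in range(design.n_background_networks):
        rng = _rng(design.seed, 5, j)
        vol = ndimage.gaussian_filter(rng.standard_normal(design.grid_shape), sigma)
        vec = mask.flatten(vol)
        maps[j] = vec * np.sqrt(target / (vec @ vec))
    return maps


def make_background(design: SimDesign, mask: MaskGeometry | None = None,
                    include_networks: bool = True) -> list[SubjectSeries]:
    """Per-subject background emulating resting-state data.

    Two ingredients: (i) subject-unique noise — spatially smoothed,
    temporally AR(1)-correlated Gaussian fields, normalized to unit mean
    voxel variance; (ii) shared network modes — the common spatial maps of
    :func:`background_network_maps`, each driven by an independent
    band-limited (0.01-0.1 Hz) unit-variance time course per subject and
    run. The shared modes give the two groups the cross-group spatial
    correlation structure real resting-state data has; without it no
    direction of the aggregate data is preferentially shared or specific.

    Runs are generated independently and concatenated in time. Each
    subject's combined field is rescaled so its mean in-mask voxel variance
    equals the configured background variance exactly, then demeaned.
    """
    mask = mask or design.mask()
    if mask.n_voxels < 32:
        raise ValueError(f"degenerate mask with {mask.n_voxels} voxels (< 32)")
    n_nets = design.n_background_networks if include_networks else 0
    if n_nets > 0 and design.T < 50:
        raise ValueError("T must be >= 50 to band-limit the shared network "
                         "time courses (or set n_background_networks=0)")
    sigma = design.background_fwhm_voxels / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rho = design.background_ar1
    nets = background_network_maps(design, mask) if n_nets > 0 else None
    out: list[SubjectSeries] = []
    for gi, gid in enumerate(GROUP_IDS):
        for si in range(design.subjects_per_group):
            runs = []
            for ri in range(design.runs_per_subject):
                rng = _rng(design.seed, 0, gi, si, ri)
                vol = rng.standard_normal((design.T, *design.grid_shape))
                if sigma > 0:
                    vol = ndimage.gaussian_filter(vol, sigma=(0, sigma, sigma, sigma))
                flat = mask.flatten(vol)
                if rho != 0.0:
                    flat = signal.lfilter([1.0], [1.0, -rho], flat * np.sqrt(1 - rho**2), axis=0)
                flat /= np.sqrt(flat.var(axis=0, ddof=1).mean())
                if nets is not None:
                    for j in range(n_nets):
                        trng = _rng(design.seed, 6, gi, si, ri, j)
                        tc = _bandpass(trng.standard_normal(design.T), design.tr_seconds)
                        tc /= tc.std(ddof=1)
                        flat += np.outer(tc, nets[j])
                runs.append(flat)
            data = np.vstack(runs)
            mv = data.var(axis=0, ddof=1).mean()
            data = data * np.sqrt(design.background_variance / mv)
            data -= data.mean(axis=0, keepdims=True)
            out.append(SubjectSeries(data, design.tr_seconds,
                                     subject_id=f"{gid}_s{si}", group_id=gid))
    return out


def make_patch_map(patch: PatchSpec, mask: MaskGeometry) -> np.ndarray:
    """Patch spatial map as a 3-D volume: radial amplitude gradient from 1.3
    at each blob centre to 0.7 at its edge, overlapping blobs take the
    maximum, then rescaled so the mean over the support is exactly 1."""
    vol = np.zeros(mask.shape)
    x, y, z = np.indices(mask.shape)
    for blob in patch.blobs:
        cx, cy, cz = blob.center
        if not (0 <= cx < mask.shape[0] and 0 <= cy < mask.shape[1] and 0 <= cz < mask.shape[2]):
            raise ValueError(f"blob centre {blob.center} outside grid {mask.shape}")
        if blob.shape == "sphere":
            d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        else:
            d = np.maximum.reduce([np.abs(x - cx), np.abs(y - cy), np.abs(z - cz)])
        inside = d <= blob.radius_voxels
        amp = 0.7 + 0.6 * (1.0 - d / blob.radius_voxels)
        vol = np.where(inside, np.maximum(vol, amp), vol)
    vol = np.where(mask.mask, vol, 0.0)
    support = vol > 0
    if not support.any():
        raise ValueError("patch has empty support inside the mask")
    vol[support] /= vol[support].mean()
    return vol


def blob_supports(patch: PatchSpec, mask: MaskGeometry) -> list[np.ndarray]:
    """In-mask boolean support of each blob (jitter-free), in blob order."""
    x, y, z = np.indices(mask.shape)
    outs = []
    for blob in patch.blobs:
        cx, cy, cz = blob.center
        if blob.shape == "sphere":
            d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        else:
            d = np.maximum.reduce([np.abs(x - cx), np.abs(y - cy), np.abs(z - cz)])
        outs.append(mask.flatten((d <= blob.radius_voxels) & mask.mask))
    return outs


def apply_jitter(map_vol: np.ndarray, n: int, rng: np.random.Generator,
                 mask: MaskGeometry) -> tuple[np.ndarray, tuple[int, int]]:
    """Translate a patch volume by a uniform integer shift in the axial
    (first two) axes; voxels shifted outside the mask are dropped."""
    if n < 0:
        raise ValueError("jitter range n must be >= 0")
    half = n // 2
    dx, dy = (int(rng.integers(-half, half + 1)), int(rng.integers(-half, half + 1))) \
        if half > 0 else (0, 0)
    shifted = np.zeros_like(map_vol)
    nx, ny = map_vol.shape[0], map_vol.shape[1]
    xs_src = slice(max(0, -dx), min(nx, nx - dx))
    xs_dst = slice(max(0, dx), min(nx, nx + dx))
    ys_src = slice(max(0, -dy), min(ny, ny - dy))
    ys_dst = slice(max(0, dy), min(ny, ny + dy))
    shifted[xs_dst, ys_dst, :] = map_vol[xs_src, ys_src, :]
    shifted = np.where(mask.mask, shifted, 0.0)
    if not (shifted > 0).any():
        raise ValueError(f"jitter ({dx}, {dy}) shifted the patch entirely out of the mask")
    return shifted, (dx, dy)


def _bandpass(x: np.ndarray, tr: float, band=(0.01, 0.1)) -> np.ndarray:
    fs = 1.0 / tr
    sos = signal.butter(4, band, btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def make_patch_timecourses(
    patch: PatchSpec,
    design: SimDesign,
    rng: np.random.Generator,
    effective_snr: float,
    bg_variance: float,
) -> np.ndarray:
    """Per-blob time courses for one run: a shared band-limited Gaussian base
    scaled so the patch power (variance / mean background voxel variance)
    equals ``effective_snr``, plus per-blob band-limited perturbations of
    variance ``k * bg_variance`` when k > 0. Shape (n_blobs, T)."""
    if effective_snr < 0:
        raise ValueError("snr must be >= 0")
    if design.T < 50:
        raise ValueError("T must be >= 50 for band-limited time courses")
    n_blobs = len(patch.blobs)
    if effective_snr == 0.0:
        return np.zeros((n_blobs, design.T))
    base = _bandpass(rng.standard_normal(design.T), design.tr_seconds)
    base = base / base.std(ddof=1) * np.sqrt(effective_snr * bg_variance)
    k = patch.within_component_variability
    if k == 0.0:
        return np.tile(base, (n_blobs, 1))
    out = np.empty((n_blobs, design.T))
    for b in range(n_blobs):
        noise = rng.standard_normal(design.T) * np.sqrt(k * bg_variance)
        out[b] = _bandpass(base + noise, design.tr_seconds)
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _patch_power_in_group(patch: PatchSpec, group_id: str, design: SimDesign,
                          strong: bool) -> float:
    """Effective power (variance ratio) of a patch in one group's subjects."""
    snr = patch.snr * (design.unbalance_ratio if strong else 1.0)
    if patch.membership == "shared":
        return snr
    if patch.membership.startswith("specific"):
        return snr if patch.matching_group == group_id else 0.0
    # partial
    return snr if patch.matching_group == group_id else snr * patch.power_ratio


def generate_dataset(design: SimDesign) -> HybridDataset:
    """Background plus planted patches, with complete ground truth."""
    mask = design.mask()
    series = make_background(design, mask)
    bg_var = design.background_variance

    # the first-listed specific patch of each group is the "strong" one
    strong_idx: dict[str, int | None] = {g: None for g in GROUP_IDS}
    if design.unbalance_ratio > 1:
        for pi, p in enumerate(design.patches):
            g = p.matching_group
            if p.membership.startswith("specific") and g and strong_idx[g] is None:
                strong_idx[g] = pi

    base_maps = {}
    supports = {}
    for pi, patch in enumerate(design.patches):
        base_maps[pi] = make_patch_map(patch, mask)
        supports[pi] = blob_supports(patch, mask)

    truth_maps: dict[int, dict[str, np.ndarray]] = {pi: {} for pi in base_maps}
    truth_tcs: dict[int, dict[str, np.ndarray]] = {pi: {} for pi in base_maps}
    jitters: dict[str, dict[int, tuple[int, int]]] = {}

    sub_index = {s.subject_id: i for i, s in enumerate(series)}
    for gi, gid in enumerate(GROUP_IDS):
        for si in range(design.subjects_per_group):
            sid = f"{gid}_s{si}"
            s = series[sub_index[sid]]
            jitters[sid] = {}
            for pi, patch in enumerate(design.patches):
                power = _patch_power_in_group(patch, gid, design, strong=(strong_idx[gid] == pi))
                jrng = _rng(design.seed, 1, gi, si, pi)
                map_vol, shift = apply_jitter(base_maps[pi], design.anatomical_noise, jrng, mask)
                jitters[sid][pi] = shift
                map_vec = mask.flatten(map_vol)
                truth_maps[pi][sid] = map_vec
                if power == 0.0:
                    truth_tcs[pi][sid] = np.zeros(design.T * design.runs_per_subject)
                    continue
                blob_vols = _split_map_by_blobs(map_vol, patch, mask)
                run_tcs = []
                for ri in range(design.runs_per_subject):
                    trng = _rng(design.seed, 2, gi, si, pi, ri)
                    tcs = make_patch_timecourses(patch, design, trng, power, bg_var)
                    for b, bvec in enumerate(blob_vols):
                        s.data[ri * design.T:(ri + 1) * design.T] += np.outer(tcs[b], bvec)
                    run_tcs.append(tcs.mean(axis=0))
                truth_tcs[pi][sid] = np.concatenate(run_tcs)

    provenance = {
        "design": design_to_dict(design),
        "jitters": {sid: {pi: list(sh) for pi, sh in d.items()} for sid, d in jitters.items()},
    }
    return HybridDataset(
        series=series,
        truth_maps=truth_maps,
        truth_base_maps={pi: mask.flatten(v) for pi, v in base_maps.items()},
        truth_labels={pi: p.membership for pi, p in enumerate(design.patches)},
        truth_timecourses=truth_tcs,
        truth_blob_supports=supports,
        mask=mask,
        provenance=provenance,
    )


def _split_map_by_blobs(map_vol: np.ndarray, patch: PatchSpec, mask: MaskGeometry) -> list[np.ndarray]:
    """Partition a (jittered) patch map into per-blob masked vectors by
    nearest blob centre; the jitter moved all blobs together so relative
    geometry is preserved."""
    map_vec = mask.flatten(map_vol)
    support = map_vec > 0
    if len(patch.blobs) == 1:
        return [np.where(support, map_vec, 0.0)]
    xi = np.argwhere(map_vol > 0)
    centers = np.array([b.center for b in patch.blobs], dtype=float)
    # recover the common shift from the support centroid displacement
    base_centroid = centers.mean(axis=0)
    cur_centroid = xi.mean(axis=0)
    shift = np.round(cur_centroid - base_centroid)
    shifted_centers = centers + shift
    out = []
    d = np.linalg.norm(mask.voxel_coords[:, None, :] - shifted_centers[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    for b in range(len(patch.blobs)):
        sel = support & (nearest == b)
        out.append(np.where(sel, map_vec, 0.0))
    return out


# ---------------------------------------------------------------------------
# design grids
# ---------------------------------------------------------------------------

_GRID_FIELDS = {"snr", "anatomical_noise", "unbalance_ratio", "power_ratio",
                "within_component_variability"}


def enumerate_grid(
    grid: dict[str, list],
    permutations: int,
    base: SimDesign,
) -> list[SimDesign]:
    """Cartesian product of parameter lists x random patch-membership
    permutations, each with a deterministic derived seed. The design count is
    the product of the list sizes times ``permutations``."""
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    unknown = set(grid) - _GRID_FIELDS
    if unknown:
        raise ValueError(f"unknown grid field(s) {sorted(unknown)}; allowed: {sorted(_GRID_FIELDS)}")
    for k, v in grid.items():
        if not v:
            raise ValueError(f"grid list for {k!r} is empty")
    keys = sorted(grid)
    designs: list[SimDesign] = []
    idx = 0
    for combo in itertools.product(*(grid[k] for k in keys)):
        values = dict(zip(keys, combo))
        for p in range(permutations):
            seed = int(_rng(base.seed, 3, idx, p).integers(0, 2**31 - 1))
            rng = _rng(base.seed, 4, idx, p)
            memberships = [pt.membership for pt in base.patches]
            rng.shuffle(memberships)
            patches = []
            for pt, mem in zip(base.patches, memberships):
                patches.append(replace(
                    pt,
                    membership=mem,
                    snr=values.get("snr", pt.snr),
                    power_ratio=values.get("power_ratio", pt.power_ratio),
                    within_component_variability=values.get(
                        "within_component_variability", pt.within_component_variability),
                ))
            designs.append(replace(
                base,
                patches=patches,
                anatomical_noise=int(values.get("anatomical_noise", base.anatomical_noise)),
                unbalance_ratio=float(values.get("unbalance_ratio", base.unbalance_ratio)),
                seed=seed,
            ))
        idx += 1
    return designs


# ---------------------------------------------------------------------------
# default desk-scale layouts and serialization
# ---------------------------------------------------------------------------

def default_patches(layout: str = "recovery") -> list[PatchSpec]:
    """Preset patch layouts on the default 16x16x8 grid.

    ``recovery``: one specific patch per group plus one shared patch.
    ``five``: the five-patch layout (2 specific per group + 1 shared).
    ``over``: one specific per group + 2 shared (over-capacity experiments).
    """
    # focal blobs: ~2.5% of the mask per patch, proportionally matching the
    # small blob-to-brain ratio of realistically simulated activations
    mk = lambda centers, mem: PatchSpec(  # noqa: E731
        blobs=[BlobSpec(c, 1.6) for c in centers], membership=mem)
    if layout == "recovery":
        return [
            mk([(4, 4, 3), (7, 4, 4)], "specific_g1"),
            mk([(11, 11, 3), (8, 11, 4)], "specific_g2"),
            mk([(4, 11, 4), (7, 11, 3)], "shared"),
        ]
    if layout == "five":
        return [
            mk([(4, 4, 3), (7, 4, 4)], "specific_g1"),
            mk([(11, 4, 4), (11, 7, 3)], "specific_g1"),
            mk([(7, 7, 4), (5, 8, 3)], "shared"),
            mk([(11, 11, 3), (8, 11, 4)], "specific_g2"),
            mk([(4, 11, 4), (4, 8, 3)], "specific_g2"),
        ]
    if layout == "over":
        # larger blobs here: the splitting experiment needs the within-patch
        # difference direction (energy ~ (1 - blob-tc correlation) x blob
        # energy) to survive the group-level PCA noise floor
        mk_big = lambda centers, mem: PatchSpec(  # noqa: E731
            blobs=[BlobSpec(c, 2.5) for c in centers], membership=mem)
        return [
            mk_big([(4, 4, 3), (7, 4, 4)], "specific_g1"),
            mk_big([(11, 11, 3), (8, 11, 4)], "specific_g2"),
            mk([(4, 11, 4), (7, 11, 3)], "shared"),
            mk([(11, 4, 4), (11, 7, 3)], "shared"),
        ]
    raise ValueError(f"unknown layout {layout!r}")


def design_to_dict(design: SimDesign) -> dict:
    return {
        "grid_shape": list(design.grid_shape),
        "subjects_per_group": design.subjects_per_group,
        "runs_per_subject": design.runs_per_subject,
        "T": design.T,
        "tr_seconds": design.tr_seconds,
        "anatomical_noise": design.anatomical_noise,
        "unbalance_ratio": design.unbalance_ratio,
        "background_fwhm_voxels": design.background_fwhm_voxels,
        "background_ar1": design.background_ar1,
        "background_variance": design.background_variance,
        "n_background_networks": design.n_background_networks,
        "network_fwhm_voxels": design.network_fwhm_voxels,
        "network_energy_fraction": design.network_energy_fraction,
        "seed": design.seed,
        "patches": [
            {
                "blobs": [{"center": list(b.center), "radius_voxels": b.radius_voxels,
                           "shape": b.shape} for b in p.blobs],
                "membership": p.membership,
                "snr": p.snr,
                "power_ratio": p.power_ratio,
                "within_component_variability": p.within_component_variability,
            }
            for p in design.patches
        ],
    }


def design_from_dict(d: dict) -> SimDesign:
    patches = [
        PatchSpec(
            blobs=[BlobSpec(tuple(b["center"]), b["radius_voxels"], b.get("shape", "sphere"))
                   for b in p["blobs"]],
            membership=p["membership"],
            snr=p.get("snr", 1.0),
            power_ratio=p.get("power_ratio", 1.0),
            within_component_variability=p.get("within_component_variability", 0.0),
        )
        for p in d.get("patches", [])
    ]
    return SimDesign(
        grid_shape=tuple(d.get("grid_shape", (16, 16, 8))),
        subjects_per_group=d.get("subjects_per_group", 6),
        runs_per_subject=d.get("runs_per_subject", 2),
        T=d.get("T", 100),
        tr_seconds=d.get("tr_seconds", 2.0),
        patches=patches,
        anatomical_noise=d.get("anatomical_noise", 0),
        unbalance_ratio=d.get("unbalance_ratio", 1.0),
        background_fwhm_voxels=d.get("background_fwhm_voxels", 1.5),
        background_ar1=d.get("background_ar1", 0.3),
        background_variance=d.get("background_variance", 1.0),
        n_background_networks=d.get("n_background_networks", 6),
        network_fwhm_voxels=d.get("network_fwhm_voxels", 3.0),
        network_energy_fraction=d.get("network_energy_fraction", 0.1),
        seed=d.get("seed", 0),
    )
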