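"""Synthetic acinar phantoms with exact voxel-level ground truth.

A phantom emulates an extracted acinus from a high-resolution tomographic
stack: a connected, air-filled branching duct tree carrying alveoli that
open into the duct lumen through a single mouth, surrounded by bright
tissue. Every phantom ships with a manifest holding its *exact* truth —
air-voxel count (hence volume) and alveolus count — so that the stereology
estimators downstream (Cavalieri point counting, physical disector) can be
validated without any external data.

Geometry is generated in micrometres and rasterized onto an isotropic voxel
grid indexed ``(z, y, x)``. Phantoms are deliberately small (tens of µm
radii, well under 256³ voxels): the estimators under test are scale-free,
so a reduced-scale phantom exercises them exactly as a full-scale acinus
would.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volio import VoxelStack

__all__ = [
    "DuctTree",
    "AcinusPhantom",
    "CohortProfile",
    "SizingError",
    "PlacementError",
    "build_duct_tree",
    "rasterize_tree",
    "synthesize_acinus",
    "add_parent_airway",
    "render_grayscale",
    "synthesize_cohort",
]

#: 6-connectivity structuring element (face neighbours only).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class SizingError(ValueError):
    """Requested geometry does not fit the requested stack bounds."""


class PlacementError(RuntimeError):
    """Alveoli could not all be placed without merging."""


@dataclasses.dataclass
class DuctTree:
    """Branching duct centreline skeleton in micrometre coordinates.

    ``nodes`` are ``(position_um, radius_um)`` with positions as (z, y, x)
    triples; ``edges`` are ``(parent_index, child_index)`` pairs. The
    ``entrance_plane`` ``(point_um, unit_normal)`` marks the transition from
    conducting to gas-exchanging airway, i.e. where a segmentation stopper
    would be placed.
    """

    nodes: list[tuple[np.ndarray, float]]
    edges: list[tuple[int, int]]
    entrance_plane: tuple[np.ndarray, np.ndarray]

    @property
    def n_tips(self) -> int:
        parents = {p for p, _ in self.edges}
        return sum(1 for i in range(len(self.nodes)) if i not in parents)

    def segments(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        """Return ``(start_um, end_um, radius_um)`` per edge (child radius)."""
        return [
            (self.nodes[p][0], self.nodes[c][0], self.nodes[c][1])
            for p, c in self.edges
        ]


@dataclasses.dataclass
class AcinusPhantom:
    """Label volume plus ground-truth manifest for one synthetic acinus.

    Labels: 0 background/tissue, 1 duct lumen, k >= 2 one label per
    alveolus. The manifest volume is exactly (nonzero-label voxel count) ×
    voxel volume; the manifest count is exactly the number of labels >= 2.
    """

    labels: np.ndarray
    voxel_size_um: float
    truth: dict
    entrance_plane: tuple[np.ndarray, np.ndarray] | None = None
    gray: VoxelStack | None = None

    @property
    def air_mask(self) -> np.ndarray:
        return self.labels > 0

    def verify(self) -> None:
        """Assert the ground-truth invariants (exact volume/count, 6-connected air)."""
        n_air = int(np.count_nonzero(self.labels))
        vol = n_air * self.voxel_size_um**3 * 1e-9
        if not np.isclose(vol, self.truth["true_volume_mm3"], rtol=0, atol=1e-15 * max(1.0, vol)):
            raise AssertionError("manifest volume does not match voxel count")
        labels_present = np.unique(self.labels)
        n_alv = int(np.sum(labels_present >= 2))
        if n_alv != self.truth["n_alveoli"]:
            raise AssertionError("manifest alveolus count does not match labels")
        if n_air:
            _, n_comp = ndimage.label(self.air_mask, structure=STRUCT_6)
            if n_comp != 1:
                raise AssertionError(f"air region has {n_comp} 6-connected components")


@dataclasses.dataclass
class CohortProfile:
    """Day-level target distribution for a cohort of acini.

    ``mean_volume_mm3`` and ``cv_volume`` parameterize a log-normal size law
    by moment matching; ``skew_direction`` is informational (a log-normal is
    always right-skewed; at low CV it is nearly symmetric).
    """

    day: int
    mean_volume_mm3: float
    cv_volume: float
    mean_alveoli: float
    n_acini: int
    skew_direction: str = "right"

    def __post_init__(self) -> None:
        if self.mean_volume_mm3 <= 0 or self.mean_alveoli <= 0:
            raise ValueError("profile means must be positive")
        if self.cv_volume <= 0:
            raise ValueError(f"cv_volume must be positive, got {self.cv_volume}")
        if self.n_acini < 1:
            raise ValueError("n_acini must be >= 1")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector perpendicular to ``axis``."""
    while True:
        v = rng.normal(size=3)
        v -= v.dot(axis) * axis
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def build_duct_tree(
    branching_depth: int,
    segment_length_um: float,
    radius_um: float,
    seed: int,
    bounds_um: Sequence[float] | None = None,
    length_decay: float = 0.8,
    radius_decay: float = 0.85,
    branch_angle_deg: float = 35.0,
) -> DuctTree:
    """Build a binary-branching duct centreline tree.

    The root segment starts at the origin and runs along +z; each generation
    splits into two children rotated by ``branch_angle_deg`` around the
    parent axis at random azimuths. Segment lengths and radii shrink
    geometrically with generation. Deterministic for a fixed ``seed``.

    A depth-``d`` tree has ``2**d`` tips and ``2**(d+1) - 1`` segments.
    ``bounds_um``, when given, is a (z, y, x) extent; any node outside
    raises :class:`SizingError` naming the offending segment.
    """
    if branching_depth < 0:
        raise ValueError("branching_depth must be >= 0")
    if segment_length_um <= 0 or radius_um <= 0:
        raise ValueError("segment_length_um and radius_um must be positive")
    rng = np.random.default_rng(seed)
    root_dir = np.array([1.0, 0.0, 0.0])  # +z in (z, y, x)
    nodes: list[tuple[np.ndarray, float]] = [(np.zeros(3), radius_um)]
    edges: list[tuple[int, int]] = []
    # frontier: (node index, direction, generation)
    frontier = [(0, root_dir, 0)]
    while frontier:
        idx, direction, gen = frontier.pop(0)
        length = segment_length_um * length_decay**gen
        radius = radius_um * radius_decay**gen
        pos, _ = nodes[idx]
        end = pos + direction * length
        nodes.append((end, radius))
        child = len(nodes) - 1
        edges.append((idx, child))
        if gen < branching_depth:
            theta = np.deg2rad(branch_angle_deg)
            perp = _perpendicular(direction, rng)
            perp2 = np.cross(direction, perp)
            phi = rng.uniform(0, 2 * np.pi)
            u = np.cos(phi) * perp + np.sin(phi) * perp2
            for sign in (+1.0, -1.0):
                d = _unit(np.cos(theta) * direction + sign * np.sin(theta) * u)
                frontier.append((child, d, gen + 1))
    if bounds_um is not None:
        lo = np.zeros(3)
        for i, (p, c) in enumerate(edges):
            for j in (p, c):
                pos = nodes[j][0]
                if np.any(pos < lo - 1e-9) or np.any(pos > np.asarray(bounds_um) + 1e-9):
                    raise SizingError(
                        f"segment {i} (nodes {p}->{c}) at {pos} exceeds bounds {bounds_um}"
                    )
    entrance = (nodes[0][0].copy(), root_dir.copy())
    return DuctTree(nodes=nodes, edges=edges, entrance_plane=entrance)


def _paint_capsule(
    mask: np.ndarray,
    p0_vox: np.ndarray,
    p1_vox: np.ndarray,
    radius_vox: float,
) -> None:
    """Set voxels within ``radius_vox`` of segment p0–p1 (capsule) in-place."""
    lo = np.floor(np.minimum(p0_vox, p1_vox) - radius_vox - 1).astype(int)
    hi = np.ceil(np.maximum(p0_vox, p1_vox) + radius_vox + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1_vox - p0_vox
    seg_len2 = float(d.dot(d))
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0_vox, axis=-1)
    else:
        t = np.clip((pts - p0_vox).dot(d) / seg_len2, 0.0, 1.0)
        proj = p0_vox + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= dist <= radius_vox


def rasterize_tree(
    tree: DuctTree,
    voxel_size_um: float,
    shape: tuple[int, int, int],
    origin_um: np.ndarray,
) -> np.ndarray:
    """Rasterize the duct tree as a boolean lumen mask on the given grid.

    ``origin_um`` maps voxel index 0 to a micrometre coordinate. Radii
    smaller than 2 voxel edges are rejected (they cannot stay 6-connected).
    """
    mask = np.zeros(shape, dtype=bool)
    for i, (p0, p1, r) in enumerate(tree.segments()):
        r_vox = r / voxel_size_um
        if r_vox <= 2.0:
            raise SizingError(
                f"segment {i} radius {r:.2f} um is <= 2 voxel edges at "
                f"{voxel_size_um} um/voxel"
            )
        _paint_capsule(
            mask,
            (p0 - origin_um) / voxel_size_um,
            (p1 - origin_um) / voxel_size_um,
            r_vox,
        )
    return mask


def _sphere_local(center_vox: np.ndarray, radius_vox: float, shape) -> tuple:
    """Boolean ball and its bounding slices on the global grid."""
    lo = np.maximum(np.floor(center_vox - radius_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + radius_vox + 2).astype(int), shape)
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij"
    )
    dist = np.sqrt(
        (zz - center_vox[0]) ** 2 + (yy - center_vox[1]) ** 2 + (xx - center_vox[2]) ** 2
    )
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    return dist <= radius_vox, sl


def _touches_6(a: np.ndarray, b: np.ndarray) -> bool:
    """True if any voxel of ``a`` is identical to or 6-adjacent to one of ``b``."""
    if not a.any() or not b.any():
        return False
    grown = ndimage.binary_dilation(b, structure=STRUCT_6)
    return bool(np.any(a & grown))


def synthesize_acinus(
    tree: DuctTree,
    n_alveoli: int,
    alveolus_radius_um: float,
    voxel_size_um: float,
    seed: int,
    mouth_depth_frac: float = 0.5,
    max_attempts_per_alveolus: int = 100,
) -> AcinusPhantom:
    """Rasterize a duct tree and attach ``n_alveoli`` alveoli to its walls.

    Alveoli are spheres whose centres sit just outside the duct wall so the
    sphere overlaps the lumen, carving a single circular mouth — the only
    wall interruption of that alveolus, which is the assumption behind
    entrance-ring disector counting. Placement is rejection-sampled: a
    candidate is discarded if it would merge with (touch, under
    6-connectivity) a previously placed alveolus or leave the stack margin.
    After ``100 × n_alveoli`` failed attempts a :class:`PlacementError`
    reports how many alveoli were placed.

    The returned manifest is exact by construction and re-checked by
    :meth:`AcinusPhantom.verify`.
    """
    if n_alveoli < 0:
        raise ValueError("n_alveoli must be >= 0")
    rng = np.random.default_rng(seed)
    # margin keeps all air off the stack faces: empty first/last slices make
    # every alveolus appear AND disappear inside the stack (disector needs both)
    margin_um = alveolus_radius_um * 2.5 + 4 * voxel_size_um
    positions = np.array([n[0] for n in tree.nodes])
    radii = np.array([n[1] for n in tree.nodes])
    lo_um = (positions - radii[:, None]).min(axis=0) - margin_um
    hi_um = (positions + radii[:, None]).max(axis=0) + margin_um
    shape = tuple(np.ceil((hi_um - lo_um) / voxel_size_um).astype(int) + 1)
    duct = rasterize_tree(tree, voxel_size_um, shape, lo_um)
    labels = np.zeros(shape, dtype=np.uint16)
    labels[duct] = 1

    segs = tree.segments()
    seg_lengths = np.array([np.linalg.norm(p1 - p0) for p0, p1, _ in segs])
    seg_weights = seg_lengths / seg_lengths.sum()
    r_alv_vox = alveolus_radius_um / voxel_size_um

    placed = 0
    attempts = 0
    budget = max(1, max_attempts_per_alveolus * max(n_alveoli, 1))
    while placed < n_alveoli:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {placed} of {n_alveoli} alveoli after {attempts} attempts"
            )
        attempts += 1
        si = rng.choice(len(segs), p=seg_weights)
        p0, p1, r_seg = segs[si]
        axis = _unit(p1 - p0)
        t = rng.uniform(0.15, 0.85)
        point = p0 + t * (p1 - p0)
        direction = _perpendicular(axis, rng)
        # centre just outside the wall: the sphere dips mouth_depth into the lumen
        mouth_depth = mouth_depth_frac * min(alveolus_radius_um, r_seg)
        center_um = point + direction * (r_seg + alveolus_radius_um - mouth_depth)
        center_vox = (center_um - lo_um) / voxel_size_um
        if np.any(center_vox - r_alv_vox < 2) or np.any(
            center_vox + r_alv_vox > np.array(shape) - 3
        ):
            continue
        sphere, sl = _sphere_local(center_vox, r_alv_vox, shape)
        local = labels[sl]
        new_vox = sphere & (local == 0)
        if not new_vox.any():
            continue
        # mouth: must open into the duct lumen (air path), via overlap or adjacency
        if not _touches_6(sphere, local == 1):
            continue
        # non-merging: may not touch any other alveolus
        if _touches_6(ndimage.binary_dilation(new_vox, structure=STRUCT_6), local >= 2):
            continue
        local[new_vox] = placed + 2
        labels[sl] = local
        placed += 1

    n_air = int(np.count_nonzero(labels))
    truth = {
        "true_volume_mm3": n_air * voxel_size_um**3 * 1e-9,
        "n_alveoli": n_alveoli,
        "voxel_size_um": voxel_size_um,
        "seed": int(seed),
    }
    ent_point_vox = (tree.entrance_plane[0] - lo_um) / voxel_size_um
    phantom = AcinusPhantom(
        labels=labels,
        voxel_size_um=voxel_size_um,
        truth=truth,
        entrance_plane=(ent_point_vox, tree.entrance_plane[1].copy()),
    )
    phantom.verify()
    return phantom


def add_parent_airway(
    phantom: AcinusPhantom,
    radius_um: float,
    length_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Prepend a conducting-airway stub proximal of the acinar entrance.

    Returns ``(labels, proximal_mask)`` on an enlarged grid in which a
    cylindrical airway of the given radius extends from the entrance plane
    *against* the entrance normal (towards the z=0 face). The stub is air
    (label 1) but not part of the acinus truth; ``proximal_mask`` marks it so
    callers can verify that a segmentation stopper keeps region growing out
    of it.
    """
    if phantom.entrance_plane is None:
        raise ValueError("phantom has no entrance plane")
    point_vox, normal = phantom.entrance_plane
    if not np.allclose(normal, [1.0, 0.0, 0.0]):
        raise NotImplementedError("parent airway extension assumes a +z entrance normal")
    vox = phantom.voxel_size_um
    pad = int(np.ceil(length_um / vox))
    shape = phantom.labels.shape
    labels = np.zeros((shape[0] + pad, shape[1], shape[2]), dtype=phantom.labels.dtype)
    labels[pad:] = phantom.labels
    proximal = np.zeros_like(labels, dtype=bool)
    r_vox = radius_um / vox
    zz, yy, xx = np.meshgrid(
        np.arange(0, pad + int(np.ceil(point_vox[0])) + 1),
        np.arange(shape[1]),
        np.arange(shape[2]),
        indexing="ij",
    )
    dist = np.sqrt((yy - point_vox[1]) ** 2 + (xx - point_vox[2]) ** 2)
    tube = dist <= r_vox
    proximal[: tube.shape[0]][tube] = True
    proximal &= labels == 0
    labels[proximal] = 1
    return labels, proximal


def render_grayscale(
    labels: np.ndarray,
    tissue_level: int = 200,
    air_level: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    dtype=np.uint8,
) -> VoxelStack:
    """Render a label volume as a tomography-like grayscale stack.

    Air (any nonzero label) is dark, tissue septa and embedding background
    bright, mimicking absorption-contrast stacks of osmium-stained lung.
    Additive Gaussian noise (``noise_sd`` gray levels) is applied per voxel,
    deterministically for a fixed seed. If the noise is so large that an
    Otsu threshold no longer separates the two known levels, a warning is
    logged but the stack is still produced.

    Note: the ``voxel_size_um`` of the output is 1.0 placeholder-free only
    when labels came from a phantom — use :func:`render_phantom` for that.
    """
    if tissue_level <= air_level:
        raise ValueError("tissue_level must exceed air_level")
    gray = np.where(labels > 0, float(air_level), float(tissue_level))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
        info = np.iinfo(dtype)
        gray = np.clip(gray, info.min, info.max)
        try:
            from skimage.filters import threshold_otsu

            thr = threshold_otsu(gray.astype(dtype))
            if not (air_level < thr < tissue_level):
                import logging

                logging.getLogger(__name__).warning(
                    "Otsu threshold %.1f does not separate air %d from tissue %d",
                    thr,
                    air_level,
                    tissue_level,
                )
        except ValueError:
            pass
    return VoxelStack(gray.astype(dtype), voxel_size_um=1.0)


def render_phantom(
    phantom: AcinusPhantom,
    tissue_level: int = 200,
    air_level: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelStack:
    """Render a phantom's labels with the phantom's own voxel size attached."""
    stack = render_grayscale(phantom.labels, tissue_level, air_level, noise_sd, seed)
    return VoxelStack(stack.data, voxel_size_um=phantom.voxel_size_um)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Moment-match (mean, CV) to log-normal (mu, sigma) of the underlying normal."""
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def synthesize_cohort(
    profile: CohortProfile,
    seed: int,
    n_alveoli_render: int = 8,
    branching_depth: int = 2,
    base_voxel_size_um: float = 1.48,
) -> list[AcinusPhantom]:
    """Generate a cohort of phantoms whose true volumes follow the profile.

    Target volumes are drawn from a log-normal moment-matched to the
    profile's (mean, CV) — acinar volume distributions are right-skewed
    early in development and near-symmetric at low CV, which the log-normal
    reproduces. Each phantom's geometry is rendered at desk scale with
    ``n_alveoli_render`` alveoli (full-scale alveolar numbers are not
    needed to exercise the estimators, which are scale-free); the voxel
    size is then set so the realized air volume equals the drawn target
    exactly. Realized volumes and counts live in each truth manifest.
    """
    rng = np.random.default_rng(seed)
    mu, sigma = _lognormal_params(profile.mean_volume_mm3, profile.cv_volume)
    targets = rng.lognormal(mu, sigma, size=profile.n_acini)
    phantoms = []
    for k, target in enumerate(targets):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        # Poisson-jittered alveolar number, clipped to the packing capacity of
        # the desk-scale tree so placement never exhausts its retry budget
        n_alv = int(np.clip(rng.poisson(n_alveoli_render), 1, n_alveoli_render + 4))
        tree = build_duct_tree(
            branching_depth,
            segment_length_um=40.0,
            radius_um=9.0,
            seed=sub_seed,
        )
        ph = synthesize_acinus(
            tree,
            n_alveoli=n_alv,
            alveolus_radius_um=10.0,
            voxel_size_um=base_voxel_size_um,
            seed=sub_seed,
        )
        n_air = int(np.count_nonzero(ph.labels))
        # rescale the grid so the realized physical volume equals the draw
        vox = (target * 1e9 / n_air) ** (1.0 / 3.0)
        ph.voxel_size_um = vox
        ph.truth["voxel_size_um"] = vox
        ph.truth["true_volume_mm3"] = n_air * vox**3 * 1e-9
        ph.truth["profile_day"] = profile.day
        ph.truth["acinus_index"] = k
        ph.verify()
        phantoms.append(ph)
    return phantoms
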