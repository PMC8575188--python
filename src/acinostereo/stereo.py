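"""Design-based stereology: SURS designs, Cavalieri volumes, disector counts.

The estimators here follow the classical design-based canon. Volume is
estimated by the Cavalieri principle on a systematic uniform random (SURS)
set of sections, V = t · a_p · ΣP, with section separation ``t``, area per
test point ``a_p`` and total point count ΣP. Particle (alveolus) number is
estimated with the physical disector on paired sections: an alveolar
entrance ring contributes one counting event when it appears or disappears
between the two sections of a pair; summing both event kinds over pairs
spanning the object and halving gives an unbiased count.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

__all__ = [
    "SliceSample",
    "PointGrid",
    "CavalieriEstimate",
    "DisectorResult",
    "ShrinkageFactor",
    "surs_slices",
    "subsample_acini",
    "count_points",
    "cavalieri_volume",
    "disector_count",
    "detect_interruptions",
    "shrinkage_factor",
    "apply_correction",
]


@dataclasses.dataclass(frozen=True)
class SliceSample:
    """A systematic set of slice indices: {offset, offset+interval, ...} ∩ [0, depth)."""

    depth: int
    interval: int
    offset: int

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.interval > self.depth:
            raise ValueError(f"interval {self.interval} exceeds depth {self.depth}")
        if not (0 <= self.offset < self.interval):
            raise ValueError(f"offset must lie in [0, {self.interval})")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.offset, self.depth, self.interval)

    def __len__(self) -> int:
        return len(self.indices)


@dataclasses.dataclass(frozen=True)
class PointGrid:
    """A square test-point grid with spacing in µm and a 2D origin offset.

    The area per point is a_p = spacing². Offsets are in µm within
    [0, spacing)²; a uniformly random offset makes point counting unbiased.
    """

    spacing_um: float
    origin_offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if not all(0 <= o < self.spacing_um for o in self.origin_offset_um):
            raise ValueError("origin offsets must lie in [0, spacing)")

    @property
    def a_p_um2(self) -> float:
        return self.spacing_um**2


@dataclasses.dataclass
class CavalieriEstimate:
    """Cavalieri volume estimate V = t · a_p · ΣP (µm³ → mm³)."""

    sum_points: int
    a_p_um2: float
    t_um: float
    volume_mm3: float
    ce: float | None = None
    per_slice_counts: list[int] | None = None


@dataclasses.dataclass
class DisectorResult:
    """Counting events from paired sections.

    ``n_estimate = (q_appear + q_disappear) / 2 × pairs_total / pairs_examined``:
    each particle whose extent lies inside the stack appears exactly once and
    disappears exactly once over the exhaustive pair set, so the halved event
    sum counts it once; the pair fraction scales a subsampled design back up.
    """

    q_appear: int
    q_disappear: int
    pairs_examined: int
    pairs_total: int

    @property
    def n_estimate(self) -> float:
        if self.pairs_examined == 0:
            return 0.0
        return (self.q_appear + self.q_disappear) / 2.0 * (
            self.pairs_total / self.pairs_examined
        )


@dataclasses.dataclass
class ShrinkageFactor:
    """Fresh-versus-processed volume ratio used to correct estimated volumes.

    ``v_displacement`` is the fresh lobe volume by fluid displacement;
    ``v_cavalieri`` the same lobe re-estimated on processed sections. Their
    ratio multiplies tissue-derived volume estimates to undo processing
    shrinkage.
    """

    v_displacement: float
    v_cavalieri: float

    def __post_init__(self) -> None:
        if self.v_displacement <= 0 or self.v_cavalieri <= 0:
            raise ValueError("both volumes must be positive")

    @property
    def factor(self) -> float:
        return self.v_displacement / self.v_cavalieri


def surs_slices(depth: int, interval: int, seed: int | None = None, offset: int | None = None) -> SliceSample:
    """Draw a systematic uniform random slice set.

    The offset is uniform on {0, …, interval−1} from ``seed`` unless pinned
    explicitly with ``offset``.
    """
    if offset is None:
        rng = np.random.default_rng(seed)
        offset = int(rng.integers(0, interval))
    return SliceSample(depth=depth, interval=interval, offset=offset)


def subsample_acini(
    acinus_ids: Sequence, fraction_denominator: int, seed: int | None = None, start: int | None = None
) -> list:
    """Systematically subsample every k-th acinus from an ordered list.

    With denominator k, selects ``ids[start::k]`` where ``start`` is uniform
    on {0, …, k−1} — e.g. every third acinus, randomly starting with the
    first, second, or third one. An empty list yields an empty selection.
    """
    if fraction_denominator < 1:
        raise ValueError("fraction_denominator must be >= 1")
    ids = list(acinus_ids)
    if not ids:
        return []
    if start is None:
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, fraction_denominator))
    if not (0 <= start < fraction_denominator):
        raise ValueError("start must lie in [0, denominator)")
    return ids[start::fraction_denominator]


def count_points(
    mask_slice: np.ndarray, grid: PointGrid, voxel_size_um: float
) -> int:
    """Count grid nodes whose nearest voxel lies inside a 2D mask.

    Nodes sit at ``origin_offset + k·spacing`` in µm over the slice plane
    (y, x); the nearest voxel is the rounded node position in voxel units.
    """
    mask_slice = np.asarray(mask_slice).astype(bool)
    ny, nx = mask_slice.shape
    spacing_vox = grid.spacing_um / voxel_size_um
    oy = grid.origin_offset_um[0] / voxel_size_um
    ox = grid.origin_offset_um[1] / voxel_size_um
    ys = np.arange(oy, ny, spacing_vox)
    xs = np.arange(ox, nx, spacing_vox)
    if ys.size == 0 or xs.size == 0:
        return 0
    yi = np.rint(ys).astype(int)
    xi = np.rint(xs).astype(int)
    yi = yi[(yi >= 0) & (yi < ny)]
    xi = xi[(xi >= 0) & (xi < nx)]
    return int(mask_slice[np.ix_(yi, xi)].sum())


def _gundersen_jensen_ce(counts: np.ndarray) -> float | None:
    """Gundersen–Jensen CE of a Cavalieri estimate, smoothness class 0.

    With per-section point counts P_i, A = ΣP_i², B = ΣP_iP_{i+1},
    C = ΣP_iP_{i+2}; Var_SURS = (3A − 4B + C)/12 and CE = √Var / ΣP.
    Requires at least 3 sections.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 3:
        return None
    total = counts.sum()
    if total == 0:
        return None
    a = float((counts * counts).sum())
    b = float((counts[:-1] * counts[1:]).sum())
    c = float((counts[:-2] * counts[2:]).sum())
    var = max(0.0, (3.0 * a - 4.0 * b + c) / 12.0)
    return math.sqrt(var) / total


def cavalieri_volume(
    mask_or_counts,
    sample: SliceSample,
    grid: PointGrid,
    voxel_size_um: float,
) -> CavalieriEstimate:
    """Cavalieri volume from a binary volume or precomputed per-slice counts.

    V = t · a_p · ΣP with t = interval × voxel size. The Gundersen–Jensen
    smoothness-class-0 CE is attached when at least 3 sections were counted.
    """
    if len(sample) == 0:
        raise ValueError("empty slice sample")
    if isinstance(mask_or_counts, (list, tuple)) or (
        isinstance(mask_or_counts, np.ndarray) and mask_or_counts.ndim == 1
    ):
        counts = [int(c) for c in mask_or_counts]
        if len(counts) != len(sample):
            raise ValueError("per-slice counts do not match the sample size")
    else:
        mask = np.asarray(mask_or_counts)
        if mask.ndim != 3:
            raise ValueError("mask must be a 3D binary volume")
        counts = [count_points(mask[z], grid, voxel_size_um) for z in sample.indices]
    sum_points = int(sum(counts))
    t_um = sample.interval * voxel_size_um
    volume_mm3 = t_um * grid.a_p_um2 * sum_points * 1e-9
    return CavalieriEstimate(
        sum_points=sum_points,
        a_p_um2=grid.a_p_um2,
        t_um=t_um,
        volume_mm3=volume_mm3,
        ce=_gundersen_jensen_ce(np.array(counts)),
        per_slice_counts=counts,
    )


def _presence_sets(labels_or_events, min_label: int = 2) -> list[set]:
    """Per-slice sets of particle identities.

    Accepts a 3D label volume (labels >= ``min_label`` are particles; the
    duct lumen label 1 and background 0 are ignored) or an explicit
    per-slice list of identity collections.
    """
    if isinstance(labels_or_events, np.ndarray) and labels_or_events.ndim == 3:
        out = []
        for z in range(labels_or_events.shape[0]):
            present = np.unique(labels_or_events[z])
            out.append({int(v) for v in present if v >= min_label})
        return out
    return [set(ev) for ev in labels_or_events]


def disector_count(labels_or_events, sample: SliceSample | None = None, pair_step: int = 1) -> DisectorResult:
    """Physical disector count of alveoli over paired consecutive sections.

    For each examined pair (i, i+1), a particle present in section i+1 but
    not i is an appearance (Q⁺-type event); present in i but not i+1 a
    disappearance. ``n = (q_appear + q_disappear)/2`` over the exhaustive
    pair set, scaled by the examined-pair fraction for subsampled designs.
    On a phantom label volume with exhaustive pairs the result equals the
    manifest count exactly.

    ``sample`` selects which pairs are examined: pair i is examined when i
    is in the sample (default: all pairs). ``pair_step`` examines every
    k-th pair when no explicit sample is given.
    """
    presence = _presence_sets(labels_or_events)
    depth = len(presence)
    if depth < 2:
        raise ValueError("disector needs at least 2 sections")
    pairs_total = depth - 1
    if sample is not None:
        pair_indices = [int(i) for i in sample.indices if i < pairs_total]
    else:
        pair_indices = list(range(0, pairs_total, pair_step))
    if not pair_indices:
        raise ValueError("no section pairs selected")
    q_app = 0
    q_dis = 0
    for i in pair_indices:
        a, b = presence[i], presence[i + 1]
        q_app += len(b - a)
        q_dis += len(a - b)
    return DisectorResult(
        q_appear=q_app,
        q_disappear=q_dis,
        pairs_examined=len(pair_indices),
        pairs_total=pairs_total,
    )


def detect_interruptions(mask_slice: np.ndarray) -> list[tuple[float, float]]:
    """Best-effort detection of alveolar wall interruptions on one section.

    An open alveolar mouth shows up on a section as a gap in the septal wall
    separating the alveolar profile from the duct lumen: the two free septal
    tips flanking the gap. The heuristic skeletonizes the wall (tissue
    adjacent to air), finds skeleton endpoints (free septal tips), and pairs
    nearest tips — each pair is one candidate entrance-ring crossing,
    returned as the gap midpoint.

    This detector is approximate by design: quantitative counting runs on
    label volumes where ground truth is exact; this helper exists for
    exploratory work on grayscale data. An all-air or all-tissue section
    has no wall to interrupt and yields no events; a closed air profile has
    an endpoint-free wall and likewise yields none.
    """
    from scipy import ndimage as ndi
    from skimage.morphology import skeletonize

    mask = np.asarray(mask_slice).astype(bool)
    if not mask.any() or mask.all():
        return []
    tissue = ~mask
    wall = tissue & ndi.binary_dilation(mask, structure=np.ones((3, 3), bool))
    if not wall.any():
        return []
    # septa floating inside the air space (not connected to the section frame)
    # are taken whole, so their skeleton is a line with free tips rather than
    # a surface annulus; the outer tissue contributes only its air boundary
    comp, n_comp = ndi.label(tissue, structure=np.ones((3, 3), int))
    border_labels = set(np.unique(np.concatenate([
        comp[0], comp[-1], comp[:, 0], comp[:, -1]
    ])))
    interior = tissue & ~np.isin(comp, sorted(border_labels))
    skel = skeletonize(wall | interior)
    neigh = ndi.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant")
    endpoints = skel & (neigh == 2)  # self + exactly one neighbour
    ys, xs = np.nonzero(endpoints)
    tips = [(int(y), int(x)) for y, x in zip(ys, xs)]
    # pair nearest free tips; each pair flanks one wall gap
    events: list[tuple[float, float]] = []
    remaining = tips[:]
    while len(remaining) >= 2:
        a = remaining.pop(0)
        dists = [((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2, j) for j, b in enumerate(remaining)]
        _, j = min(dists)
        b = remaining.pop(j)
        events.append(((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0))
    return events


def shrinkage_factor(v_displacement: float, v_cavalieri: float) -> ShrinkageFactor:
    """Shrinkage from a fresh (displacement) and processed (Cavalieri) lobe volume."""
    return ShrinkageFactor(v_displacement=v_displacement, v_cavalieri=v_cavalieri)


def apply_correction(volume: float, factor: ShrinkageFactor | float) -> float:
    """Multiply an estimated volume by the shrinkage factor."""
    f = factor.factor if isinstance(factor, ShrinkageFactor) else float(factor)
    if f <= 0:
        raise ValueError("shrinkage factor must be positive")
    return volume * f
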