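"""Single-acinus extraction by stopper-bounded threshold region growing.

An acinus is isolated from a grayscale stack by (1) placing disk-shaped
segmentation stoppers across the airway lumen at the acinar entrance — the
bronchioalveolar duct junction — so that (2) a gray-level threshold region
growing started from a seed point just distal of the stopper floods exactly
the air space of that one acinus and cannot escape into the conducting
airways.

Air growth uses 6-connectivity: a flood that can step diagonally would leak
through single-voxel septal gaps, whereas a stopper two or more voxels
thick is airtight against face-connected growth by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volio import VoxelStack, write_overlay

__all__ = [
    "SegmentationStopper",
    "SegmentationResult",
    "SeedError",
    "rasterize_stopper",
    "rasterize_stoppers",
    "suggest_threshold",
    "suggest_seed_point",
    "region_grow",
    "extract_acinus",
    "load_stoppers",
]

STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class SeedError(ValueError):
    """Seed point unusable: in tissue, inside a stopper, or out of bounds."""


@dataclasses.dataclass
class SegmentationStopper:
    """A solid oriented disk blocking an airway cross-section.

    ``center`` is a (z, y, x) voxel triple, ``normal`` the disk axis,
    ``radius_um`` the disk radius (it should cover the airway caliber it
    blocks), and ``thickness_vox`` the extent along the axis — at least 2
    voxels so the plug is airtight under 6-connectivity.
    """

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius_um: float
    thickness_vox: int = 3

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("stopper normal must be nonzero")
        self.normal = tuple(np.asarray(self.normal, float) / n)
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.thickness_vox < 2:
            raise ValueError("thickness_vox must be >= 2 to be airtight")


@dataclasses.dataclass
class SegmentationResult:
    """Output of a stopper-bounded region growing run."""

    mask: np.ndarray
    seed_point: tuple[int, int, int]
    threshold: float
    stoppers_used: list[SegmentationStopper]
    voxel_count: int
    touches_boundary: bool = False

    def provenance(self) -> dict:
        return {
            "seed_point": [int(v) for v in self.seed_point],
            "threshold": float(self.threshold),
            "stoppers": [
                {
                    "center": [float(v) for v in s.center],
                    "normal": [float(v) for v in s.normal],
                    "radius_um": float(s.radius_um),
                    "thickness_vox": int(s.thickness_vox),
                }
                for s in self.stoppers_used
            ],
            "voxel_count": int(self.voxel_count),
        }


def rasterize_stopper(
    stopper: SegmentationStopper,
    shape: tuple[int, int, int],
    voxel_size_um: float,
) -> np.ndarray:
    """Rasterize a stopper as a solid oriented cylinder of voxels.

    A voxel belongs to the plug when its axial distance from the disk plane
    is within half the thickness and its radial distance within the radius.
    Disks reaching past the stack edge are clipped, never an error.
    """
    center = np.asarray(stopper.center, float)
    if np.any(center < 0) or np.any(center >= np.asarray(shape)):
        raise ValueError(f"stopper center {stopper.center} outside stack shape {shape}")
    normal = np.asarray(stopper.normal, float)
    r_vox = stopper.radius_um / voxel_size_um
    half_t = stopper.thickness_vox / 2.0
    reach = int(np.ceil(max(r_vox, half_t))) + 1
    lo = np.maximum(np.floor(center - reach).astype(int), 0)
    hi = np.minimum(np.ceil(center + reach).astype(int) + 1, shape)
    zz, yy, xx = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(3)), indexing="ij")
    rel = np.stack([zz, yy, xx], axis=-1) - center
    axial = rel @ normal
    radial = np.linalg.norm(rel - axial[..., None] * normal, axis=-1)
    out = np.zeros(shape, dtype=bool)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = (np.abs(axial) <= half_t) & (
        radial <= r_vox
    )
    return out


def rasterize_stoppers(
    stoppers: Sequence[SegmentationStopper],
    shape: tuple[int, int, int],
    voxel_size_um: float,
) -> np.ndarray:
    """Union of all stopper rasterizations."""
    out = np.zeros(shape, dtype=bool)
    for s in stoppers:
        out |= rasterize_stopper(s, shape, voxel_size_um)
    return out


def suggest_threshold(gray: VoxelStack, override: float | None = None) -> float:
    """Suggest an air/tissue gray threshold (Otsu), or return the override.

    Acinar stacks are strongly bimodal — dark air, bright osmium-stained
    tissue — so Otsu's criterion lands between the modes. A constant stack
    has no threshold and raises.
    """
    if override is not None:
        return float(override)
    from skimage.filters import threshold_otsu

    data = gray.data
    if data.min() == data.max():
        raise ValueError("constant stack: no threshold separates air from tissue")
    otsu = threshold_otsu(data)
    # place the cut mid-gap so it lies strictly between the two classes
    lower = data[data <= otsu].max()
    upper = data[data > otsu].min()
    return float(lower + upper) / 2.0


def suggest_seed_point(
    stopper: SegmentationStopper, distal_sign: float = 1.0
) -> tuple[int, int, int]:
    """Place a seed one stopper-thickness distal of the stopper along its normal."""
    center = np.asarray(stopper.center, float)
    normal = np.asarray(stopper.normal, float)
    seed = center + distal_sign * normal * (stopper.thickness_vox + 1)
    return tuple(int(round(v)) for v in seed)


def region_grow(
    gray: VoxelStack,
    seed_point: Sequence[int],
    threshold: float,
    stoppers: Sequence[SegmentationStopper] = (),
) -> SegmentationResult:
    """Grow the 6-connected air region containing the seed, bounded by stoppers.

    The mask is the 6-connected component of ``{gray <= threshold} minus
    stopper voxels`` that contains the seed: deterministic, and idempotent in
    the sense that growing again from any voxel of the result reproduces it.
    A mask touching the stack boundary is flagged (a possible stopper leak)
    but not an error.
    """
    seed = tuple(int(v) for v in seed_point)
    shape = gray.data.shape
    if any(not (0 <= seed[i] < shape[i]) for i in range(3)):
        raise SeedError(f"seed {seed} outside stack shape {shape}")
    if gray.data[seed] > threshold:
        raise SeedError(
            f"seed {seed} lies in tissue: gray {gray.data[seed]} > threshold {threshold}"
        )
    plug = rasterize_stoppers(stoppers, shape, gray.voxel_size_um)
    if plug[seed]:
        raise SeedError(f"seed {seed} lies inside a segmentation stopper")
    air = (gray.data <= threshold) & ~plug
    comp, _ = ndimage.label(air, structure=STRUCT_6)
    mask = comp == comp[seed]
    touches = bool(
        mask[0].any()
        or mask[-1].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
        or mask[:, :, 0].any()
        or mask[:, :, -1].any()
    )
    if touches:
        import logging

        logging.getLogger(__name__).warning(
            "segmentation mask touches the stack boundary; an undersized "
            "stopper may have let the region leak"
        )
    return SegmentationResult(
        mask=mask,
        seed_point=seed,
        threshold=float(threshold),
        stoppers_used=list(stoppers),
        voxel_count=int(mask.sum()),
        touches_boundary=touches,
    )


def _manifest_digest(provenance: dict) -> str:
    return hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()
    ).hexdigest()


def extract_acinus(
    gray: VoxelStack, result: SegmentationResult, path: str | Path
) -> Path:
    """Export a segmented acinus as an overlay stack plus provenance manifest.

    The overlay shows the mask brightened over the original background; the
    JSON sidecar records seed, threshold, and stopper list with an integrity
    digest so tampering is detectable on re-read.
    """
    path = Path(path)
    write_overlay(gray, result.mask, path)
    prov = result.provenance()
    manifest = {"provenance": prov, "digest": _manifest_digest(prov)}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def read_acinus_manifest(path: str | Path) -> dict:
    """Read and integrity-check an extraction manifest."""
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    if _manifest_digest(manifest["provenance"]) != manifest.get("digest"):
        raise ValueError(f"{path}: manifest digest mismatch (tampered or corrupt)")
    return manifest["provenance"]


def load_stoppers(path: str | Path) -> list[SegmentationStopper]:
    """Load a stopper list from JSON or YAML.

    Format: ``[{center: [z, y, x], normal: [dz, dy, dx], radius_um, thickness_vox}]``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        entries = yaml.safe_load(text)
    else:
        entries = json.loads(text)
    return [
        SegmentationStopper(
            center=tuple(e["center"]),
            normal=tuple(e["normal"]),
            radius_um=float(e["radius_um"]),
            thickness_vox=int(e.get("thickness_vox", 3)),
        )
        for e in entries
    ]
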