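"""Volumetric image and counting-table I/O with explicit geometry conventions.

All volumes are indexed ``(z, y, x)``, 0-based, with an isotropic voxel edge
length in micrometres carried alongside the array. Slice sets are half-open
``[offset, depth)``. Voxel size is mandatory metadata everywhere: readers
raise rather than silently assuming 1 µm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "VoxelStack",
    "CountingTable",
    "read_stack",
    "write_stack",
    "write_overlay",
    "read_overlay",
    "export_slice_set",
    "read_counting_table",
    "write_counting_table",
    "load_packaged_table",
    "load_reference_values",
    "load_expected_aggregates",
]

_DATA_DIR = Path(__file__).parent / "data"

#: Names of the per-animal tables bundled with the package, keyed by quantity.
PACKAGED_TABLES = {
    "counts": "alveolar_counts.csv",
    "volume_mm3": "acinar_volumes.csv",
    "density_per_mm3": "alveolar_densities.csv",
}

_TABLE_COLUMNS = [
    "animal_id",
    "day",
    "assessed_acini",
    "average",
    "sd",
    "minimum",
    "maximum",
]


@dataclasses.dataclass
class VoxelStack:
    """A 3D grayscale (or label) volume with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``.
    voxel_size_um:
        Isotropic voxel edge length in micrometres; must be positive.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm³ (1 µm³ = 1e-9 mm³)."""
        return self.voxel_size_um**3 * 1e-9


@dataclasses.dataclass
class CountingTable:
    """Per-animal summary rows for one morphometric quantity.

    Each row holds (animal_id, day, assessed_acini, average, sd, minimum,
    maximum) for one animal, mirroring the layout of per-animal stereology
    result tables.
    """

    quantity: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"counting table missing columns {missing}")
        self.frame = self.frame[_TABLE_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for idx, row in self.frame.iterrows():
            rid = f"{row['animal_id']} (row {idx})"
            if row["assessed_acini"] < 1:
                raise ValueError(f"{rid}: assessed_acini must be >= 1")
            if row["sd"] < 0:
                raise ValueError(f"{rid}: sd must be >= 0")
            if not (row["minimum"] <= row["average"] <= row["maximum"]):
                raise ValueError(
                    f"{rid}: requires minimum <= average <= maximum, got "
                    f"{row['minimum']} / {row['average']} / {row['maximum']}"
                )

    def rows_for_day(self, day: int) -> pd.DataFrame:
        sub = self.frame[self.frame["day"] == day]
        if sub.empty:
            raise ValueError(f"no animals recorded for day {day}")
        return sub

    @property
    def days(self) -> list[int]:
        return sorted(self.frame["day"].unique().tolist())


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF with voxel size in metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.data,
        metadata={"voxel_size_um": stack.voxel_size_um, "axes": "ZYX"},
    )
    return path


def _read_tiff_stack(path: Path, voxel_size_um: float | None) -> VoxelStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata or tif.imagej_metadata
    if data.ndim == 2:
        data = data[None]
    size = voxel_size_um
    if size is None and meta:
        entry = meta[0] if isinstance(meta, (list, tuple)) else meta
        size = entry.get("voxel_size_um")
    if size is None:
        raise ValueError(
            f"{path}: no voxel size in TIFF metadata; pass voxel_size_um explicitly"
        )
    return VoxelStack(data, float(size))


def _read_dicom_series(path: Path, voxel_size_um: float | None) -> VoxelStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"})
    if not files:
        raise FileNotFoundError(f"{path}: no DICOM slices (*.dcm) found")
    datasets = [pydicom.dcmread(f) for f in files]
    # slice order follows InstanceNumber, not file name
    datasets.sort(key=lambda ds: int(ds.InstanceNumber))
    data = np.stack([ds.pixel_array for ds in datasets])
    size = voxel_size_um
    if size is None:
        ds0 = datasets[0]
        spacing = getattr(ds0, "PixelSpacing", None)
        if spacing is not None:
            size = float(spacing[0]) * 1000.0  # DICOM spacing is mm
    if size is None:
        raise ValueError(
            f"{path}: no PixelSpacing in DICOM metadata; pass voxel_size_um explicitly"
        )
    return VoxelStack(data, float(size))


def read_stack(path: str | Path, voxel_size_um: float | None = None) -> VoxelStack:
    """Read a multi-page TIFF or a directory of single-frame DICOM slices.

    The voxel size is taken from file metadata; an explicit ``voxel_size_um``
    overrides it. A stack without any voxel size is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    if path.is_dir():
        return _read_dicom_series(path, voxel_size_um)
    return _read_tiff_stack(path, voxel_size_um)


def write_dicom_series(stack: VoxelStack, directory: str | Path) -> list[Path]:
    """Write a stack as a directory of single-frame DICOM files.

    One file per slice, ``InstanceNumber`` ascending with z; voxel size stored
    in ``PixelSpacing``/``SliceThickness`` (mm).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(stack.data.astype(np.uint16))
    series_uid = generate_uid()
    spacing_mm = stack.voxel_size_um / 1000.0
    paths = []
    for z in range(data.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.InstanceNumber = z + 1
        ds.PixelSpacing = [spacing_mm, spacing_mm]
        ds.SliceThickness = spacing_mm
        ds.Rows, ds.Columns = data.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = data[z].tobytes()
        out = directory / f"slice_{z:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        paths.append(out)
    return paths


def _mask_path(path: Path) -> Path:
    return path.with_name(path.stem + ".mask" + path.suffix)


def write_overlay(gray: VoxelStack, mask: np.ndarray, path: str | Path) -> Path:
    """Persist a segmented region overlaid on its grayscale background.

    Masked voxels are brightened towards white over the original gray so the
    segmentation is visible in any viewer; the exact binary mask is stored in
    a paired ``*.mask.tif`` file so it round-trips losslessly.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != gray.data.shape:
        raise ValueError(
            f"shape mismatch: gray {gray.data.shape} vs mask {mask.shape}"
        )
    path = Path(path)
    gmax = float(np.iinfo(gray.data.dtype).max) if np.issubdtype(
        gray.data.dtype, np.integer
    ) else float(gray.data.max() or 1.0)
    over = gray.data.astype(np.float64)
    over[mask] = over[mask] * 0.5 + gmax * 0.5
    over = over.astype(gray.data.dtype)
    write_stack(VoxelStack(over, gray.voxel_size_um), path)
    write_stack(VoxelStack(mask.astype(np.uint8), gray.voxel_size_um), _mask_path(path))
    return path


def read_overlay(path: str | Path) -> tuple[VoxelStack, np.ndarray]:
    """Read an overlay written by :func:`write_overlay`; returns (stack, mask)."""
    path = Path(path)
    stack = read_stack(path)
    mask = read_stack(_mask_path(path)).data.astype(bool)
    return stack, mask


def _burn_scalebar(img: np.ndarray, voxel_size_um: float, bar_um: float = 100.0) -> np.ndarray:
    """Burn a horizontal scale bar of ``bar_um`` micrometres into a 2D image."""
    img = img.copy()
    bar_px = int(round(bar_um / voxel_size_um))
    bar_px = min(bar_px, img.shape[1] - 2)
    h = max(2, img.shape[0] // 100)
    white = np.iinfo(img.dtype).max if np.issubdtype(img.dtype, np.integer) else img.max()
    img[-(h + 4) : -4, 4 : 4 + bar_px] = white
    return img


def export_slice_set(
    stack: VoxelStack,
    sample,
    directory: str | Path,
    burn_scalebar: bool = False,
    fmt: str = "png",
) -> list[Path]:
    """Export a systematic set of single slices as 2D images, named by index.

    ``sample`` is a :class:`acinostereo.stereo.SliceSample` (or anything with
    an ``indices`` attribute). With ``burn_scalebar`` a 100 µm bar is rendered
    into each slice from the voxel size.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    indices = np.asarray(getattr(sample, "indices", sample), dtype=int)
    depth = stack.data.shape[0]
    bad = indices[(indices < 0) | (indices >= depth)]
    if bad.size:
        raise IndexError(f"slice indices {bad.tolist()} outside stack depth {depth}")
    paths = []
    for z in indices:
        img = stack.data[z]
        if img.dtype not in (np.uint8, np.uint16):
            lo, hi = float(img.min()), float(img.max())
            img = ((img - lo) / (hi - lo or 1.0) * 255).astype(np.uint8)
        if burn_scalebar:
            img = _burn_scalebar(img, stack.voxel_size_um)
        out = directory / f"slice_{int(z):04d}.{fmt}"
        Image.fromarray(img).save(out)
        paths.append(out)
    return paths


def read_counting_table(path: str | Path, quantity: str = "counts") -> CountingTable:
    """Read a per-animal CSV counting table and validate its invariants."""
    frame = pd.read_csv(path)
    return CountingTable(quantity=quantity, frame=frame)


def write_counting_table(table: CountingTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    return path


def load_packaged_table(quantity: str) -> CountingTable:
    """Load one of the bundled per-animal tables.

    ``quantity`` is one of ``counts`` (alveoli per acinus), ``volume_mm3``
    (acinar volume) or ``density_per_mm3`` (alveoli per acinar volume).
    """
    if quantity not in PACKAGED_TABLES:
        raise KeyError(f"unknown quantity {quantity!r}; choose from {sorted(PACKAGED_TABLES)}")
    return read_counting_table(_DATA_DIR / PACKAGED_TABLES[quantity], quantity)


def load_reference_values() -> dict:
    """Published day-level reference inputs (cohort profiles, ductal fractions,
    cross-study series) bundled with the package."""
    with open(_DATA_DIR / "reference_values.json") as fh:
        return json.load(fh)


def load_expected_aggregates() -> dict:
    """Published day-level aggregates used by the reproduce-tables check."""
    with open(_DATA_DIR / "expected_aggregates.json") as fh:
        return json.load(fh)
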