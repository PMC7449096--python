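"""Volume and trait-table input/output.

All volumes in this package live on an isotropic voxel grid in canonical
``(z, y, x)`` axis order, with a single voxel edge length in millimetres.
Anisotropic spacing is rejected at ingest rather than resampled, because the
morphometric measurements downstream assume cubic voxels.

Supported on-disk formats: multi-page TIFF stacks (one slice per page), NRRD
and MetaImage (``.mhd``/``.mha``).  The proprietary scanner container is not
supported; its scientific content is format-independent.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

__all__ = [
    "Volume3D",
    "BinaryMask",
    "LabelMap",
    "TRAIT_COLUMNS",
    "read_volume",
    "write_volume",
    "read_trait_table",
    "write_trait_table",
]

#: Trait-table schema: identifier columns followed by the 14 measured traits.
TRAIT_COLUMNS = [
    "L_mm",
    "F_mm",
    "P_mm",
    "Vn_mm3",
    "VA3D",
    "Feret3D",
    "A_mm2",
    "Sphericity",
    "Vs_mm3",
    "T_mm",
    "Rugosity",
    "Vk_mm3",
    "FillingRatio_pct",
    "Ve_mm3",
]

ID_COLUMNS = ["accession_id", "nut_id"]

_SPACING_RTOL = 1e-4  # relative isotropy tolerance on metadata spacing


@dataclasses.dataclass
class Volume3D:
    """A 3D greyscale image ``I(z, y, x)`` on an isotropic grid.

    Parameters
    ----------
    data:
        3D array of finite scalar intensities, axis order ``(z, y, x)``.
    voxel_size_mm:
        Edge length of the cubic voxel, in mm (``> 0``).
    """

    data: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3


@dataclasses.dataclass
class BinaryMask:
    """A boolean foreground mask ``M(z, y, x)`` sharing its source's grid."""

    data: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3


@dataclasses.dataclass
class LabelMap:
    """Per-object integer labels: 0 = background, objects numbered 1..n."""

    data: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D label map, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be of integer dtype")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        labels = np.unique(self.data)
        positive = labels[labels > 0]
        if positive.size and not np.array_equal(
            positive, np.arange(1, positive.size + 1)
        ):
            raise ValueError(
                f"labels must be consecutive 1..n, got {positive.tolist()}"
            )
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")

    @property
    def n_labels(self) -> int:
        return int(self.data.max())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_ITK_SUFFIXES = {".nrrd", ".nhdr", ".mhd", ".mha"}


def read_volume(path: str | os.PathLike, voxel_size_mm: float | None = None) -> Volume3D:
    """Read a volume from TIFF stack, NRRD or MetaImage into canonical order.

    For NRRD/MetaImage the voxel size is taken from the file's spacing
    metadata (which must be isotropic); an explicit ``voxel_size_mm``
    overrides it only if consistent is not required — it must match.  TIFF
    carries no reliable 3D spacing, so ``voxel_size_mm`` is mandatory there.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        if voxel_size_mm is None:
            raise ValueError(
                f"TIFF stacks carry no 3D spacing: pass voxel_size_mm explicitly "
                f"for {path}"
            )
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        return Volume3D(data=data, voxel_size_mm=float(voxel_size_mm))
    if suffix in _ITK_SUFFIXES:
        img = sitk.ReadImage(str(path))
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        if voxel_size_mm is None:
            if not np.allclose(spacing, spacing[0], rtol=_SPACING_RTOL):
                raise ValueError(
                    f"anisotropic spacing {spacing.tolist()} in {path}: this "
                    "package requires isotropic voxels and does not resample"
                )
            voxel_size_mm = float(spacing[0])
        # GetArrayFromImage returns (z, y, x) — already canonical.
        data = sitk.GetArrayFromImage(img)
        return Volume3D(data=data, voxel_size_mm=float(voxel_size_mm))
    raise ValueError(
        f"unsupported volume format '{suffix}' for {path}: "
        "use .tif/.tiff, .nrrd/.nhdr or .mhd/.mha"
    )


def read_label_map(path: str | os.PathLike, voxel_size_mm: float | None = None) -> LabelMap:
    """Read an integer label map (same formats as :func:`read_volume`)."""
    vol = read_volume(path, voxel_size_mm=voxel_size_mm)
    return LabelMap(data=np.asarray(vol.data).astype(np.int32), voxel_size_mm=vol.voxel_size_mm)


def write_volume(vol: Volume3D | LabelMap | BinaryMask, path: str | os.PathLike) -> None:
    """Write a volume or label map; format chosen by file extension."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(
            f"cannot write {path}: parent directory {path.parent} does not exist"
        )
    data = np.asarray(vol.data)
    if isinstance(vol, LabelMap):
        data = data.astype(np.int32)
    elif isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    suffix = path.suffix.lower()
    try:
        if suffix in _TIFF_SUFFIXES:
            tifffile.imwrite(path, data)
        elif suffix in _ITK_SUFFIXES:
            img = sitk.GetImageFromArray(data)
            img.SetSpacing((vol.voxel_size_mm,) * 3)
            sitk.WriteImage(img, str(path))
        else:
            raise ValueError(f"unsupported volume format '{suffix}'")
    except (OSError, RuntimeError) as exc:
        raise OSError(f"failed to write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


def read_trait_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-nut trait table (CSV) and validate its schema.

    Required columns are the two identifiers plus the 14 trait columns of the
    measurement schema; trait columns are coerced to float and identifier
    pairs must be unique.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS + TRAIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"trait table {path} is missing required column(s): {', '.join(missing)}"
        )
    for col in TRAIT_COLUMNS:
        table[col] = pd.to_numeric(table[col], errors="raise")
    dup = table.duplicated(subset=ID_COLUMNS)
    if dup.any():
        pairs = table.loc[dup, ID_COLUMNS].to_records(index=False).tolist()
        raise ValueError(f"duplicated (accession_id, nut_id) pairs: {pairs}")
    table["accession_id"] = table["accession_id"].astype(str)
    table["nut_id"] = table["nut_id"].astype(str)
    return table


def write_trait_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a trait table as CSV with a stable column order and formatting."""
    path = Path(path)
    cols = [c for c in ID_COLUMNS + TRAIT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    # repr-based float formatting keeps round-trips exact and output
    # byte-stable across runs
    table[cols + extra].to_csv(path, index=False, float_format="%.10g")
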