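"""Quantification of the 14 walnut morphological descriptors.

From a part-labelled nut the package measures:

* compartment volumes ``Vs`` (shell), ``Vk`` (kernel), ``Ve`` (empty space)
  and their exact sum ``Vn`` (nut), in mm³;
* the three caliper sizes ``L`` (length along the first principal axis),
  ``F`` (face diameter) and ``P`` (profile diameter), in mm;
* the surface area ``A`` (mm²) of the nut from a marching-cubes mesh;
* the isoperimetric indices

  - sphericity  Ψ = π^(1/3) (6 Vn)^(2/3) / A            (1 for a sphere),
  - rugosity    Ω = A / (36 π Vn²)^(1/3) = 1/Ψ          (≥ 1),
  - shape VA3D  S1 = A³ / (36 π Vn²) = Ω³;

* the Feret shape S2 = D/d, with d the minimum caliper width over all 3D
  directions and D the maximum caliper width restricted to directions
  orthogonal to d's direction;
* the mean shell thickness ``T`` (mm) by the inscribed-sphere rule;
* the kernel filling ratio ``R`` = 100·Vk/Vn (%).

Ψ·Ω = 1 and S1 = Ω³ hold exactly because all three indices are evaluated
from the same (Vn, A) pair.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._geometry import (
    hull_vertices_mm,
    local_thickness_mean,
    max_feret_orthogonal,
    mesh_surface_area,
    min_feret,
    principal_extents,
)
from .partition import EMPTY, KERNEL, SHELL, PartLabelMap, qc_shell_integrity
from .volume_io import BinaryMask

__all__ = [
    "WalnutTraits",
    "FeretResult",
    "part_volumes",
    "principal_axes",
    "surface_area",
    "feret_shape",
    "sphericity",
    "rugosity",
    "shape_va3d",
    "shell_thickness",
    "filling_ratio",
    "measure_walnut",
]


@dataclasses.dataclass
class FeretResult:
    """Minimum caliper width d (with its direction) and the orthogonal
    maximum caliper width D; S2 = D/d >= 1."""

    d: float
    d_direction: np.ndarray
    D: float

    @property
    def s2(self) -> float:
        return self.D / self.d


@dataclasses.dataclass
class WalnutTraits:
    """The measured descriptor set for one nut (``None`` when QC failed)."""

    L: float | None = None
    F: float | None = None
    P: float | None = None
    Vn: float | None = None
    S1: float | None = None
    S2: float | None = None
    A: float | None = None
    Psi: float | None = None
    Vs: float | None = None
    T: float | None = None
    Omega: float | None = None
    Vk: float | None = None
    R: float | None = None
    Ve: float | None = None
    qc: str = "pass"
    qc_detail: str = ""

    _CSV_FIELDS = {
        "L_mm": "L",
        "F_mm": "F",
        "P_mm": "P",
        "Vn_mm3": "Vn",
        "VA3D": "S1",
        "Feret3D": "S2",
        "A_mm2": "A",
        "Sphericity": "Psi",
        "Vs_mm3": "Vs",
        "T_mm": "T",
        "Rugosity": "Omega",
        "Vk_mm3": "Vk",
        "FillingRatio_pct": "R",
        "Ve_mm3": "Ve",
    }

    def to_row(self) -> dict[str, float | None]:
        """Trait values keyed by the trait-table column names."""
        return {col: getattr(self, attr) for col, attr in self._CSV_FIELDS.items()}


def part_volumes(partmap: PartLabelMap) -> tuple[float, float, float, float]:
    """(Vs, Vk, Ve, Vn) in mm³; Vn is returned as the exact sum."""
    vv = partmap.voxel_volume_mm3
    counts = np.bincount(partmap.data.ravel(), minlength=4)
    vs = float(counts[SHELL]) * vv
    vk = float(counts[KERNEL]) * vv
    ve = float(counts[EMPTY]) * vv
    return vs, vk, ve, vs + vk + ve


def principal_axes(
    mask: BinaryMask, swap_face_profile: bool = False
) -> tuple[float, float, float, np.ndarray]:
    """(L, F, P, axes) from second-moment analysis of the nut voxels.

    L is the extent along the first principal axis; F and P are the extents
    along the second and third.  The suture plane is not detectable from
    geometry alone, so which transverse extent is "face" and which is
    "profile" is a convention — ``swap_face_profile`` flips it.
    """
    extents, axes = principal_extents(mask.data, mask.voxel_size_mm)
    L, e2, e3 = (float(v) for v in extents)
    F, P = (e3, e2) if swap_face_profile else (e2, e3)
    return L, F, P, axes


def surface_area(mask: BinaryMask, smooth_sigma_vox: float = 1.0) -> float:
    """Nut surface area in mm² from a smoothed marching-cubes mesh."""
    return mesh_surface_area(mask.data, mask.voxel_size_mm, smooth_sigma_vox)


def feret_shape(
    hull_vertices: np.ndarray, n_directions: int = 2000, refine: bool = True
) -> FeretResult:
    """Feret shape from convex-hull vertices (mm).

    d: minimum caliper width over quasi-uniform sampled 3D directions with
    local refinement; D: maximum caliper width over directions orthogonal
    (90°) to d's direction.
    """
    pts = np.asarray(hull_vertices, dtype=float)
    if pts.shape[0] < 4 or np.linalg.matrix_rank(pts - pts.mean(0)) < 3:
        raise ValueError("need at least 4 non-coplanar hull vertices")
    d, d_dir = min_feret(pts, n_directions=n_directions, refine=refine)
    D = max_feret_orthogonal(pts, d_dir)
    return FeretResult(d=d, d_direction=d_dir, D=D)


def sphericity(Vn: float, A: float) -> float:
    """Ψ = π^(1/3) (6 Vn)^(2/3) / A; equals 1 for a sphere, < 1 otherwise."""
    if Vn <= 0 or A <= 0:
        raise ValueError("Vn and A must be positive")
    return math.pi ** (1.0 / 3.0) * (6.0 * Vn) ** (2.0 / 3.0) / A


def rugosity(Vn: float, A: float) -> float:
    """Ω = A / (36 π Vn²)^(1/3); the algebraic reciprocal of sphericity."""
    if Vn <= 0 or A <= 0:
        raise ValueError("Vn and A must be positive")
    return A / (36.0 * math.pi * Vn**2) ** (1.0 / 3.0)


def shape_va3d(Vn: float, A: float) -> float:
    """S1 = A³ / (36 π Vn²) = Ω³."""
    if Vn <= 0 or A <= 0:
        raise ValueError("Vn and A must be positive")
    return A**3 / (36.0 * math.pi * Vn**2)


def shell_thickness(shell_mask: BinaryMask) -> float:
    """Mean local shell thickness (mm), inscribed-sphere definition."""
    return local_thickness_mean(shell_mask.data, shell_mask.voxel_size_mm)


def filling_ratio(Vk: float, Vn: float) -> float:
    """R = 100 · Vk / Vn, in percent."""
    if Vn <= 0:
        raise ValueError("Vn must be positive")
    if not (0 <= Vk <= Vn):
        raise ValueError("Vk must satisfy 0 <= Vk <= Vn")
    return 100.0 * Vk / Vn


def measure_walnut(
    partmap: PartLabelMap,
    swap_face_profile: bool = False,
    feret_directions: int = 2000,
) -> WalnutTraits:
    """All 14 descriptors of one part-labelled nut, gated by shell QC.

    A nut whose shell fails the integrity check gets ``qc='fail'`` and no
    trait values — a breached shell makes the cavity and shell volumes
    meaningless, so such nuts are excluded rather than mis-reported.
    """
    ok, detail = qc_shell_integrity(partmap)
    if not ok:
        return WalnutTraits(qc="fail", qc_detail=detail)
    vs, vk, ve, vn = part_volumes(partmap)
    nut = BinaryMask(data=partmap.nut_mask, voxel_size_mm=partmap.voxel_size_mm)
    L, F, P, _ = principal_axes(nut, swap_face_profile=swap_face_profile)
    A = surface_area(nut)
    verts = hull_vertices_mm(nut.data, nut.voxel_size_mm)
    feret = feret_shape(verts, n_directions=feret_directions)
    shell = BinaryMask(data=partmap.class_mask(SHELL), voxel_size_mm=partmap.voxel_size_mm)
    return WalnutTraits(
        L=L,
        F=F,
        P=P,
        Vn=vn,
        S1=shape_va3d(vn, A),
        S2=feret.s2,
        A=A,
        Psi=sphericity(vn, A),
        Vs=vs,
        T=shell_thickness(shell),
        Omega=rugosity(vn, A),
        Vk=vk,
        R=filling_ratio(vk, vn),
        Ve=ve,
        qc="pass",
        qc_detail=detail,
    )
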