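"""Synthetic walnut CT phantoms with known ground truth.

A phantom nut is built from analytic geometry: a base ellipsoid whose
radius is modulated by a deterministic band-limited function on the sphere
of directions (a low-order spherical-harmonic mixture keyed by the seed),
a shell obtained by inward radial offset, and a kernel made of two
ellipsoidal lobes scaled to hit a target filling ratio.  The cavity air
deliberately shares the exterior-air greyscale, so the part-segmentation
stage must identify empty space by enclosure — exactly the situation in a
real scan.  Intensities mimic the four attenuation populations of a real
acquisition (air < foam < kernel < shell) and additive Gaussian noise
stands in for reconstruction noise.

Because the geometry is analytic it can be re-digitised on an arbitrarily
fine grid; :func:`oracle_traits` measures the ground-truth label map by
brute force (voxel counting, fine-grid meshing, exhaustive Feret direction
sampling, inscribed-sphere thickness) and serves as the independent
reference for every trait estimator in the pipeline.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from . import traits as _traits
from ._geometry import (
    fibonacci_directions,
    hull_vertices_mm,
    local_thickness_mean,
    max_feret_orthogonal,
    mesh_surface_area,
    principal_extents,
    projection_widths,
)
from .partition import BACKGROUND, EMPTY, KERNEL, SHELL, PartLabelMap
from .volume_io import LabelMap, Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_spherical_nut",
    "make_bumpy_nut",
    "make_scan",
    "make_touching_pair",
    "damage_shell",
    "oracle_traits",
]

#: default greyscale means for (air, foam, kernel, shell)
DEFAULT_INTENSITIES = (10.0, 40.0, 110.0, 200.0)

# kernel lobe geometry relative to the cavity semi-axes: two lobes offset
# along the local y axis — a stylised two-half kernel.  The lobes are sized
# to protrude past the inner shell surface (they are clipped back to the
# cavity), so the kernel always touches the shell wall and each nut is one
# connected body of material, as in a real walnut.
_LOBE_SEMIAXES = np.array([0.80, 0.90, 0.80])
_LOBE_OFFSET_Y = 0.50


@dataclasses.dataclass
class PhantomSpec:
    """Generation parameters for one synthetic nut.

    Default radii give a nut with real-walnut aspect ratios (length a bit
    larger than the two transverse diameters), shell thickness 1 mm and a
    30% kernel filling target, matching typical in-shell walnut proportions
    at a size that keeps a 0.1 mm-voxel working grid around 200³.
    """

    outer_radii_mm: tuple[float, float, float] = (8.5, 7.2, 7.4)
    shell_thickness_mm: float = 1.0
    bump_amplitude_mm: float = 0.3
    bump_frequency: int = 4
    kernel_fill_target: float = 0.30
    intensity_levels: tuple[float, float, float, float] = DEFAULT_INTENSITIES
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_thickness_mm >= min(self.outer_radii_mm):
            raise ValueError("shell thickness must be smaller than every semi-axis")
        air, foam, kernel, shell = self.intensity_levels
        if not (air < foam < kernel < shell):
            raise ValueError("intensities must satisfy air < foam < kernel < shell")
        if not (0 < self.kernel_fill_target < 1):
            raise ValueError("kernel_fill_target must lie in (0, 1)")
        if self.bump_amplitude_mm < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes and noise must be non-negative")
        if self.bump_amplitude_mm >= self.shell_thickness_mm:
            raise ValueError(
                "bump amplitude must stay below the shell thickness (the radial "
                "inner offset would otherwise self-intersect)"
            )

    @property
    def max_radius_mm(self) -> float:
        return max(self.outer_radii_mm) + self.bump_amplitude_mm


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth for a generated nut.

    ``traits`` holds true values for the measured descriptors (closed form
    for spheres, fine-grid oracle otherwise; ``None`` when not requested);
    ``part_labels`` is the per-voxel ground-truth class map on the nut's
    local grid and ``origin_vox`` its offset inside the parent volume.
    """

    traits: dict[str, float] | None
    part_labels: PartLabelMap
    origin_vox: tuple[int, int, int] = (0, 0, 0)
    params: dict | None = None


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------


class _BumpField:
    """Seeded band-limited angular bump, tabulated once on a (θ, φ) grid.

    The field is a mixture of real spherical harmonics of degree 2 up to
    ``bump_frequency`` with normal coefficients drawn from the spec's seed,
    normalised to unit maximum amplitude.  Evaluation is bilinear
    interpolation in the table, so digitising the same nut at different
    resolutions sees the identical surface.
    """

    N_THETA, N_PHI = 256, 512

    def __init__(self, spec: PhantomSpec) -> None:
        rng = np.random.default_rng(spec.seed)
        theta = np.linspace(0.0, np.pi, self.N_THETA)
        phi = np.linspace(-np.pi, np.pi, self.N_PHI)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        table = np.zeros(tt.shape)
        for l in range(2, max(2, spec.bump_frequency) + 1):
            for m in range(0, l + 1):
                a, b = rng.normal(size=2)
                y = sph_harm_y(l, m, tt, pp)
                table += a * y.real
                if m > 0:
                    table += b * y.imag
        peak = float(np.abs(table).max())
        self.table = (table / (peak or 1.0)).astype(np.float32)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Field values at unit directions ``u`` of shape (..., 3)."""
        theta = np.arccos(np.clip(u[..., 0], -1.0, 1.0))
        phi = np.arctan2(u[..., 1], u[..., 2])
        ti = theta * ((self.N_THETA - 1) / np.pi)
        pi_ = (phi + np.pi) * ((self.N_PHI - 1) / (2.0 * np.pi))
        t0 = np.clip(ti.astype(np.int32), 0, self.N_THETA - 2)
        p0 = np.clip(pi_.astype(np.int32), 0, self.N_PHI - 2)
        ft = (ti - t0).astype(np.float32)
        fp = (pi_ - p0).astype(np.float32)
        tab = self.table
        return (
            tab[t0, p0] * (1 - ft) * (1 - fp)
            + tab[t0 + 1, p0] * ft * (1 - fp)
            + tab[t0, p0 + 1] * (1 - ft) * fp
            + tab[t0 + 1, p0 + 1] * ft * fp
        )


def _radius_fields(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    center_mm: np.ndarray,
    voxel_size_mm: float,
    rotation: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel distance to centre r and ellipsoid radius r_ell(u).

    For an unrotated nut both fields are separable sums of 1-D terms, which
    keeps the memory footprint to two float32 grids.
    """
    a, b, c = spec.outer_radii_mm
    axes = [
        (np.arange(n, dtype=np.float32) * voxel_size_mm - cm)
        for n, cm in zip(shape, np.asarray(center_mm, dtype=np.float32))
    ]
    if rotation is None:
        z, y, x = axes
        r2 = (z**2)[:, None, None] + (y**2)[None, :, None] + (x**2)[None, None, :]
        s2 = (
            ((z / a) ** 2)[:, None, None]
            + ((y / b) ** 2)[None, :, None]
            + ((x / c) ** 2)[None, None, :]
        )
    else:
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        R = rotation.astype(np.float32)
        p0 = zz * R[0, 0] + yy * R[1, 0] + xx * R[2, 0]
        p1 = zz * R[0, 1] + yy * R[1, 1] + xx * R[2, 1]
        p2 = zz * R[0, 2] + yy * R[1, 2] + xx * R[2, 2]
        r2 = p0**2 + p1**2 + p2**2
        s2 = (p0 / a) ** 2 + (p1 / b) ** 2 + (p2 / c) ** 2
    r = np.sqrt(r2)
    r_ell = r / np.sqrt(np.maximum(s2, 1e-12))
    r_ell[r < 1e-6] = min(a, b, c)  # direction undefined at the exact centre
    return r, r_ell


def _coords_of(
    idx: np.ndarray,
    center_mm: np.ndarray,
    voxel_size_mm: float,
    rotation: np.ndarray | None,
) -> np.ndarray:
    """Local-frame mm coordinates of the voxel indices ``idx`` (M, 3)."""
    p = idx.astype(np.float32) * voxel_size_mm - np.asarray(
        center_mm, dtype=np.float32
    )
    if rotation is not None:
        p = p @ rotation.astype(np.float32)
    return p


def _nut_interior_masks(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    center_mm: np.ndarray,
    voxel_size_mm: float,
    rotation: np.ndarray | None,
    bump: "_BumpField | None",
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (nut, interior) for the analytic geometry.

    The bump field is evaluated only inside the narrow band around the two
    surfaces where it can change the answer.
    """
    r, r_ell = _radius_fields(spec, shape, center_mm, voxel_size_mm, rotation)
    t = np.float32(spec.shell_thickness_mm)
    amp = np.float32(spec.bump_amplitude_mm)
    if amp > 0 and bump is not None:
        eps = np.float32(1e-4)
        band = (np.abs(r - r_ell) <= amp + eps) | (
            np.abs(r - (r_ell - t)) <= amp + eps
        )
        idx = np.argwhere(band)
        p = _coords_of(idx, center_mm, voxel_size_mm, rotation)
        rb = np.linalg.norm(p, axis=1)
        u = p / np.maximum(rb, 1e-6)[:, None]
        r_out_band = r_ell[band] + amp * bump(u)
        nut = r <= r_ell - amp
        nut[band] = r[band] <= r_out_band
        interior = r <= r_ell - t - amp
        interior[band] = r[band] <= r_out_band - t
    else:
        nut = r <= r_ell
        interior = r <= r_ell - t
    return nut, interior


def _lobe_membership(p: np.ndarray, spec: PhantomSpec, scale: float) -> np.ndarray:
    """Kernel-lobe membership of local-frame points ``p`` (M, 3)."""
    a, b, c = spec.outer_radii_mm
    t = spec.shell_thickness_mm
    inner = np.array([a - t, b - t, c - t], dtype=np.float32)
    semi = _LOBE_SEMIAXES.astype(np.float32) * inner * np.float32(scale)
    offset = np.float32(_LOBE_OFFSET_Y) * inner[1]
    out = np.zeros(p.shape[0], dtype=bool)
    for sign in (np.float32(1.0), np.float32(-1.0)):
        q0 = p[:, 0] / semi[0]
        q1 = (p[:, 1] - sign * offset) / semi[1]
        q2 = p[:, 2] / semi[2]
        out |= q0 * q0 + q1 * q1 + q2 * q2 <= 1.0
    return out


def _evaluate_nut_parts(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    center_mm: np.ndarray,
    voxel_size_mm: float,
    kernel_scale: float,
    rotation: np.ndarray | None = None,
    bump: "_BumpField | None" = None,
) -> np.ndarray:
    """Digitise the analytic nut onto a grid as a part-class array."""
    if spec.bump_amplitude_mm > 0 and bump is None:
        bump = _BumpField(spec)
    nut, interior = _nut_interior_masks(
        spec, shape, center_mm, voxel_size_mm, rotation, bump
    )
    part = np.zeros(shape, dtype=np.int8)
    part[nut & ~interior] = SHELL
    idx = np.argwhere(interior)
    if idx.size:
        p = _coords_of(idx, center_mm, voxel_size_mm, rotation)
        lob = _lobe_membership(p, spec, kernel_scale)
        part[interior] = np.where(lob, KERNEL, EMPTY).astype(np.int8)
    return part


def _render_intensity(
    part: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    background: float | None = None,
) -> np.ndarray:
    air, foam, kernel, shell = spec.intensity_levels
    bg = air if background is None else background
    vol = np.full(part.shape, bg, dtype=np.float32)
    vol[part == SHELL] = shell
    vol[part == KERNEL] = kernel
    vol[part == EMPTY] = air  # cavity air is real air
    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=part.shape).astype(np.float32)
    return vol


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_spherical_nut(
    outer_radius_mm: float,
    shell_thickness_mm: float,
    kernel_radius_mm: float,
    voxel_size_mm: float = 0.1,
    intensity_levels: tuple[float, float, float, float] = DEFAULT_INTENSITIES,
    noise_sigma: float = 0.0,
    seed: int = 0,
    margin_mm: float = 1.5,
) -> tuple[Volume3D, PhantomTruth]:
    """Spherical nut with closed-form ground truth.

    Shell = spherical annulus, kernel = centred sphere, cavity = enclosed
    air.  All trait truths are closed form: volumes from 4/3·π·r³, surface
    from 4·π·r², Ψ = Ω = S1 = S2 = 1, T = the annulus thickness.
    """
    r_out = float(outer_radius_mm)
    t = float(shell_thickness_mm)
    r_k = float(kernel_radius_mm)
    r_in = r_out - t
    if not (0 < r_k < r_in):
        raise ValueError("need 0 < kernel_radius < outer_radius - shell_thickness")
    n = 2 * int(math.ceil((r_out + margin_mm) / voxel_size_mm)) + 1
    center = np.full(3, (n // 2) * voxel_size_mm, dtype=np.float32)
    ax = np.arange(n, dtype=np.float32) * voxel_size_mm - center[0]
    r = np.sqrt(
        (ax**2)[:, None, None] + (ax**2)[None, :, None] + (ax**2)[None, None, :]
    )
    part = np.zeros((n, n, n), dtype=np.int8)
    part[(r <= r_out) & (r > r_in)] = SHELL
    part[r <= r_k] = KERNEL
    part[(r <= r_in) & (r > r_k)] = EMPTY
    spec = PhantomSpec(
        outer_radii_mm=(r_out, r_out, r_out),
        shell_thickness_mm=t,
        bump_amplitude_mm=0.0,
        intensity_levels=intensity_levels,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    vol = _render_intensity(part, spec, rng)
    vn = 4.0 / 3.0 * math.pi * r_out**3
    vs = 4.0 / 3.0 * math.pi * (r_out**3 - r_in**3)
    vk = 4.0 / 3.0 * math.pi * r_k**3
    truth_traits = {
        "L": 2 * r_out,
        "F": 2 * r_out,
        "P": 2 * r_out,
        "Vn": vn,
        "S1": 1.0,
        "S2": 1.0,
        "A": 4.0 * math.pi * r_out**2,
        "Psi": 1.0,
        "Vs": vs,
        "T": t,
        "Omega": 1.0,
        "Vk": vk,
        "R": 100.0 * vk / vn,
        "Ve": vn - vs - vk,
    }
    truth = PhantomTruth(
        traits=truth_traits,
        part_labels=PartLabelMap(data=part, voxel_size_mm=voxel_size_mm),
        params={"spec": spec, "center_mm": center.tolist()},
    )
    return Volume3D(data=vol, voxel_size_mm=voxel_size_mm), truth


def _solve_kernel_scale(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    center_mm: np.ndarray,
    voxel_size_mm: float,
    rotation: np.ndarray | None = None,
    bump: "_BumpField | None" = None,
) -> float:
    """Scale of the kernel lobes hitting the fill target (±1 point)."""
    if spec.bump_amplitude_mm > 0 and bump is None:
        bump = _BumpField(spec)
    nut, interior = _nut_interior_masks(
        spec, shape, center_mm, voxel_size_mm, rotation, bump
    )
    n_nut = int(nut.sum())
    if n_nut == 0:
        raise ValueError("phantom does not intersect the grid")
    p_int = _coords_of(np.argwhere(interior), center_mm, voxel_size_mm, rotation)

    def fill(s: float) -> float:
        return float(_lobe_membership(p_int, spec, s).sum()) / n_nut

    lo, hi = 0.05, 1.6
    if fill(hi) < spec.kernel_fill_target - 0.01:
        raise ValueError(
            "kernel fill target unreachable: lobes would breach the shell"
        )
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        f = fill(mid)
        if abs(f - spec.kernel_fill_target) < 1e-4:
            return mid
        if f < spec.kernel_fill_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_bumpy_nut(
    spec: PhantomSpec,
    voxel_size_mm: float = 0.1,
    margin_mm: float = 1.5,
    rotation: np.ndarray | None = None,
    compute_truth: bool = True,
    truth_oracle_factor: int = 2,
    feret_oracle_directions: int = 20000,
) -> tuple[Volume3D, PhantomTruth]:
    """Bumpy ellipsoidal nut; ground truth measured on a finer grid.

    The outer surface is the base ellipsoid radius plus a seeded band-limited
    angular bump field scaled to ``bump_amplitude_mm``; the shell is an
    inward radial offset of that surface; the kernel is two smoothed lobes
    scaled so the filling ratio hits ``kernel_fill_target`` within one
    percentage point.  When ``compute_truth`` is set, trait truths come from
    :func:`oracle_traits` run on the analytic geometry re-digitised at
    ``truth_oracle_factor`` times finer resolution.
    """
    if truth_oracle_factor < 2:
        raise ValueError("truth oracle must run at >= 2x finer resolution")
    rad = spec.max_radius_mm + margin_mm
    n = 2 * int(math.ceil(rad / voxel_size_mm)) + 1
    shape = (n, n, n)
    center = np.full(3, (n // 2) * voxel_size_mm, dtype=np.float32)
    bump = _BumpField(spec) if spec.bump_amplitude_mm > 0 else None
    scale = _solve_kernel_scale(spec, shape, center, voxel_size_mm, bump=bump)
    part = _evaluate_nut_parts(
        spec, shape, center, voxel_size_mm, scale, rotation, bump
    )
    rng = np.random.default_rng(spec.seed)
    vol = _render_intensity(part, spec, rng)
    truth_traits = None
    if compute_truth:
        fine_vox = voxel_size_mm / truth_oracle_factor
        nf = 2 * int(math.ceil(rad / fine_vox)) + 1
        center_f = np.full(3, (nf // 2) * fine_vox, dtype=np.float32)
        part_f = _evaluate_nut_parts(
            spec, (nf, nf, nf), center_f, fine_vox, scale, rotation, bump
        )
        truth_traits = oracle_traits(
            PartLabelMap(data=part_f, voxel_size_mm=fine_vox),
            n_feret_directions=feret_oracle_directions,
        )
    truth = PhantomTruth(
        traits=truth_traits,
        part_labels=PartLabelMap(data=part, voxel_size_mm=voxel_size_mm),
        params={"spec": spec, "kernel_scale": scale, "center_mm": center.tolist()},
    )
    return Volume3D(data=vol, voxel_size_mm=voxel_size_mm), truth


def make_scan(
    n_nuts: int,
    specs: list[PhantomSpec] | None = None,
    layout: str = "grid",
    foam: bool = True,
    voxel_size_mm: float = 0.25,
    seed: int = 0,
    spacing_mm: float = 4.0,
) -> tuple[Volume3D, list[PhantomTruth], LabelMap]:
    """A batch scan: several nuts in a foam block, randomly rotated.

    Nuts are placed on a 3D grid (``layout='grid'``) or at rejection-sampled
    random positions (``layout='random'``); the returned label map numbers
    the nut material (shell ∪ kernel) 1..n in placement order.  Real batches
    held 5–16 nuts; 12 per scan is typical.
    """
    if n_nuts < 1:
        raise ValueError("n_nuts must be >= 1")
    if layout not in ("grid", "random"):
        raise ValueError("layout must be 'grid' or 'random'")
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = [
            dataclasses.replace(PhantomSpec(), seed=seed * 1000 + i)
            for i in range(n_nuts)
        ]
    specs = [specs[i % len(specs)] for i in range(n_nuts)]
    cell = 2 * max(s.max_radius_mm for s in specs) + spacing_mm
    if layout == "grid":
        nx = int(math.ceil(n_nuts ** (1.0 / 3.0)))
        ny = int(math.ceil(math.sqrt(n_nuts / nx)))
        nz = int(math.ceil(n_nuts / (nx * ny)))
        dims = np.array([nz, ny, nx], dtype=float) * cell
        centers = []
        for i in range(n_nuts):
            iz, rem = divmod(i, ny * nx)
            iy, ix = divmod(rem, nx)
            centers.append((np.array([iz, iy, ix]) + 0.5) * cell)
    else:
        side = cell * max(1.0, n_nuts ** (1.0 / 3.0)) * 1.3
        dims = np.full(3, side)
        centers = []
        for i in range(n_nuts):
            r_i = specs[i].max_radius_mm
            for _attempt in range(2000):
                pos = rng.uniform(r_i + 1.0, side - r_i - 1.0, size=3)
                if all(
                    np.linalg.norm(pos - c) > r_i + specs[j].max_radius_mm + 1.0
                    for j, c in enumerate(centers)
                ):
                    centers.append(pos)
                    break
            else:
                raise RuntimeError(
                    f"could not place nut {i + 1} without overlap after 2000 tries"
                )
    shape = tuple(int(math.ceil(d / voxel_size_mm)) + 1 for d in dims)
    air, foam_level = specs[0].intensity_levels[0], specs[0].intensity_levels[1]
    volume = np.full(shape, foam_level if foam else air, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    truths: list[PhantomTruth] = []
    for i, (spec_i, center) in enumerate(zip(specs, centers), start=1):
        rot = Rotation.random(random_state=rng).as_matrix()
        rad = spec_i.max_radius_mm + 1.0
        local_n = 2 * int(math.ceil(rad / voxel_size_mm)) + 1
        origin = np.round(center / voxel_size_mm).astype(int) - local_n // 2
        local_center = center - origin * voxel_size_mm
        bump = _BumpField(spec_i) if spec_i.bump_amplitude_mm > 0 else None
        scale = _solve_kernel_scale(
            spec_i, (local_n,) * 3, local_center.astype(np.float32),
            voxel_size_mm, rot, bump,
        )
        part = _evaluate_nut_parts(
            spec_i, (local_n,) * 3, local_center.astype(np.float32),
            voxel_size_mm, scale, rot, bump,
        )
        sl = tuple(slice(o, o + local_n) for o in origin)
        region = volume[sl]
        if region.shape != part.shape:
            raise RuntimeError("nut does not fit inside the scan volume")
        a_, _f, kern, shell = spec_i.intensity_levels
        region[part == SHELL] = shell
        region[part == KERNEL] = kern
        region[part == EMPTY] = a_
        labels[sl][(part == SHELL) | (part == KERNEL)] = i
        truths.append(
            PhantomTruth(
                traits=None,
                part_labels=PartLabelMap(data=part, voxel_size_mm=voxel_size_mm),
                origin_vox=tuple(int(o) for o in origin),
                params={"spec": spec_i, "kernel_scale": scale,
                        "center_mm": local_center.tolist(), "rotation": rot.tolist()},
            )
        )
    sigma = specs[0].noise_sigma
    if sigma > 0:
        volume += rng.normal(0.0, sigma, size=shape).astype(np.float32)
    return (
        Volume3D(data=volume, voxel_size_mm=voxel_size_mm),
        truths,
        LabelMap(data=labels, voxel_size_mm=voxel_size_mm),
    )


def make_touching_pair(
    outer_radius_mm: float = 15.0,
    center_distance_mm: float = 29.0,
    shell_thickness_mm: float = 1.5,
    kernel_radius_mm: float | None = None,
    voxel_size_mm: float = 0.25,
    intensity_levels: tuple[float, float, float, float] = DEFAULT_INTENSITIES,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Volume3D, LabelMap]:
    """Two overlapping spherical nuts along x — a fused-pair test case.

    With ``center_distance < 2 * outer_radius`` the two nuts form a single
    connected component under any connectivity; the truth label map assigns
    each material voxel to its nearest sphere centre.  By default the kernel
    fills the whole cavity (a "stuffed" nut), giving the solid bodies whose
    distance-transform maxima the watershed splitter relies on.
    """
    r = float(outer_radius_mm)
    d = float(center_distance_mm)
    r_k = kernel_radius_mm if kernel_radius_mm is not None else r - shell_thickness_mm
    if not (0 < r_k <= r - shell_thickness_mm):
        raise ValueError("kernel radius incompatible with shell geometry")
    margin = 2.0
    nx = int(math.ceil((d + 2 * r + 2 * margin) / voxel_size_mm)) + 1
    n = 2 * int(math.ceil((r + margin) / voxel_size_mm)) + 1
    shape = (n, n, nx)
    c1 = np.array([(n // 2), (n // 2), (r + margin) / voxel_size_mm]) * voxel_size_mm
    c2 = c1 + np.array([0.0, 0.0, d])
    zz, yy, xx = np.meshgrid(
        *[np.arange(s, dtype=np.float32) * voxel_size_mm for s in shape], indexing="ij"
    )
    part = np.zeros(shape, dtype=np.int8)
    owner = np.zeros(shape, dtype=np.int32)
    r_in = r - shell_thickness_mm
    d1 = np.sqrt((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2)
    d2 = np.sqrt((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2)
    for idx, dist in ((1, d1), (2, d2)):
        shell_m = (dist <= r) & (dist > r_in) & (part != SHELL)
        kern_m = dist <= r_k
        part[shell_m] = SHELL
        part[kern_m] = KERNEL
        part[(dist <= r_in) & (dist > r_k) & (part == BACKGROUND)] = EMPTY
    material = (part == SHELL) | (part == KERNEL)
    owner[material & (d1 <= d2)] = 1
    owner[material & (d1 > d2)] = 2
    air, _foam, kern_i, shell_i = intensity_levels
    vol = np.full(shape, air, dtype=np.float32)
    vol[part == SHELL] = shell_i
    vol[part == KERNEL] = kern_i
    if noise_sigma > 0:
        vol += np.random.default_rng(seed).normal(0, noise_sigma, shape).astype(
            np.float32
        )
    return (
        Volume3D(data=vol, voxel_size_mm=voxel_size_mm),
        LabelMap(data=owner, voxel_size_mm=voxel_size_mm),
    )


def damage_shell(
    vol: Volume3D, truth: PhantomTruth, hole_radius_mm: float
) -> Volume3D:
    """Pierce the shell with an air channel from the cavity to the exterior.

    A cylindrical channel of the requested radius is drilled along +z from
    the nut centre through the top of the volume and set to the air
    greyscale.  A voxel joins the channel only if its full footprint lies
    inside the cylinder, so a radius below the voxel size changes nothing.
    """
    spec: PhantomSpec = truth.params["spec"]
    air = spec.intensity_levels[0]
    vox = vol.voxel_size_mm
    cz, cy, cx = (
        np.array(truth.origin_vox) + np.array(truth.part_labels.data.shape) // 2
    )
    data = np.array(vol.data, copy=True)
    yy, xx = np.meshgrid(
        np.arange(data.shape[1], dtype=float),
        np.arange(data.shape[2], dtype=float),
        indexing="ij",
    )
    # axis offset by a sub-voxel amount so it never passes exactly through
    # voxel centres; footprint rule: centre distance + half diagonal <= radius
    dist = np.sqrt((yy - (cy + 0.31)) ** 2 + (xx - (cx + 0.43)) ** 2) * vox
    channel = dist + 0.5 * math.sqrt(2.0) * vox <= hole_radius_mm
    data[cz:, channel] = air
    return Volume3D(data=data, voxel_size_mm=vol.voxel_size_mm)


def oracle_traits(
    partmap: PartLabelMap, n_feret_directions: int = 20000
) -> dict[str, float]:
    """Brute-force trait measurement of a ground-truth part label map.

    Volumes by voxel counting; surface area by fine-grid meshing; Feret d
    and orthogonal D by exhaustive direction sampling over convex-hull
    vertices; thickness by the inscribed-sphere transform; the derived
    indices from the oracle (Vn, A) pair.  Intended to run on a grid at
    least twice finer than the pipeline's working resolution.
    """
    vs, vk, ve, vn = _traits.part_volumes(partmap)
    nut = partmap.nut_mask
    vox = partmap.voxel_size_mm
    area = mesh_surface_area(nut, vox)
    extents, _ = principal_extents(nut, vox)
    verts = hull_vertices_mm(nut, vox)
    dirs = fibonacci_directions(n_feret_directions)
    widths = projection_widths(verts, dirs)
    i_min = int(np.argmin(widths))
    d = float(widths[i_min])
    D = max_feret_orthogonal(verts, dirs[i_min], n_angles=1440)
    thickness = local_thickness_mean(partmap.class_mask(SHELL), vox)
    return {
        "L": float(extents[0]),
        "F": float(extents[1]),
        "P": float(extents[2]),
        "Vn": vn,
        "S1": _traits.shape_va3d(vn, area),
        "S2": D / d,
        "A": area,
        "Psi": _traits.sphericity(vn, area),
        "Vs": vs,
        "T": thickness,
        "Omega": _traits.rugosity(vn, area),
        "Vk": vk,
        "R": _traits.filling_ratio(vk, vn),
        "Ve": ve,
    }
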