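"""Ground-truth stented-vessel phantom.

The physical object being emulated is a 200-mm soft-tissue-equivalent
cylinder (2% agar-water) with a contrast-filled artery (15 mg/mL iodine) at
its axis.  Inside the artery lumen sits one metal stent, or two stents whose
axial extents overlap so that their rings run close together in the overlap
band (the intertwined-pair condition used for inter-stent distinction).

Each stent is modelled as a thin annulus: in every axial slice within the
stent's axial range, voxels whose in-plane distance to the stent axis falls
within ``strut_thickness_mm / 2`` of the centerline radius
(``diameter_mm / 2``) take the metal HU.  The polymer cover of a covered
stent is radiolucent and is not modelled.

HU assignments (the study reports concentrations, not HU): 2% agar background
10 HU, iodine lumen at 15 mg/mL and 120 kVp 390 HU (~26 HU per mg/mL),
vessel wall 50 HU, stainless-steel strut 8000 HU before blurring.

Rasterization is nearest-material (each voxel takes the HU of the material
containing its center) on a grid that oversamples the finest strut; partial
volume arises downstream from blurring and detector-grid binning, exactly as
in a real reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, InvalidParameterError

#: Coarsest allowed rasterization spacing (mm); a 0.15-mm strut must be
#: sampled by several voxels across its thickness.
MAX_RASTER_SPACING_MM = 0.02

AIR_HU = -1000.0


@dataclass(frozen=True)
class StentSpec:
    """Geometry of one stent, reduced to a thin annulus.

    ``diameter_mm`` is the strut-ring centerline diameter (the ground-truth
    quantity recovered by peak-to-peak measurement).  ``center_offset_mm``
    shifts the stent axis in-plane relative to the vessel axis, used to
    emulate an intertwined pair.  ``z_center_mm``/``axial_extent_mm`` place
    the stent along the phantom axis; an infinite extent spans the volume.
    """

    diameter_mm: float
    strut_thickness_mm: float = 0.15
    center_offset_mm: tuple[float, float] = (0.0, 0.0)
    axial_extent_mm: float = math.inf
    z_center_mm: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_offset_mm", tuple(self.center_offset_mm))
        if self.strut_thickness_mm <= 0:
            raise InvalidParameterError("strut_thickness_mm must be > 0")
        if self.diameter_mm <= 2 * self.strut_thickness_mm:
            raise InvalidParameterError(
                "diameter_mm must exceed twice the strut thickness"
            )
        if self.axial_extent_mm <= 0:
            raise InvalidParameterError("axial_extent_mm must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def z_range(self) -> tuple[float, float]:
        half = self.axial_extent_mm / 2.0
        return (self.z_center_mm - half, self.z_center_mm + half)


@dataclass(frozen=True)
class PhantomSpec:
    """Materials and geometry of the cylinder + vessel + stent(s) phantom."""

    stents: tuple[StentSpec, ...]
    vessel_lumen_diameter_mm: float
    cylinder_diameter_mm: float = 200.0
    wall_thickness_mm: float = 1.0
    background_hu: float = 10.0
    lumen_hu: float = 390.0
    wall_hu: float = 50.0
    metal_hu: float = 8000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stents", tuple(self.stents))
        if not 1 <= len(self.stents) <= 2:
            raise InvalidParameterError("phantom must contain 1 or 2 stents")
        if not (self.metal_hu > self.lumen_hu > self.background_hu):
            raise InvalidParameterError(
                "HU ordering violated: need metal_hu > lumen_hu > background_hu"
            )
        for name in ("vessel_lumen_diameter_mm", "cylinder_diameter_mm", "wall_thickness_mm"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        r_lumen = self.vessel_lumen_diameter_mm / 2.0
        for s in self.stents:
            cx, cy = s.center_offset_mm
            reach = math.hypot(cx, cy) + s.radius_mm + s.strut_thickness_mm / 2.0
            if reach >= r_lumen:
                raise GeometryError(
                    f"stent (d={s.diameter_mm} mm, offset {s.center_offset_mm}) does not "
                    f"fit inside the vessel lumen (d={self.vessel_lumen_diameter_mm} mm)"
                )


@dataclass
class ImageVolume:
    """A 3-D HU grid with physical spacing.

    ``voxels`` has shape (nz, ny, nx); ``spacing_mm`` is (dx, dy, dz);
    ``origin_mm`` is the world (x, y, z) of the center of voxel [0, 0, 0].
    World coordinates: x = origin[0] + i*dx for index i along the last axis,
    and likewise for y (axis 1) and z (axis 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise InvalidParameterError("voxels must be a non-empty 3-D array")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise InvalidParameterError("spacing components must be strictly positive")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def slice_z_centers(self) -> np.ndarray:
        nz = self.voxels.shape[0]
        return self.origin_mm[2] + np.arange(nz) * self.spacing_mm[2]

    def x_coords(self) -> np.ndarray:
        return self.origin_mm[0] + np.arange(self.voxels.shape[2]) * self.spacing_mm[0]

    def y_coords(self) -> np.ndarray:
        return self.origin_mm[1] + np.arange(self.voxels.shape[1]) * self.spacing_mm[1]


def _active_stents(spec: PhantomSpec, z: float) -> tuple[int, ...]:
    out = []
    for idx, s in enumerate(spec.stents):
        lo, hi = s.z_range()
        if lo <= z <= hi:
            out.append(idx)
    return tuple(out)


def rasterize_phantom(
    spec: PhantomSpec,
    supersample_spacing_mm: float,
    *,
    extent_xy_mm: float = 24.0,
    z_extent_mm: float = 2.52,
    dz_mm: float = 0.21,
) -> ImageVolume:
    """Rasterize the ground-truth phantom on a fine, centered grid.

    The grid is centered on the vessel axis; in-plane extent
    ``extent_xy_mm`` is realized as ``round(extent / spacing)`` voxels per
    axis, and similarly along z.  Spacing must not exceed
    :data:`MAX_RASTER_SPACING_MM` in-plane so the thinnest strut is
    oversampled.

    Axially identical slices share one array pass: material patterns only
    change where a stent's axial range starts or ends.
    """
    h = float(supersample_spacing_mm)
    if not (0 < h <= MAX_RASTER_SPACING_MM):
        raise InvalidParameterError(
            f"supersample_spacing_mm must be in (0, {MAX_RASTER_SPACING_MM}] mm "
            f"to oversample the finest strut; got {h}"
        )
    if extent_xy_mm <= 0 or z_extent_mm <= 0 or dz_mm <= 0:
        raise InvalidParameterError("extents and dz must be > 0")

    n = int(round(extent_xy_mm / h))
    nz = max(1, int(round(z_extent_mm / dz_mm)))
    # voxel centers, symmetric about the axis
    x = (np.arange(n) - (n - 1) / 2.0) * h
    y = x.copy()
    z = (np.arange(nz) - (nz - 1) / 2.0) * dz_mm

    xx = x[np.newaxis, :]
    yy = y[:, np.newaxis]
    r2 = xx**2 + yy**2

    r_lumen = spec.vessel_lumen_diameter_mm / 2.0
    r_wall = r_lumen + spec.wall_thickness_mm
    r_cyl = spec.cylinder_diameter_mm / 2.0

    base = np.full((n, n), spec.background_hu, dtype=np.float32)
    base[r2 > r_cyl**2] = AIR_HU
    base[r2 <= r_wall**2] = spec.wall_hu
    base[r2 <= r_lumen**2] = spec.lumen_hu

    ring_masks = []
    for s in spec.stents:
        cx, cy = s.center_offset_mm
        rs = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        ring_masks.append(np.abs(rs - s.radius_mm) <= s.strut_thickness_mm / 2.0)

    cache: dict[tuple[int, ...], np.ndarray] = {}
    vol = np.empty((nz, n, n), dtype=np.float32)
    for k, zk in enumerate(z):
        active = _active_stents(spec, zk)
        if active not in cache:
            sl = base.copy()
            for idx in active:
                sl[ring_masks[idx]] = spec.metal_hu
            cache[active] = sl
        vol[k] = cache[active]

    origin = (float(x[0]), float(y[0]), float(z[0]))
    return ImageVolume(vol, spacing_mm=(h, h, float(dz_mm)), origin_mm=origin)


def single_stent_phantom(
    diameter_mm: float,
    *,
    strut_thickness_mm: float = 0.15,
    lumen_clearance_mm: float = 1.5,
) -> PhantomSpec:
    """Convenience builder: one centered stent in a contrast-filled vessel."""
    stent = StentSpec(diameter_mm=diameter_mm, strut_thickness_mm=strut_thickness_mm)
    lumen = diameter_mm + strut_thickness_mm + lumen_clearance_mm
    return PhantomSpec(stents=(stent,), vessel_lumen_diameter_mm=lumen)


def intertwined_pair_phantom(
    d_outer_mm: float = 7.0,
    d_inner_mm: float = 5.8,
    *,
    strut_thickness_mm: float = 0.15,
    inner_offset_mm: float = 0.25,
    overlap_mm: float = 2.52,
    stent_length_mm: float = 5.67,
    lumen_diameter_mm: float = 8.5,
) -> PhantomSpec:
    """Two stents of different diameter overlapping over a central axial band.

    The outer stent is centered on the vessel axis; the inner one is offset
    in-plane by ``inner_offset_mm`` so the ring gap varies around the
    circumference (widest on the side away from the offset, where the
    distinction profile is read).  Their axial extents overlap by
    ``overlap_mm`` around z = 0.
    """
    if d_inner_mm >= d_outer_mm:
        raise InvalidParameterError("d_inner_mm must be smaller than d_outer_mm")
    # each stent spans [z_center - L/2, z_center + L/2]; overlap = [-ov/2, ov/2]
    z1 = -(stent_length_mm / 2.0 - overlap_mm / 2.0)
    z2 = +(stent_length_mm / 2.0 - overlap_mm / 2.0)
    outer = StentSpec(
        diameter_mm=d_outer_mm,
        strut_thickness_mm=strut_thickness_mm,
        axial_extent_mm=stent_length_mm,
        z_center_mm=z1,
    )
    inner = StentSpec(
        diameter_mm=d_inner_mm,
        strut_thickness_mm=strut_thickness_mm,
        center_offset_mm=(inner_offset_mm, 0.0),
        axial_extent_mm=stent_length_mm,
        z_center_mm=z2,
    )
    return PhantomSpec(stents=(outer, inner), vessel_lumen_diameter_mm=lumen_diameter_mm)
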