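"""Pixel ↔ frame-of-reference coordinate transforms and ROI geometry.

DICOM localises image planes in a 3D frame of reference — patient-based in
radiology, slide-based in microscopy — through the plane position (origin of
the top-left pixel, in mm), the direction cosines of the pixel rows and
columns, and the pixel spacing.  Those five quantities define an affine map
between 2D pixel indices and 3D millimetre coordinates, which is what lets
ROI coordinates and measurements (area, diameter) be expressed in physical
units independent of any image resampling, rotation or cropping.

Index convention (used everywhere in the package): indices are ``(column,
row)`` pairs, 0-based, addressing pixel *centers*; the geometry's ``position``
is the frame-of-reference coordinate of the center of the top-left pixel.
``reference_to_pixel`` returns fractional indices; rounding is the caller's
concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import GeometryError, OutOfPlaneError

__all__ = [
    "CoordinateSystem",
    "PlaneGeometry",
    "build_affine",
    "pixel_to_reference",
    "reference_to_pixel",
    "polygon_area_mm2",
    "bounding_box_3d",
]

_ORTHO_TOL = 1e-6


class CoordinateSystem(str, Enum):
    PATIENT = "PATIENT"
    SLIDE = "SLIDE"


@dataclass(frozen=True)
class PlaneGeometry:
    """Position, orientation and spacing of one image plane.

    Parameters
    ----------
    position:
        Frame-of-reference coordinates (mm) of the center of the top-left
        pixel.
    row_direction:
        Unit vector along which the *row index* increases (down the image).
    col_direction:
        Unit vector along which the *column index* increases (across the
        image).
    pixel_spacing:
        ``(between_rows_mm, between_columns_mm)``, both positive.
    coordinate_system:
        PATIENT or SLIDE.
    """

    position: tuple
    row_direction: tuple
    col_direction: tuple
    pixel_spacing: tuple
    coordinate_system: CoordinateSystem = CoordinateSystem.PATIENT

    def __post_init__(self):
        r = np.asarray(self.row_direction, dtype=float)
        c = np.asarray(self.col_direction, dtype=float)
        if abs(np.linalg.norm(r) - 1) > _ORTHO_TOL or \
                abs(np.linalg.norm(c) - 1) > _ORTHO_TOL:
            raise GeometryError("direction cosines must be unit vectors")
        if abs(float(np.dot(r, c))) > _ORTHO_TOL:
            raise GeometryError("row and column directions must be orthogonal")
        if len(self.position) != 3:
            raise GeometryError("position must be a 3-vector")
        dr, dc = self.pixel_spacing
        if dr <= 0 or dc <= 0:
            raise GeometryError("pixel spacings must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the plane (col_direction × row_direction)."""
        return np.cross(np.asarray(self.col_direction, dtype=float),
                        np.asarray(self.row_direction, dtype=float))

    @classmethod
    def from_image_dataset(cls, ds, frame: Optional[int] = None
                           ) -> "PlaneGeometry":
        """Extract the geometry of a source image (or one frame of it).

        Supports single-frame patient-based images (ImagePositionPatient /
        ImageOrientationPatient / PixelSpacing) and tiled slide-based images
        (total pixel matrix origin + ImageOrientationSlide).  DICOM encodes
        the orientation as (column-direction triplet, row-direction triplet)
        and spacing as (between-rows, between-columns).
        """
        if "ImageOrientationPatient" in ds:
            iop = [float(v) for v in ds.ImageOrientationPatient]
            pos = [float(v) for v in ds.ImagePositionPatient]
            spacing = [float(v) for v in ds.PixelSpacing]
            return cls(
                position=tuple(pos),
                col_direction=tuple(iop[:3]),
                row_direction=tuple(iop[3:]),
                pixel_spacing=(spacing[0], spacing[1]),
                coordinate_system=CoordinateSystem.PATIENT,
            )
        if "ImageOrientationSlide" in ds:
            ios = [float(v) for v in ds.ImageOrientationSlide]
            origin = ds.TotalPixelMatrixOriginSequence[0]
            pos = (
                float(origin.XOffsetInSlideCoordinateSystem),
                float(origin.YOffsetInSlideCoordinateSystem),
                float(getattr(origin, "ZOffsetInSlideCoordinateSystem", 0.0)),
            )
            shared = ds.SharedFunctionalGroupsSequence[0]
            spacing = [float(v)
                       for v in shared.PixelMeasuresSequence[0].PixelSpacing]
            return cls(
                position=pos,
                col_direction=tuple(ios[:3]),
                row_direction=tuple(ios[3:]),
                pixel_spacing=(spacing[0], spacing[1]),
                coordinate_system=CoordinateSystem.SLIDE,
            )
        raise GeometryError("dataset carries no recognised plane geometry")


def build_affine(geometry: PlaneGeometry) -> np.ndarray:
    """4×4 affine mapping homogeneous (column, row, 0, 1) → (x, y, z, 1) mm.

    The third column is the plane's unit normal, so the matrix is invertible
    and the third input coordinate measures out-of-plane offset in mm.
    """
    dr, dc = geometry.pixel_spacing
    a = np.eye(4)
    a[:3, 0] = np.asarray(geometry.col_direction, dtype=float) * dc
    a[:3, 1] = np.asarray(geometry.row_direction, dtype=float) * dr
    a[:3, 2] = geometry.normal
    a[:3, 3] = np.asarray(geometry.position, dtype=float)
    return a


def pixel_to_reference(indices: np.ndarray, geometry: PlaneGeometry
                       ) -> np.ndarray:
    """Map N×2 (column, row) pixel indices to N×3 mm coordinates."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    if idx.shape[1] != 2 or not np.all(np.isfinite(idx)):
        raise ValueError("indices must be a finite N×2 array of (col, row)")
    a = build_affine(geometry)
    homo = np.column_stack([idx, np.zeros(len(idx)), np.ones(len(idx))])
    return (a @ homo.T).T[:, :3]


def default_tolerance(geometry: PlaneGeometry) -> float:
    """Default out-of-plane tolerance: half the smaller pixel spacing."""
    return min(geometry.pixel_spacing) / 2.0


def reference_to_pixel(coords: np.ndarray, geometry: PlaneGeometry,
                       tolerance_mm: Optional[float] = None) -> np.ndarray:
    """Map N×3 mm coordinates to N×2 fractional (column, row) indices.

    Points whose orthogonal distance from the plane exceeds ``tolerance_mm``
    (default: half the smaller pixel spacing) raise :class:`OutOfPlaneError`
    reporting the largest offending distance; accepted points are projected
    onto the plane.
    """
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    if pts.shape[1] != 3 or not np.all(np.isfinite(pts)):
        raise ValueError("coords must be a finite N×3 array")
    if tolerance_mm is None:
        tolerance_mm = default_tolerance(geometry)
    a_inv = np.linalg.inv(build_affine(geometry))
    homo = np.column_stack([pts, np.ones(len(pts))])
    crz = (a_inv @ homo.T).T
    distances = np.abs(crz[:, 2])
    worst = float(distances.max()) if len(distances) else 0.0
    if worst > tolerance_mm:
        raise OutOfPlaneError(worst, tolerance_mm)
    return crz[:, :2]


def _plane_basis_2d(ring: np.ndarray, geometry: Optional[PlaneGeometry],
                    tol: float) -> np.ndarray:
    """Project in-plane 3D points onto a 2D orthonormal basis of their plane."""
    if geometry is not None:
        u = np.asarray(geometry.col_direction, dtype=float)
        v = np.asarray(geometry.row_direction, dtype=float)
        origin = np.asarray(geometry.position, dtype=float)
    else:
        # derive a basis from the ring itself
        origin = ring[0]
        diffs = ring - origin
        u = None
        for d in diffs[1:]:
            if np.linalg.norm(d) > 1e-12:
                u = d / np.linalg.norm(d)
                break
        if u is None:
            raise GeometryError("degenerate ring: all vertices coincide")
        normal = None
        for d in diffs[1:]:
            n = np.cross(u, d)
            if np.linalg.norm(n) > 1e-9:
                normal = n / np.linalg.norm(n)
                break
        if normal is None:
            raise GeometryError("degenerate ring: vertices are collinear")
        v = np.cross(normal, u)
    rel = ring - origin
    uv = np.column_stack([rel @ u, rel @ v])
    # planarity check
    recon = np.outer(uv[:, 0], u) + np.outer(uv[:, 1], v)
    off = np.linalg.norm(rel - recon, axis=1)
    if off.size and float(off.max()) > tol:
        raise GeometryError(
            f"ring is non-planar: max out-of-plane offset {off.max():.3g} mm"
        )
    return uv


def polygon_area_mm2(ring: np.ndarray,
                     geometry: Optional[PlaneGeometry] = None,
                     planarity_tol_mm: float = 1e-3) -> float:
    """Area (mm²) of a closed planar 3D ring, by the shoelace formula.

    The ring must be closed (first vertex equals last) and planar within
    ``planarity_tol_mm``.  The result is orientation-independent.
    """
    pts = np.atleast_2d(np.asarray(ring, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("ring must be an N×3 array of mm coordinates")
    if not np.allclose(pts[0], pts[-1], atol=1e-9):
        raise GeometryError("ring is not closed (first vertex must equal last)")
    distinct = np.unique(np.round(pts[:-1], 9), axis=0)
    if len(distinct) < 3:
        raise GeometryError("degenerate ring: fewer than 3 distinct vertices")
    uv = _plane_basis_2d(pts, geometry, planarity_tol_mm)
    x, y = uv[:-1, 0], uv[:-1, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(area))


def bounding_box_3d(points: np.ndarray, geometry: PlaneGeometry
                    ) -> np.ndarray:
    """Tight axis-aligned (in the plane basis) box around in-plane points.

    Returns a closed 5-vertex POLYGON ring in mm, traversed in order of
    increasing column then row index, with the first vertex repeated last.
    A single point yields a degenerate box expanded to one pixel's extent
    (the pixel's footprint, centered on the point).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("at least one point is required")
    idx = reference_to_pixel(pts, geometry)
    cmin, rmin = idx.min(axis=0)
    cmax, rmax = idx.max(axis=0)
    if cmax - cmin < 1e-12 and rmax - rmin < 1e-12:
        cmin, cmax = cmin - 0.5, cmax + 0.5
        rmin, rmax = rmin - 0.5, rmax + 0.5
    corners = np.array([
        [cmin, rmin],
        [cmax, rmin],
        [cmax, rmax],
        [cmin, rmax],
        [cmin, rmin],
    ])
    return pixel_to_reference(corners, geometry)
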