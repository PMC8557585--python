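"""Regions of interest on sonogram rasters.

A :class:`RoiPolygon` is a named planar polygon (or axis-aligned rectangle
given as two corners) drawn by the examiner on a sonogram frame.  Roles follow
the study design: ``node_A`` is the nodule region, ``parenchyma_B`` a matched
region of normal thyroid parenchyma, and ``total_node`` / ``total_parenchyma``
are the nodal and parenchymal sub-areas of the whole-lobe rectangle.

Coordinates are (row, col) with a 0-based top-left origin.  Rasterization uses
the pixel-center rule: pixel (r, c) belongs to the mask iff its center
(r + 0.5, c + 0.5) lies strictly inside the polygon, which makes integer-corner
rectangles behave half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

ROLES = ("node_A", "parenchyma_B", "total_node", "total_parenchyma")
PLANES = ("longitudinal", "cross")


class GeometryError(ValueError):
    """ROI lies outside the image or rasterizes to nothing."""


@dataclass(frozen=True)
class RoiPolygon:
    """A simple polygon with a role tag and a view plane.

    Parameters
    ----------
    vertices
        Ordered (row, col) coordinates.  Two vertices are interpreted as
        opposite corners of an axis-aligned rectangle; three or more as a
        simple polygon.
    role
        One of ``node_A``, ``parenchyma_B``, ``total_node``,
        ``total_parenchyma``.
    plane
        ``longitudinal`` or ``cross``.
    """

    vertices: tuple[tuple[float, float], ...]
    role: str = "node_A"
    plane: str = "longitudinal"

    def __init__(self, vertices: Sequence[Sequence[float]], role: str = "node_A",
                 plane: str = "longitudinal") -> None:
        verts = tuple((float(r), float(c)) for r, c in vertices)
        if len(verts) < 2:
            raise GeometryError("an ROI needs at least 2 vertices")
        if role not in ROLES:
            raise ValueError(f"unknown ROI role {role!r}; expected one of {ROLES}")
        if plane not in PLANES:
            raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "plane", plane)

    def as_shapely(self) -> shapely.Polygon:
        """The polygon in shapely's (x, y) = (col, row) convention."""
        if len(self.vertices) == 2:
            (r0, c0), (r1, c1) = self.vertices
            rmin, rmax = sorted((r0, r1))
            cmin, cmax = sorted((c0, c1))
            poly = shapely.box(cmin, rmin, cmax, rmax)
        else:
            poly = shapely.Polygon([(c, r) for r, c in self.vertices])
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("ROI polygon is self-intersecting or degenerate")
        return poly

    def bounds(self) -> tuple[float, float, float, float]:
        """(rmin, cmin, rmax, cmax) bounding box."""
        cmin, rmin, cmax, rmax = self.as_shapely().bounds
        return rmin, cmin, rmax, cmax


def rasterize_roi(roi: RoiPolygon, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of *roi* on an image of ``image_shape``.

    A pixel is in the mask iff its center lies inside the polygon; pixel
    centers exactly on the boundary are excluded.

    Raises
    ------
    GeometryError
        If the polygon extends outside the image bounds or rasterizes to an
        empty mask.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    poly = roi.as_shapely()
    rmin, cmin, rmax, cmax = roi.bounds()
    if rmin < 0 or cmin < 0 or rmax > h or cmax > w:
        raise GeometryError(
            f"ROI bounds (rows {rmin}..{rmax}, cols {cmin}..{cmax}) exceed "
            f"image shape {h}x{w}")
    # only evaluate centers inside the bounding box
    r0, r1 = max(0, int(np.floor(rmin))), min(h, int(np.ceil(rmax)))
    c0, c1 = max(0, int(np.floor(cmin))), min(w, int(np.ceil(cmax)))
    mask = np.zeros((h, w), dtype=bool)
    if r1 > r0 and c1 > c0:
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        inside = shapely.contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
        mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    if not mask.any():
        raise GeometryError("ROI rasterizes to an empty mask (degenerate ROI)")
    return mask
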