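"""Isodose contour extraction from dose grids.

Contours are extracted per plane by marching squares with linear edge
interpolation (scikit-image); levels may be absolute dose rates (cGy/h) or
percentages of the dose at a normalization point.  The "3D" product is a
stack of per-plane contour sets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .dose_engine import DoseGrid

__all__ = ["IsodoseSet", "Contour", "extract_contours"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class Contour:
    """One planar polyline of an isodose level, vertices in cm."""
    level: float            # absolute dose rate, cGy/h
    level_label: str        # e.g. "100%" or "50 cGy/h"
    plane_axis: str
    plane_offset: float
    vertices: np.ndarray    # (n, 3)


@dataclass
class IsodoseSet:
    normalization_point: tuple | None
    normalization_dose: float | None
    contours: list = field(default_factory=list)

    def levels(self) -> list:
        return sorted({c.level for c in self.contours})

    def for_level(self, level: float) -> list:
        return [c for c in self.contours if math.isclose(c.level, level)]


def extract_contours(grid: DoseGrid, plane, levels, normalization=None,
                     percent: bool | None = None) -> IsodoseSet:
    """Extract isodose polylines in one grid plane.

    ``plane`` is (axis, offset) with axis in 'x'/'y'/'z'; the nearest grid
    plane is used.  ``levels`` are percentages of the normalization dose
    when ``normalization`` (a point) is given, else absolute cGy/h; pass
    ``percent`` explicitly to override.  Masked (NaN) nodes are excluded.
    """
    axis_name, offset = plane
    ax = _AXES[axis_name]
    coords = grid.axis_points(ax)
    if offset < coords[0] - 1e-9 or offset > coords[-1] + 1e-9:
        raise ValueError(f"plane {axis_name}={offset} does not intersect the grid")
    idx = int(np.argmin(np.abs(coords - offset)))
    actual_offset = float(coords[idx])

    norm_dose = None
    if normalization is not None:
        norm_dose = grid.interp(normalization)
    use_percent = percent if percent is not None else (normalization is not None)
    if use_percent and norm_dose is None:
        raise ValueError("percent levels require a normalization point")

    slicer = [slice(None)] * 3
    slicer[ax] = idx
    plane_vals = grid.values[tuple(slicer)]
    rem = [k for k in range(3) if k != ax]

    out = IsodoseSet(normalization_point=tuple(normalization) if normalization
                     is not None else None, normalization_dose=norm_dose)
    for lv in levels:
        if lv <= 0:
            raise ValueError("isodose levels must be > 0")
        abs_level = lv / 100.0 * norm_dose if use_percent else float(lv)
        label = f"{lv:g}%" if use_percent else f"{lv:g} cGy/h"
        for poly in measure.find_contours(plane_vals, abs_level):
            verts = np.empty((len(poly), 3))
            verts[:, ax] = actual_offset
            for col, k in enumerate(rem):
                verts[:, k] = grid.origin[k] + poly[:, col] * grid.spacing[k]
            out.contours.append(Contour(abs_level, label, axis_name,
                                        actual_offset, verts))
    return out


def contours_to_table(iso: IsodoseSet) -> str:
    """Delimited-text dump: level, plane, polyline id, vertex index, x, y, z."""
    lines = ["level_cGy_h\tlabel\tplane\tpolyline\tvertex\tx_cm\ty_cm\tz_cm"]
    for pid, c in enumerate(iso.contours):
        for vi, v in enumerate(c.vertices):
            lines.append(f"{c.level:.6g}\t{c.level_label}\t"
                         f"{c.plane_axis}={c.plane_offset:g}\t{pid}\t{vi}\t"
                         f"{v[0]:.4f}\t{v[1]:.4f}\t{v[2]:.4f}")
    return "\n".join(lines) + "\n"
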