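"""Point-kernel dose-rate evaluation at points, reference sets and grids.

For every point emitter and every spectrum line the engine traces the
source-to-detector ray through the geometry, attenuates the uncollided
energy fluence rate by the summed optical thickness, multiplies by the
effective multi-layer buildup factor, and converts to collision kerma in
water through the mass energy-absorption coefficient:

    D[Gy/h] = sum_i  R_i E_i exp(-sum_j mu_j s_j) B(path, E_i) / (4 pi d^2)
              * (mu_en/rho)_w(E_i) * 1.602e-13 J/MeV * 1e3 g/kg * 3600 s/h

with R_i the line emission rate (photons/s).  Everything is additive over
emitters and lines; the engine is fully deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .buildup import Layer, effective_buildup
from .geometry import Geometry, trace_ray
from .physics_data import AbsorberTable, PhysicsLibrary
from .source_model import DEFAULT_DELTA_L, PointEmitter, discretize

__all__ = ["DoseModel", "ReferencePointSet", "DoseGrid", "SingularityError",
           "dose_rate_at_point", "evaluate_plan", "applicator_attenuation_ratio",
           "dose_rate_grid", "angular_profile", "prescription_time_h",
           "GRID_DELTA_L"]

#: coarser emitter spacing (cm) used by default for 3D grids (speed).
GRID_DELTA_L = 0.05

_KCONV = 1.602e-13 * 1.0e3 * 3600.0  # MeV/g/s -> Gy/h


class SingularityError(ValueError):
    """Dose requested at or inside an active source region."""


@dataclass
class ReferencePointSet:
    """Named evaluation points (cm); names are unique by construction."""
    points: dict = field(default_factory=dict)

    @classmethod
    def manchester(cls, extra: dict | None = None,
                   base: dict | None = None) -> "ReferencePointSet":
        from .applicators import manchester_points
        pts = dict(base if base is not None else manchester_points())
        if extra:
            for name, p in extra.items():
                if name in pts:
                    raise ValueError(f"duplicate reference point name {name!r}")
                pts[name] = tuple(p)
        return cls(pts)

    def items(self):
        return self.points.items()

    def __len__(self):
        return len(self.points)


@dataclass
class DoseGrid:
    """Dose rates on a regular 3D lattice; NaN marks masked source nodes."""
    origin: tuple
    spacing: tuple
    values: np.ndarray  # indexed [ix, iy, iz], cGy/h

    def coords(self, idx) -> tuple:
        return tuple(o + i * s for o, i, s in zip(self.origin, idx, self.spacing))

    def axis_points(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def interp(self, p) -> float:
        """Trilinear interpolation at point p (cm)."""
        idx = [(p[k] - self.origin[k]) / self.spacing[k] for k in range(3)]
        lo = [int(math.floor(i)) for i in idx]
        for k in range(3):
            if lo[k] < 0 or lo[k] + 1 >= self.values.shape[k]:
                if abs(idx[k] - round(idx[k])) < 1e-9 and \
                        0 <= round(idx[k]) < self.values.shape[k]:
                    lo[k] = min(int(round(idx[k])), self.values.shape[k] - 2)
                else:
                    raise ValueError(f"point {p} outside grid")
        f = [idx[k] - lo[k] for k in range(3)]
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((f[0] if dx else 1 - f[0]) *
                         (f[1] if dy else 1 - f[1]) *
                         (f[2] if dz else 1 - f[2]))
                    out += w * self.values[lo[0] + dx, lo[1] + dy, lo[2] + dz]
        return out


class DoseModel:
    """Sources + geometry + ambient absorber: the object dose queries run on.

    Emission weights: each source's per-line rate is activity * p_i, further
    scaled by its dwell-time fraction when any source carries a non-default
    dwell time (HDR stepping-source plans report the time-averaged rate).
    """

    def __init__(self, geometry: Geometry, sources: list,
                 library: PhysicsLibrary, delta_l: float = DEFAULT_DELTA_L,
                 absorber: AbsorberTable | None = None):
        if not sources:
            raise ValueError("a dose model needs at least one source")
        self.geometry = geometry
        self.sources = list(sources)
        self.library = library
        self.delta_l = delta_l
        self.absorber = absorber or library.absorbers["water"]

        times = [s.dwell_time_s for s in self.sources]
        weighted = any(abs(t - 1.0) > 1e-12 for t in times) or len(set(times)) > 1
        total_t = sum(times)
        self.emitters: list[PointEmitter] = []
        self.emitters_by_source: dict = {}
        for s in self.sources:
            ems = discretize(s, library, delta_l=delta_l)
            if weighted:
                w = s.dwell_time_s / total_t
                ems = [PointEmitter(e.position,
                                    tuple((en, r * w) for en, r in e.lines))
                       for e in ems]
            self.emitters_by_source[s.name or f"src{len(self.emitters_by_source)}"] = ems
            self.emitters.extend(ems)

        self._line_cache: dict = {}
        self._cores = geometry.active_core_regions()

    def _line_ctx(self, e_mev: float):
        ctx = self._line_cache.get(e_mev)
        if ctx is None:
            mus = {r.material.name: r.material.mu_at(e_mev)
                   for r in self.geometry.regions}
            mus[self.geometry.ambient.name] = self.geometry.ambient.mu_at(e_mev)
            ctx = (mus, self.absorber.at(e_mev))
            self._line_cache[e_mev] = ctx
        return ctx

    def check_point(self, p) -> None:
        for core in self._cores:
            if core.contains(p):
                raise SingularityError(
                    f"point {tuple(p)} lies inside active source region "
                    f"{core.name!r}")

    def point_dose(self, p, emitters=None) -> float:
        """Dose rate at p in cGy/h."""
        self.check_point(p)
        if emitters is None:
            emitters = self.emitters
        geom = self.geometry
        total = 0.0
        for em in emitters:
            ex, ey, ez = em.position
            dx, dy, dz = p[0] - ex, p[1] - ey, p[2] - ez
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < 1e-12:
                raise SingularityError(f"point {tuple(p)} coincides with an emitter")
            segs = trace_ray(geom, em.position, p)
            for e_mev, rate in em.lines:
                if rate == 0.0:
                    continue
                mus, muen = self._line_ctx(e_mev)
                opt = 0.0
                layers = []
                for seg in segs:
                    l = mus[seg.material.name] * seg.length_cm
                    opt += l
                    layers.append(Layer(seg.material, seg.length_cm, l))
                b = effective_buildup(layers, e_mev)
                psi = rate * e_mev * math.exp(-opt) / (4.0 * math.pi * d2)
                total += psi * b * muen
        return total * _KCONV * 100.0  # Gy/h -> cGy/h


def dose_rate_at_point(model: DoseModel, p) -> float:
    """Point-kernel dose rate at p, cGy/h (collision kerma in water)."""
    return model.point_dose(p)


def evaluate_plan(model: DoseModel, points: ReferencePointSet,
                  per_source: bool = False, unit: str = "cGy/h") -> pd.DataFrame:
    """Dose-rate table at named reference points.

    With per_source=True the table carries one column per source plus the
    total (the per-source breakdown of the printed applicator tables).
    """
    scale = {"cGy/h": 1.0, "Gy/h": 0.01}[unit]
    rows = []
    for name, p in points.items():
        row = {"point": name, "x_cm": p[0], "y_cm": p[1], "z_cm": p[2]}
        if per_source:
            total = 0.0
            for sname, ems in model.emitters_by_source.items():
                d = model.point_dose(p, emitters=ems) * scale
                row[sname] = d
                total += d
            row["dose_rate"] = total
        else:
            row["dose_rate"] = model.point_dose(p) * scale
        row["unit"] = unit
        rows.append(row)
    cols = ["point", "x_cm", "y_cm", "z_cm"]
    if rows:
        cols += [c for c in rows[0] if c not in cols]
    return pd.DataFrame(rows, columns=cols if rows else
                        ["point", "x_cm", "y_cm", "z_cm", "dose_rate", "unit"])


def applicator_attenuation_ratio(model_with_walls: DoseModel,
                                 model_sources_only: DoseModel, p) -> float:
    """Percent dose-rate reduction caused by the applicator walls at p.

    100 * (1 - D_with / D_without); negative if buildup outweighs the extra
    attenuation.  Both models must share identical emitter layouts.
    """
    ems_w = [(e.position, e.lines) for e in model_with_walls.emitters]
    ems_o = [(e.position, e.lines) for e in model_sources_only.emitters]
    if ems_w != ems_o:
        raise ValueError("models do not share identical emitters")
    d_without = model_sources_only.point_dose(p)
    if d_without == 0.0:
        raise ZeroDivisionError("sources-only dose rate is zero at this point")
    d_with = model_with_walls.point_dose(p)
    return 100.0 * (1.0 - d_with / d_without)


def dose_rate_grid(model: DoseModel, origin, spacing, shape) -> DoseGrid:
    """Dose rates on a regular lattice (cGy/h); active-core nodes are NaN."""
    spacing = tuple(float(s) for s in (spacing if hasattr(spacing, "__len__")
                                       else (spacing,) * 3))
    if any(s <= 0 for s in spacing):
        raise ValueError("grid spacing must be > 0")
    vals = np.empty(shape, dtype=float)
    for ix in range(shape[0]):
        for iy in range(shape[1]):
            for iz in range(shape[2]):
                p = (origin[0] + ix * spacing[0],
                     origin[1] + iy * spacing[1],
                     origin[2] + iz * spacing[2])
                try:
                    vals[ix, iy, iz] = model.point_dose(p)
                except SingularityError:
                    vals[ix, iy, iz] = math.nan
    return DoseGrid(tuple(origin), spacing, vals)


def angular_profile(model: DoseModel, radii, angles_deg, center=None,
                    axis_point_fn=None, min_radius: float = 1.5,
                    mirror: bool = False) -> pd.DataFrame:
    """Dose rates over (r, theta) in the transverse plane of a cylinder.

    Points are taken at center + r*(sin(theta) x + cos(theta) z) — azimuth
    0 deg along +z, increasing toward +x, matching the shielded-cylinder
    frame (shield centered on 180 deg).  With mirror=True the 180-360 deg
    half is duplicated from 0-180.
    """
    if center is None:
        center = (0.0, 4.5, 0.0)
    rows = []
    for r in radii:
        if r < min_radius:
            raise ValueError(f"radius {r} cm lies inside the applicator "
                             f"(minimum {min_radius} cm)")
        for th in angles_deg:
            rad = math.radians(th)
            p = (center[0] + r * math.sin(rad), center[1],
                 center[2] + r * math.cos(rad))
            rows.append({"r_cm": r, "theta_deg": th,
                         "dose_rate_cGy_h": model.point_dose(p)})
    if mirror:
        mirrored = [{"r_cm": row["r_cm"], "theta_deg": 360.0 - row["theta_deg"],
                     "dose_rate_cGy_h": row["dose_rate_cGy_h"]}
                    for row in rows if 0.0 < row["theta_deg"] < 180.0]
        rows.extend(mirrored)
    return pd.DataFrame(rows)


def prescription_time_h(model: DoseModel, points: ReferencePointSet,
                        prescribed_dose_gy: float,
                        point_names=("A_left", "A_right")) -> float:
    """Treatment time (h) delivering a prescribed dose at the mean of the
    named reference points (the usual left/right point-A prescription).

    A post-scaling utility: dwell times or source strengths are inputs and
    are not optimized; the plan's time-averaged dose rate is simply scaled.
    """
    if prescribed_dose_gy <= 0:
        raise ValueError("prescribed dose must be > 0")
    rates = [model.point_dose(points.points[n]) * 0.01  # Gy/h
             for n in point_names]
    mean_rate = sum(rates) / len(rates)
    if mean_rate == 0:
        raise ZeroDivisionError("zero dose rate at the prescription points")
    return prescribed_dose_gy / mean_rate
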