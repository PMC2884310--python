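"""Combinatorial-geometry solids and ray tracing into per-material paths.

A Geometry is an ordered set of prioritized material Regions over an ambient
medium (water by default).  Every point classifies to exactly one material:
the highest-priority region containing it, else the ambient.  Rays are
traced by collecting every surface-crossing parameter of every primitive
along the segment, splitting the segment there, and classifying midpoints;
adjacent same-material pieces are merged.  Segment lengths therefore sum to
the chord length exactly (up to float rounding).

Lengths are cm; angles in public interfaces are degrees.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .physics_data import Material

__all__ = ["Primitive", "Cylinder", "Sphere", "Box", "SectorShell",
           "Region", "Geometry", "RaySegment", "classify", "trace_ray",
           "DegenerateRayError"]

_EPS = 1e-9


class DegenerateRayError(ValueError):
    """Ray endpoints coincide."""


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _sub(a, b):
    return (a[0] - b[0], a[1] - b[1], a[2] - b[2])


def _unit(v):
    n = math.sqrt(_dot(v, v))
    if n == 0:
        raise ValueError("zero-length vector")
    return (v[0] / n, v[1] / n, v[2] / n)


class Primitive:
    """Interface: point containment and ray surface crossings."""

    def contains(self, p) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def crossings(self, a, d, length) -> list:
        """Parameters t in (0, length) where segment a + t*d crosses a
        surface of this primitive; d is the unit ray direction."""
        raise NotImplementedError  # pragma: no cover


def _quadratic_ts(qa, qb, qc, length):
    """Real roots of qa t^2 + qb t + qc = 0 inside (0, length)."""
    out = []
    if abs(qa) < 1e-14:
        if abs(qb) > 1e-14:
            t = -qc / qb
            if _EPS < t < length - _EPS:
                out.append(t)
        return out
    disc = qb * qb - 4.0 * qa * qc
    if disc <= 0.0:
        return out
    s = math.sqrt(disc)
    for t in ((-qb - s) / (2 * qa), (-qb + s) / (2 * qa)):
        if _EPS < t < length - _EPS:
            out.append(t)
    return out


@dataclass(frozen=True)
class Cylinder(Primitive):
    """Finite solid cylinder: base point, unit axis, radius, length."""
    base: tuple
    axis: tuple
    radius: float
    length: float

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("cylinder radius and length must be > 0")
        object.__setattr__(self, "axis", _unit(self.axis))

    def contains(self, p) -> bool:
        v = _sub(p, self.base)
        h = _dot(v, self.axis)
        if h < 0.0 or h > self.length:
            return False
        r2 = _dot(v, v) - h * h
        return r2 <= self.radius * self.radius

    def crossings(self, a, d, length) -> list:
        v = _sub(a, self.base)
        vh = _dot(v, self.axis)
        dh = _dot(d, self.axis)
        # lateral surface: |v_perp + t d_perp| = R
        qa = 1.0 - dh * dh
        qb = 2.0 * (_dot(v, d) - vh * dh)
        qc = (_dot(v, v) - vh * vh) - self.radius * self.radius
        ts = _quadratic_ts(qa, qb, qc, length)
        # cap planes
        if abs(dh) > 1e-14:
            for plane_h in (0.0, self.length):
                t = (plane_h - vh) / dh
                if _EPS < t < length - _EPS:
                    ts.append(t)
        return ts


@dataclass(frozen=True)
class Sphere(Primitive):
    center: tuple
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")

    def contains(self, p) -> bool:
        v = _sub(p, self.center)
        return _dot(v, v) <= self.radius * self.radius

    def crossings(self, a, d, length) -> list:
        v = _sub(a, self.center)
        return _quadratic_ts(1.0, 2.0 * _dot(v, d),
                             _dot(v, v) - self.radius * self.radius, length)


@dataclass(frozen=True)
class Box(Primitive):
    """Parallelepiped from a corner and three mutually orthogonal edges."""
    corner: tuple
    edges: tuple  # three edge vectors

    def __post_init__(self):
        e1, e2, e3 = self.edges
        for u, w in ((e1, e2), (e1, e3), (e2, e3)):
            if abs(_dot(u, w)) > 1e-9 * math.sqrt(_dot(u, u) * _dot(w, w)):
                raise ValueError("box edges must be orthogonal")

    def _frame(self):
        return [( _unit(e), math.sqrt(_dot(e, e)) ) for e in self.edges]

    def contains(self, p) -> bool:
        v = _sub(p, self.corner)
        for u, ln in self._frame():
            h = _dot(v, u)
            if h < 0.0 or h > ln:
                return False
        return True

    def crossings(self, a, d, length) -> list:
        v = _sub(a, self.corner)
        ts = []
        for u, ln in self._frame():
            dh = _dot(d, u)
            if abs(dh) < 1e-14:
                continue
            vh = _dot(v, u)
            for plane in (0.0, ln):
                t = (plane - vh) / dh
                if _EPS < t < length - _EPS:
                    ts.append(t)
        return ts


@dataclass(frozen=True)
class SectorShell(Primitive):
    """Angular sector of a cylindrical shell (e.g. a tungsten shield).

    base/axis/length as for Cylinder; radial span [inner_radius,
    outer_radius]; azimuth measured in degrees from ``ref_dir`` (projected
    perpendicular to the axis) increasing toward ref_dir x axis ... the
    right-handed sweep; span [start_deg, stop_deg] within [0, 360].
    """
    base: tuple
    axis: tuple
    inner_radius: float
    outer_radius: float
    length: float
    start_deg: float
    stop_deg: float
    ref_dir: tuple

    def __post_init__(self):
        if not (0.0 < self.inner_radius < self.outer_radius):
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not (0.0 <= self.start_deg < self.stop_deg <= 360.0):
            raise ValueError("need 0 <= start < stop <= 360 degrees")
        object.__setattr__(self, "axis", _unit(self.axis))
        r = self.ref_dir
        h = _dot(r, self.axis)
        perp = (r[0] - h * self.axis[0], r[1] - h * self.axis[1], r[2] - h * self.axis[2])
        object.__setattr__(self, "ref_dir", _unit(perp))

    def _w(self):
        a, r = self.axis, self.ref_dir
        return (a[1] * r[2] - a[2] * r[1],
                a[2] * r[0] - a[0] * r[2],
                a[0] * r[1] - a[1] * r[0])

    def _azimuth_deg(self, v) -> float:
        x = _dot(v, self.ref_dir)
        y = _dot(v, self._w())
        ang = math.degrees(math.atan2(y, x))
        return ang + 360.0 if ang < 0 else ang

    def contains(self, p) -> bool:
        v = _sub(p, self.base)
        h = _dot(v, self.axis)
        if h < 0.0 or h > self.length:
            return False
        perp = (v[0] - h * self.axis[0], v[1] - h * self.axis[1], v[2] - h * self.axis[2])
        r2 = _dot(perp, perp)
        if not (self.inner_radius ** 2 <= r2 <= self.outer_radius ** 2):
            return False
        return self.start_deg <= self._azimuth_deg(perp) <= self.stop_deg

    def crossings(self, a, d, length) -> list:
        v = _sub(a, self.base)
        vh = _dot(v, self.axis)
        dh = _dot(d, self.axis)
        qa = 1.0 - dh * dh
        qb = 2.0 * (_dot(v, d) - vh * dh)
        ts = []
        for radius in (self.inner_radius, self.outer_radius):
            qc = (_dot(v, v) - vh * vh) - radius * radius
            ts.extend(_quadratic_ts(qa, qb, qc, length))
        if abs(dh) > 1e-14:
            for plane_h in (0.0, self.length):
                t = (plane_h - vh) / dh
                if _EPS < t < length - _EPS:
                    ts.append(t)
        # azimuthal boundary half-planes: plane with normal n = w*cos(th) - u*sin(th)
        u, w = self.ref_dir, self._w()
        for ang in (self.start_deg, self.stop_deg):
            th = math.radians(ang)
            n = (w[0] * math.cos(th) - u[0] * math.sin(th),
                 w[1] * math.cos(th) - u[1] * math.sin(th),
                 w[2] * math.cos(th) - u[2] * math.sin(th))
            dn = _dot(d, n)
            if abs(dn) > 1e-14:
                t = -_dot(v, n) / dn
                if _EPS < t < length - _EPS:
                    ts.append(t)
        return ts


@dataclass(frozen=True)
class Region:
    """Prioritized material region: intersection of ``primitives`` minus
    ``subtract``; higher priority wins where regions overlap."""
    primitives: tuple
    material: Material
    priority: int
    name: str = ""
    subtract: tuple = ()
    is_active_core: bool = False

    def contains(self, p) -> bool:
        for prim in self.primitives:
            if not prim.contains(p):
                return False
        for prim in self.subtract:
            if prim.contains(p):
                return False
        return True


@dataclass
class Geometry:
    """Ordered material regions over an ambient medium."""
    regions: list = field(default_factory=list)
    ambient: Material | None = None

    def __post_init__(self):
        self.regions = sorted(self.regions, key=lambda r: -r.priority)

    def add(self, region: Region) -> None:
        self.regions.append(region)
        self.regions.sort(key=lambda r: -r.priority)

    def classify(self, p) -> Material:
        for region in self.regions:
            if region.contains(p):
                return region.material
        return self.ambient

    def active_core_regions(self) -> list:
        return [r for r in self.regions if r.is_active_core]

    def describe(self) -> str:
        """Delimited-text debug dump of regions."""
        lines = ["name\tmaterial\tpriority\tn_primitives"]
        for r in self.regions:
            lines.append(f"{r.name}\t{r.material.name}\t{r.priority}\t{len(r.primitives)}")
        lines.append(f"(ambient)\t{self.ambient.name}\t-\t-")
        return "\n".join(lines)


@dataclass(frozen=True)
class RaySegment:
    material: Material
    length_cm: float


def classify(geometry: Geometry, p) -> Material:
    """Material of the highest-priority region containing p (ambient if none)."""
    return geometry.classify(p)


def trace_ray(geometry: Geometry, a, b) -> list:
    """Ordered per-material segments of the chord from a to b.

    Returns a list of RaySegment whose lengths sum to |b - a|; adjacent
    same-material segments are merged.
    """
    diff = _sub(b, a)
    length = math.sqrt(_dot(diff, diff))
    if length < 1e-12:
        raise DegenerateRayError("ray endpoints coincide")
    d = (diff[0] / length, diff[1] / length, diff[2] / length)

    ts = [0.0, length]
    for region in geometry.regions:
        for prim in region.primitives + region.subtract:
            ts.extend(prim.crossings(a, d, length))
    ts.sort()
    # dedupe near-coincident crossings
    cuts = [ts[0]]
    for t in ts[1:]:
        if t - cuts[-1] > 1e-9:
            cuts.append(t)
    if cuts[-1] < length:
        cuts[-1] = length

    segments: list = []
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        tm = 0.5 * (t0 + t1)
        mid = (a[0] + tm * d[0], a[1] + tm * d[1], a[2] + tm * d[2])
        mat = geometry.classify(mid)
        seg_len = t1 - t0
        if segments and segments[-1].material == mat:
            segments[-1] = RaySegment(mat, segments[-1].length_cm + seg_len)
        else:
            segments.append(RaySegment(mat, seg_len))
    return segments
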