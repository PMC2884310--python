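"""Builders for the four modeled intracavitary applicators.

Coordinate frame: origin at the external os on the tandem axis, +y superior
along the straight tandem, +x lateral, +z anterior.  Tandem angulation
bends the tube anteriorly (about the x axis through the os); the Manchester
reference points are defined in the tandem frame and rotate with it, which
is why the tandem contribution at point A is insensitive to angulation.

Source trains are stacked gap-free from the inner fundus end downward with
the capsule (physical) length setting the pitch; the long-tube train top
sits 6.2 cm above the os, the medium-tube train top 4.2 cm.  These stacking
lengths are reconstruction assumptions (see docs/methods.md) and are the
dominant uncertainty in reference-point comparisons.
"""
from __future__ import annotations

import dataclasses
import math
import warnings

from .geometry import Cylinder, Geometry, Region, SectorShell
from .physics_data import PhysicsLibrary
from .source_model import EncapsulatedSource, SourceStrength

__all__ = ["build_brit_ldr", "build_vaginal_cylinder", "build_fletcher_green",
           "build_fletcher_williamson", "manchester_points"]

# capsule geometry: (active_len, active_dia, capsule_od, capsule_len,
#                    capsule_material, core_material)
_CSA1 = (1.5, 0.18, 0.3, 2.0, "SS", "pollucite")
_CSA2 = (1.0, 0.18, 0.3, 2.0, "SS", "pollucite")
_CDCJ = (1.35, 0.165, 0.265, 2.0, "Pt-Fe", "pollucite")
_MHDR = (0.36, 0.065, 0.09, 0.5, "SS", "iridium")

_LONG_TRAIN_TOP = 6.2   # cm above the os, long intrauterine tube
_MEDIUM_TRAIN_TOP = 4.2


def _rot_x(p, deg):
    """Rotate about the x axis: +y toward +z (anterior bend)."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return (p[0], c * p[1] - s * p[2], s * p[1] + c * p[2])


def manchester_points(angulation_deg: float = 0.0) -> dict:
    """Points A and B (left/right), defined in the tandem frame."""
    pts = {
        "A_right": (2.0, 2.0, 0.0), "A_left": (-2.0, 2.0, 0.0),
        "B_right": (5.0, 2.0, 0.0), "B_left": (-5.0, 2.0, 0.0),
    }
    return {k: _rot_x(p, angulation_deg) for k, p in pts.items()}


def _make_source(spec, nuclide, center, axis, strength, name):
    al, ad, cod, cl, cmat, core = spec
    return EncapsulatedSource(
        nuclide=nuclide, active_length=al, active_diameter=ad,
        capsule_outer_diameter=cod, capsule_length=cl,
        capsule_material=cmat, core_material=core,
        center=center, axis=axis, strength=strength, name=name,
    )


def add_source_regions(geom: Geometry, source: EncapsulatedSource,
                       library: PhysicsLibrary, priority: int) -> None:
    """Capsule shell + active core regions for one source."""
    ax = source.axis
    half_c = source.capsule_length / 2.0
    base_c = tuple(c - half_c * a for c, a in zip(source.center, ax))
    geom.add(Region(
        primitives=(Cylinder(base_c, ax, source.capsule_outer_diameter / 2.0,
                             source.capsule_length),),
        material=library.material(source.capsule_material),
        priority=priority, name=f"{source.name}-capsule"))
    if source.active_length > 0:
        half_a = source.active_length / 2.0
        base_a = tuple(c - half_a * a for c, a in zip(source.center, ax))
        geom.add(Region(
            primitives=(Cylinder(base_a, ax, source.active_diameter / 2.0,
                                 source.active_length),),
            material=library.material(source.core_material),
            priority=priority + 1, name=f"{source.name}-core",
            is_active_core=True))


def _check_range(name, value, lo, hi):
    if not (lo <= value <= hi):
        warnings.warn(f"{name}={value} outside the studied range [{lo}, {hi}]",
                      stacklevel=3)


def _tandem_tube_regions(library, length, inner_r=0.25, outer_r=0.30):
    # wall shell only; the tube interior is treated as water-equivalent,
    # matching the homogenized applicator treatment the engine reproduces
    steel = Region(
        primitives=(Cylinder((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), outer_r, length),),
        material=library.material("SS"), priority=5, name="tandem-tube")
    inner = Region(
        primitives=(Cylinder((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), inner_r, length - 0.1),),
        material=library.material("water"), priority=6, name="tandem-lumen")
    return [steel, inner]


def _ovoid_tube_regions(library, center, axis, tag, inner_r=0.25, outer_r=0.30,
                        length=2.4):
    base = tuple(c - length / 2.0 * a for c, a in zip(center, axis))
    base_in = tuple(c - (length - 0.1) / 2.0 * a for c, a in zip(center, axis))
    steel = Region(
        primitives=(Cylinder(base, axis, outer_r, length),),
        material=library.material("SS"), priority=5, name=f"ovoid-tube-{tag}")
    inner = Region(
        primitives=(Cylinder(base_in, axis, inner_r, length - 0.1),),
        material=library.material("water"), priority=6, name=f"ovoid-lumen-{tag}")
    return [steel, inner]


def build_brit_ldr(library: PhysicsLibrary, tube: str = "long",
                   angulation_deg: float = 0.0, separation_cm: float = 3.0,
                   depth_cm: float = 1.5, with_walls: bool = True,
                   ovoid_angulation_deg: float = -40.0):
    """BRIT LDR applicator: steel tandem + two ovoid tubes, CSA Cs-137 train.

    Long tube loads CSA-1/CSA-2/CSA-2 at 350/230/230 uGy h^-1 m^2 from the
    fundus; the medium tube loads 350/230.  Ovoids carry one CSA-2 each at
    230.  Returns (geometry, sources, reference_points).
    """
    if tube not in ("long", "medium"):
        raise ValueError(f"unknown tandem length class {tube!r}")
    _check_range("angulation_deg", angulation_deg, 0.0, 45.0)
    _check_range("separation_cm", separation_cm, 2.5, 4.0)
    _check_range("depth_cm", depth_cm, 1.25, 2.0)

    geom = Geometry(ambient=library.material("water"))
    sources = []

    if tube == "long":
        loading = [(_CSA1, 350.0), (_CSA2, 230.0), (_CSA2, 230.0)]
        top = _LONG_TRAIN_TOP
    else:
        loading = [(_CSA1, 350.0), (_CSA2, 230.0)]
        top = _MEDIUM_TRAIN_TOP
    tandem_axis = _rot_x((0.0, 1.0, 0.0), angulation_deg)
    y = top
    for i, (spec, sk) in enumerate(loading):
        y_center = y - spec[3] / 2.0
        center = _rot_x((0.0, y_center, 0.0), angulation_deg)
        sources.append(_make_source(
            spec, "Cs-137", center, tandem_axis,
            SourceStrength("air_kerma_strength", sk), f"S{i + 1}"))
        y -= spec[3]

    ov_axis = _rot_x((0.0, 1.0, 0.0), ovoid_angulation_deg)
    half_sep = separation_cm / 2.0
    for tag, x in (("right", half_sep), ("left", -half_sep)):
        center = (x, -depth_cm, 0.0)
        sources.append(_make_source(
            _CSA2, "Cs-137", center, ov_axis,
            SourceStrength("air_kerma_strength", 230.0),
            f"S{4 if tag == 'right' else 5}"))

    if with_walls:
        tube_len = top + 0.2
        for region in _tandem_tube_regions(library, tube_len):
            geom.add(Region(
                primitives=tuple(
                    Cylinder(_rot_x(p.base, angulation_deg),
                             _rot_x(p.axis, angulation_deg), p.radius, p.length)
                    for p in region.primitives),
                material=region.material, priority=region.priority,
                name=region.name))
        for src in sources[-2:]:
            for region in _ovoid_tube_regions(library, src.center, src.axis,
                                              src.name):
                geom.add(region)

    for i, src in enumerate(sources):
        add_source_regions(geom, src, library, priority=20 + 2 * i)

    return geom, sources, manchester_points(angulation_deg)


def build_fletcher_green(library: PhysicsLibrary, angulation_deg: float = 15.0,
                         separation_cm: float = 3.0, depth_cm: float = 1.5,
                         with_walls: bool = False,
                         ovoid_angulation_deg: float = 30.0,
                         tandem_linear_rates=(54.2, 36.2, 36.2),
                         colpostat_total_linear_rate: float = 72.3):
    """Fletcher Green type LDR applicator with CDC-J Cs-137 sources.

    Strengths are linear reference air-kerma rates (uGy h^-1 m^2 cm^-1)
    referred to the 2.0 cm physical source length; the colpostat total is
    split equally between the two sources.  The paper's comparisons model
    the sources only (no walls), which is the default here.
    """
    _check_range("separation_cm", separation_cm, 2.5, 4.0)
    geom = Geometry(ambient=library.material("water"))
    sources = []

    tandem_axis = _rot_x((0.0, 1.0, 0.0), angulation_deg)
    y = _LONG_TRAIN_TOP
    for i, rate in enumerate(tandem_linear_rates):
        y_center = y - _CDCJ[3] / 2.0
        center = _rot_x((0.0, y_center, 0.0), angulation_deg)
        sources.append(_make_source(
            _CDCJ, "Cs-137", center, tandem_axis,
            SourceStrength("linear_air_kerma_rate", rate), f"S{i + 1}"))
        y -= _CDCJ[3]

    ov_axis = _rot_x((0.0, 1.0, 0.0), ovoid_angulation_deg)
    per_colpostat = colpostat_total_linear_rate / 2.0
    for i, (tag, x) in enumerate((("right", separation_cm / 2.0),
                                  ("left", -separation_cm / 2.0))):
        sources.append(_make_source(
            _CDCJ, "Cs-137", (x, -depth_cm, 0.0), ov_axis,
            SourceStrength("linear_air_kerma_rate", per_colpostat), f"S{4 + i}"))

    if with_walls:
        tube_len = _LONG_TRAIN_TOP + 0.2
        for region in _tandem_tube_regions(library, tube_len,
                                           inner_r=0.20, outer_r=0.30):
            geom.add(Region(
                primitives=tuple(
                    Cylinder(_rot_x(p.base, angulation_deg),
                             _rot_x(p.axis, angulation_deg), p.radius, p.length)
                    for p in region.primitives),
                material=region.material, priority=region.priority,
                name=region.name))
        for src in sources[-2:]:
            for region in _ovoid_tube_regions(library, src.center, src.axis,
                                              src.name, inner_r=0.20):
                geom.add(region)

    for i, src in enumerate(sources):
        add_source_regions(geom, src, library, priority=20 + 2 * i)

    return geom, sources, manchester_points(angulation_deg)


def build_fletcher_williamson(library: PhysicsLibrary,
                              angulation_deg: float = 15.0,
                              separation_cm: float = 3.0,
                              depth_cm: float = 1.5,
                              air_kerma_strength: float = 40800.0,
                              dwell_times_s=None,
                              step_cm: float = 0.5):
    """Fletcher-Williamson HDR applicator: stepping mHDR Ir-192 source.

    20 active dwell positions (14 in the tandem, 3 in each ovoid) at 5 mm
    step; each dwell is represented as a source instance sharing the single
    physical source's strength, weighted by its dwell time.
    """
    geom = Geometry(ambient=library.material("water"))
    sources = []
    n_tandem, n_ovoid = 14, 3
    total = n_tandem + 2 * n_ovoid
    if dwell_times_s is None:
        dwell_times_s = [1.0] * total
    if len(dwell_times_s) != total:
        raise ValueError(f"expected {total} dwell times, got {len(dwell_times_s)}")

    tandem_axis = _rot_x((0.0, 1.0, 0.0), angulation_deg)
    k = 0
    y0 = _LONG_TRAIN_TOP + 0.55  # first dwell near the tandem tip
    for i in range(n_tandem):
        center = _rot_x((0.0, y0 - i * step_cm, 0.0), angulation_deg)
        src = _make_source(_MHDR, "Ir-192", center, tandem_axis,
                           SourceStrength("air_kerma_strength", air_kerma_strength),
                           f"T{i + 1}")
        sources.append(dataclasses.replace(src, dwell_time_s=dwell_times_s[k]))
        k += 1
    ov_axis = _rot_x((0.0, 1.0, 0.0), 30.0)
    for tag, x in (("right", separation_cm / 2.0), ("left", -separation_cm / 2.0)):
        for j in range(n_ovoid):
            off = (j - 1) * step_cm
            center = tuple(c + off * a for c, a in
                           zip((x, -depth_cm, 0.0), ov_axis))
            src = _make_source(_MHDR, "Ir-192", center, ov_axis,
                               SourceStrength("air_kerma_strength",
                                              air_kerma_strength),
                               f"O{tag[0].upper()}{j + 1}")
            sources.append(dataclasses.replace(src, dwell_time_s=dwell_times_s[k]))
            k += 1

    for i, src in enumerate(sources):
        add_source_regions(geom, src, library, priority=20 + 2 * i)
    return geom, sources, manchester_points(angulation_deg)


def build_vaginal_cylinder(library: PhysicsLibrary, shield_angle_deg: int = 180,
                           activity_bq: float = 3.7e10,
                           source_tip_distance_cm: float = 4.5):
    """Shielded vaginal cylindrical applicator with an mHDR Ir-192 source.

    15 cm PMMA shell (OD 3.0 cm, 0.5 cm wall) on a thin-wall steel tube
    (0.4 cm OD) with an air gap that can hold a 0.8 cm thick tungsten
    sector shield of 90/180/270 degrees.  Azimuth 0 deg is the unshielded
    +z reference direction; the shield is centered on 180 deg.  The
    cylinder axis runs along +y with the tip at y = 0.
    """
    if shield_angle_deg not in (0, 90, 180, 270):
        raise ValueError("shield_angle_deg must be one of 0, 90, 180, 270")
    geom = Geometry(ambient=library.material("water"))
    axis = (0.0, 1.0, 0.0)
    geom.add(Region((Cylinder((0.0, 0.0, 0.0), axis, 1.5, 15.0),),
                    library.material("PMMA"), 10, "shell"))
    geom.add(Region((Cylinder((0.0, 0.5, 0.0), axis, 1.0, 14.5),),
                    library.material("air"), 20, "shell-air"))
    src_y = source_tip_distance_cm
    if shield_angle_deg:
        half = shield_angle_deg / 2.0
        geom.add(Region(
            (SectorShell(base=(0.0, src_y - 5.0, 0.0), axis=axis,
                         inner_radius=0.2, outer_radius=1.0, length=10.0,
                         start_deg=180.0 - half, stop_deg=180.0 + half,
                         ref_dir=(0.0, 0.0, 1.0)),),
            library.material("tungsten"), 30, "shield"))
    geom.add(Region((Cylinder((0.0, 0.5, 0.0), axis, 0.2, 14.5),),
                    library.material("SS"), 40, "source-tube"))
    geom.add(Region((Cylinder((0.0, 0.5, 0.0), axis, 0.15, 14.5),),
                    library.material("air"), 50, "source-channel"))
    source = _make_source(_MHDR, "Ir-192", (0.0, src_y, 0.0), axis,
                          SourceStrength("activity", activity_bq), "mHDR")
    add_source_regions(geom, source, library, priority=60)
    return geom, [source], {}
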