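"""Plan configuration: YAML parsing and validation into a DoseModel.

A plan file has an ``applicator`` block naming one of the built applicators
(or a bare single source) plus its geometric parameters, optional
``sources`` overrides, a ``points`` block of extra named reference points,
and a ``computation`` block (emitter spacing, output unit).  Optional
``grid``, ``isodose`` and ``profile`` blocks drive the grid/contour/angular
outputs.  The engine is deterministic, so no seeds appear anywhere.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import yaml

from . import applicators
from .dose_engine import DoseModel, ReferencePointSet
from .physics_data import PhysicsLibrary, build_standard_library
from .source_model import (DEFAULT_DELTA_L, EncapsulatedSource, SourceStrength,
                           air_kerma_rate_constant, strength_to_activity)

__all__ = ["PlanConfig", "PlanConfigError", "load_plan", "parse_plan"]


class PlanConfigError(ValueError):
    """Invalid plan configuration; message names the offending field."""


_APPLICATORS = ("brit_ldr", "fletcher_green", "fletcher_williamson",
                "vaginal_cylinder", "single_source")

_UNITS = ("cGy/h", "Gy/h")


@dataclass
class PlanConfig:
    """A validated plan: model + reference points + output settings."""
    raw: dict
    model: DoseModel
    points: ReferencePointSet
    unit: str = "cGy/h"
    delta_l: float = DEFAULT_DELTA_L
    grid: dict | None = None
    isodose: dict | None = None
    profile: dict | None = None


def _require(block: dict, key: str, context: str):
    if key not in block:
        raise PlanConfigError(f"missing field {context}.{key}")
    return block[key]


def _apply_strength_overrides(sources, overrides, library):
    if not overrides:
        return sources
    by_name = {s.name: s for s in sources}
    for name, spec in overrides.items():
        if name not in by_name:
            raise PlanConfigError(f"sources.{name}: no such source in applicator")
        src = by_name[name]
        sk = spec.get("air_kerma_strength")
        act = spec.get("activity_bq")
        if sk is not None and act is not None:
            # S_k is the clinical standard; cross-check the stated activity
            implied = SourceStrength("air_kerma_strength", sk)
            probe = dataclasses.replace(src, strength=implied)
            act_from_sk = strength_to_activity(probe, library)
            if abs(act - act_from_sk) > 0.05 * act_from_sk:
                warnings.warn(
                    f"sources.{name}: stated activity disagrees with air-kerma "
                    f"strength by more than 5%; using the air-kerma strength")
            strength = implied
        elif sk is not None:
            strength = SourceStrength("air_kerma_strength", sk)
        elif act is not None:
            strength = SourceStrength("activity", act)
        elif "linear_air_kerma_rate" in spec:
            strength = SourceStrength("linear_air_kerma_rate",
                                      spec["linear_air_kerma_rate"])
        else:
            raise PlanConfigError(f"sources.{name}: no strength given")
        by_name[name] = dataclasses.replace(src, strength=strength)
    return [by_name[s.name] for s in sources]


def _build_single_source(block: dict, library: PhysicsLibrary):
    from .geometry import Geometry
    nuclide = _require(block, "nuclide", "applicator")
    pos = tuple(_require(block, "position_cm", "applicator"))
    axis = tuple(block.get("axis", (0.0, 1.0, 0.0)))
    skind, sval = None, None
    for kind, key in (("air_kerma_strength", "air_kerma_strength"),
                      ("activity", "activity_bq"),
                      ("linear_air_kerma_rate", "linear_air_kerma_rate")):
        if key in block:
            skind, sval = kind, float(block[key])
    if skind is None:
        raise PlanConfigError("applicator: single_source needs a strength "
                              "(air_kerma_strength / activity_bq / "
                              "linear_air_kerma_rate)")
    src = EncapsulatedSource(
        nuclide=nuclide,
        active_length=float(block.get("active_length_cm", 0.0)),
        active_diameter=float(block.get("active_diameter_cm", 0.05)),
        capsule_outer_diameter=float(block.get("capsule_od_cm", 0.1)),
        capsule_length=float(block.get("capsule_length_cm", 0.2)),
        capsule_material=block.get("capsule_material", "SS"),
        core_material=block.get("core_material", "pollucite"),
        center=pos, axis=axis,
        strength=SourceStrength(skind, sval), name="S1")
    geom = Geometry(ambient=library.material(block.get("ambient", "water")))
    if block.get("model_capsule", False):
        applicators.add_source_regions(geom, src, library, priority=20)
    return geom, [src], {}


def parse_plan(doc: dict, library: PhysicsLibrary | None = None) -> PlanConfig:
    """Validate a parsed YAML document into a PlanConfig."""
    if library is None:
        library = build_standard_library()
    if not isinstance(doc, dict):
        raise PlanConfigError("plan file must contain a mapping")
    app = _require(doc, "applicator", "plan")
    atype = _require(app, "type", "applicator")
    if atype not in _APPLICATORS:
        raise PlanConfigError(
            f"applicator.type: unknown applicator {atype!r} "
            f"(expected one of {', '.join(_APPLICATORS)})")

    if atype == "brit_ldr":
        geom, sources, base_pts = applicators.build_brit_ldr(
            library, tube=app.get("tube", "long"),
            angulation_deg=float(app.get("angulation_deg", 0.0)),
            separation_cm=float(app.get("separation_cm", 3.0)),
            depth_cm=float(app.get("depth_cm", 1.5)),
            with_walls=bool(app.get("with_walls", True)))
    elif atype == "fletcher_green":
        geom, sources, base_pts = applicators.build_fletcher_green(
            library, angulation_deg=float(app.get("angulation_deg", 15.0)),
            separation_cm=float(app.get("separation_cm", 3.0)),
            depth_cm=float(app.get("depth_cm", 1.5)),
            with_walls=bool(app.get("with_walls", False)))
    elif atype == "fletcher_williamson":
        geom, sources, base_pts = applicators.build_fletcher_williamson(
            library, angulation_deg=float(app.get("angulation_deg", 15.0)),
            separation_cm=float(app.get("separation_cm", 3.0)),
            depth_cm=float(app.get("depth_cm", 1.5)),
            air_kerma_strength=float(app.get("air_kerma_strength", 40800.0)),
            dwell_times_s=app.get("dwell_times_s"))
    elif atype == "vaginal_cylinder":
        geom, sources, base_pts = applicators.build_vaginal_cylinder(
            library, shield_angle_deg=int(app.get("shield_angle_deg", 180)),
            activity_bq=float(app.get("activity_bq", 3.7e10)))
    else:
        geom, sources, base_pts = _build_single_source(app, library)

    sources = _apply_strength_overrides(sources, doc.get("sources"), library)

    comp = doc.get("computation", {})
    unit = comp.get("unit", "cGy/h")
    if unit not in _UNITS:
        raise PlanConfigError(f"computation.unit: expected one of {_UNITS}")
    delta_l = float(comp.get("delta_l_cm", DEFAULT_DELTA_L))
    if delta_l <= 0:
        raise PlanConfigError("computation.delta_l_cm must be > 0")

    extra = {k: tuple(float(x) for x in v)
             for k, v in (doc.get("points") or {}).items()}
    points = ReferencePointSet.manchester(extra=extra, base=base_pts)

    model = DoseModel(geom, sources, library, delta_l=delta_l)
    return PlanConfig(raw=doc, model=model, points=points, unit=unit,
                      delta_l=delta_l, grid=doc.get("grid"),
                      isodose=doc.get("isodose"), profile=doc.get("profile"))


def load_plan(path, library: PhysicsLibrary | None = None) -> PlanConfig:
    """Read and validate a YAML plan file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise PlanConfigError(f"{path}: not valid YAML ({exc})") from None
    try:
        return parse_plan(doc, library=library)
    except PlanConfigError as exc:
        raise PlanConfigError(f"{path}: {exc}") from None
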