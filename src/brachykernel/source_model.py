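"""Encapsulated line sources: strength conversion and point discretization.

Source strengths may be given as air-kerma strength S_k (uGy h^-1 m^2),
as a linear reference air-kerma rate (uGy h^-1 m^2 per cm of source), or
directly as contained activity (Bq).  Kerma-based strengths are converted
to activity through the unfiltered spectrum-weighted air-kerma rate
constant; capsule filtration is subsequently accounted for by the ray
trace through the capsule geometry.

A line source of active length L is replaced by ceil(L / delta_l) equally
weighted point emitters at segment centers along the source axis; the
paper-scale default for reference-point work is delta_l = 0.005 cm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .physics_data import AbsorberTable, NuclideSpectrum, PhysicsLibrary

__all__ = ["SourceStrength", "EncapsulatedSource", "PointEmitter",
           "air_kerma_rate_constant", "strength_to_activity", "discretize",
           "DEFAULT_DELTA_L"]

#: emitter spacing (cm) used for reference-point evaluation.
DEFAULT_DELTA_L = 0.005

_J_PER_MEV = 1.602e-13
_G_PER_KG = 1.0e3
_S_PER_H = 3600.0
_CM2_PER_M2 = 1.0e4
_UGY_PER_GY = 1.0e6


@dataclass(frozen=True)
class SourceStrength:
    """Source strength with an explicit unit tag.

    kind is one of 'air_kerma_strength' (uGy h^-1 m^2),
    'linear_air_kerma_rate' (uGy h^-1 m^2 cm^-1, referred to the physical
    source length) or 'activity' (Bq).
    """
    kind: str
    value: float

    _KINDS = ("air_kerma_strength", "linear_air_kerma_rate", "activity")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown strength kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("source strength must be >= 0")


@dataclass(frozen=True)
class EncapsulatedSource:
    """A radioactive line source inside a capsule.

    ``center`` is the capsule center (cm); ``axis`` the unit source axis.
    ``capsule_length`` is the physical (outer) length, which also sets the
    reference length for linear air-kerma rates.
    """
    nuclide: str
    active_length: float
    active_diameter: float
    capsule_outer_diameter: float
    capsule_length: float
    capsule_material: str
    core_material: str
    center: tuple
    axis: tuple
    strength: SourceStrength
    name: str = ""
    dwell_time_s: float = 1.0  # relative weight for HDR dwells

    def __post_init__(self) -> None:
        if self.active_length < 0:
            raise ValueError("active_length must be >= 0")
        if self.active_diameter >= self.capsule_outer_diameter:
            raise ValueError("active diameter must be smaller than capsule OD")
        n = math.sqrt(sum(c * c for c in self.axis))
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "axis", tuple(c / n for c in self.axis))


@dataclass(frozen=True)
class PointEmitter:
    """A weighted point emitter carrying per-line emission rates (photons/s)."""
    position: tuple
    lines: tuple  # ((E_MeV, photons_per_s), ...)


def air_kerma_rate_constant(spectrum: NuclideSpectrum,
                            air: AbsorberTable) -> float:
    """Unfiltered air-kerma rate constant Gamma_delta, uGy h^-1 m^2 / Bq.

    Point-source air collision kerma at 1 m per unit activity, summed over
    the line spectrum: Gamma = sum_i p_i E_i (mu_en/rho)_air(E_i) * const.
    """
    per_decay = sum(p * e * air.at(e) for e, p in spectrum.lines)  # MeV cm^2/g
    gy_per_h = per_decay * _J_PER_MEV * _G_PER_KG * _S_PER_H / (4.0 * math.pi * _CM2_PER_M2)
    return gy_per_h * _UGY_PER_GY  # at 1 m -> uGy h^-1 m^2 per Bq


def strength_to_activity(source: EncapsulatedSource, library: PhysicsLibrary) -> float:
    """Contained activity in Bq implied by the source's stated strength."""
    s = source.strength
    if s.kind == "activity":
        return s.value
    spectrum = library.spectrum(source.nuclide)
    gamma = air_kerma_rate_constant(spectrum, library.absorbers["air"])
    sk = s.value
    if s.kind == "linear_air_kerma_rate":
        sk = s.value * source.capsule_length
    return sk / gamma


def discretize(source: EncapsulatedSource, library: PhysicsLibrary,
               delta_l: float = DEFAULT_DELTA_L,
               activity_bq: float | None = None) -> list:
    """Replace a line source by equally weighted point emitters.

    Returns ceil(active_length/delta_l) emitters at segment centers along
    the axis (one central emitter for a zero-length source).  The summed
    per-line emission rate equals activity * p_i exactly.
    """
    if delta_l <= 0:
        raise ValueError("delta_l must be > 0")
    if activity_bq is None:
        activity_bq = strength_to_activity(source, library)
    spectrum = library.spectrum(source.nuclide)
    n = max(1, math.ceil(source.active_length / delta_l - 1e-12))
    cx, cy, cz = source.center
    ax, ay, az = source.axis
    emitters = []
    lines_per = tuple((e, activity_bq * p / n) for e, p in spectrum.lines)
    for i in range(n):
        # segment centers, symmetric about the source center
        off = (i + 0.5) / n * source.active_length - source.active_length / 2.0
        emitters.append(PointEmitter(
            position=(cx + off * ax, cy + off * ay, cz + off * az),
            lines=lines_per,
        ))
    return emitters
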