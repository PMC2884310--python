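"""Energy-dependent physics constants: attenuation, absorption, buildup, spectra.

All tables are packaged as plain-text TSV files covering 0.05-1.5 MeV, the
working range of the Cs-137 / Ir-192 sources the engine models.  Linear
attenuation and mass energy-absorption coefficients interpolate log-log;
geometric-progression (GP) buildup coefficients interpolate linearly in
log(E).  Interpolators are exact at grid nodes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

__all__ = [
    "GPCoefficients", "Material", "AbsorberTable", "NuclideSpectrum",
    "PhysicsLibrary", "lookup_mu", "lookup_gp", "build_standard_library",
    "EnergyRangeError", "PhysicsConfigError",
]


class EnergyRangeError(ValueError):
    """Requested energy lies outside a material's tabulated range."""


class PhysicsConfigError(ValueError):
    """Missing or inconsistent physics data (no GP table, bad file, ...)."""


@dataclass(frozen=True)
class GPCoefficients:
    """Five-parameter geometric-progression buildup fit at one energy.

    ``b`` is the buildup factor at 1 mean free path; ``c``, ``a``, ``x_K``
    and ``d`` shape the dose-weighted multiplication factor K(x).
    """
    b: float
    c: float
    a: float
    x_K: float
    d: float

    def __post_init__(self) -> None:
        if self.b < 1.0:
            raise PhysicsConfigError(f"GP coefficient b must be >= 1, got {self.b}")


def _loglog_interp(e: float, grid: Sequence[float], vals: Sequence[float]) -> float:
    if e < grid[0] or e > grid[-1]:
        raise EnergyRangeError(f"energy {e} MeV outside table range [{grid[0]}, {grid[-1]}]")
    # bisect on the (short) grid
    lo, hi = 0, len(grid) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if grid[mid] <= e:
            lo = mid
        else:
            hi = mid
    if e == grid[lo]:
        return vals[lo]
    if e == grid[hi]:
        return vals[hi]
    t = (math.log(e) - math.log(grid[lo])) / (math.log(grid[hi]) - math.log(grid[lo]))
    return math.exp((1 - t) * math.log(vals[lo]) + t * math.log(vals[hi]))


def _loglin_interp(e: float, grid: Sequence[float], vals: Sequence[float]) -> float:
    if e < grid[0] or e > grid[-1]:
        raise EnergyRangeError(f"energy {e} MeV outside table range [{grid[0]}, {grid[-1]}]")
    lo, hi = 0, len(grid) - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if grid[mid] <= e:
            lo = mid
        else:
            hi = mid
    if e == grid[lo]:
        return vals[lo]
    if e == grid[hi]:
        return vals[hi]
    t = (math.log(e) - math.log(grid[lo])) / (math.log(grid[hi]) - math.log(grid[lo]))
    return (1 - t) * vals[lo] + t * vals[hi]


@dataclass(frozen=True)
class Material:
    """A homogeneous medium with energy-dependent photon data.

    ``mu_table`` maps energy (MeV) to the linear attenuation coefficient
    (cm^-1) at the material's bulk density; ``compton_table`` holds the
    Compton fraction mu_C/mu used by the low-Z-over-high-Z buildup branch;
    ``gp_table`` holds GP buildup coefficients (may be None for media that
    never act as a buildup layer).
    """
    name: str
    density: float
    effective_Z: float
    energies: tuple
    mu: tuple
    compton: tuple
    gp: tuple | None  # tuple of GPCoefficients aligned with energies, or None
    is_vacuum: bool = False

    def mu_at(self, e_mev: float) -> float:
        if self.is_vacuum:
            return 0.0
        try:
            return _loglog_interp(e_mev, self.energies, self.mu)
        except EnergyRangeError as exc:
            raise EnergyRangeError(f"{self.name}: {exc}") from None

    def compton_fraction_at(self, e_mev: float) -> float:
        if self.is_vacuum:
            return 1.0
        return _loglin_interp(e_mev, self.energies, self.compton)

    def gp_at(self, e_mev: float) -> GPCoefficients:
        if self.is_vacuum:
            return GPCoefficients(1.0, 1.0, 0.0, 10.0, 0.0)
        if self.gp is None:
            raise PhysicsConfigError(f"material {self.name!r} has no GP buildup data")
        comps = []
        for idx in range(5):
            vals = tuple(getattr(g, ("b", "c", "a", "x_K", "d")[idx]) for g in self.gp)
            comps.append(_loglin_interp(e_mev, self.energies, vals))
        return GPCoefficients(*comps)

    def __hash__(self) -> int:  # used as cache key in the dose engine
        return hash(self.name)

    def __eq__(self, other) -> bool:
        return isinstance(other, Material) and other.name == self.name


def vacuum() -> Material:
    """A non-attenuating, non-scattering ambient medium (testing aid)."""
    return Material("vacuum", 0.0, 0.0, (0.05, 15.0), (0.0, 0.0), (1.0, 1.0),
                    None, is_vacuum=True)


@dataclass(frozen=True)
class AbsorberTable:
    """Mass energy-absorption coefficients (cm^2/g) for a dose medium."""
    medium: str
    energies: tuple
    mu_en_over_rho: tuple

    def at(self, e_mev: float) -> float:
        try:
            return _loglog_interp(e_mev, self.energies, self.mu_en_over_rho)
        except EnergyRangeError as exc:
            raise EnergyRangeError(f"{self.medium}: {exc}") from None


@dataclass(frozen=True)
class NuclideSpectrum:
    """Discrete photon line spectrum of a nuclide."""
    nuclide: str
    lines: tuple  # ((E_MeV, photons_per_decay), ...)

    @property
    def total_yield(self) -> float:
        return sum(p for _, p in self.lines)

    @property
    def mean_energy(self) -> float:
        return sum(e * p for e, p in self.lines) / self.total_yield


@dataclass
class PhysicsLibrary:
    materials: dict = field(default_factory=dict)
    absorbers: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        for pool in (self.materials, self.spectra, self.absorbers):
            if key in pool:
                return pool[key]
        raise KeyError(key)

    def material(self, name: str) -> Material:
        try:
            return self.materials[name]
        except KeyError:
            raise PhysicsConfigError(f"unknown material {name!r}") from None

    def spectrum(self, nuclide: str) -> NuclideSpectrum:
        try:
            return self.spectra[nuclide]
        except KeyError:
            raise PhysicsConfigError(f"unknown nuclide {nuclide!r}") from None


def lookup_mu(material: Material, e_mev: float) -> float:
    """Linear attenuation coefficient (cm^-1), log-log interpolated."""
    return material.mu_at(e_mev)


def lookup_gp(material: Material, e_mev: float) -> GPCoefficients:
    """GP buildup coefficients, component-wise linear in log(E)."""
    return material.gp_at(e_mev)


def _read_rows(fname: str):
    try:
        text = resources.files("brachykernel.data").joinpath(fname).read_text()
    except FileNotFoundError:
        raise PhysicsConfigError(f"missing physics data file {fname!r}") from None
    header = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line.lstrip("# ").split("=", 1)
                header[k.strip()] = float(v)
            continue
        rows.append([float(x) for x in line.split("\t")])
    if not rows:
        raise PhysicsConfigError(f"corrupt physics data file {fname!r}")
    return header, rows


def _load_material(key: str) -> Material:
    header, rows = _read_rows(f"material_{key}.tsv")
    e = tuple(r[0] for r in rows)
    if any(b >= a for a, b in zip(e[1:], e)):
        raise PhysicsConfigError(f"material {key!r}: energy grid not strictly increasing")
    gp = tuple(GPCoefficients(r[3], r[4], r[5], r[6], r[7]) for r in rows)
    return Material(
        name=key,
        density=header["density_g_cm3"],
        effective_Z=header["effective_Z"],
        energies=e,
        mu=tuple(r[1] for r in rows),
        compton=tuple(r[2] for r in rows),
        gp=gp,
    )


def build_standard_library() -> PhysicsLibrary:
    """Load the packaged materials, absorbers and nuclide spectra.

    Covers the media the modeled applicators are made of: water, air,
    stainless steel (8.02 g/cm^3), tungsten, 80%Pt/20%Fe capsule alloy
    (21.644 g/cm^3), PMMA shell plastic, the Cs glass pellet and iridium
    metal, plus the Cs-137 and Ir-192 line spectra.
    """
    lib = PhysicsLibrary()
    for key in ("water", "air", "SS", "tungsten", "Pt-Fe", "PMMA",
                "pollucite", "iridium"):
        lib.materials[key] = _load_material(key)
    lib.materials["vacuum"] = vacuum()
    for key in ("water", "air"):
        _, rows = _read_rows(f"absorber_{key}.tsv")
        lib.absorbers[key] = AbsorberTable(
            medium=key,
            energies=tuple(r[0] for r in rows),
            mu_en_over_rho=tuple(r[1] for r in rows),
        )
    for key in ("Cs-137", "Ir-192"):
        _, rows = _read_rows(f"spectrum_{key}.tsv")
        lib.spectra[key] = NuclideSpectrum(key, tuple((r[0], r[1]) for r in rows))
    return lib
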