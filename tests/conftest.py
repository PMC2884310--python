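import pytest

import brachykernel as bk


@pytest.fixture(scope="session")
def lib():
    return bk.build_standard_library()


@pytest.fixture(scope="session")
def water(lib):
    return lib.material("water")


@pytest.fixture(scope="session")
def steel(lib):
    return lib.material("SS")


@pytest.fixture(scope="session")
def tungsten(lib):
    return lib.material("tungsten")


@pytest.fixture(scope="session")
def brit_models(lib):
    """BRIT long straight standard loading, with and without walls."""
    g1, s1, pts = bk.build_brit_ldr(lib, with_walls=True)
    g0, s0, _ = bk.build_brit_ldr(lib, with_walls=False)
    m1 = bk.DoseModel(g1, s1, lib, delta_l=0.005)
    m0 = bk.DoseModel(g0, s0, lib, delta_l=0.005)
    return m1, m0, pts


def bare_point_model(lib, activity_bq=1.0e9, nuclide="Cs-137",
                     ambient="water", position=(0.0, 0.0, 0.0)):
    """Single bare point emitter in a homogeneous ambient medium."""
    geom = bk.Geometry(ambient=lib.material(ambient))
    src = bk.EncapsulatedSource(
        nuclide=nuclide, active_length=0.0, active_diameter=0.05,
        capsule_outer_diameter=0.1, capsule_length=0.2,
        capsule_material="SS", core_material="pollucite",
        center=position, axis=(0.0, 1.0, 0.0),
        strength=bk.SourceStrength("activity", activity_bq), name="S1")
    return bk.DoseModel(geom, [src], lib)
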