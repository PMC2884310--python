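import math

import numpy as np
import pytest

import brachykernel as bk
from brachykernel.geometry import Box, DegenerateRayError


@pytest.fixture()
def empty_geom(lib):
    return bk.Geometry(ambient=lib.material("water"))


@pytest.fixture()
def shell_geom(lib):
    """Cylindrical steel shell, inner r 0.25, outer r 0.30, along y."""
    geom = bk.Geometry(ambient=lib.material("water"))
    geom.add(bk.Region((bk.Cylinder((0, -5.0, 0), (0, 1, 0), 0.30, 10.0),),
                       lib.material("SS"), 5, "tube"))
    geom.add(bk.Region((bk.Cylinder((0, -5.0, 0), (0, 1, 0), 0.25, 10.0),),
                       lib.material("water"), 6, "lumen"))
    return geom


class TestClassify:
    def test_empty_geometry_is_ambient(self, empty_geom, lib):
        assert bk.classify(empty_geom, (0, 0, 0)) == lib.material("water")
        assert bk.classify(empty_geom, (10, -3, 7)) == lib.material("water")

    def test_vaginal_cylinder_materials(self, lib):
        geom, _, _ = bk.build_vaginal_cylinder(lib, shield_angle_deg=180)
        assert bk.classify(geom, (0.175, 8.0, 0.0)).name == "SS"   # steel tube wall
        assert bk.classify(geom, (0.0, 8.0, -0.6)).name == "tungsten"
        assert bk.classify(geom, (0.0, 8.0, 0.6)).name == "air"
        assert bk.classify(geom, (1.3, 8.0, 0.0)).name == "PMMA"
        assert bk.classify(geom, (10.0, 8.0, 0.0)).name == "water"

    def test_priority_wins(self, shell_geom):
        assert bk.classify(shell_geom, (0.28, 0, 0)).name == "SS"
        assert bk.classify(shell_geom, (0.1, 0, 0)).name == "water"


class TestTraceRay:
    def test_homogeneous(self, empty_geom):
        segs = bk.trace_ray(empty_geom, (0, 0, 0), (3, 4, 0))
        assert len(segs) == 1
        assert segs[0].material.name == "water"
        assert segs[0].length_cm == pytest.approx(5.0, abs=1e-12)

    def test_degenerate_ray(self, empty_geom):
        with pytest.raises(DegenerateRayError):
            bk.trace_ray(empty_geom, (1, 1, 1), (1, 1, 1))

    def test_shell_chord(self, shell_geom):
        """Perpendicular ray through the tube crosses 2 x 0.05 cm of steel."""
        segs = bk.trace_ray(shell_geom, (-2.0, 0.0, 0.0), (2.0, 0.0, 0.0))
        steel = sum(s.length_cm for s in segs if s.material.name == "SS")
        water = sum(s.length_cm for s in segs if s.material.name == "water")
        assert steel == pytest.approx(0.1, abs=1e-9)
        assert water == pytest.approx(3.9, abs=1e-9)

    def test_oblique_slab_path(self, lib):
        """45 deg incidence through a plane slab: path = thickness/cos(45),
        cross-checked by a dense point-sampling integration."""
        geom = bk.Geometry(ambient=lib.material("water"))
        slab = Box(corner=(-5.0, 0.0, -5.0),
                   edges=((10.0, 0.0, 0.0), (0.0, 0.2, 0.0), (0.0, 0.0, 10.0)))
        geom.add(bk.Region((slab,), lib.material("SS"), 5, "slab"))
        a = (-0.5, -0.4, 0.0)
        b = (0.5, 0.6, 0.0)
        segs = bk.trace_ray(geom, a, b)
        steel = sum(s.length_cm for s in segs if s.material.name == "SS")
        assert steel == pytest.approx(0.2 / math.cos(math.radians(45)),
                                      abs=1e-9)
        # sampling oracle: occupancy of 1e6 midpoints along the ray
        n = 1_000_000
        ts = (np.arange(n) + 0.5) / n
        length = math.dist(a, b)
        count = 0
        for t in ts[::1]:
            y = a[1] + t * (b[1] - a[1])
            if 0.0 <= y <= 0.2:  # slab occupancy is a pure y-interval here
                count += 1
        assert steel == pytest.approx(count / n * length, abs=5e-5)

    def test_length_conservation_random_rays(self, lib):
        geom, _, _ = bk.build_brit_ldr(lib, with_walls=True)
        rng = np.random.RandomState(42)
        for _ in range(300):
            a = tuple(rng.uniform(-6, 8, 3))
            b = tuple(rng.uniform(-6, 8, 3))
            if math.dist(a, b) < 1e-6:
                continue
            segs = bk.trace_ray(geom, a, b)
            assert sum(s.length_cm for s in segs) == pytest.approx(
                math.dist(a, b), abs=1e-9)

    def test_reversal_symmetry(self, lib):
        geom, _, _ = bk.build_vaginal_cylinder(lib, shield_angle_deg=90)
        a, b = (-4.0, 2.0, 3.0), (5.0, 6.5, -2.0)
        fwd = bk.trace_ray(geom, a, b)
        rev = bk.trace_ray(geom, b, a)
        assert [(s.material.name, pytest.approx(s.length_cm, abs=1e-9))
                for s in fwd] == \
               [(s.material.name, s.length_cm) for s in reversed(rev)]

    def test_midpoints_classify_to_segment_material(self, lib):
        geom, _, _ = bk.build_brit_ldr(lib, with_walls=True)
        rng = np.random.RandomState(7)
        for _ in range(50):
            a = tuple(rng.uniform(-4, 7, 3))
            b = tuple(rng.uniform(-4, 7, 3))
            segs = bk.trace_ray(geom, a, b)
            length = math.dist(a, b)
            d = tuple((bb - aa) / length for aa, bb in zip(a, b))
            t = 0.0
            for s in segs:
                tm = t + s.length_cm / 2
                mid = tuple(aa + tm * dd for aa, dd in zip(a, d))
                assert bk.classify(geom, mid) == s.material
                t += s.length_cm


class TestPrimitives:
    def test_sphere_crossings(self, lib):
        geom = bk.Geometry(ambient=lib.material("water"))
        geom.add(bk.Region((bk.Sphere((0, 0, 0), 1.0),),
                           lib.material("SS"), 5, "ball"))
        segs = bk.trace_ray(geom, (-3, 0, 0), (3, 0, 0))
        steel = sum(s.length_cm for s in segs if s.material.name == "SS")
        assert steel == pytest.approx(2.0, abs=1e-9)

    def test_sector_shell_volume_monte_carlo(self, lib, tungsten):
        """90 deg sector shell volume = pi (r_o^2 - r_i^2) h / 4."""
        shell = bk.SectorShell(base=(0, 0, 0), axis=(0, 1, 0),
                               inner_radius=0.2, outer_radius=1.0,
                               length=10.0, start_deg=135.0, stop_deg=225.0,
                               ref_dir=(0, 0, 1))
        rng = np.random.RandomState(3)
        n = 40000
        pts = np.column_stack([rng.uniform(-1, 1, n), rng.uniform(0, 10, n),
                               rng.uniform(-1, 1, n)])
        inside = sum(shell.contains(tuple(p)) for p in pts)
        box_vol = 2.0 * 10.0 * 2.0
        mc_vol = inside / n * box_vol
        exact = math.pi * (1.0 ** 2 - 0.2 ** 2) * 10.0 / 4.0
        assert mc_vol == pytest.approx(exact, rel=0.05)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            bk.Cylinder((0, 0, 0), (0, 1, 0), -1.0, 5.0)
        with pytest.raises(ValueError):
            bk.SectorShell((0, 0, 0), (0, 1, 0), 1.0, 0.5, 5.0, 0.0, 90.0,
                           (0, 0, 1))
        with pytest.raises(ValueError):
            bk.SectorShell((0, 0, 0), (0, 1, 0), 0.2, 1.0, 5.0, 200.0, 100.0,
                           (0, 0, 1))
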