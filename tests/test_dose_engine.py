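import math

import numpy as np
import pytest

import brachykernel as bk
import brachykernel.dose_engine as de
from conftest import bare_point_model

import oracles


class TestPointKernel:
    def test_inverse_square_in_vacuum(self, lib):
        m = bare_point_model(lib, ambient="vacuum")
        d1 = m.point_dose((1.0, 0.0, 0.0))
        d2 = m.point_dose((2.0, 0.0, 0.0))
        assert d2 / d1 == pytest.approx(0.25, rel=1e-12)

    def test_additivity_over_sources(self, lib):
        geom = bk.Geometry(ambient=lib.material("water"))
        def src(name):
            return bk.EncapsulatedSource(
                nuclide="Cs-137", active_length=0.0, active_diameter=0.05,
                capsule_outer_diameter=0.1, capsule_length=0.2,
                capsule_material="SS", core_material="pollucite",
                center=(0, 0, 0), axis=(0, 1, 0),
                strength=bk.SourceStrength("activity", 1e9), name=name)
        single = bk.DoseModel(geom, [src("a")], lib)
        double = bk.DoseModel(geom, [src("a"), src("b")], lib)
        p = (2.5, 1.0, 0.0)
        assert double.point_dose(p) == pytest.approx(2 * single.point_dose(p),
                                                     rel=1e-12)

    def test_single_emitter_chain_regression(self, lib):
        """1 GBq bare Cs-137 point emitter in water at 1 cm, against the
        closed-form hand evaluation of the full chain (frozen)."""
        m = bare_point_model(lib, activity_bq=1e9)
        assert m.point_dose((1.0, 0.0, 0.0)) == pytest.approx(
            83.6603565673588, rel=1e-12)

    def test_chain_matches_live_oracle_at_radii(self, lib):
        m = bare_point_model(lib, activity_bq=2.5e9)
        for r in (0.5, 2.0, 7.0):
            assert m.point_dose((0.0, r, 0.0)) == pytest.approx(
                oracles.bare_point_dose_water(2.5e9, r), rel=1e-9)

    def test_r2_weighted_dose_decreases_in_water(self, lib):
        """For Cs-137 in water attenuation beats buildup over 1-10 cm."""
        m = bare_point_model(lib)
        vals = [r * r * m.point_dose((r, 0.0, 0.0))
                for r in np.linspace(1.0, 10.0, 10)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_singularity_inside_core(self, lib):
        geom = bk.Geometry(ambient=lib.material("water"))
        src = bk.EncapsulatedSource(
            nuclide="Cs-137", active_length=1.0, active_diameter=0.2,
            capsule_outer_diameter=0.3, capsule_length=1.4,
            capsule_material="SS", core_material="pollucite",
            center=(0, 0, 0), axis=(0, 1, 0),
            strength=bk.SourceStrength("activity", 1e9), name="S1")
        from brachykernel.applicators import add_source_regions
        add_source_regions(geom, src, lib, priority=20)
        m = bk.DoseModel(geom, [src], lib, delta_l=0.1)
        with pytest.raises(bk.SingularityError):
            m.point_dose((0.0, 0.2, 0.0))

    def test_emitter_coincidence(self, lib):
        m = bare_point_model(lib)
        with pytest.raises(bk.SingularityError):
            m.point_dose((0.0, 0.0, 0.0))

    def test_walls_attenuate_everywhere(self, brit_models):
        m_walls, m_bare, pts = brit_models
        for p in pts.values():
            assert m_walls.point_dose(p) <= m_bare.point_dose(p)


class TestAttenuationRatio:
    def test_identical_models_zero(self, lib):
        g, s, _ = bk.build_brit_ldr(lib, with_walls=False)
        m = bk.DoseModel(g, s, lib, delta_l=0.05)
        assert de.applicator_attenuation_ratio(m, m, (2, 2, 0)) == 0.0

    def test_thicker_wall_increases_reduction(self, lib):
        """Doubling the steel shell thickness strictly increases the
        percent reduction at point A."""
        def shell_model(outer_r):
            geom = bk.Geometry(ambient=lib.material("water"))
            geom.add(bk.Region(
                (bk.Cylinder((0, -3.0, 0), (0, 1, 0), outer_r, 8.0),),
                lib.material("SS"), 5, "tube"))
            geom.add(bk.Region(
                (bk.Cylinder((0, -3.0, 0), (0, 1, 0), 0.25, 8.0),),
                lib.material("water"), 6, "lumen"))
            src = bk.EncapsulatedSource(
                nuclide="Cs-137", active_length=0.0, active_diameter=0.05,
                capsule_outer_diameter=0.1, capsule_length=0.2,
                capsule_material="SS", core_material="pollucite",
                center=(0, 1.0, 0), axis=(0, 1, 0),
                strength=bk.SourceStrength("activity", 1e9), name="S1")
            return bk.DoseModel(geom, [src], lib)
        bare = shell_model(0.2500001)  # vanishing wall
        thin = shell_model(0.30)
        thick = shell_model(0.35)
        p = (2.0, 2.0, 0.0)
        r_thin = de.applicator_attenuation_ratio(thin, bare, p)
        r_thick = de.applicator_attenuation_ratio(thick, bare, p)
        assert 0.0 < r_thin < r_thick

    def test_mismatched_emitters_rejected(self, lib):
        g0, s0, _ = bk.build_brit_ldr(lib, with_walls=False)
        m0 = bk.DoseModel(g0, s0, lib, delta_l=0.05)
        m1 = bk.DoseModel(g0, s0, lib, delta_l=0.1)
        with pytest.raises(ValueError, match="emitters"):
            de.applicator_attenuation_ratio(m1, m0, (2, 2, 0))


class TestEvaluatePlan:
    def test_empty_point_set(self, lib):
        g, s, _ = bk.build_brit_ldr(lib, with_walls=False)
        m = bk.DoseModel(g, s, lib, delta_l=0.1)
        table = de.evaluate_plan(m, bk.ReferencePointSet({}))
        assert len(table) == 0

    def test_mirror_symmetry(self, lib):
        """Symmetric left/right loading: A_left and A_right agree to 1e-9."""
        g, s, pts = bk.build_brit_ldr(lib, with_walls=True)
        m = bk.DoseModel(g, s, lib, delta_l=0.05)
        table = de.evaluate_plan(m, bk.ReferencePointSet(pts))
        t = table.set_index("point")["dose_rate"]
        assert t["A_left"] == pytest.approx(t["A_right"], rel=1e-9)
        assert t["B_left"] == pytest.approx(t["B_right"], rel=1e-9)

    def test_per_source_breakdown_sums_to_total(self, lib):
        g, s, _ = bk.build_brit_ldr(lib, with_walls=False)
        m = bk.DoseModel(g, s, lib, delta_l=0.1)
        table = de.evaluate_plan(m, bk.ReferencePointSet(
            {"A": (2.0, 2.0, 0.0)}), per_source=True)
        row = table.iloc[0]
        assert row["dose_rate"] == pytest.approx(
            sum(row[f"S{i}"] for i in range(1, 6)), rel=1e-12)

    def test_unit_scaling(self, lib):
        m = bare_point_model(lib)
        pts = bk.ReferencePointSet({"p": (2.0, 0.0, 0.0)})
        cgy = de.evaluate_plan(m, pts, unit="cGy/h").iloc[0]["dose_rate"]
        gy = de.evaluate_plan(m, pts, unit="Gy/h").iloc[0]["dose_rate"]
        assert gy == pytest.approx(cgy / 100.0, rel=1e-12)

    def test_duplicate_point_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            bk.ReferencePointSet.manchester(extra={"A_right": (1, 1, 1)})


class TestDoseGrid:
    def test_single_node_matches_point(self, lib):
        m = bare_point_model(lib)
        p = (2.0, 2.0, 0.0)
        grid = de.dose_rate_grid(m, origin=p, spacing=(0.1, 0.1, 0.1),
                                 shape=(1, 1, 1))
        assert grid.values[0, 0, 0] == m.point_dose(p)

    def test_isotropy_in_vacuum(self, lib):
        m = bare_point_model(lib, ambient="vacuum")
        r = 2.0
        vals = []
        for th in np.linspace(0, math.pi, 7)[1:-1]:
            for ph in np.linspace(0, 2 * math.pi, 5):
                p = (r * math.sin(th) * math.cos(ph),
                     r * math.sin(th) * math.sin(ph), r * math.cos(th))
                vals.append(m.point_dose(p))
        assert max(vals) - min(vals) <= 1e-9 * max(vals)

    def test_grid_point_consistency(self, lib):
        g, s, _ = bk.build_brit_ldr(lib, with_walls=False)
        m = bk.DoseModel(g, s, lib, delta_l=0.1)
        grid = de.dose_rate_grid(m, origin=(1.0, 1.0, 0.0),
                                 spacing=(0.5, 0.5, 0.5), shape=(3, 3, 2))
        rng = np.random.RandomState(11)
        for _ in range(10):
            idx = tuple(rng.randint(0, n) for n in grid.values.shape)
            assert grid.values[idx] == m.point_dose(grid.coords(idx))

    def test_masked_core_nodes(self, lib):
        geom = bk.Geometry(ambient=lib.material("water"))
        src = bk.EncapsulatedSource(
            nuclide="Cs-137", active_length=1.0, active_diameter=0.2,
            capsule_outer_diameter=0.3, capsule_length=1.4,
            capsule_material="SS", core_material="pollucite",
            center=(0, 0, 0), axis=(0, 1, 0),
            strength=bk.SourceStrength("activity", 1e9), name="S1")
        from brachykernel.applicators import add_source_regions
        add_source_regions(geom, src, lib, priority=20)
        m = bk.DoseModel(geom, [src], lib, delta_l=0.1)
        grid = de.dose_rate_grid(m, origin=(0.0, 0.0, 0.0),
                                 spacing=(0.5, 0.5, 0.5), shape=(3, 2, 1))
        assert math.isnan(grid.values[0, 0, 0])
        assert not math.isnan(grid.values[2, 0, 0])


class TestAngularProfile:
    def test_unshielded_profile_flat(self, lib):
        g, s, _ = bk.build_vaginal_cylinder(lib, shield_angle_deg=0)
        m = bk.DoseModel(g, s, lib, delta_l=0.05)
        prof = de.angular_profile(m, radii=[3.0],
                                  angles_deg=[0, 30, 77, 120, 180])
        vals = prof["dose_rate_cGy_h"].to_numpy()
        assert np.ptp(vals) <= 1e-6 * vals.max()

    def test_mirror_duplication_rule(self, lib):
        g, s, _ = bk.build_vaginal_cylinder(lib, shield_angle_deg=180)
        m = bk.DoseModel(g, s, lib, delta_l=0.05)
        prof = de.angular_profile(m, radii=[2.0], angles_deg=[0, 45, 90, 135, 180],
                                  mirror=True)
        by = prof.set_index("theta_deg")["dose_rate_cGy_h"]
        for th in (45.0, 90.0, 135.0):
            assert by[360.0 - th] == by[th]

    def test_shadowed_less_than_open(self, lib):
        g, s, _ = bk.build_vaginal_cylinder(lib, shield_angle_deg=90)
        m = bk.DoseModel(g, s, lib, delta_l=0.05)
        prof = de.angular_profile(m, radii=[1.5, 4.0, 8.0],
                                  angles_deg=[0, 180])
        piv = prof.pivot(index="r_cm", columns="theta_deg",
                        values="dose_rate_cGy_h")
        assert (piv[180] < piv[0]).all()

    def test_radius_inside_applicator_rejected(self, lib):
        g, s, _ = bk.build_vaginal_cylinder(lib, shield_angle_deg=0)
        m = bk.DoseModel(g, s, lib, delta_l=0.05)
        with pytest.raises(ValueError, match="radius"):
            de.angular_profile(m, radii=[1.0], angles_deg=[0])


class TestPrescription:
    def test_time_scales_inversely_with_strength(self, lib):
        """7.5 Gy at the mean of left/right point A: doubling every dwell
        strength halves the treatment time."""
        g, s, pts = bk.build_fletcher_williamson(lib)
        m1 = bk.DoseModel(g, s, lib, delta_l=0.05)
        t1 = de.prescription_time_h(m1, bk.ReferencePointSet(pts), 7.5)
        import dataclasses
        s2 = [dataclasses.replace(
            x, strength=bk.SourceStrength("air_kerma_strength",
                                          2 * x.strength.value)) for x in s]
        m2 = bk.DoseModel(g, s2, lib, delta_l=0.05)
        t2 = de.prescription_time_h(m2, bk.ReferencePointSet(pts), 7.5)
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-9)
        assert t1 > 0
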