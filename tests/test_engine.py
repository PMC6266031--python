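"""Dose engine: superposition, oracles, conservation, LET averaging."""

import numpy as np
import pytest

from ionpb import engine
from ionpb.beam import RangeShifter, Spot, fwhm_to_sigma
from ionpb.errors import ValidationError
from ionpb.geometry import VoxelGrid, hu_to_rsp, make_phantom
from ionpb.plans import Beam, Plan


def one_spot_plan(energy=150.0, n=1e8, ion="proton", x=0.0, y=0.0,
                  iso=(50.0, 50.0, 0.0), rs=None):
    spot = Spot(energy, x, y, n)
    beam = Beam((0.0, 0.0, 1.0), iso, rs or RangeShifter(), [spot])
    return Plan(ion, [beam])


class TestSuperposition:
    def test_two_identical_spots_double_dose(self, proton_db, water_tank):
        grid, _ = water_tank
        cfg = engine.EngineConfig()
        p1 = one_spot_plan()
        p2 = Plan("proton", [Beam((0, 0, 1.0), (50.0, 50.0, 0.0),
                                  RangeShifter(),
                                  [Spot(150.0, 0.0, 0.0, 1e8),
                                   Spot(150.0, 0.0, 0.0, 1e8)])])
        s1 = engine.compute_plan(grid, proton_db, p1, cfg)
        s2 = engine.compute_plan(grid, proton_db, p2, cfg)
        assert np.allclose(s2.dose, 2.0 * s1.dose, rtol=1e-12)

    def test_on_axis_peak_at_database_bragg_depth(self, proton_db,
                                                  water_tank):
        grid, _ = water_tank
        scores = engine.compute_plan(grid, proton_db, one_spot_plan(),
                                     engine.EngineConfig())
        k = np.unravel_index(scores.dose.argmax(), scores.dose.shape)
        zmax = scores.grid.axis_centers(2)[k[2]]
        peak = proton_db.entry("proton", 150.0).peak_depth
        assert abs(zmax - peak) <= scores.grid.spacing[2]

    def test_lateral_profile_matches_kernel(self, proton_db, water_tank):
        grid, _ = water_tank
        scores = engine.compute_plan(grid, proton_db, one_spot_plan(),
                                     engine.EngineConfig())
        kz = 40  # depth 81 mm
        z = scores.grid.axis_centers(2)[kz]
        entry = proton_db.entry("proton", 150.0)
        smp = entry.sample(z)
        sig_air = fwhm_to_sigma(proton_db.fwhm_air_at("proton", 150.0))
        sigmas = tuple(np.sqrt(smp[f"sigma{i}"] ** 2 + sig_air ** 2)
                       for i in (1, 2, 3))
        weights = (smp["w1"], smp["w2"], smp["w3"])
        from ionpb.beam import triple_gaussian
        xs = scores.grid.axis_centers(0)
        y25 = scores.grid.axis_centers(1)[25]
        r = np.hypot(xs - 50.0, y25 - 50.0)
        expected = 1e8 * smp["idd"] * triple_gaussian(r, sigmas, weights)
        got = scores.dose[:, 25, kz]
        mask = r < 3.0 * sigmas[2]
        assert np.max(np.abs(got - expected)[mask]) < 0.005 * expected.max()

    def test_empty_plan_is_all_zero(self, proton_db, water_tank):
        grid, _ = water_tank
        plan = Plan("proton", [Beam((0, 0, 1.0), (50, 50, 0),
                                    RangeShifter(), [])])
        scores = engine.compute_plan(grid, proton_db, plan)
        assert not np.any(scores.dose)

    def test_plan_additivity(self, proton_db_multi, water_tank):
        grid, _ = water_tank
        cfg = engine.EngineConfig()
        spots_a = [Spot(130.0, -5.0, 0.0, 1e7), Spot(140.0, 5.0, 0.0, 2e7)]
        spots_b = [Spot(150.0, 0.0, 5.0, 3e7)]
        mk = lambda sp: Plan("proton", [Beam((0, 0, 1.0), (50, 50, 0),  # noqa
                                             RangeShifter(), sp)])
        full = engine.compute_plan(grid, proton_db_multi, mk(spots_a + spots_b),
                                   cfg)
        half = engine.compute_plan(grid, proton_db_multi, mk(spots_a), cfg)
        half2 = engine.compute_plan(grid, proton_db_multi, mk(spots_b), cfg)
        num = np.abs(full.dose - (half.dose + half2.dose))
        assert np.max(num) <= 1e-10 * full.dose.max()

    def test_missing_energy_listed(self, proton_db, water_tank):
        grid, _ = water_tank
        plan = one_spot_plan(energy=200.0)
        with pytest.raises(ValidationError, match="200"):
            engine.compute_plan(grid, proton_db, plan)

    def test_proton_path_skips_bio_accumulators(self, proton_db, water_tank):
        grid, _ = water_tank
        scores = engine.compute_plan(grid, proton_db, one_spot_plan())
        assert not np.any(scores.sum_d_alpha)
        assert not np.any(scores.sum_d_zstar)
        assert np.any(scores.sum_d_let)


class TestOracles:
    def test_brute_force_equivalence_small_water_grid(self, proton_db):
        """Engine vs direct kernel evaluation with no cutoff, all voxels."""
        grid = VoxelGrid(np.ones((30, 30, 40)), (2.0, 2.0, 2.0),
                         value_kind="RSP")
        plan = one_spot_plan(iso=(30.0, 30.0, 0.0), n=1e7)
        scores = engine.compute_plan(grid, proton_db, plan,
                                     engine.EngineConfig())
        entry = proton_db.entry("proton", 150.0)
        sig_air = fwhm_to_sigma(proton_db.fwhm_air_at("proton", 150.0))
        # independent scalar-loop oracle on the dose grid
        gx = scores.grid.axis_centers(0)
        gy = scores.grid.axis_centers(1)
        gz = scores.grid.axis_centers(2)
        oracle = np.zeros(scores.grid.shape)
        d = entry.depths
        for i, x in enumerate(gx):
            for j, y in enumerate(gy):
                r2 = (x - 30.0) ** 2 + (y - 30.0) ** 2
                for k, z in enumerate(gz):
                    idd = np.interp(z, d, entry.ddc.idd)
                    acc = 0.0
                    for c, wname in ((1, "w1"), (2, "w2"), (3, "w3")):
                        sig = np.interp(z, d, getattr(entry.lateral,
                                                      f"sigma{c}"))
                        w = np.interp(z, d, getattr(entry.lateral, wname))
                        s2 = sig ** 2 + sig_air ** 2
                        acc += w / (2 * np.pi * s2) * np.exp(-0.5 * r2 / s2)
                    oracle[i, j, k] = 1e7 * idd * acc
        err = np.abs(scores.dose - oracle) / oracle.max()
        assert err.max() < 0.005

    def test_energy_conservation_single_spot(self, proton_db):
        grid = VoxelGrid(np.ones((60, 60, 100)), (2.0, 2.0, 2.0),
                         value_kind="RSP")
        plan = one_spot_plan(iso=(60.0, 60.0, 0.0))
        scores = engine.compute_plan(grid, proton_db, plan)
        entry = proton_db.entry("proton", 150.0)
        expected = 1e8 * np.trapezoid(entry.ddc.idd, entry.depths)
        total = scores.dose.sum() * scores.grid.voxel_volume
        assert abs(total - expected) / expected < 0.01

    def test_air_slab_shifts_peak_deeper(self, proton_db):
        vals = np.zeros((20, 20, 100))            # HU water
        vals[:, :, 15:25] = -1000.0               # 20 mm air slab
        het = hu_to_rsp(VoxelGrid(vals, (2.0, 2.0, 2.0), value_kind="HU"))
        hom = VoxelGrid(np.ones((20, 20, 100)), (2.0, 2.0, 2.0),
                        value_kind="RSP")
        plan = one_spot_plan(iso=(20.0, 20.0, 0.0))
        cfg = engine.EngineConfig()
        s_het = engine.compute_plan(het, proton_db, plan, cfg)
        s_hom = engine.compute_plan(hom, proton_db, plan, cfg)
        z = s_hom.grid.axis_centers(2)
        z_het = z[s_het.dose[10, 10, :].argmax()]
        z_hom = z[s_hom.dose[10, 10, :].argmax()]
        missing_wet = 20.0 * (1.0 - 0.001 * 0)    # slab wet deficit ~ 20 mm
        air_rsp = np.interp(-1000.0, [-1024, -700], [0.001, 0.25])
        missing_wet = 20.0 * (1 - air_rsp)
        assert abs((z_het - z_hom) - missing_wet) <= s_hom.grid.spacing[2]


class TestSplittingInWater:
    def test_split_matches_unsplit(self, proton_db):
        """349-way split vs unsplit in homogeneous water (0.5% of peak)."""
        grid = VoxelGrid(np.ones((40, 40, 100)), (2.0, 2.0, 2.0),
                         value_kind="RSP")
        plan = one_spot_plan(iso=(40.0, 40.0, 0.0), n=1e7)
        s_plain = engine.compute_plan(grid, proton_db, plan,
                                      engine.EngineConfig(n_splits=1))
        s_split = engine.compute_plan(grid, proton_db, plan,
                                      engine.EngineConfig(n_splits=349))
        peak = s_plain.dose.max()
        # on-axis depth profile
        axis_err = np.abs(s_split.dose[20, 20, :] - s_plain.dose[20, 20, :])
        assert axis_err.max() < 0.005 * peak
        # lateral profile at the peak slice
        kz = int(s_plain.dose[20, 20, :].argmax())
        lat_err = np.abs(s_split.dose[:, 20, kz] - s_plain.dose[:, 20, kz])
        assert lat_err.max() < 0.005 * peak

    def test_split_conserves_integral(self, proton_db):
        grid = VoxelGrid(np.ones((40, 40, 100)), (2.0, 2.0, 2.0),
                         value_kind="RSP")
        plan = one_spot_plan(iso=(40.0, 40.0, 0.0), n=1e7)
        a = engine.compute_plan(grid, proton_db, plan,
                                engine.EngineConfig(n_splits=1))
        b = engine.compute_plan(grid, proton_db, plan,
                                engine.EngineConfig(n_splits=97))
        assert abs(b.dose.sum() - a.dose.sum()) / a.dose.sum() < 2e-3


class TestLETMap:
    def _scores_with(self, dose, dlet):
        g = VoxelGrid(np.ones((1, 1, len(dose))), (1, 1, 1),
                      value_kind="RSP")
        s = engine.ScoreMaps.zeros(g)
        s.dose[0, 0, :] = dose
        s.sum_d_let[0, 0, :] = dlet
        return s

    def test_constant_let(self):
        s = self._scores_with([2.0, 4.0], [6.0, 12.0])
        assert np.allclose(engine.let_d_map(s).values[0, 0], 3.0)

    def test_equal_dose_mixture(self):
        # equal doses at LET 1 and 3 accumulate to (1*1 + 1*3)/2 = 2
        s = self._scores_with([2.0], [1.0 * 1 + 1.0 * 3])
        assert np.isclose(engine.let_d_map(s).values[0, 0, 0], 2.0)

    def test_weighted_mixture(self):
        # 1 Gy @ 1 keV/um + 3 Gy @ 3 keV/um -> (1 + 9)/4 = 2.5
        s = self._scores_with([4.0], [1.0 * 1 + 3.0 * 3])
        assert np.isclose(engine.let_d_map(s).values[0, 0, 0], 2.5)

    def test_zero_dose_gives_zero_let(self):
        s = self._scores_with([0.0, 1.0], [0.0, 2.0])
        vals = engine.let_d_map(s).values[0, 0]
        assert vals[0] == 0.0 and vals[1] == 2.0
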