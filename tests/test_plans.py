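"""Plan model, JSON round trip, spot layout and SOBP optimisation."""

import numpy as np
import pytest

from ionpb import engine
from ionpb.beam import Spot
from ionpb.errors import ValidationError
from ionpb.geometry import make_phantom
from ionpb.plans import (Beam, Plan, layout_spots, optimize_sobp, plan_from_dict,
                         plan_to_dict, read_plan, write_plan)


def small_setup(db, side=30.0, depth=60.0):
    grid, rois = make_phantom("water_tank", size=(100.0, 100.0, 140.0),
                              spacing=(2.0, 2.0, 2.0), target_side=side,
                              target_depth=depth)
    return grid, rois["target"]


@pytest.fixture(scope="module")
def sobp_db():
    from ionpb import synthesize_proton_database
    from ionpb.pipeline import auto_energies
    energies = auto_energies("proton", 60.0, 90.0, layer_step=5.0)
    return synthesize_proton_database(energies, depth_step=1.0, seed=7)


class TestPlanIO:
    def _plan(self):
        return Plan("proton", [Beam((0, 0, 1.0), (50, 50, 0),
                                    spots=[Spot(150.0, -3.0, 4.0, 1e6)])],
                    prescription=2.0)

    def test_round_trip(self, tmp_path):
        p = self._plan()
        write_plan(p, tmp_path / "p.json")
        q = read_plan(tmp_path / "p.json")
        assert plan_to_dict(p) == plan_to_dict(q)

    def test_missing_energy_field_names_spot(self):
        d = plan_to_dict(self._plan())
        del d["beams"][0]["spots"][0]["energy"]
        with pytest.raises(ValidationError, match="spot 0"):
            plan_from_dict(d)

    def test_unknown_field_rejected(self):
        d = plan_to_dict(self._plan())
        d["gantry"] = 42
        with pytest.raises(ValidationError, match="gantry"):
            plan_from_dict(d)

    def test_negative_particles_rejected(self):
        d = plan_to_dict(self._plan())
        d["beams"][0]["spots"][0]["n_particles"] = -1.0
        with pytest.raises(ValidationError, match="negative"):
            plan_from_dict(d)

    def test_energy_outside_db_rejected_at_validation(self, proton_db):
        p = self._plan()
        p.beams[0].spots[0].energy = 90.0
        with pytest.raises(ValidationError, match="90"):
            p.validate_against_db(proton_db)


class TestLayout:
    def test_peaks_cover_target_extent(self, sobp_db):
        grid, target = small_setup(sobp_db)
        beam, spots = layout_spots(target, grid, sobp_db, "proton")
        peaks = sorted({sobp_db.entry("proton", s.energy).peak_depth
                        for s in spots})
        # target spans 60..90 mm WET; one extra layer each side allowed
        assert peaks[0] >= 60.0 - 10.0
        assert peaks[-1] <= 90.0 + 10.0
        assert min(peaks) <= 66.0 and max(peaks) >= 84.0

    def test_empty_target_rejected(self, sobp_db):
        grid, target = small_setup(sobp_db)
        target.mask[:] = False
        with pytest.raises(ValidationError, match="empty"):
            layout_spots(target, grid, sobp_db, "proton")

    def test_target_beyond_range_names_limit(self, sobp_db):
        grid, target = small_setup(sobp_db, depth=100.0, side=30.0)
        with pytest.raises(ValidationError, match="deepest"):
            layout_spots(target, grid, sobp_db, "proton")

    def test_doubling_spacing_quarters_spot_count(self, sobp_db):
        grid, target = small_setup(sobp_db)
        _, s3 = layout_spots(target, grid, sobp_db, "proton",
                             lateral_spacing=3.0)
        _, s6 = layout_spots(target, grid, sobp_db, "proton",
                             lateral_spacing=6.0)
        ratio = len(s3) / len(s6)
        assert 3.0 < ratio < 5.5

    def test_deterministic(self, sobp_db):
        grid, target = small_setup(sobp_db)
        _, a = layout_spots(target, grid, sobp_db, "proton")
        _, b = layout_spots(target, grid, sobp_db, "proton")
        assert [(s.energy, s.x, s.y) for s in a] == \
            [(s.energy, s.x, s.y) for s in b]


@pytest.fixture(scope="module")
def optimised(sobp_db):
    grid, target = small_setup(sobp_db)
    beam, _ = layout_spots(target, grid, sobp_db, "proton",
                           lateral_spacing=4.0)
    skeleton = Plan("proton", [beam], 2.0)
    cfg = engine.EngineConfig(dose_spacing=(2.0, 2.0, 2.0))
    res = optimize_sobp(skeleton, target, grid, sobp_db, 2.0,
                        model="rbe1.1", config=cfg)
    return grid, target, cfg, res


class TestOptimizer:
    def test_converged_d50_within_tolerance(self, optimised):
        _, _, _, res = optimised
        assert res.converged
        assert abs(res.d50 - 2.0) <= 0.01 * 2.0

    def test_full_map_d50_matches(self, sobp_db, optimised):
        grid, target, cfg, res = optimised
        from ionpb import analysis, biology
        scores = engine.compute_plan(grid, sobp_db, res.plan, cfg)
        drbe = biology.rbe_fixed_1p1(scores.dose)
        tmask = engine.roi_on_dose_grid(target, scores.grid)
        d50 = analysis.dx(drbe[tmask], 50.0)
        assert abs(d50 - 2.0) <= 0.01 * 2.0

    def test_physical_dose_is_prescription_over_rbe(self, sobp_db, optimised):
        grid, target, cfg, res = optimised
        from ionpb import analysis
        scores = engine.compute_plan(grid, sobp_db, res.plan, cfg)
        tmask = engine.roi_on_dose_grid(target, scores.grid)
        d50_phys = analysis.dx(scores.dose[tmask], 50.0)
        assert abs(d50_phys - 2.0 / 1.1) <= 0.01 * (2.0 / 1.1)

    def test_objective_non_increasing(self, optimised):
        _, _, _, res = optimised
        objs = [t["objective"] for t in res.trace]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_prescription_linearity(self, sobp_db, optimised):
        grid, target, cfg, res2 = optimised
        beam, _ = layout_spots(target, grid, sobp_db, "proton",
                               lateral_spacing=4.0)
        skeleton = Plan("proton", [beam], 4.0)
        res4 = optimize_sobp(skeleton, target, grid, sobp_db, 4.0,
                             model="rbe1.1", config=cfg)
        w2 = np.array([s.n_particles for s in res2.plan.beams[0].spots])
        w4 = np.array([s.n_particles for s in res4.plan.beams[0].spots])
        assert np.allclose(w4, 2.0 * w2, rtol=0.01)

    @pytest.mark.parametrize("model", ["lem", "mkm"])
    def test_carbon_models_converge(self, model):
        from ionpb import analysis, biology
        from ionpb.database import synthesize_carbon_database
        from ionpb.pipeline import auto_energies
        energies = auto_energies("carbon", 60.0, 90.0, layer_step=5.0)
        db = synthesize_carbon_database(energies, depth_step=1.0, seed=5)
        grid, target = small_setup(db)
        beam, _ = layout_spots(target, grid, db, "carbon",
                               lateral_spacing=5.0)
        skeleton = Plan("carbon", [beam], 2.0)
        cfg = engine.EngineConfig()
        res = optimize_sobp(skeleton, target, grid, db, 2.0, model=model,
                            config=cfg)
        scores = engine.compute_plan(grid, db, res.plan, cfg)
        drbe = biology.carbon_drbe(scores, model, biology.PhotonLQ(),
                                   biology.MKMParams())
        tmask = engine.roi_on_dose_grid(target, scores.grid)
        assert abs(analysis.dx(drbe[tmask], 50.0) - 2.0) <= 0.02

    def test_determinism(self, sobp_db, optimised):
        grid, target, cfg, res = optimised
        beam, _ = layout_spots(target, grid, sobp_db, "proton",
                               lateral_spacing=4.0)
        skeleton = Plan("proton", [beam], 2.0)
        res_b = optimize_sobp(skeleton, target, grid, sobp_db, 2.0,
                              model="rbe1.1", config=cfg)
        wa = [s.n_particles for s in res.plan.beams[0].spots]
        wb = [s.n_particles for s in res_b.plan.beams[0].spots]
        assert wa == wb
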