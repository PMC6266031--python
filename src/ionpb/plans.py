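"""Spot-scanning plan model, layout and SOBP weight optimisation.

The optimiser is deliberately a simple damped dose-ratio fixed point: its
job is to manufacture spread-out-Bragg-peak test plans with homogeneous
RBE-weighted target coverage, standing in for the treatment-planning-system
plans a clinic would supply.  It is not a constrained inverse planner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .beam import RangeShifter, Spot, fwhm_to_sigma
from .database import BeamDatabase
from .errors import ConvergenceError, ValidationError
from .geometry import ROIMask, VoxelGrid, wepl_profile

PLAN_SCHEMA_VERSION = 1


@dataclass
class Beam:
    direction: tuple                      # unit 3-vector
    isocenter: tuple                      # mm
    range_shifter: RangeShifter = field(default_factory=RangeShifter)
    spots: list = field(default_factory=list)

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValidationError("beam direction must be nonzero")
        self.direction = tuple(d / n)
        self.isocenter = tuple(float(v) for v in self.isocenter)


@dataclass
class Plan:
    ion: str
    beams: list
    prescription: float = 2.0             # Gy (RBE) per fraction
    fractions: int = 1

    def __post_init__(self):
        if not self.beams:
            raise ValidationError("plan must contain at least one beam")
        if self.prescription <= 0:
            raise ValidationError("prescription must be positive")

    def spot_count(self) -> int:
        return sum(len(b.spots) for b in self.beams)

    def validate_against_db(self, db: BeamDatabase) -> None:
        grid = db.energies(self.ion)
        bad = []
        for bi, beam in enumerate(self.beams):
            for si, spot in enumerate(beam.spots):
                if not (grid[0] <= spot.energy <= grid[-1]):
                    bad.append((bi, si, spot.energy))
        if bad:
            raise ValidationError(
                "spot energies outside database grid "
                f"[{grid[0]}, {grid[-1]}]: " +
                ", ".join(f"beam {b} spot {s} ({e} MeV/u)" for b, s, e in bad))


# ---------------------------------------------------------------------------
# JSON I/O (versioned schema, unknown fields rejected)
# ---------------------------------------------------------------------------

def _check_keys(obj: dict, allowed, required, where: str):
    unknown = set(obj) - set(allowed)
    if unknown:
        raise ValidationError(f"{where}: unknown fields {sorted(unknown)}")
    missing = set(required) - set(obj)
    if missing:
        raise ValidationError(f"{where}: missing fields {sorted(missing)}")


def plan_to_dict(plan: Plan) -> dict:
    return {
        "schema_version": PLAN_SCHEMA_VERSION,
        "ion": plan.ion,
        "prescription": plan.prescription,
        "fractions": plan.fractions,
        "beams": [
            {
                "direction": list(b.direction),
                "isocenter": list(b.isocenter),
                "range_shifter": {"wet": b.range_shifter.wet,
                                  "air_gap": b.range_shifter.air_gap,
                                  "present": b.range_shifter.present},
                "spots": [
                    {"energy": s.energy, "x": s.x, "y": s.y,
                     "n_particles": s.n_particles, "fwhm_air": s.fwhm_air}
                    for s in b.spots],
            } for b in plan.beams],
    }


def plan_from_dict(obj: dict) -> Plan:
    _check_keys(obj, ["schema_version", "ion", "prescription", "fractions",
                      "beams"],
                ["schema_version", "ion", "beams"], "plan")
    if obj["schema_version"] != PLAN_SCHEMA_VERSION:
        raise ValidationError("unsupported plan schema version")
    beams = []
    for bi, b in enumerate(obj["beams"]):
        _check_keys(b, ["direction", "isocenter", "range_shifter", "spots"],
                    ["direction", "isocenter", "spots"], f"beam {bi}")
        rs = b.get("range_shifter", {})
        _check_keys(rs, ["wet", "air_gap", "present"], [], f"beam {bi} RS")
        spots = []
        for si, s in enumerate(b["spots"]):
            _check_keys(s, ["energy", "x", "y", "n_particles", "fwhm_air"],
                        ["energy", "x", "y", "n_particles"],
                        f"beam {bi} spot {si}")
            if s["n_particles"] < 0:
                raise ValidationError(
                    f"beam {bi} spot {si}: negative particle number")
            spots.append(Spot(s["energy"], s["x"], s["y"], s["n_particles"],
                              s.get("fwhm_air")))
        beams.append(Beam(b["direction"], b["isocenter"],
                          RangeShifter(rs.get("wet", 0.0),
                                       rs.get("air_gap", 0.0),
                                       rs.get("present", False)),
                          spots))
    return Plan(obj["ion"], beams, obj.get("prescription", 2.0),
                obj.get("fractions", 1))


def write_plan(plan: Plan, path) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=1))


def read_plan(path) -> Plan:
    return plan_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# spot layout
# ---------------------------------------------------------------------------

def beam_basis(direction):
    """Right-handed orthonormal (u, v, d) with d the beam direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v, d


def layout_spots(target: ROIMask, rsp_grid: VoxelGrid, db: BeamDatabase,
                 ion: str, lateral_spacing: float = 3.0,
                 direction=(0.0, 0.0, 1.0), margin_sigma: float = 2.0):
    """Energy layers and a square lateral lattice covering the target.

    Layers are the database energies whose Bragg peaks fall inside the
    target's water-equivalent depth extent (measured on the central axis),
    extended by one layer proximally and distally.  Each layer carries the
    same lattice over the target's lateral bounding box plus an in-air-sigma
    margin.  Returns ``(beam, spots)`` with unit initial spot weights.
    """
    if lateral_spacing <= 0:
        raise ValidationError("lateral_spacing must be positive")
    if not np.any(target.mask):
        raise ValidationError("target ROI is empty")
    u, v, d = beam_basis(direction)
    grid = target.grid
    ii = np.asarray(np.nonzero(target.mask)).T
    centers = (np.asarray(grid.origin)[None, :]
               + (ii + 0.5) * np.asarray(grid.spacing)[None, :])
    centroid = centers.mean(axis=0)

    # depth extent along the central axis, converted to WET
    t = (centers - centroid) @ d
    source = centroid - 500.0 * d
    s_knots, w_knots, t_entry = wepl_profile(rsp_grid, source, d)
    if s_knots.size < 2:
        raise ValidationError("beam axis misses the grid")
    t0 = 500.0 - t_entry   # centroid's distance past the grid entry
    half_vox = max(grid.spacing) / 2
    wet_lo = float(np.interp(t0 + t.min() - half_vox, s_knots, w_knots))
    wet_hi = float(np.interp(t0 + t.max() + half_vox, s_knots, w_knots))

    energies = db.energies(ion)
    peaks = np.array([db.entries[(ion, e)].peak_depth for e in energies])
    if wet_hi > peaks[-1]:
        raise ValidationError(
            f"target WET extent {wet_hi:.1f} mm beyond deepest tabulated "
            f"range {peaks[-1]:.1f} mm")
    inside = np.nonzero((peaks >= wet_lo) & (peaks <= wet_hi))[0]
    if inside.size == 0:
        inside = np.array([int(np.argmin(np.abs(peaks - 0.5 * (wet_lo + wet_hi))))])
    lo = max(inside[0] - 1, 0)
    hi = min(inside[-1] + 1, energies.size - 1)
    layer_energies = energies[lo:hi + 1]

    pu = (centers - centroid) @ u
    pv = (centers - centroid) @ v
    sig = fwhm_to_sigma(db.fwhm_air_at(ion, float(layer_energies[-1])))
    m = margin_sigma * sig

    # simple centred lattice covering [min - m, max + m]
    def axis_positions(lo_, hi_):
        span = (hi_ + m) - (lo_ - m)
        n = max(int(np.floor(span / lateral_spacing)) + 1, 1)
        mid = 0.5 * (lo_ + hi_)
        return mid + (np.arange(n) - (n - 1) / 2) * lateral_spacing

    xs = axis_positions(pu.min(), pu.max())
    ys = axis_positions(pv.min(), pv.max())
    spots = []
    for e in layer_energies:
        for x in xs:
            for y in ys:
                spots.append(Spot(float(e), float(x), float(y), 1.0))
    beam = Beam(tuple(d), tuple(centroid), RangeShifter(), spots)
    return beam, spots


# ---------------------------------------------------------------------------
# SOBP weight optimisation
# ---------------------------------------------------------------------------

@dataclass
class SobpResult:
    plan: Plan
    trace: list                    # accepted iterations: (iter, D50, objective)
    converged: bool
    d50: float


def _drbe_from_influence(w, infl, model, photon_lq, mkm):
    from . import biology
    dose = infl["dose"].T @ w
    if model == "rbe1.1":
        return biology.rbe_fixed_1p1(dose), dose
    with np.errstate(invalid="ignore", divide="ignore"):
        if model == "lem":
            alpha = np.where(dose > 0, (infl["alpha"].T @ w) / dose, 0.0)
            sqrtb = np.where(dose > 0, (infl["sqrtbeta"].T @ w) / dose, 0.0)
            beta = sqrtb ** 2
        elif model == "mkm":
            zst = np.where(dose > 0, (infl["zstar"].T @ w) / dose, 0.0)
            alpha = mkm.alpha0 + mkm.beta0 * zst
            beta = np.full_like(dose, mkm.beta0)
        else:
            raise ValidationError(f"unknown model {model!r}")
    return biology.photon_equivalent_dose(dose, alpha, beta, photon_lq), dose


def optimize_sobp(plan: Plan, target: ROIMask, rsp_grid: VoxelGrid,
                  db: BeamDatabase, prescription: float,
                  model: str = "rbe1.1", photon_lq=None, mkm=None,
                  max_iter: int = 60, tol: float = 0.005, damping: float = 0.7,
                  seed: int = 0, config=None) -> SobpResult:
    """Damped dose-ratio fixed-point optimisation of spot weights.

    Each sweep recomputes D_RBE (via a per-spot influence decomposition,
    exactly linear in the weights) at every target voxel and at each spot's
    own Bragg-peak point, then scales weights by
    ``(prescription / D_RBE_at_peak) ** step``.  A sweep is accepted only if
    the objective ``max |D_RBE - prescription|`` over the target does not
    increase; otherwise the step is halved.  Stops when the target D50 is
    within ``tol`` of the prescription.
    """
    from . import analysis, biology, engine

    if model not in ("rbe1.1", "lem", "mkm"):
        raise ValidationError(f"unknown model {model!r}")
    if plan.ion == "proton" and model != "rbe1.1":
        raise ValidationError("proton plans use the fixed-RBE model")
    photon_lq = photon_lq or biology.PhotonLQ()
    mkm = mkm or biology.MKMParams()
    config = config or engine.EngineConfig()
    plan.validate_against_db(db)

    dose_grid = engine.make_dose_grid(rsp_grid, config.dose_spacing)
    tmask = engine.roi_on_dose_grid(target, dose_grid)
    cx, cy, cz = dose_grid.center_mesh()
    pts_target = np.stack(np.broadcast_arrays(cx, cy, cz), axis=-1)[tmask]

    # one Bragg-peak probe point per spot, on its own axis
    peak_pts = []
    for beam in plan.beams:
        u, v, d = beam_basis(beam.direction)
        iso = np.asarray(beam.isocenter)
        for spot in beam.spots:
            p0 = iso + spot.x * u + spot.y * v - 500.0 * d
            s_kn, w_kn, t_entry = wepl_profile(rsp_grid, p0, d)
            peak = db.entry(plan.ion, spot.energy).peak_depth
            wet_target = peak - beam.range_shifter.wet * beam.range_shifter.present
            s_peak = float(np.interp(wet_target, w_kn, s_kn))
            peak_pts.append(p0 + (t_entry + s_peak) * d)
    pts = np.vstack([pts_target, np.asarray(peak_pts)])
    ntar = pts_target.shape[0]

    need = ("dose",) if model == "rbe1.1" else (
        ("dose", "alpha", "sqrtbeta") if model == "lem" else ("dose", "zstar"))
    infl = engine.spot_influence(rsp_grid, db, plan, config, pts, fields=need)

    nspots = plan.spot_count()

    def evaluate(wvec):
        drbe, _ = _drbe_from_influence(wvec, infl, model, photon_lq, mkm)
        return drbe, float(analysis.dx(drbe[:ntar], 50.0))

    def rescale_to_d50(wvec):
        # scalar renormalisation onto D50 = prescription.  D_RBE responds
        # superlinearly to a uniform weight scale under the LQ models, so
        # solve for the scale by a secant iteration in log space (exact in
        # one step for the linear fixed-RBE model).
        drbe, d50 = evaluate(wvec)
        if d50 <= 0:
            raise ConvergenceError("no dose reaches the target")
        s, s_prev, d50_prev = 1.0, None, None
        for _ in range(12):
            if abs(d50 - prescription) <= 1e-10 * prescription:
                break
            p = 1.0
            if s_prev is not None and abs(np.log(s / s_prev)) > 1e-14:
                p = np.log(d50 / d50_prev) / np.log(s / s_prev)
                p = float(np.clip(p, 0.5, 3.0))
            s_prev, d50_prev = s, d50
            s = s * (prescription / d50) ** (1.0 / p)
            drbe, d50 = evaluate(s * wvec)
        return s * wvec, drbe, d50

    def deviations(drbe):
        dev = drbe[:ntar] - prescription
        return (float(np.max(np.abs(dev))),
                float(np.sqrt(np.mean(dev ** 2))))

    w = np.full(nspots, 1.0)
    w, drbe, d50 = rescale_to_d50(w)
    obj, rms = deviations(drbe)
    trace = [{"iteration": 0, "d50": d50, "objective": obj, "rms": rms}]
    step = damping
    it = 0
    while it < max_iter:
        it += 1
        ratio = prescription / np.clip(drbe[ntar:], 1e-12, None)
        w_try = w * np.clip(ratio, 0.2, 5.0) ** step
        try:
            w_try, drbe_try, d50_try = rescale_to_d50(w_try)
        except ConvergenceError:
            break
        obj_try, rms_try = deviations(drbe_try)
        # accept only sweeps that keep the worst deviation from growing and
        # improve the overall (rms) homogeneity; stop once the latter stalls
        if obj_try <= obj + 1e-12 and rms_try <= rms + 1e-12:
            improvement = (rms - rms_try) / max(rms, 1e-300)
            w, drbe, obj, rms, d50 = w_try, drbe_try, obj_try, rms_try, d50_try
            trace.append({"iteration": it, "d50": d50, "objective": obj,
                          "rms": rms})
            step = min(damping, step * 1.25)
            if improvement < 1e-3:
                break
        else:
            step *= 0.5
            if step < 1e-3:
                break

    converged = abs(d50 - prescription) <= tol * prescription
    if not converged:
        raise ConvergenceError(
            f"SOBP optimisation did not reach D50 within {tol:.1%} of the "
            f"prescription (best D50 = {d50:.4f})", trace=trace)

    out_beams = []
    k = 0
    for beam in plan.beams:
        spots = []
        for spot in beam.spots:
            spots.append(replace(spot, n_particles=float(w[k])))
            k += 1
        out_beams.append(Beam(beam.direction, beam.isocenter,
                              beam.range_shifter, spots))
    out = Plan(plan.ion, out_beams, prescription, plan.fractions)
    return SobpResult(out, trace, True, d50)
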