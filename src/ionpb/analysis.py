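"""Evaluation suite: DVH and D_x metrics, LET statistics, global
gamma-index, and the water-phantom patient-QA point statistic.

D_x convention (fixed here; planning systems differ): the dose received by
x% of the volume is read from the sorted voxel values with Hazen plotting
positions — sample ``k`` (1-based, ascending) carries volume fraction
``(n - k + 0.5)/n`` above it — interpolating linearly between order
statistics.  One hundred voxels valued 1..100 Gy thus give D50 = 50.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, ValidationError
from .geometry import ROIMask, VoxelGrid


def dx(values, x: float) -> float:
    """Hazen-interpolated dose received by x% of the samples."""
    if not 0 < x < 100:
        raise ValidationError("x must be in (0, 100)")
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = v.size
    if n == 0:
        raise GeometryError("no samples")
    k = n - 0.5 - n * (x / 100.0)
    k = min(max(k, 0.0), n - 1.0)
    lo = int(np.floor(k))
    f = k - lo
    hi = min(lo + 1, n - 1)
    return float(v[lo] * (1 - f) + v[hi] * f)


@dataclass
class DVHCurve:
    """Cumulative volume-fraction-above-dose curve (exact, sample-based)."""

    samples: np.ndarray          # sorted ascending voxel values
    unit: str = "Gy"

    def __post_init__(self):
        self.samples = np.sort(np.asarray(self.samples, dtype=float).ravel())
        if self.samples.size == 0:
            raise GeometryError("DVH over an empty ROI")

    def volume_fraction(self, dose) -> np.ndarray:
        """Fraction of the volume receiving more than ``dose``."""
        d = np.asarray(dose, dtype=float)
        above = self.samples.size - np.searchsorted(self.samples, d,
                                                    side="right")
        return above / self.samples.size

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    def binned(self, bin_width: float):
        """(dose_edges, fraction_above) for CSV export."""
        if bin_width <= 0:
            raise ValidationError("bin width must be positive")
        top = float(self.samples[-1]) + bin_width
        edges = np.arange(0.0, top + bin_width, bin_width)
        return edges, self.volume_fraction(edges)

    def export_csv(self, path, bin_width: float) -> None:
        edges, frac = self.binned(bin_width)
        arr = np.column_stack([edges, frac])
        np.savetxt(path, arr, delimiter=",", fmt="%.10g",
                   header=f"dose_{self.unit},volume_fraction", comments="")


def dvh(map_values, roi: ROIMask, unit: str = "Gy") -> DVHCurve:
    """DVH of a map (VoxelGrid or array on the ROI's grid) over a ROI."""
    vals = (map_values.values if isinstance(map_values, VoxelGrid)
            else np.asarray(map_values, dtype=float))
    if vals.shape != roi.mask.shape:
        raise ValidationError("map and ROI must share a grid")
    if not np.any(roi.mask):
        raise GeometryError("empty ROI")
    return DVHCurve(vals[roi.mask], unit=unit)


def d_metric(curve: DVHCurve, x: float) -> float:
    """D_x from a DVH curve (see module docstring for the convention)."""
    return dx(curve.samples, x)


def let_metrics(let_map, roi: ROIMask):
    """(mean LET_d, LET_d,2) over the ROI."""
    curve = dvh(let_map, roi, unit="keV/um")
    return curve.mean, d_metric(curve, 2.0)


# ---------------------------------------------------------------------------
# gamma index
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    gamma: np.ndarray            # NaN outside the evaluated (included) set
    pass_rate: float             # % of included voxels with gamma <= 1
    criteria: tuple              # (dta mm, dose %, threshold %)
    n_evaluated: int


def gamma_index(reference: VoxelGrid, evaluated: VoxelGrid, dta: float = 2.0,
                dose_crit: float = 2.0, threshold: float = 10.0,
                search_factor: float = 3.0) -> GammaResult:
    """Globally normalised 3-D gamma index.

    For each reference voxel above ``threshold``% of the reference maximum,
    the evaluated map is probed (trilinear interpolation) on a sphere of
    radius ``search_factor * dta`` sampled at dta/10 steps:

        gamma = min sqrt(|dr|^2/dta^2 + dD^2/(dose_crit% * max_ref)^2)

    Offsets are visited in increasing radius with early termination once the
    geometric term alone exceeds every remaining voxel's current value.
    """
    if dta <= 0 or dose_crit <= 0:
        raise ValidationError("dta and dose_crit must be positive")
    if reference.shape != evaluated.shape:
        raise ValidationError("maps must share a grid")
    ref = reference.values
    ev = evaluated.values
    maxref = float(ref.max())
    if maxref <= 0:
        raise ValidationError("reference map has no positive dose")
    include = ref >= threshold / 100.0 * maxref
    if not np.any(include):
        raise ValidationError("all voxels below the low-dose threshold")
    denom = dose_crit / 100.0 * maxref
    spacing = np.asarray(reference.spacing)

    idx = np.asarray(np.nonzero(include)).T.astype(float)
    refv = ref[include]

    step = dta / 10.0
    radius = search_factor * dta
    n1 = int(np.floor(radius / step))
    ax = np.arange(-n1, n1 + 1) * step
    OX, OY, OZ = np.meshgrid(ax, ax, ax, indexing="ij")
    rr = OX ** 2 + OY ** 2 + OZ ** 2
    keep = rr <= radius ** 2 + 1e-12
    offs = np.column_stack([OX[keep], OY[keep], OZ[keep]])
    r2 = rr[keep]
    order = np.argsort(r2, kind="stable")
    offs = offs[order]
    r2 = r2[order]

    g2 = np.full(refv.size, np.inf)
    active = np.arange(refv.size)
    for o, rr2 in zip(offs, r2):
        geo = rr2 / dta ** 2
        still = g2[active] > geo
        active = active[still]
        if active.size == 0:
            break
        coords = (idx[active] + o[None, :] / spacing[None, :]).T
        vals = map_coordinates(ev, coords, order=1, mode="nearest")
        cand = geo + ((vals - refv[active]) / denom) ** 2
        g2[active] = np.minimum(g2[active], cand)
    gamma_inc = np.sqrt(g2)
    gmap = np.full(ref.shape, np.nan)
    gmap[include] = gamma_inc
    rate = float(100.0 * np.count_nonzero(gamma_inc <= 1.0) / gamma_inc.size)
    return GammaResult(gmap, rate, (dta, dose_crit, threshold),
                       int(gamma_inc.size))


# ---------------------------------------------------------------------------
# patient-QA point statistic
# ---------------------------------------------------------------------------

@dataclass
class QAStat:
    """Chamber-point comparison normalised to the maximum field dose.

    Protocol verdict: pass iff |mean| <= 5% and sd < 5% (sample sd, n-1).
    """

    diffs: np.ndarray            # (measured - calculated) / max field dose
    mean: float
    sd: float
    passed: bool


def point_dose(computed: VoxelGrid, positions) -> np.ndarray:
    """Trilinear dose at world positions (mm); errors list off-grid points."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    origin = np.asarray(computed.origin)
    spacing = np.asarray(computed.spacing)
    extent = np.asarray(computed.extent)
    bad = [i for i, p in enumerate(pos)
           if np.any(p < origin) or np.any(p >= extent)]
    if bad:
        raise GeometryError(f"points outside the grid: indices {bad}")
    coords = ((pos - origin[None, :]) / spacing[None, :] - 0.5).T
    return map_coordinates(computed.values, coords, order=1, mode="nearest")


def qa_compare(computed: VoxelGrid, points) -> QAStat:
    """CNAO-style QA statistic over measured chamber points.

    ``points``: iterable of ((x, y, z) mm, measured_dose Gy).
    """
    points = list(points)
    if not points:
        raise ValidationError("need at least one QA point")
    pos = np.asarray([p[0] for p in points], dtype=float)
    measured = np.asarray([p[1] for p in points], dtype=float)
    calc = point_dose(computed, pos)
    maxfield = float(computed.values.max())
    if maxfield <= 0:
        raise ValidationError("computed field has no positive dose")
    diffs = (measured - calc) / maxfield
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    passed = (abs(mean) <= 0.05) and (sd < 0.05)
    return QAStat(diffs, mean, sd, passed)
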