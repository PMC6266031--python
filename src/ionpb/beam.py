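"""Per-spot lateral beam model.

A scanned spot enters the patient with an in-air Gaussian fluence whose
FWHM is interpolated from the machine table.  In water the lateral dose is
the depth-dependent triple-Gaussian kernel from the database; the in-air
sigma and any range-shifter widening are added in quadrature to each of the
three tabulated components.  For heterogeneous geometries a spot can be
split into a lattice of sub-beams that discretises the entrance fluence so
each sub-beam samples its own radiological path; the sub-beams are then
transported with the tabulated in-water kernel only, which makes splitting
an exact no-op in homogeneous water in the many-sub-beam limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .database import BeamDatabase, RS_NOMINAL_WET_MM, cell_gaussian_weights
from .errors import ValidationError

#: 2 * sqrt(2 ln 2)
FWHM_PER_SIGMA = 2.354820045


@dataclass
class RangeShifter:
    """Upstream degrader: water-equivalent thickness + air gap to the skin."""

    wet: float = 0.0           # mm water-equivalent
    air_gap: float = 0.0       # mm from RS exit to entry point
    present: bool = False

    def __post_init__(self):
        if self.wet < 0 or self.air_gap < 0:
            raise ValidationError("range-shifter wet and air_gap must be >= 0")


@dataclass
class Spot:
    """One scanned pencil beam at the isocenter plane."""

    energy: float              # MeV/u
    x: float                   # mm, transverse
    y: float                   # mm, transverse
    n_particles: float
    fwhm_air: float = None     # mm at entrance; None -> machine table

    def __post_init__(self):
        if self.n_particles < 0:
            raise ValidationError("n_particles must be >= 0")


@dataclass
class SubBeam:
    offset: tuple              # (dx, dy) mm from the parent spot axis
    weight: float              # fraction of parent fluence
    sigma_cell: float = 0.0    # mm residual in-cell spread of the fluence


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma from FWHM."""
    if fwhm <= 0:
        raise ValidationError("fwhm must be positive")
    return fwhm / FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_PER_SIGMA


def compose_sigma(sigma_air, sigma_mcs, sigma_rs):
    """Quadrature sum of independent Gaussian widths (vectorised)."""
    return np.sqrt(np.square(sigma_air) + np.square(sigma_mcs)
                   + np.square(sigma_rs))


def rs_sigma(db: BeamDatabase, ion: str, energy: float, rs: RangeShifter,
             depth_geo):
    """Lateral widening (mm) from the range shifter at geometric depth.

    The database tabulates the angular spread theta(E) for the nominal RS
    thickness; scattering in a different thickness scales ~ sqrt(wet).  The
    displacement grows linearly over the air gap plus the in-patient depth.
    """
    if not rs.present or rs.wet == 0:
        return np.zeros_like(np.asarray(depth_geo, dtype=float))
    theta = db.rs_theta(ion, energy) * math.sqrt(rs.wet / RS_NOMINAL_WET_MM)
    return theta * (rs.air_gap + np.asarray(depth_geo, dtype=float))


def triple_gaussian(r, sigmas, weights):
    """Normalised radial kernel: integral of L(r) 2 pi r dr over [0, inf) is 1."""
    r = np.asarray(r, dtype=float)
    s1, s2, s3 = sigmas
    w1, w2, w3 = weights
    r2 = np.square(r)
    return (w1 / (2 * np.pi * np.square(s1)) * np.exp(-0.5 * r2 / np.square(s1))
            + w2 / (2 * np.pi * np.square(s2)) * np.exp(-0.5 * r2 / np.square(s2))
            + w3 / (2 * np.pi * np.square(s3)) * np.exp(-0.5 * r2 / np.square(s3)))


def split_spot(spot: Spot, n_splits: int, sigma_entrance: float,
               bound_sigma: float = 3.5):
    """Discretise the entrance fluence into a square sub-beam lattice.

    The lattice is an m x m grid of equal cells (m = ceil(sqrt(n_splits)))
    covering [-bound_sigma, +bound_sigma] sigma per axis; each weight is the
    parent Gaussian mass in its cell, renormalised so the truncated lattice
    carries exactly the parent fluence.  Each sub-beam sits at its cell's
    fluence centroid and carries the residual in-cell spread as a small
    extra Gaussian width, so the superposition preserves the parent's first
    and second moments (making splitting a near-exact no-op in water).
    """
    if n_splits < 1:
        raise ValidationError("n_splits must be >= 1")
    if sigma_entrance <= 0:
        raise ValidationError("sigma_entrance must be positive")
    from scipy.stats import norm

    m = int(math.ceil(math.sqrt(n_splits)))
    half = bound_sigma * sigma_entrance
    edges = np.linspace(-half, half, m + 1)
    w1d = cell_gaussian_weights(edges, sigma_entrance)
    # truncated-Gaussian moments per cell (alpha, beta = scaled cell edges)
    a = edges[:-1] / sigma_entrance
    b = edges[1:] / sigma_entrance
    phi_a, phi_b = norm.pdf(a), norm.pdf(b)
    z = w1d / 1.0
    mean1d = sigma_entrance * (phi_a - phi_b) / z
    var1d = sigma_entrance ** 2 * (
        1.0 + (a * phi_a - b * phi_b) / z) - mean1d ** 2
    var1d = np.clip(var1d, 0.0, None)
    w2d = np.outer(w1d, w1d)
    w2d /= w2d.sum()
    subs = []
    for i in range(m):
        for j in range(m):
            sig_cell = math.sqrt(0.5 * (var1d[i] + var1d[j]))
            subs.append(SubBeam((float(mean1d[i]), float(mean1d[j])),
                                float(w2d[i, j]), sig_cell))
    return subs
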