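"""RBE-weighted dose from the score maps.

Protons use the clinical fixed RBE of 1.1.  Carbon ions use the mixed-field
linear-quadratic route: the engine accumulates dose-weighted alpha and
sqrt(beta) (Zaider-Rossi mixing) for the local-effect-model tables, or the
dose-weighted saturation-corrected specific energy zstar for the modified
microdosimetric kinetic model (alpha_mix = alpha0 + beta0 * zstar); the
photon-equivalent dose then inverts the photon LQ curve at equal effect:

    E = alpha_mix D + beta_mix D^2
    D_RBE = (sqrt(alpha_x^2 + 4 beta_x E) - alpha_x) / (2 beta_x)

Biology tables depend on depth only; lateral variation of the mixed field
is deliberately not modelled (a stated approximation of this engine class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ScoreMaps
from .errors import GeometryError, ValidationError
from .geometry import ROIMask, VoxelGrid


@dataclass
class PhotonLQ:
    """Photon reference linear-quadratic parameters (tissue config)."""

    alpha_x: float = 0.1      # 1/Gy
    beta_x: float = 0.05      # 1/Gy^2
    name: str = "default"

    def __post_init__(self):
        if self.alpha_x <= 0 or self.beta_x < 0:
            raise ValidationError("need alpha_x > 0 and beta_x >= 0")


@dataclass
class MKMParams:
    alpha0: float = 0.13      # 1/Gy
    beta0: float = 0.05       # 1/Gy^2

    def __post_init__(self):
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValidationError("MKM parameters must be positive")


def rbe_fixed_1p1(dose):
    """Proton biological dose: D_RBE = 1.1 x physical dose."""
    return 1.1 * np.asarray(dose, dtype=float)


def _safe_ratio(num, dose):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(dose > 0, num / np.where(dose > 0, dose, 1.0), 0.0)


def mixed_lem_coeffs(scores: ScoreMaps):
    """Dose-averaged alpha and (dose-averaged sqrt(beta))^2 per voxel."""
    alpha = _safe_ratio(scores.sum_d_alpha, scores.dose)
    sqrtb = _safe_ratio(scores.sum_d_sqrtbeta, scores.dose)
    return alpha, sqrtb ** 2


def mixed_mkm_alpha(scores: ScoreMaps, p: MKMParams):
    """MKM mixing: alpha_mix = alpha0 + beta0 * zstar_mix; beta_mix = beta0."""
    zstar = _safe_ratio(scores.sum_d_zstar, scores.dose)
    alpha = np.where(scores.dose > 0, p.alpha0 + p.beta0 * zstar, 0.0)
    beta = np.where(scores.dose > 0, p.beta0, 0.0)
    return alpha, beta


def photon_equivalent_dose(dose, alpha_mix, beta_mix, ref: PhotonLQ):
    """Iso-effect inversion of the photon LQ curve; zero where undosed."""
    d = np.asarray(dose, dtype=float)
    effect = alpha_mix * d + beta_mix * d ** 2
    if ref.beta_x == 0:
        out = effect / ref.alpha_x
    else:
        out = ((np.sqrt(ref.alpha_x ** 2 + 4 * ref.beta_x * effect)
                - ref.alpha_x) / (2 * ref.beta_x))
    return np.where(d > 0, out, 0.0)


def carbon_drbe(scores: ScoreMaps, model: str, photon_lq: PhotonLQ,
                mkm: MKMParams | None = None):
    """Convenience: ScoreMaps -> D_RBE array under 'lem' or 'mkm'."""
    if model == "lem":
        alpha, beta = mixed_lem_coeffs(scores)
    elif model == "mkm":
        alpha, beta = mixed_mkm_alpha(scores, mkm or MKMParams())
    else:
        raise ValidationError(f"unknown carbon model {model!r}")
    return photon_equivalent_dose(scores.dose, alpha, beta, photon_lq)


def lem_mkm_ratio(d_lem, d_mkm, scaling: float, roi: ROIMask):
    """Scaled MKM/LEM ratio inside a ROI plus the derived scaling factor.

    The ratio map is ``scaling * D_MKM / D_LEM`` where the LEM dose is
    positive inside the ROI (NaN elsewhere); the summary reports the
    engine-derived scaling factor D_RBE,LEM,50 / D_RBE,MKM,50 over the ROI.
    """
    from .analysis import dx

    d_lem = d_lem.values if isinstance(d_lem, VoxelGrid) else np.asarray(d_lem)
    d_mkm = d_mkm.values if isinstance(d_mkm, VoxelGrid) else np.asarray(d_mkm)
    if d_lem.shape != d_mkm.shape:
        raise ValidationError("D_RBE maps must share a grid")
    if not np.any(roi.mask):
        raise GeometryError("empty ROI")
    sel = roi.mask & (d_lem > 0)
    ratio = np.full(d_lem.shape, np.nan)
    ratio[sel] = scaling * d_mkm[sel] / d_lem[sel]
    lem50 = dx(d_lem[roi.mask], 50.0)
    mkm50 = dx(d_mkm[roi.mask], 50.0)
    summary = {
        "d50_lem": float(lem50),
        "d50_mkm": float(mkm50),
        "derived_scaling": float(lem50 / mkm50) if mkm50 > 0 else np.nan,
        "applied_scaling": float(scaling),
    }
    return ratio, summary
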