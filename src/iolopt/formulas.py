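"""Refraction prediction and IOL-power inversion for four classical formulae.

Implements SRK/T, Hoffer Q, Holladay 1 and the simplified Haigis formula.
Each formula maps a single tunable constant (A-constant, pACD, surgeon
factor SF, or Haigis intercept a0) to an effective lens position (ELP) —
the fictitious axial depth of a thin IOL behind the corneal apex — and then
propagates vergences through a thin-lens pseudophakic eye model to predict
the spherical-equivalent refraction (SEQ) at the spectacle plane for an
implanted IOL power, or conversely the power achieving a target SEQ.

Two further tuning parameters are supported uniformly: a refractive offset
RO added to the predicted SEQ, and a keratometer index nK replacing the
formula-native index in the corneal-power conversion.

All computational kernels broadcast over numpy arrays, so a whole cohort
(or a grid of candidate constants against a cohort) is evaluated in one
call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .biometry import JAVAL_INDEX, BiometryRecord, Cohort

logger = logging.getLogger(__name__)

#: Aqueous/vitreous refractive index of the thin-lens eye model.
NA = 1.336
#: Spectacle vertex distance (mm) for corneal-plane <-> spectacle-plane conversion.
VERTEX_MM = 12.0

#: Corneal index of the simplified Haigis formula's keratometry conversion.
HAIGIS_INDEX = 1.3315


class FormulaId(str, Enum):
    """The four classical formulae under test."""

    SRKT = "SRKT"
    HOFFERQ = "HofferQ"
    HOLLADAY1 = "Holladay1"
    HAIGIS = "Haigis"


#: Plausibility bounds for each formula's primary constant (also the default
#: search interval for constant optimization).
FC_BOUNDS: dict[FormulaId, tuple[float, float]] = {
    FormulaId.SRKT: (110.0, 125.0),
    FormulaId.HOFFERQ: (2.0, 9.0),
    FormulaId.HOLLADAY1: (-2.0, 5.0),
    FormulaId.HAIGIS: (-3.0, 5.0),
}

#: Fallback start values when no manufacturer-nominal constant is supplied.
FC_DEFAULTS: dict[FormulaId, float] = {
    FormulaId.SRKT: 119.0,
    FormulaId.HOFFERQ: 5.6,
    FormulaId.HOLLADAY1: 1.8,
    FormulaId.HAIGIS: 1.3,
}


class FormulaError(ValueError):
    """Constant set or vergence chain outside the computable domain."""


@dataclass(frozen=True)
class FormulaConstants:
    """A formula's tunable constant set.

    Parameters
    ----------
    formula
        Which formula the constants parameterize.
    fc
        Primary constant in formula-native units: A-constant (SRK/T),
        personalized ACD pACD (Hoffer Q), surgeon factor SF (Holladay 1),
        or ELP intercept a0 (simplified Haigis).
    a1, a2
        Haigis ELP slopes on ACD and AL; preset 0.4 / 0.1 and held fixed
        during single-constant optimization.  Ignored by other formulae.
    ro
        Refractive offset (D) added to the predicted SEQ.
    nk
        Keratometer index overriding the formula-native corneal-power
        conversion; ``None`` keeps the native index (Javal 1.3375 for
        SRK/T, Hoffer Q and Holladay 1; 1.3315 for Haigis).
    """

    formula: FormulaId
    fc: float
    a1: float = 0.4
    a2: float = 0.1
    ro: float = 0.0
    nk: float | None = None

    def __post_init__(self) -> None:
        lo, hi = FC_BOUNDS[FormulaId(self.formula)]
        if not lo <= self.fc <= hi:
            raise FormulaError(
                f"{self.formula}: constant {self.fc} outside plausibility bounds [{lo}, {hi}]"
            )
        if self.nk is not None and not 1.30 < self.nk < 1.38:
            raise FormulaError(f"keratometer index {self.nk} outside (1.30, 1.38)")
        if not np.isfinite(self.ro):
            raise FormulaError("refractive offset must be finite")


@dataclass(frozen=True)
class PredictedRefraction:
    """Predicted spectacle-plane SEQ (D) and the ELP (mm) used to obtain it."""

    seq_pred: float
    elp: float


# ---------------------------------------------------------------------------
# Corneal inputs
# ---------------------------------------------------------------------------

def _corneal_inputs(r12, nk_override):
    """Effective keratometric power K (D) and Javal-equivalent radius (mm).

    With the native Javal index the effective radius equals the measured
    radius; overriding nK rescales the corneal power (and hence the radius
    handed to radius-based formulae) by (nK - 1) / 0.3375.
    """
    r12 = np.asarray(r12, dtype=float)
    nk = JAVAL_INDEX if nk_override is None else float(nk_override)
    k = (nk - 1.0) * 1000.0 / r12
    r_eff = (JAVAL_INDEX - 1.0) * 1000.0 / k
    return k, r_eff


# ---------------------------------------------------------------------------
# ELP models
# ---------------------------------------------------------------------------

def _elp_srkt(a_const, al, r, k):
    """SRK/T effective lens position: corneal-height model plus A-constant offset.

    Uses the published quadratic axial-length correction for long eyes and
    the corneal-height guard (the square-root argument is clamped at zero
    when the corneal width exceeds the corneal diameter the radius allows).
    """
    a_const = np.asarray(a_const, dtype=float)
    lcor = np.where(al > 24.2, -3.446 + 1.715 * al - 0.0237 * al**2, al)
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    sq = r**2 - cw**2 / 4.0
    n_clamped = int(np.sum(sq < 0))
    if n_clamped:
        logger.warning("SRK/T corneal height: clamped %d negative sqrt argument(s)", n_clamped)
    h = r - np.sqrt(np.maximum(sq, 0.0))
    acd_const = 0.62467 * a_const - 68.747
    return h + (acd_const - 3.336)


def _elp_hofferq(pacd, al, k):
    """Hoffer Q effective lens position (tangent-based, with published AL clamps)."""
    pacd = np.asarray(pacd, dtype=float)
    alc = np.clip(al, 18.5, 31.0)
    m = np.where(alc <= 23.0, 1.0, -1.0)
    g = np.where(alc <= 23.0, 28.0, 23.5)
    tan = lambda deg: np.tan(np.deg2rad(deg))
    return (
        pacd
        + 0.3 * (alc - 23.5)
        + tan(k) ** 2
        + 0.1 * m * (23.5 - alc) ** 2 * tan(0.1 * (g - alc) ** 2)
        - 0.99166
    )


def _elp_holladay1(sf, al, r):
    """Holladay 1 effective lens position: anatomical ACD plus surgeon factor."""
    sf = np.asarray(sf, dtype=float)
    ag = np.minimum(12.5 * al / 23.45, 13.5)
    rag = np.maximum(r, 7.0)
    sq = rag**2 - ag**2 / 4.0
    n_clamped = int(np.sum(sq < 0))
    if n_clamped:
        logger.warning("Holladay 1 anatomical ACD: clamped %d negative sqrt argument(s)", n_clamped)
    acd = 0.56 + rag - np.sqrt(np.maximum(sq, 0.0))
    return acd + sf


def _elp_haigis(a0, a1, a2, acd, al):
    """Simplified Haigis effective lens position: a0 + a1*ACD + a2*AL."""
    return np.asarray(a0, dtype=float) + a1 * acd + a2 * al


# ---------------------------------------------------------------------------
# Thin-lens vergence chain
# ---------------------------------------------------------------------------

def _vergence_refraction(p, k, elp, l_opt):
    """Corneal-plane refraction for an implanted power ``p`` (all mm / D).

    Propagates the vergence needed on the retina back through the thin IOL
    at depth ``elp`` to the corneal plane: the required corneal-plane
    refraction R satisfies  n/(L-d) - P = n / (n/(K+R) - d)  with
    n = 1336 (aqueous index x 1000, mm units).
    """
    x = 1336.0 / (l_opt - elp) - p  # vergence just behind the IOL
    if np.any(x == 0):
        raise FormulaError("non-physical vergence chain: IOL power focuses at infinity")
    denom = 1336.0 / x + elp
    if np.any(denom == 0):
        raise FormulaError("non-physical vergence chain: zero distance to corneal focus")
    return 1336.0 / denom - k


def _vergence_power(target_corneal, k, elp, l_opt):
    """Implanted power producing corneal-plane refraction ``target_corneal``."""
    v0 = k + target_corneal
    if np.any(v0 == 0):
        raise FormulaError("non-physical vergence chain: zero corneal vergence")
    denom = 1336.0 / v0 - elp
    if np.any(denom == 0):
        raise FormulaError("non-physical vergence chain: focus at IOL plane")
    return 1336.0 / (l_opt - elp) - 1336.0 / denom


def _spectacle_from_corneal(rc):
    return rc / (1.0 + (VERTEX_MM / 1000.0) * rc)


def _corneal_from_spectacle(rx):
    return rx / (1.0 - (VERTEX_MM / 1000.0) * rx)


# ---------------------------------------------------------------------------
# Per-formula assembly
# ---------------------------------------------------------------------------

def _chain_parts(constants: FormulaConstants, al, acd, r12):
    """(K for the vergence chain, ELP, optical axial length) per formula.

    SRK/T adds its retinal-thickness term to AL and runs the vergence chain
    on the radius with corneal index 1.333; Holladay 1 adds 0.2 mm and uses
    corneal index 4/3; Hoffer Q keeps AL but shifts the IOL plane by
    +0.05 mm and uses the keratometric power directly; Haigis uses AL and
    its own 1.3315 keratometry index.
    """
    fid = FormulaId(constants.formula)
    al = np.asarray(al, dtype=float)
    acd = np.asarray(acd, dtype=float)
    if fid is FormulaId.HAIGIS:
        nk = HAIGIS_INDEX if constants.nk is None else constants.nk
        k_chain = (nk - 1.0) * 1000.0 / np.asarray(r12, dtype=float)
        elp = _elp_haigis(constants.fc, constants.a1, constants.a2, acd, al)
        return k_chain, elp, al
    k, r_eff = _corneal_inputs(r12, constants.nk)
    if fid is FormulaId.SRKT:
        elp = _elp_srkt(constants.fc, al, r_eff, k)
        l_opt = al + (0.65696 - 0.02029 * al)
        k_chain = 333.0 / r_eff  # corneal index 1.333 of the SRK/T eye model
    elif fid is FormulaId.HOFFERQ:
        elp = _elp_hofferq(constants.fc, al, k) + 0.05
        l_opt = al
        k_chain = k
    elif fid is FormulaId.HOLLADAY1:
        elp = _elp_holladay1(constants.fc, al, r_eff)
        l_opt = al + 0.2
        k_chain = (1000.0 / 3.0) / r_eff  # corneal index 4/3 of the Holladay eye model
    else:  # pragma: no cover - closed enumeration
        raise FormulaError(f"unknown formula {constants.formula}")
    return k_chain, elp, l_opt


# ---------------------------------------------------------------------------
# Array API (cohort-level)
# ---------------------------------------------------------------------------

def predict_seq_arrays(constants: FormulaConstants, al, acd, r12, iolp):
    """Predicted spectacle-plane SEQ (D) for arrays of eyes (broadcasting)."""
    k_chain, elp, l_opt = _chain_parts(constants, al, acd, r12)
    rc = _vergence_refraction(np.asarray(iolp, dtype=float), k_chain, elp, l_opt)
    return _spectacle_from_corneal(rc) + constants.ro


def elp_arrays(constants: FormulaConstants, al, acd, r12):
    """Effective lens position (mm) for arrays of eyes."""
    _, elp, _ = _chain_parts(constants, al, acd, r12)
    return elp


def iol_power_arrays(constants: FormulaConstants, al, acd, r12, target_seq):
    """Exact (unrounded) IOL power (D) achieving ``target_seq`` for arrays of eyes."""
    k_chain, elp, l_opt = _chain_parts(constants, al, acd, r12)
    rc = _corneal_from_spectacle(np.asarray(target_seq, dtype=float) - constants.ro)
    return _vergence_power(rc, k_chain, elp, l_opt)


# ---------------------------------------------------------------------------
# Record API
# ---------------------------------------------------------------------------

def effective_lens_position(constants: FormulaConstants, rec: BiometryRecord) -> float:
    """ELP (mm) the formula assigns to one eye under these constants."""
    return float(elp_arrays(constants, rec.al, rec.acd, rec.r12))


def predict_refraction(constants: FormulaConstants, rec: BiometryRecord) -> PredictedRefraction:
    """Back-calculated spectacle-plane SEQ (D) for the implanted power of one eye."""
    k_chain, elp, l_opt = _chain_parts(constants, rec.al, rec.acd, rec.r12)
    try:
        rc = _vergence_refraction(rec.iolp, k_chain, elp, l_opt)
    except FormulaError as exc:
        raise FormulaError(f"eye {rec.eye_id}: {exc}") from None
    return PredictedRefraction(
        seq_pred=float(_spectacle_from_corneal(rc) + constants.ro), elp=float(elp)
    )


def calc_iol_power(
    constants: FormulaConstants,
    rec: BiometryRecord,
    target_seq: float,
    rounding_step: float | None = 0.5,
) -> float:
    """IOL power (D) whose predicted SEQ equals ``target_seq`` for one eye.

    With ``rounding_step`` set (manufacturer labelling granularity, 0.5 D by
    default) the exact power is rounded to the nearest step.  Raises if no
    power in [-10, 40] D achieves the target.
    """
    if not np.isfinite(target_seq):
        raise FormulaError("target refraction must be finite")
    p = float(iol_power_arrays(constants, rec.al, rec.acd, rec.r12, target_seq))
    if rounding_step:
        p = round(p / rounding_step) * rounding_step
    if not -10.0 <= p <= 40.0:
        raise FormulaError(
            f"eye {rec.eye_id}: required power {p:.2f} D outside the [-10, 40] D range"
        )
    return p


# ---------------------------------------------------------------------------
# Constant interconversion helpers (never applied implicitly)
# ---------------------------------------------------------------------------

def a_constant_to_pacd(a_const: float) -> float:
    """Published regression from SRK/T A-constant to a Hoffer-style pACD."""
    return 0.58357 * a_const - 63.896


def a_constant_to_sf(a_const: float) -> float:
    """Published regression from SRK/T A-constant to a Holladay surgeon factor."""
    return 0.5663 * a_const - 65.60


def a_constant_to_acd(a_const: float) -> float:
    """SRK/T's own A-constant to ACD-constant conversion."""
    return 0.62467 * a_const - 68.747
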