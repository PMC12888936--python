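"""Prediction-error vectors and summary metrics (MPE, SDPE, RMSPE, |PE| quantiles).

The refraction prediction error of one eye is PE = achieved SEQ minus
formula-predicted SEQ (both at the spectacle plane, in D).  Under this sign
convention a positive refractive offset RO added to the prediction lowers
every PE by the same amount, so the offset that zeroes the mean error equals
the mean error measured at RO = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .biometry import Cohort
from .formulas import FormulaConstants, predict_seq_arrays


@dataclass(frozen=True)
class PEVector:
    """Ordered refraction prediction errors (D), one per eye."""

    pe: np.ndarray
    eye_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pe = np.asarray(self.pe, dtype=float)
        object.__setattr__(self, "pe", pe)
        if pe.ndim != 1 or pe.size < 1:
            raise ValueError("PE vector must be 1-D and non-empty")
        if not np.all(np.isfinite(pe)):
            raise ValueError("PE vector contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.pe.size)


@dataclass(frozen=True)
class PEStats:
    """Summary of a prediction-error vector.

    mpe/sdpe/rmspe are the mean, sample standard deviation (n-1 denominator)
    and root mean square of the signed errors; the remaining fields summarize
    the absolute errors (median, quartiles, 2.5%/97.5% quantiles) as drawn in
    the study's boxplots.  ``sdpe`` is NaN for a single-eye vector (undefined,
    not zero).
    """

    n: int
    mpe: float
    sdpe: float
    rmspe: float
    medae: float
    abs_q25: float
    abs_q75: float
    abs_ci_lo: float
    abs_ci_hi: float


def prediction_errors(constants: FormulaConstants, cohort: Cohort) -> PEVector:
    """PE_i = achieved SEQ_i - predicted SEQ_i over a cohort (vectorized)."""
    a = cohort.arrays()
    pred = predict_seq_arrays(constants, a["al"], a["acd"], a["r12"], a["iolp"])
    return PEVector(
        pe=a["seq_achieved"] - pred, eye_ids=tuple(r.eye_id for r in cohort.records)
    )


def summarize(pev: PEVector) -> PEStats:
    """MPE, SDPE, RMSPE and absolute-error quantiles of a PE vector."""
    pe = pev.pe
    n = pev.n
    ape = np.abs(pe)
    return PEStats(
        n=n,
        mpe=float(np.mean(pe)),
        sdpe=float(np.std(pe, ddof=1)) if n >= 2 else math.nan,
        rmspe=float(np.sqrt(np.mean(pe**2))),
        medae=float(np.median(ape)),
        abs_q25=float(np.quantile(ape, 0.25)),
        abs_q75=float(np.quantile(ape, 0.75)),
        abs_ci_lo=float(np.quantile(ape, 0.025)),
        abs_ci_hi=float(np.quantile(ape, 0.975)),
    )
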