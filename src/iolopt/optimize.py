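"""Formula-constant optimization strategies.

Six strategies are provided, matching the comparison grid of the study
design this package supports:

(a) ``A_ZERO_MPE``   — tune the formula constant FC so the mean prediction
    error is zero (bracketed scalar root finding);
(b) ``B_MIN_SDPE``   — tune FC for minimal standard deviation of the
    prediction error (bounded scalar minimization);
(c) ``C_MIN_RMSPE``  — tune FC for minimal root-mean-square prediction error;
(d) ``D_JOINT_FC_RO`` — jointly tune FC and a refractive offset RO for
    minimal RMSPE.  Because RO is purely additive, the inner optimum for any
    FC is RO(FC) = mean PE at RO=0, so the joint problem reduces exactly to
    minimizing the standard deviation over FC alone (profiling); a naive 2-D
    simplex search is available behind ``joint_mode="direct2d"`` for
    comparison;
(e) ``E_JOINT_FC_NK`` — jointly tune FC and the keratometer index nK for
    minimal RMSPE (nested bounded 1-D searches);
(f) ``F_TWO_STEP``   — the two-step procedure: first minimize SDPE over FC,
    then set RO to the mean prediction error at that constant, which zeroes
    the mean exactly.  ``two_step_mode="exact"`` solves step 1 to tolerance;
    ``"single_update"`` takes one damped Newton step on d(SDPE)/dFC from the
    start value, emulating a one-iteration clinical update.

The objectives are smooth functions of one or two scalars, so bracketed root
finding and bounded derivative-free minimization replace general-purpose
constrained solvers; step and function tolerances default to 1e-10 / 1e-12.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize as sopt

from .biometry import Cohort
from .formulas import FC_BOUNDS, FC_DEFAULTS, FormulaConstants, FormulaId, predict_seq_arrays
from .metrics import PEStats, PEVector, summarize

logger = logging.getLogger(__name__)


class StrategyId(str, Enum):
    """Closed enumeration of the optimization strategies (a)-(f)."""

    A_ZERO_MPE = "a"
    B_MIN_SDPE = "b"
    C_MIN_RMSPE = "c"
    D_JOINT_FC_RO = "d"
    E_JOINT_FC_NK = "e"
    F_TWO_STEP = "f"


class OptimizationError(RuntimeError):
    """Bracketing failure, degenerate cohort, or non-convergence."""


@dataclass(frozen=True)
class OptimizerSettings:
    """Stopping criteria and search bounds.

    ``step_tol``/``fun_tol`` are the step-size and function tolerances of the
    scalar searches; ``fc_bounds`` overrides the per-formula constant bounds;
    ``nk_bounds`` bounds the keratometer index; ``two_step_mode`` selects the
    exact or single-Newton-update first step of strategy (f); ``joint_mode``
    selects profiled or direct 2-D search for strategy (d); ``min_n`` is the
    cohort-size policy floor (override with ``allow_small=True``).
    """

    step_tol: float = 1e-10
    fun_tol: float = 1e-12
    fc_bounds: tuple[float, float] | None = None
    nk_bounds: tuple[float, float] = (1.30, 1.38)
    max_iter: int = 500
    two_step_mode: str = "exact"
    joint_mode: str = "profile"
    min_n: int = 10
    allow_small: bool = False

    def __post_init__(self) -> None:
        if self.step_tol <= 0 or self.fun_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.two_step_mode not in ("exact", "single_update"):
            raise ValueError(f"unknown two_step_mode {self.two_step_mode!r}")
        if self.joint_mode not in ("profile", "direct2d"):
            raise ValueError(f"unknown joint_mode {self.joint_mode!r}")


@dataclass(frozen=True)
class OptimizationResult:
    """Fitted constants, PE summary at the fit, and convergence diagnostics."""

    strategy: StrategyId
    formula: FormulaId
    constants: FormulaConstants
    stats: PEStats
    converged: bool
    iterations: int
    objective_value: float
    notes: str = ""


# ---------------------------------------------------------------------------
# Objective plumbing
# ---------------------------------------------------------------------------

class _PEFunction:
    """PE vector at RO = 0 as a function of (fc, nk) on a fixed cohort."""

    def __init__(self, formula: FormulaId, cohort: Cohort):
        self.formula = FormulaId(formula)
        a = cohort.arrays()
        self.al, self.acd, self.r12 = a["al"], a["acd"], a["r12"]
        self.iolp, self.seq = a["iolp"], a["seq_achieved"]
        self.n = len(cohort)

    def pe0(self, fc: float, nk: float | None = None) -> np.ndarray:
        c = FormulaConstants(formula=self.formula, fc=float(fc), nk=nk)
        pred = predict_seq_arrays(c, self.al, self.acd, self.r12, self.iolp)
        return self.seq - pred

    def mpe(self, fc: float, nk: float | None = None) -> float:
        return float(np.mean(self.pe0(fc, nk)))

    def sdpe(self, fc: float, nk: float | None = None) -> float:
        return float(np.std(self.pe0(fc, nk), ddof=1))

    def rmspe(self, fc: float, nk: float | None = None, ro: float = 0.0) -> float:
        return float(np.sqrt(np.mean((self.pe0(fc, nk) - ro) ** 2)))


def _check_cohort(cohort: Cohort, settings: OptimizerSettings) -> None:
    if len(cohort) < settings.min_n:
        msg = f"cohort has {len(cohort)} eyes (< {settings.min_n})"
        if not settings.allow_small:
            raise OptimizationError(msg + "; pass allow_small=True to proceed")
        logger.warning("optimization on small cohort: %s", msg)


def _bounds(formula: FormulaId, settings: OptimizerSettings) -> tuple[float, float]:
    return settings.fc_bounds if settings.fc_bounds is not None else FC_BOUNDS[FormulaId(formula)]


def _minimize_scalar(fn, bounds, settings: OptimizerSettings):
    res = sopt.minimize_scalar(
        fn,
        bounds=bounds,
        method="bounded",
        options={"xatol": settings.step_tol, "maxiter": settings.max_iter},
    )
    return float(res.x), bool(res.success), int(res.nfev)


def _root_mpe(pef: _PEFunction, bounds, settings: OptimizerSettings):
    lo, hi = bounds
    flo, fhi = pef.mpe(lo), pef.mpe(hi)
    if flo == 0.0:
        return lo, True, 0
    if fhi == 0.0:
        return hi, True, 0
    if flo * fhi > 0:
        raise OptimizationError(
            f"mean PE does not change sign over fc bounds [{lo}, {hi}] "
            f"(MPE({lo})={flo:.4f}, MPE({hi})={fhi:.4f})"
        )
    fc, r = sopt.brentq(
        pef.mpe,
        lo,
        hi,
        xtol=min(settings.step_tol, 1e-12),
        rtol=8.882e-16,
        maxiter=settings.max_iter,
        full_output=True,
    )
    iterations = r.iterations
    # polish with secant steps until the residual meets the function tolerance
    f = pef.mpe(fc)
    h = 1e-6
    for _ in range(5):
        if abs(f) <= settings.fun_tol:
            break
        dfdx = (pef.mpe(fc + h) - pef.mpe(fc - h)) / (2 * h)
        if dfdx == 0 or not np.isfinite(dfdx):
            break
        fc = float(np.clip(fc - f / dfdx, lo, hi))
        f = pef.mpe(fc)
        iterations += 1
    return fc, bool(r.converged), iterations


def _argmin_sdpe(pef: _PEFunction, bounds, settings: OptimizerSettings, nk=None):
    """Shared step used by strategies (b), (d, profiled) and (f, exact).

    Minimizes the sample SD of the PE at RO = 0; because the RMSPE at the
    inner-optimal offset is the population SD (a fixed positive multiple of
    the sample SD), this single search is the profiled joint (FC, RO)
    problem as well.
    """
    lo, hi = bounds
    probe = [pef.sdpe(x, nk) for x in np.linspace(lo, hi, 5)]
    if max(probe) - min(probe) < settings.fun_tol:
        raise OptimizationError(
            "SDPE is flat over the constant bounds; the cohort does not identify the constant"
        )
    return _minimize_scalar(lambda fc: pef.sdpe(fc, nk), bounds, settings)


def _result(strategy, pef, constants, converged, iterations, objective_value, notes=""):
    pe = pef.seq - predict_seq_arrays(constants, pef.al, pef.acd, pef.r12, pef.iolp)
    stats = summarize(PEVector(pe=pe))
    return OptimizationResult(
        strategy=StrategyId(strategy),
        formula=pef.formula,
        constants=constants,
        stats=stats,
        converged=converged,
        iterations=iterations,
        objective_value=float(objective_value),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------

def optimize_fc(
    formula: FormulaId,
    cohort: Cohort,
    objective: str,
    settings: OptimizerSettings = OptimizerSettings(),
) -> OptimizationResult:
    """Single-constant strategies (a)/(b)/(c): tune FC for one PE metric.

    ``objective`` is one of ``"zero_mpe"``, ``"min_sdpe"``, ``"min_rmspe"``.
    """
    _check_cohort(cohort, settings)
    pef = _PEFunction(formula, cohort)
    bounds = _bounds(formula, settings)
    if objective == "zero_mpe":
        fc, ok, it = _root_mpe(pef, bounds, settings)
        strategy, obj = StrategyId.A_ZERO_MPE, abs(pef.mpe(fc))
    elif objective == "min_sdpe":
        fc, ok, it = _argmin_sdpe(pef, bounds, settings)
        strategy, obj = StrategyId.B_MIN_SDPE, pef.sdpe(fc)
    elif objective == "min_rmspe":
        fc, ok, it = _minimize_scalar(pef.rmspe, bounds, settings)
        strategy, obj = StrategyId.C_MIN_RMSPE, pef.rmspe(fc)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    constants = FormulaConstants(formula=FormulaId(formula), fc=fc)
    return _result(strategy, pef, constants, ok, it, obj)


def optimize_joint(
    formula: FormulaId,
    cohort: Cohort,
    second: str,
    settings: OptimizerSettings = OptimizerSettings(),
) -> OptimizationResult:
    """Joint two-parameter strategies (d)/(e): minimize RMSPE over (FC, RO) or (FC, nK)."""
    _check_cohort(cohort, settings)
    pef = _PEFunction(formula, cohort)
    bounds = _bounds(formula, settings)
    if second == "ro":
        if settings.joint_mode == "profile":
            fc, ok, it = _argmin_sdpe(pef, bounds, settings)
            ro = pef.mpe(fc)
        else:
            ro0 = pef.mpe(FC_DEFAULTS[FormulaId(formula)])
            res = sopt.minimize(
                lambda x: pef.rmspe(x[0], ro=x[1]),
                x0=[FC_DEFAULTS[FormulaId(formula)], ro0],
                method="Nelder-Mead",
                bounds=[bounds, (-5.0, 5.0)],
                options={
                    "xatol": settings.step_tol,
                    "fatol": settings.fun_tol,
                    "maxiter": settings.max_iter * 4,
                },
            )
            fc, ro = float(res.x[0]), float(res.x[1])
            ok, it = bool(res.success), int(res.nfev)
        constants = FormulaConstants(formula=FormulaId(formula), fc=fc, ro=ro)
        return _result(
            StrategyId.D_JOINT_FC_RO, pef, constants, ok, it, pef.rmspe(fc, ro=ro)
        )
    if second == "nk":
        nk_lo, nk_hi = settings.nk_bounds
        inner_cache: dict[float, float] = {}

        def profile(nk: float) -> float:
            fc_i, _, _ = _minimize_scalar(lambda x: pef.rmspe(x, nk=nk), bounds, settings)
            inner_cache[nk] = fc_i
            return pef.rmspe(fc_i, nk=nk)

        # nested bounded 1-D searches: profile out fc for each candidate nk
        res = sopt.minimize_scalar(
            profile,
            bounds=(nk_lo + 1e-9, nk_hi - 1e-9),
            method="bounded",
            options={"xatol": 1e-9, "maxiter": settings.max_iter},
        )
        nk = float(res.x)
        fc = inner_cache[nk]
        notes = ""
        if min(nk - nk_lo, nk_hi - nk) < 1e-5:
            notes = f"nk at bound of {settings.nk_bounds}"
            logger.warning("joint FC/nK optimization: %s", notes)
        constants = FormulaConstants(formula=FormulaId(formula), fc=fc, nk=nk)
        return _result(
            StrategyId.E_JOINT_FC_NK,
            pef,
            constants,
            bool(res.success),
            int(res.nfev),
            pef.rmspe(fc, nk=nk),
            notes=notes,
        )
    raise ValueError(f"unknown second parameter {second!r}")


def two_step_gatinel(
    formula: FormulaId,
    cohort: Cohort,
    settings: OptimizerSettings = OptimizerSettings(),
    start_fc: float | None = None,
) -> OptimizationResult:
    """Two-step strategy (f): minimize SDPE over FC, then zero MPE with RO.

    In ``exact`` mode step 1 is solved to tolerance; in ``single_update``
    mode step 1 takes one damped Newton step on the numerical derivative of
    the SDPE from ``start_fc`` (default: per-formula nominal constant).
    Step 2 sets RO to the mean prediction error at the step-1 constant, so
    the mean error with the offset applied is exactly zero.
    """
    _check_cohort(cohort, settings)
    pef = _PEFunction(formula, cohort)
    bounds = _bounds(formula, settings)
    if settings.two_step_mode == "exact":
        fc, ok, it = _argmin_sdpe(pef, bounds, settings)
        notes = ""
    else:
        fc0 = start_fc if start_fc is not None else FC_DEFAULTS[FormulaId(formula)]
        h = 1e-4
        s_minus, s_0, s_plus = pef.sdpe(fc0 - h), pef.sdpe(fc0), pef.sdpe(fc0 + h)
        d1 = (s_plus - s_minus) / (2 * h)
        d2 = (s_plus - 2 * s_0 + s_minus) / h**2
        if d2 > 0 and np.isfinite(d1 / d2):
            step = -d1 / d2
        else:  # fall back to a fixed-length descent step
            step = -math.copysign(0.1, d1)
        # damp the update to at most a tenth of the search interval
        max_step = 0.1 * (bounds[1] - bounds[0])
        step = float(np.clip(step, -max_step, max_step))
        fc = float(np.clip(fc0 + step, *bounds))
        if pef.sdpe(fc) > s_0:  # monotone safeguard: never accept an ascent
            fc = fc0
        ok, it = True, 1
        notes = f"single Newton update from start fc={fc0}"
    ro = pef.mpe(fc)
    constants = FormulaConstants(formula=FormulaId(formula), fc=fc, ro=ro)
    return _result(
        StrategyId.F_TWO_STEP, pef, constants, ok, it, pef.rmspe(fc, ro=ro), notes=notes
    )


# ---------------------------------------------------------------------------
# Suite runner and report tables
# ---------------------------------------------------------------------------

_STRATEGY_RUNNERS = {
    StrategyId.A_ZERO_MPE: lambda f, c, s: optimize_fc(f, c, "zero_mpe", s),
    StrategyId.B_MIN_SDPE: lambda f, c, s: optimize_fc(f, c, "min_sdpe", s),
    StrategyId.C_MIN_RMSPE: lambda f, c, s: optimize_fc(f, c, "min_rmspe", s),
    StrategyId.D_JOINT_FC_RO: lambda f, c, s: optimize_joint(f, c, "ro", s),
    StrategyId.E_JOINT_FC_NK: lambda f, c, s: optimize_joint(f, c, "nk", s),
    StrategyId.F_TWO_STEP: lambda f, c, s: two_step_gatinel(f, c, s),
}


def run_strategy_suite(
    cohort: Cohort,
    formulas: list[FormulaId] | None = None,
    settings: OptimizerSettings = OptimizerSettings(),
    strategies: list[StrategyId] | None = None,
) -> dict[tuple[FormulaId, StrategyId], OptimizationResult | Exception]:
    """Run every strategy for every requested formula.

    Individual strategy failures are recorded as the raised exception in the
    corresponding cell; the suite continues.
    """
    formulas = [FormulaId(f) for f in (formulas or list(FormulaId))]
    strategies = [StrategyId(s) for s in (strategies or list(StrategyId))]
    out: dict[tuple[FormulaId, StrategyId], OptimizationResult | Exception] = {}
    for f in formulas:
        for s in strategies:
            try:
                out[(f, s)] = _STRATEGY_RUNNERS[s](f, cohort, settings)
            except Exception as exc:  # noqa: BLE001 - per-cell capture by contract
                logger.error("strategy %s / %s failed: %s", f.value, s.value, exc)
                out[(f, s)] = exc
    return out


def constants_table(results: dict) -> pd.DataFrame:
    """Fitted constants, one row per formula, strategy-labelled columns."""
    rows = {}
    for (f, s), res in results.items():
        row = rows.setdefault(f.value, {})
        if isinstance(res, Exception):
            row[f"fc_{s.value}"] = math.nan
            continue
        row[f"fc_{s.value}"] = res.constants.fc
        if s in (StrategyId.D_JOINT_FC_RO, StrategyId.F_TWO_STEP):
            row[f"ro_{s.value}"] = res.constants.ro
        if s is StrategyId.E_JOINT_FC_NK:
            row[f"nk_{s.value}"] = res.constants.nk
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "formula"
    return df


def metrics_table(results: dict) -> pd.DataFrame:
    """MPE/SDPE/RMSPE and |PE| quantiles per (formula, strategy) cell."""
    rows = []
    for (f, s), res in results.items():
        if isinstance(res, Exception):
            rows.append({"formula": f.value, "strategy": s.value, "error": str(res)})
            continue
        st = res.stats
        rows.append(
            {
                "formula": f.value,
                "strategy": s.value,
                "n": st.n,
                "mpe": st.mpe,
                "sdpe": st.sdpe,
                "rmspe": st.rmspe,
                "medae": st.medae,
                "abs_q25": st.abs_q25,
                "abs_q75": st.abs_q75,
                "abs_ci_lo": st.abs_ci_lo,
                "abs_ci_hi": st.abs_ci_hi,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows).set_index(["formula", "strategy"])
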