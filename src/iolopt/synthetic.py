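"""Synthetic pseudophakic cohorts with known-truth formula constants.

Generates cohorts whose biometry marginals match the descriptive statistics
of four published clinical datasets (modern monofocal IOL models measured
with an optical biometer), and whose achieved refractions are produced by a
chosen formula at known constants plus Gaussian noise.  This supports
parameter-recovery experiments: an optimizer run on a generated cohort
should return the generating constant and offset up to sampling error.

The generator emulates the marginal means/SDs of AL, ACD, LT and the mean
corneal radius R12, a plausible (package-policy) correlation structure, a
clinical target-refraction mixture, and 0.5 D labelling granularity of the
implanted power.  It does not emulate device-specific measurement error,
eye laterality, or inclusion screening.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .biometry import DEFAULT_RANGES, BiometryRecord, Cohort, write_cohort
from .formulas import FormulaConstants, FormulaId, iol_power_arrays, predict_seq_arrays

logger = logging.getLogger(__name__)

_BIOMETRY_VARS = ("al", "acd", "lt", "r12")

#: Default correlation between (AL, ACD, LT, R12).  Not identifiable from
#: published marginal summaries; values are package policy from the general
#: ocular-biometry literature: longer eyes have deeper chambers and flatter
#: corneas, deeper chambers have thinner crystalline lenses.
DEFAULT_CORRELATION = np.array(
    [
        [1.00, 0.45, 0.00, 0.35],
        [0.45, 1.00, -0.35, 0.00],
        [0.00, -0.35, 1.00, 0.00],
        [0.35, 0.00, 0.00, 1.00],
    ]
)

#: Per-dataset biometry means and SDs for (AL, ACD, LT, R12) in mm, cohort
#: sizes, and a nominal true A-constant, as published for the four lens
#: models (1: Hoya Vivinex, 2: J&J ZCB00, 3: Alcon SA60AT, 4: B&L MX60).
_PRESETS = {
    1: dict(
        n=886,
        means=(24.0922, 3.1848, 4.6215, 7.7641),
        sds=(1.4034, 0.4072, 0.4499, 0.2681),
        fc_true=119.2688,
    ),
    2: dict(
        n=613,
        means=(23.4558, 3.1755, 4.6388, 7.6729),
        sds=(1.3958, 0.4084, 0.4235, 0.2636),
        fc_true=119.4441,
    ),
    3: dict(
        n=821,
        means=(23.1467, 3.0434, 4.6219, 7.6977),
        sds=(1.5107, 0.3986, 0.4120, 0.2656),
        fc_true=118.8833,
    ),
    4: dict(
        n=467,
        means=(24.4409, 3.2443, 4.6362, 7.7424),
        sds=(2.0697, 0.3521, 0.3895, 0.2431),
        fc_true=119.2534,
    ),
}


class SyntheticConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Distributional parameters and ground truth for cohort generation.

    ``biometry_means``/``biometry_sds`` describe (AL, ACD, LT, R12) in mm;
    ``astigmatism_sd`` (D) spreads R12 into flat/steep radii r1/r2 with the
    harmonic mean preserved; ``true_formula``/``fc_true``/``ro_true`` define
    the formula that "operated" the cohort; targets are drawn from a
    two-point myopia mixture; ``noise_sd`` (D) is the refraction noise added
    to the formula-ideal achieved SEQ.
    """

    n: int = 886
    biometry_means: tuple[float, float, float, float] = _PRESETS[1]["means"]
    biometry_sds: tuple[float, float, float, float] = _PRESETS[1]["sds"]
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    astigmatism_sd: float = 0.75
    true_formula: FormulaId = FormulaId.SRKT
    fc_true: float = _PRESETS[1]["fc_true"]
    ro_true: float = 0.0
    target_mix: tuple[tuple[float, float], ...] = ((-0.25, 0.85), (-2.0, 0.15))
    iol_rounding: float = 0.5
    noise_sd: float = 0.42
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticConfigError("cohort size must be >= 1")
        if any(s <= 0 for s in self.biometry_sds):
            raise SyntheticConfigError("biometry SDs must be positive")
        if self.noise_sd < 0 or self.astigmatism_sd < 0:
            raise SyntheticConfigError("noise and astigmatism SDs must be non-negative")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise SyntheticConfigError("correlation must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise SyntheticConfigError("correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise SyntheticConfigError("correlation matrix must be positive definite")
        weights = [w for _, w in self.target_mix]
        if not np.isclose(sum(weights), 1.0) or any(w < 0 for w in weights):
            raise SyntheticConfigError("target mixture weights must be non-negative and sum to 1")
        object.__setattr__(self, "correlation", corr)

    def truth_constants(self) -> FormulaConstants:
        """The generating constants (fc_true with ro_true applied)."""
        return FormulaConstants(formula=self.true_formula, fc=self.fc_true, ro=self.ro_true)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth persisted alongside a generated cohort."""

    formula: str
    fc_true: float
    ro_true: float
    noise_sd: float
    seed: int
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def preset_config(dataset: int, **overrides) -> SyntheticConfig:
    """Generator configuration matching one of the four study datasets (1-4).

    Loads the published biometry means/SDs and cohort size; remaining fields
    take the documented defaults (noise_sd 0.42 D, SRK/T truth at the
    dataset's nominal A-constant, ro_true 0).  Keyword overrides replace any
    field.
    """
    if dataset not in _PRESETS:
        raise SyntheticConfigError(f"unknown dataset {dataset!r}; choose 1, 2, 3 or 4")
    p = _PRESETS[dataset]
    cfg = dict(
        n=p["n"],
        biometry_means=p["means"],
        biometry_sds=p["sds"],
        fc_true=p["fc_true"],
        label=f"synthetic-dataset-{dataset}",
    )
    cfg.update(overrides)
    return SyntheticConfig(**cfg)


def _sample_biometry(cfg: SyntheticConfig, rng: np.random.Generator, m: int) -> np.ndarray:
    """Draw m rows of (AL, ACD, LT, R12) from the correlated Gaussian."""
    sds = np.asarray(cfg.biometry_sds)
    cov = cfg.correlation * np.outer(sds, sds)
    return rng.multivariate_normal(np.asarray(cfg.biometry_means), cov, size=m, method="cholesky")


def generate(config: SyntheticConfig) -> tuple[Cohort, TruthRecord]:
    """Generate a cohort and its ground-truth record (deterministic per seed).

    Biometry is drawn from a truncated correlated Gaussian (resampling rows
    that violate the plausibility ranges); R12 is split into r1/r2 by a
    half-normal corneal astigmatism preserving the harmonic mean; the
    implanted power is the truth-formula power for a drawn target refraction
    rounded to the labelling step; the achieved SEQ is the truth-formula
    prediction for that power plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth_constants()
    need = config.n
    rows: list[np.ndarray] = []
    attempts = 0
    while need > 0:
        attempts += 1
        if attempts > 50:
            raise SyntheticConfigError(
                "generator exceeded resampling budget; configuration too far outside "
                "the plausibility ranges"
            )
        b = _sample_biometry(config, rng, max(need * 2, 32))
        al, acd, lt, r12 = b.T
        # split R12 into flat/steep radii with the harmonic mean preserved:
        # symmetric +/- cyl/2 split of the meridional keratometric powers
        cyl = np.abs(rng.normal(0.0, config.astigmatism_sd, size=b.shape[0]))
        k12 = 337.5 / r12
        r1 = 337.5 / (k12 - cyl / 2.0)  # flat meridian, lower power
        r2 = 337.5 / (k12 + cyl / 2.0)
        targets_pts = np.array([t for t, _ in config.target_mix])
        targets_w = np.array([w for _, w in config.target_mix])
        target = rng.choice(targets_pts, size=b.shape[0], p=targets_w)
        ok = np.ones(b.shape[0], dtype=bool)
        for arr, name in ((al, "al"), (acd, "acd"), (lt, "lt"), (r1, "r1"), (r2, "r2")):
            lo, hi = DEFAULT_RANGES[name]
            ok &= (arr > lo) & (arr < hi)
        iolp = np.full(b.shape[0], np.nan)
        iolp[ok] = iol_power_arrays(truth, al[ok], acd[ok], r12[ok], target[ok])
        if config.iol_rounding:
            iolp = np.round(iolp / config.iol_rounding) * config.iol_rounding
        lo, hi = DEFAULT_RANGES["iolp"]
        ok &= np.isfinite(iolp) & (iolp > lo) & (iolp < hi)
        seq = np.full(b.shape[0], np.nan)
        seq[ok] = predict_seq_arrays(truth, al[ok], acd[ok], r12[ok], iolp[ok])
        seq[ok] += rng.normal(0.0, config.noise_sd, size=int(ok.sum()))
        lo, hi = DEFAULT_RANGES["seq_achieved"]
        ok &= np.isfinite(seq) & (seq > lo) & (seq < hi)
        n_rej = int(b.shape[0] - ok.sum())
        if n_rej:
            logger.debug("generate: resampled %d row(s) outside plausibility ranges", n_rej)
        kept = np.column_stack([al, acd, lt, r1, r2, iolp, seq])[ok]
        rows.append(kept[:need])
        need -= min(need, kept.shape[0])
    data = np.vstack(rows)
    records = [
        BiometryRecord(
            eye_id=f"syn-{i:05d}",
            al=float(row[0]),
            acd=float(row[1]),
            lt=float(row[2]),
            r1=float(row[3]),
            r2=float(row[4]),
            iolp=float(row[5]),
            seq_achieved=float(row[6]),
        )
        for i, row in enumerate(data)
    ]
    cohort = Cohort(records=records, label=config.label)
    truth_rec = TruthRecord(
        formula=FormulaId(config.true_formula).value,
        fc_true=config.fc_true,
        ro_true=config.ro_true,
        noise_sd=config.noise_sd,
        seed=config.seed,
        n=config.n,
    )
    return cohort, truth_rec


def write_synthetic(config: SyntheticConfig, cohort_path, truth_path=None) -> Cohort:
    """Generate and write a cohort CSV plus a sidecar ground-truth JSON."""
    cohort, truth = generate(config)
    write_cohort(cohort, cohort_path)
    if truth_path is None:
        truth_path = str(cohort_path) + ".truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write(truth.to_json() + "\n")
    return cohort
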