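"""Ocular biometry records, cohort CSV I/O, keratometry and descriptive statistics.

A pseudophakic study cohort is a table with one row per eye carrying the
preoperative optical-biometry measures (axial length AL, external anterior
chamber depth ACD, lens thickness LT, flat/steep corneal front radii R1/R2),
the labelled power of the implanted IOL, and the achieved postoperative
spherical-equivalent refraction (SEQ) at the spectacle plane.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Javal keratometer index used to convert a corneal radius (mm) to a
#: keratometric power (D): K = (nK - 1) * 1000 / r.
JAVAL_INDEX = 1.3375

#: Canonical CSV column names, in file order.
CANONICAL_COLUMNS = ("eye_id", "al_mm", "acd_mm", "lt_mm", "r1_mm", "r2_mm", "iolp_d", "seq_d")

#: Plausibility ranges (open intervals) enforced on records.  These are
#: package policy for screening gross data errors, not clinical inclusion
#: criteria; override via ``validation_ranges=`` where supported.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "al": (15.0, 40.0),
    "acd": (1.5, 6.0),
    "lt": (2.5, 7.0),
    "r1": (5.5, 11.0),
    "r2": (5.5, 11.0),
    "iolp": (-10.0, 40.0),
    "seq_achieved": (-15.0, 10.0),
}


class BiometryError(ValueError):
    """Invalid biometry value or malformed cohort input."""


class InsufficientDataError(ValueError):
    """Operation needs more records than the cohort provides."""


def mean_corneal_radius(r1: float, r2: float) -> float:
    """Harmonic mean of the flat- and steep-meridian corneal radii (mm).

    The harmonic mean of the radii corresponds to the arithmetic mean of the
    two meridional keratometric powers, so the single equivalent radius R12
    preserves the eye's mean corneal power.
    """
    r1a, r2a = np.asarray(r1, dtype=float), np.asarray(r2, dtype=float)
    if np.any(r1a <= 0) or np.any(r2a <= 0):
        raise BiometryError("corneal radii must be positive")
    out = 2.0 * r1a * r2a / (r1a + r2a)
    return float(out) if out.ndim == 0 else out


def keratometric_power(r12: float, nk: float = JAVAL_INDEX) -> float:
    """Convert a corneal radius r12 (mm) to keratometric power K (D).

    K = (nK - 1) * 1000 / r12 with the keratometer index nK (Javal value
    1.3375 by default).
    """
    r = np.asarray(r12, dtype=float)
    if np.any(r <= 0):
        raise BiometryError("corneal radius must be positive")
    if not 1.0 < float(nk) < 1.5:
        raise BiometryError(f"keratometer index {nk} outside (1.0, 1.5)")
    out = (nk - 1.0) * 1000.0 / r
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BiometryRecord:
    """One eye: preoperative biometry, implanted IOL power, achieved SEQ.

    Units: mm for al/acd/lt/r1/r2, diopters for iolp and seq_achieved.
    ACD is the external phakic anterior chamber depth (corneal epithelium to
    crystalline lens apex).  seq_achieved is the postoperative spherical
    equivalent at the spectacle plane.
    """

    eye_id: str
    al: float
    acd: float
    lt: float
    r1: float
    r2: float
    iolp: float
    seq_achieved: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in DEFAULT_RANGES.items():
            v = getattr(self, name)
            if not math.isfinite(v):
                raise BiometryError(f"eye {self.eye_id}: {name}={v!r} is not finite")
            if not lo < v < hi:
                raise BiometryError(
                    f"eye {self.eye_id}: {name}={v} outside plausibility range ({lo}, {hi})"
                )

    @property
    def r12(self) -> float:
        """Harmonic-mean corneal radius (mm)."""
        return mean_corneal_radius(self.r1, self.r2)


@dataclass
class Cohort:
    """Ordered collection of :class:`BiometryRecord` with unique eye ids."""

    records: list[BiometryRecord]
    label: str = ""
    _arrays: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise BiometryError("a cohort needs at least one record")
        ids = [r.eye_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise BiometryError(f"duplicate eye_id in cohort {self.label!r}")

    def __len__(self) -> int:
        return len(self.records)

    def arrays(self) -> dict[str, np.ndarray]:
        """Column arrays (al, acd, lt, r1, r2, r12, iolp, seq) for vectorized math."""
        if self._arrays is None:
            cols = {
                name: np.array([getattr(r, name) for r in self.records], dtype=float)
                for name in ("al", "acd", "lt", "r1", "r2", "iolp", "seq_achieved")
            }
            cols["r12"] = mean_corneal_radius(cols["r1"], cols["r2"])
            self._arrays = cols
        return self._arrays

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame with canonical column names."""
        return pd.DataFrame(
            {
                "eye_id": [r.eye_id for r in self.records],
                "al_mm": [r.al for r in self.records],
                "acd_mm": [r.acd for r in self.records],
                "lt_mm": [r.lt for r in self.records],
                "r1_mm": [r.r1 for r in self.records],
                "r2_mm": [r.r2 for r in self.records],
                "iolp_d": [r.iolp for r in self.records],
                "seq_d": [r.seq_achieved for r in self.records],
            }
        )


_FIELD_BY_COLUMN = {
    "eye_id": "eye_id",
    "al_mm": "al",
    "acd_mm": "acd",
    "lt_mm": "lt",
    "r1_mm": "r1",
    "r2_mm": "r2",
    "iolp_d": "iolp",
    "seq_d": "seq_achieved",
}


def read_cohort(
    path,
    dialect: dict[str, str] | None = None,
    label: str = "",
    strict: bool = True,
) -> Cohort:
    """Read a cohort CSV (UTF-8, one header row, period decimal separator).

    Parameters
    ----------
    path
        CSV file with the canonical columns (``eye_id, al_mm, acd_mm, lt_mm,
        r1_mm, r2_mm, iolp_d, seq_d``) or columns mappable to them.
    dialect
        Optional ``{canonical_name: file_column_name}`` mapping for foreign
        exports.
    strict
        If True (default) any row failing the plausibility invariants raises;
        if False such rows are dropped with a logged, row-indexed diagnostic.
        Unparseable numeric cells always raise, naming the offending row.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise BiometryError(f"{path}: unreadable cohort CSV ({exc})") from None
    dialect = dialect or {}
    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise BiometryError(f"{path}: missing required column(s) {missing}; have {list(df.columns)}")

    records: list[BiometryRecord] = []
    rejected: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        eye_id = str(row[colmap["eye_id"]])
        values = {}
        for canon in CANONICAL_COLUMNS[1:]:
            cell = row[colmap[canon]]
            try:
                values[_FIELD_BY_COLUMN[canon]] = float(cell)
            except (TypeError, ValueError):
                raise BiometryError(
                    f"{path}: row {idx + 1} (line {line}, eye {eye_id}): "
                    f"cannot parse {colmap[canon]}={cell!r} as a number"
                ) from None
        try:
            records.append(BiometryRecord(eye_id=eye_id, **values))
        except BiometryError as exc:
            msg = f"{path}: row {idx + 1} (line {line}): {exc}"
            if strict:
                raise BiometryError(msg) from None
            rejected.append(msg)
    if rejected:
        logger.warning("read_cohort: rejected %d row(s):\n%s", len(rejected), "\n".join(rejected))
    if not records:
        raise BiometryError(f"{path}: no valid records")
    return Cohort(records=records, label=label or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV with canonical column names (round-trips with read_cohort)."""
    cohort.to_frame().to_csv(path, index=False, float_format="%.6f")


_STAT_ROWS = ("Mean", "SD", "Median", "Quantile 2.5%", "Quantile 97.5%")
_DESC_COLUMNS = ("AL", "ACD", "LT", "R12", "K12", "PIOL", "SEQ")


def describe(cohort: Cohort, nk: float = JAVAL_INDEX) -> pd.DataFrame:
    """Descriptive statistics table: mean, SD, median, 2.5%/97.5% quantiles.

    Columns are AL/ACD/LT (mm), the harmonic-mean corneal radius R12 (mm),
    the keratometric power K12 (D, converted from R12 with ``nk``), the
    implanted IOL power PIOL (D) and the achieved SEQ (D).  SD is the sample
    standard deviation (n-1 denominator); quantiles use linear interpolation
    between order statistics (the "type 7" convention).
    """
    if len(cohort) < 2:
        raise InsufficientDataError("descriptive statistics need at least 2 records")
    a = cohort.arrays()
    cols = {
        "AL": a["al"],
        "ACD": a["acd"],
        "LT": a["lt"],
        "R12": a["r12"],
        "K12": keratometric_power(a["r12"], nk),
        "PIOL": a["iolp"],
        "SEQ": a["seq_achieved"],
    }
    data = {
        name: [
            float(np.mean(v)),
            float(np.std(v, ddof=1)),
            float(np.median(v)),
            float(np.quantile(v, 0.025)),
            float(np.quantile(v, 0.975)),
        ]
        for name, v in cols.items()
    }
    return pd.DataFrame(data, index=list(_STAT_ROWS))[list(_DESC_COLUMNS)]
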