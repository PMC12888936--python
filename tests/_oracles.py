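"""Independent oracle transcriptions used by the tests.

These reimplement the four formulae directly from their published expanded
closed-form refraction equations (straight-line algebra, vectorized over
eyes and over a grid of candidate constants).  They share no code with the
package's vergence-propagation engine and serve as the second-transcription
and grid-search oracles.
"""

from __future__ import annotations

import numpy as np

V = 12.0  # spectacle vertex distance, mm


def srkt_ref(a_const, al, r, p):
    """SRK/T predicted spectacle refraction, expanded published form."""
    a_const, al, r, p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a_const, al, r, p))
    )
    k = 337.5 / r
    lcor = np.where(al > 24.2, -3.446 + 1.715 * al - 0.0237 * al**2, al)
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    h = r - np.sqrt(np.maximum(r**2 - cw**2 / 4.0, 0.0))
    acd = h + (0.62467 * a_const - 68.747) - 3.336
    lopt = al + (0.65696 - 0.02029 * al)
    na, ncm1 = 1.336, 0.333
    num = 1000.0 * na * (na * r - ncm1 * lopt) - p * (lopt - acd) * (na * r - ncm1 * acd)
    den = na * (V * (na * r - ncm1 * lopt) + lopt * r) - 0.001 * p * (lopt - acd) * (
        V * (na * r - ncm1 * acd) + acd * r
    )
    return num / den


def hofferq_ref(pacd, al, r, p):
    """Hoffer Q predicted spectacle refraction, solved from the published power equation."""
    pacd, al, r, p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (pacd, al, r, p))
    )
    k = 337.5 / r
    alc = np.clip(al, 18.5, 31.0)
    m = np.where(alc <= 23.0, 1.0, -1.0)
    g = np.where(alc <= 23.0, 28.0, 23.5)
    tan = lambda deg: np.tan(np.deg2rad(deg))
    acd = (
        pacd
        + 0.3 * (alc - 23.5)
        + tan(k) ** 2
        + 0.1 * m * (23.5 - alc) ** 2 * tan(0.1 * (g - alc) ** 2)
        - 0.99166
    )
    q = 1336.0 / (al - acd - 0.05) - p
    rc = 1.336 / (1.336 / q + (acd + 0.05) / 1000.0) - k
    return rc / (1.0 + (V / 1000.0) * rc)


def holladay1_ref(sf, al, r, p):
    """Holladay 1 predicted spectacle refraction, expanded published form."""
    sf, al, r, p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (sf, al, r, p))
    )
    ag = np.minimum(12.5 * al / 23.45, 13.5)
    rag = np.maximum(r, 7.0)
    acd = 0.56 + rag - np.sqrt(np.maximum(rag**2 - ag**2 / 4.0, 0.0))
    c = acd + sf
    alm = al + 0.2
    na, ncm1 = 1.336, 1.0 / 3.0
    num = 1000.0 * na * (na * r - ncm1 * alm) - p * (alm - c) * (na * r - ncm1 * c)
    den = na * (V * (na * r - ncm1 * alm) + alm * r) - 0.001 * p * (alm - c) * (
        V * (na * r - ncm1 * c) + c * r
    )
    return num / den


def haigis_ref(a0, al, acd, r, p, a1=0.4, a2=0.1):
    """Simplified Haigis predicted spectacle refraction (corneal index 1.3315)."""
    a0, al, acd, r, p = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a0, al, acd, r, p))
    )
    d = a0 + a1 * acd + a2 * al
    dc = 331.5 / r
    x = 1336.0 / (al - d) - p
    rc = 1336.0 / (1336.0 / x + d) - dc
    return rc / (1.0 + (V / 1000.0) * rc)


#: formula name -> oracle(fc, al, acd, r12, iolp) -> predicted SEQ
ORACLES = {
    "SRKT": lambda fc, al, acd, r, p: srkt_ref(fc, al, r, p),
    "HofferQ": lambda fc, al, acd, r, p: hofferq_ref(fc, al, r, p),
    "Holladay1": lambda fc, al, acd, r, p: holladay1_ref(fc, al, r, p),
    "Haigis": lambda fc, al, acd, r, p: haigis_ref(fc, al, acd, r, p),
}

#: grid ranges for exhaustive constant searches, per formula
GRID_RANGES = {
    "SRKT": (116.0, 122.0),
    "HofferQ": (3.5, 8.0),
    "Holladay1": (0.0, 4.0),
    "Haigis": (-1.0, 3.5),
}


def grid_argmin(formula_name, cohort, objective, lo, hi, step=1e-4, chunk=400):
    """Exhaustive grid search for the constant minimizing a PE metric.

    ``objective`` is one of ``"abs_mpe"``, ``"sdpe"``, ``"rmspe"``.  Works in
    chunks of grid points to bound memory; evaluation goes through the
    oracle transcriptions, independent of the package optimizer.
    """
    a = cohort.arrays()
    al, acd, r12, iolp, seq = a["al"], a["acd"], a["r12"], a["iolp"], a["seq_achieved"]
    oracle = ORACLES[formula_name]
    grid = np.arange(lo, hi + step / 2, step)
    best_val, best_fc = np.inf, None
    for start in range(0, grid.size, chunk):
        fcs = grid[start : start + chunk][:, None]
        pe = seq[None, :] - oracle(fcs, al[None, :], acd[None, :], r12[None, :], iolp[None, :])
        if objective == "abs_mpe":
            vals = np.abs(pe.mean(axis=1))
        elif objective == "sdpe":
            vals = pe.std(axis=1, ddof=1)
        elif objective == "rmspe":
            vals = np.sqrt((pe**2).mean(axis=1))
        else:
            raise ValueError(objective)
        i = int(np.argmin(vals))
        if vals[i] < best_val:
            best_val, best_fc = float(vals[i]), float(fcs[i, 0])
    return best_fc, best_val
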