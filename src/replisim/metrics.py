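"""Small shared numerical helpers: masked correlations, coarsening, slopes."""

from __future__ import annotations

import numpy as np

__all__ = ["pearson", "through_origin_slope", "coarsen", "score_pair"]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over bins where both arrays are finite."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x with no intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    d = float(np.sum(x[ok] ** 2))
    if d == 0:
        return float("nan")
    return float(np.sum(x[ok] * y[ok]) / d)


def coarsen(values: np.ndarray, factor: int) -> np.ndarray:
    """Average consecutive groups of ``factor`` bins (NaN-aware).

    Trailing bins that do not fill a group are dropped.
    """
    n = values.size // factor
    v = values[: n * factor].reshape(n, factor)
    with np.errstate(invalid="ignore"):
        return np.nanmean(v, axis=1)


def score_pair(sim_pair, exp_pair, mrt_factor: int = 2) -> tuple[float, float]:
    """(PCC_MRT, PCC_RFD) between two profile pairs.

    MRT is compared after coarsening ``mrt_factor`` bins together (10 kb for
    a 5 kb lattice); RFD is compared at native resolution.  The union of the
    two pairs' masks is applied first.
    """
    bad = ~sim_pair.usable | ~exp_pair.usable
    ms, me = sim_pair.mrt.values.copy(), exp_pair.mrt.values.copy()
    rs, re = sim_pair.rfd.values.copy(), exp_pair.rfd.values.copy()
    for v in (ms, me, rs, re):
        v[bad] = np.nan
    pcc_mrt = pearson(coarsen(ms, mrt_factor), coarsen(me, mrt_factor))
    pcc_rfd = pearson(rs, re)
    return pcc_mrt, pcc_rfd
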