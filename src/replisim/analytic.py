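"""Closed-form origin-strength machinery.

With ``n(x)`` potential origins in a bin, reaction rate ``kon`` and free
firing factors ``F_free(t)``, the probability that the bin has fired by time
``t`` (ignoring passivation) is ``A_x(t) = 1 - exp(-kon n(x) int_0^t F_free)``.
Because a small bin is almost always replicated passively, its passivation
time is close to its mean replication time, so the observed origin
efficiency is ``OE(x) = A_x(MRT_t(x))``.  Inverting this relation yields
per-bin estimates of ``n(x)`` from measurable quantities: RFD upshifts
(``OE = dRFD/2`` at initiation zones) and MRT.  Three estimator variants are
provided: the exact integral form, a constant-``F_free`` approximation
(``~ 1/MRT``), and an empirical exponential-decay form
(``~ dRFD * exp(-6 MRT)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .lattice import Profile
from .simulate import rescale_kon  # noqa: F401  (re-exported convenience)

__all__ = [
    "FfreeTrace",
    "IZCall",
    "predicted_oe",
    "delta_rfd",
    "detect_izs",
    "estimate_n",
    "ipls_from_data",
]


@dataclass
class FfreeTrace:
    """Step trace of free firing factors over time.

    ``counts[i]`` holds between ``times[i]`` (inclusive) and ``times[i+1]``;
    the last value extends to infinity.
    """

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValueError("times and counts must be 1-D and equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def integral(self, t: np.ndarray | float) -> np.ndarray | float:
        """``int_0^t F_free(u) du`` by exact step quadrature (vectorised)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        # cumulative integral up to each step start
        widths = np.diff(self.times)
        cum = np.concatenate([[0.0], np.cumsum(self.counts[:-1] * widths)])
        idx = np.clip(np.searchsorted(self.times, t_arr, side="right") - 1, 0, None)
        out = np.where(
            t_arr <= self.times[0],
            0.0,
            cum[idx] + self.counts[idx] * (t_arr - self.times[idx]),
        )
        out = np.where(np.isnan(t_arr), np.nan, out)
        return out if np.ndim(t) else float(out[0])

    def mean_level(self, t_end: float) -> float:
        """Average free-factor count over [0, t_end] (the constant [F_free])."""
        return float(self.integral(t_end)) / t_end


@dataclass
class IZCall:
    """One detected initiation zone: a local maximum of the dRFD profile."""

    bin: int
    delta_rfd: float
    width_bins: float


def predicted_oe(
    n: np.ndarray | float,
    mrt_t: np.ndarray | float,
    trace: FfreeTrace,
    kon: float,
) -> np.ndarray | float:
    """Closed-form observed efficiency ``1 - exp(-kon n int_0^MRT_t F_free)``."""
    n_arr = np.asarray(n, dtype=float)
    m_arr = np.asarray(mrt_t, dtype=float)
    if np.nanmin(n_arr) < 0 or np.nanmin(m_arr) < 0 or kon < 0:
        raise ValueError("n, mrt_t and kon must be non-negative")
    integ = trace.integral(m_arr)
    out = 1.0 - np.exp(-kon * n_arr * integ)
    return out if (np.ndim(n) or np.ndim(mrt_t)) else float(out)


def delta_rfd(
    rfd: Profile,
    smooth_kb: float = 15.0,
    keep_top_fraction: float = 0.15,
) -> Profile:
    """RFD increment profile, thresholded to its strongest upshifts.

    The RFD profile is smoothed (running mean over ``smooth_kb``), the first
    difference between consecutive bins is taken within each chromosome,
    negative increments are zeroed, and only the top ``keep_top_fraction``
    of unmasked bins keep their value (the rest are set to 0).
    """
    from .lattice import smooth as _smooth

    lat = rfd.lattice
    sm = _smooth(rfd, smooth_kb).values
    d = np.zeros(lat.n_bins)
    off = lat.chrom_offsets
    for c in range(len(lat.chrom_names)):
        lo, hi = int(off[c]), int(off[c + 1])
        d[lo + 1 : hi] = np.diff(sm[lo:hi])
        d[lo] = 0.0
    d = np.nan_to_num(d, nan=0.0)
    d[d < 0] = 0.0
    d[d < 1e-12] = 0.0  # rounding residue from the running mean
    open_idx = np.flatnonzero(~lat.mask)
    if open_idx.size == 0:
        raise ValueError("no unmasked bins")
    k = int(np.ceil(keep_top_fraction * open_idx.size))
    vals = d[open_idx]
    if k < vals.size:
        keep = np.argpartition(vals, -k)[-k:]
        out = np.zeros(lat.n_bins)
        out[open_idx[keep]] = vals[keep]
    else:
        out = d.copy()
    out[lat.mask] = 0.0
    return Profile(out, "generic", lat)


def detect_izs(
    drfd: Profile,
    min_width_bins: float = 4,
    min_height: float = 0.02,
) -> list[IZCall]:
    """Initiation-zone calls: local maxima of dRFD with height and width floors.

    Width is measured at half prominence (``scipy.signal.find_peaks``
    semantics).  Calls are returned sorted by position.
    """
    vals = np.nan_to_num(drfd.values, nan=0.0)
    if (vals < 0).any():
        raise ValueError("dRFD profile must be non-negative")
    with warnings.catch_warnings():
        # scipy flags zero-width plateau candidates that the width floor
        # discards anyway
        warnings.simplefilter("ignore")
        peaks, props = find_peaks(vals, height=min_height, width=min_width_bins)
    return [
        IZCall(int(b), float(h), float(w))
        for b, h, w in zip(peaks, props["peak_heights"], props["widths"])
    ]


def estimate_n(
    drfd: Profile,
    mrt_t: Profile,
    trace: FfreeTrace,
    kon: float,
) -> Profile:
    """Potential-origin count per bin from dRFD and MRT (exact inverse of
    :func:`predicted_oe` with OE = dRFD/2):

        n_e(x) = -ln(1 - dRFD(x)/2) / (kon int_0^MRT_t(x) F_free du)

    Bins with dRFD = 0 get 0; dRFD/2 >= 1 anywhere raises (log divergence).
    """
    d = np.nan_to_num(drfd.values, nan=0.0)
    if (d / 2.0 >= 1.0).any():
        raise ValueError("dRFD/2 must be < 1 everywhere")
    out = np.zeros_like(d)
    nz = d > 0
    integ = trace.integral(mrt_t.values[nz])
    denom = kon * np.asarray(integ)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[nz] = -np.log(1.0 - d[nz] / 2.0) / denom
    out[~np.isfinite(out)] = 0.0
    return Profile(out, "generic", drfd.lattice)


def ipls_from_data(
    drfd: Profile,
    mrt: Profile,
    variant: str = "exp6",
    T_S: float = 720.0,
    trace: FfreeTrace | None = None,
    kon: float = 1.0,
    f_free_const: float = 1.0,
    exponent: float = 6.0,
) -> Profile:
    """IPLS estimated from dRFD and MRT profiles.

    Variants (all normalised to sum 1 over unmasked bins, negatives clipped):

    * ``integral`` — exact form ``-ln(1 - dRFD/2) / (kon int_0^{MRT*T_S} F_free)``
      (requires ``trace`` and ``kon``);
    * ``inverse_mrt`` — constant-``F_free`` approximation
      ``-ln(1 - dRFD/2) / (kon MRT T_S [F_free])``; MRT = 0 bins are excluded
      with a warning;
    * ``exp6`` — empirical form ``dRFD * exp(-exponent * MRT)`` with MRT in
      S-phase-fraction units (the overall scale cancels on normalisation).
    """
    d = np.nan_to_num(drfd.values, nan=0.0).clip(min=0.0)
    m = mrt.values
    lat = drfd.lattice
    if variant == "integral":
        if trace is None:
            raise ValueError("variant 'integral' requires an F_free trace")
        est = estimate_n(Profile(d, "generic", lat), Profile(m * T_S, "mrt_time", lat), trace, kon)
        out = est.values
    elif variant == "inverse_mrt":
        out = np.zeros_like(d)
        nz = d > 0
        zero_mrt = nz & ~(m > 0)
        if zero_mrt.any():
            warnings.warn(
                f"{int(zero_mrt.sum())} bins with MRT = 0 excluded from the "
                "inverse-MRT estimator",
                stacklevel=2,
            )
        use = nz & (m > 0)
        out[use] = -np.log(1.0 - d[use] / 2.0) / (kon * m[use] * T_S * f_free_const)
    elif variant == "exp6":
        out = d * np.exp(-exponent * np.nan_to_num(m, nan=np.inf))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out = np.nan_to_num(out, nan=0.0).clip(min=0.0)
    return Profile(out, "generic", lat).normalised()
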