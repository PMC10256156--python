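"""Binned genome lattice and per-bin signal containers.

The whole package works on a fixed-resolution lattice (5 kb bins by default):
chromosomes are concatenated into one flat bin axis, and every genome-wide
signal (MRT, RFD, an initiation probability landscape, ...) is a vector with
one value per bin.  Two distinct "absent data" states are used throughout:

* *missing* — the experiment reported nothing for the bin; stored as NaN;
* *masked* — the bin is excluded from all analyses (telomeric/centromeric
  gaps and their flanks); stored in :attr:`GenomeLattice.mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLattice",
    "Profile",
    "ProfilePair",
    "build_gap_mask",
    "smooth",
]

#: Recognised profile kinds.
PROFILE_KINDS = ("mrt_fraction", "mrt_time", "rfd", "ipls", "generic")


@dataclass
class GenomeLattice:
    """A genome binned at fixed resolution.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers, in order.
    chrom_len_bins
        Number of bins per chromosome.
    bin_size_kb
        Bin length in kb (default 5).
    mask
        Boolean per bin, ``True`` = excluded from analysis.  Defaults to all
        ``False``.
    """

    chrom_names: list[str]
    chrom_len_bins: list[int]
    bin_size_kb: float = 5.0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_size_kb <= 0:
            raise ValueError("bin_size_kb must be positive")
        if len(self.chrom_names) != len(self.chrom_len_bins):
            raise ValueError("chrom_names and chrom_len_bins length mismatch")
        if any(n <= 0 for n in self.chrom_len_bins):
            raise ValueError("chromosome lengths must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ValueError("mask length must equal total bin count")

    @property
    def n_bins(self) -> int:
        return int(sum(self.chrom_len_bins))

    @property
    def length_kb(self) -> float:
        """Total genome length L in kb."""
        return self.n_bins * self.bin_size_kb

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Start index of each chromosome on the flat bin axis (plus a final sentinel)."""
        return np.concatenate([[0], np.cumsum(self.chrom_len_bins)]).astype(np.int64)

    def chrom_slice(self, name: str) -> slice:
        try:
            i = self.chrom_names.index(name)
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None
        off = self.chrom_offsets
        return slice(int(off[i]), int(off[i + 1]))

    def chrom_of_bin(self, bin_index: int) -> str:
        off = self.chrom_offsets
        i = int(np.searchsorted(off, bin_index, side="right")) - 1
        if i < 0 or bin_index >= off[-1]:
            raise IndexError(f"bin {bin_index} outside genome")
        return self.chrom_names[i]

    def bin_centers_kb(self) -> np.ndarray:
        """Bin-center coordinate (kb) on the concatenated axis."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_size_kb

    def segments(self, extra_mask: np.ndarray | None = None) -> list[tuple[int, int]]:
        """Contiguous runs of unmasked bins, never spanning a chromosome boundary.

        Returns half-open ``(start, stop)`` bin-index pairs.
        """
        bad = self.mask.copy()
        if extra_mask is not None:
            bad |= np.asarray(extra_mask, dtype=bool)
        segs: list[tuple[int, int]] = []
        off = self.chrom_offsets
        for c in range(len(self.chrom_names)):
            lo, hi = int(off[c]), int(off[c + 1])
            good = ~bad[lo:hi]
            if not good.any():
                continue
            # boundaries of runs of True
            d = np.diff(np.concatenate([[0], good.view(np.int8), [0]]))
            starts = np.flatnonzero(d == 1)
            stops = np.flatnonzero(d == -1)
            segs.extend((lo + int(a), lo + int(b)) for a, b in zip(starts, stops))
        return segs

    def copy(self) -> "GenomeLattice":
        return GenomeLattice(
            list(self.chrom_names),
            list(self.chrom_len_bins),
            self.bin_size_kb,
            self.mask.copy(),
        )


@dataclass
class Profile:
    """A per-bin signal on a :class:`GenomeLattice`.

    ``values`` holds one float per bin; NaN marks missing data.  ``kind``
    selects validation rules: RFD in [-1, 1], MRT fraction in [0, 1], IPLS
    non-negative and summing to 1 over unmasked bins.
    """

    values: np.ndarray
    kind: str = "generic"
    lattice: GenomeLattice = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lattice is None:
            raise ValueError("Profile requires a lattice")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lattice.n_bins,):
            raise ValueError("values length must equal lattice bin count")
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")

    def validate(self) -> None:
        """Raise ``ValueError`` if the profile violates its kind's invariants."""
        ok = ~self.lattice.mask & np.isfinite(self.values)
        v = self.values[ok]
        if self.kind == "rfd":
            if v.size and (v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("RFD values must lie in [-1, 1]")
        elif self.kind == "mrt_fraction":
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("MRT fraction must lie in [0, 1]")
        elif self.kind == "ipls":
            if v.size and v.min() < -1e-12:
                raise ValueError("IPLS values must be non-negative")
            if v.size and not np.isclose(v.sum(), 1.0, atol=1e-6):
                raise ValueError("IPLS must sum to 1 over unmasked bins")

    @property
    def defined(self) -> np.ndarray:
        """Bins that are neither masked nor missing."""
        return ~self.lattice.mask & np.isfinite(self.values)

    def copy(self, kind: str | None = None) -> "Profile":
        return Profile(self.values.copy(), kind or self.kind, self.lattice)

    def normalised(self) -> "Profile":
        """Return a copy rescaled to sum 1 over unmasked, finite bins (kind 'ipls')."""
        out = np.where(self.lattice.mask, 0.0, np.nan_to_num(self.values, nan=0.0))
        total = out.sum()
        if total <= 0:
            raise ValueError("cannot normalise an all-zero profile")
        return Profile(out / total, "ipls", self.lattice)


@dataclass
class ProfilePair:
    """Aligned MRT and RFD profiles sharing a lattice and a gap mask."""

    mrt: Profile
    rfd: Profile
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mrt.lattice is not self.rfd.lattice:
            raise ValueError("MRT and RFD must share a lattice")
        if self.mask is None:
            self.mask = build_gap_mask([self.mrt, self.rfd])
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.mrt.lattice.n_bins,):
                raise ValueError("mask length mismatch")

    @property
    def lattice(self) -> GenomeLattice:
        return self.mrt.lattice

    @property
    def usable(self) -> np.ndarray:
        """Bins usable for comparisons: unmasked and defined in both profiles."""
        return (
            ~self.mask
            & ~self.lattice.mask
            & np.isfinite(self.mrt.values)
            & np.isfinite(self.rfd.values)
        )


def _missing_runs(defined: np.ndarray) -> Iterator[tuple[int, int]]:
    d = np.diff(np.concatenate([[1], defined.view(np.int8), [1]]))
    starts = np.flatnonzero(d == -1)
    stops = np.flatnonzero(d == 1)
    yield from zip(starts, stops)


def build_gap_mask(
    profiles: Sequence[Profile],
    gap_len_kb: float = 1500.0,
    flank_kb: float = 500.0,
    include_short: bool = True,
) -> np.ndarray:
    """Mask data gaps, extended by a flank on each side.

    Any run of missing bins longer than ``gap_len_kb`` in any profile is
    masked together with ``flank_kb`` on each side (the rule used before any
    simulation).  With ``include_short`` (the default, appropriate whenever
    profiles are compared bin-wise), shorter missing runs are masked with the
    same flanks as well.  The result is the union across profiles, clipped at
    chromosome boundaries.
    """
    if flank_kb < 0:
        raise ValueError("flank_kb must be non-negative")
    if not profiles:
        raise ValueError("need at least one profile")
    lat = profiles[0].lattice
    for p in profiles[1:]:
        if p.lattice is not lat:
            raise ValueError("profiles must share a lattice")
    flank = int(round(flank_kb / lat.bin_size_kb))
    mask = np.zeros(lat.n_bins, dtype=bool)
    off = lat.chrom_offsets
    for p in profiles:
        defined = np.isfinite(p.values)
        for c in range(len(lat.chrom_names)):
            lo, hi = int(off[c]), int(off[c + 1])
            for a, b in _missing_runs(defined[lo:hi]):
                run_kb = (b - a) * lat.bin_size_kb
                if run_kb > gap_len_kb or include_short:
                    mask[max(lo, lo + a - flank) : min(hi, lo + b + flank)] = True
    return mask


def smooth(profile: Profile, window_kb: float) -> Profile:
    """Centered running mean over ``window_kb``.

    The window is truncated to the available data at chromosome ends and at
    the edges of data gaps; masked bins never contribute.  A missing bin is
    filled by the windowed mean only when at least half the window is
    present, which prevents values bleeding deep into gaps.
    """
    lat = profile.lattice
    w = window_kb / lat.bin_size_kb
    if window_kb < lat.bin_size_kb or abs(w - round(w)) > 1e-9:
        raise ValueError("window_kb must be a positive multiple of the bin size")
    w = int(round(w))
    left, right = (w - 1) // 2, w // 2

    out = np.full(lat.n_bins, np.nan)
    off = lat.chrom_offsets
    for c in range(len(lat.chrom_names)):
        lo, hi = int(off[c]), int(off[c + 1])
        vals = profile.values[lo:hi]
        valid = np.isfinite(vals) & ~lat.mask[lo:hi]
        x = np.where(valid, vals, 0.0)
        cx = np.concatenate([[0.0], np.cumsum(x)])
        cn = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
        n = hi - lo
        i = np.arange(n)
        a = np.maximum(i - left, 0)
        b = np.minimum(i + right + 1, n)
        counts = cn[b] - cn[a]
        sums = cx[b] - cx[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        res = np.full(n, np.nan)
        res[valid] = mean[valid]
        fillable = ~valid & ~lat.mask[lo:hi] & (counts >= (w + 1) // 2)
        res[fillable] = mean[fillable]
        out[lo:hi] = res
    out[lat.mask] = np.nan
    return Profile(out, profile.kind, lat)
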