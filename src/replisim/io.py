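"""Reading and writing binned genome signals in standard track formats.

Supported inputs are 4-column bedGraph, BED3/BED5 peak files and fixed-step
wiggle.  Coordinates are 0-based half-open (bedGraph/BED convention; wiggle's
1-based starts are converted on read).  Bin *i* of a chromosome covers
``[i*bin, (i+1)*bin)`` in bp.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import GenomeLattice, Profile

__all__ = ["read_profile", "write_profile", "lattice_from_chrom_sizes"]


def lattice_from_chrom_sizes(sizes_bp: dict[str, int], bin_size_kb: float = 5.0) -> GenomeLattice:
    """Build a lattice from chromosome sizes in bp (lengths rounded up to whole bins)."""
    bin_bp = int(round(bin_size_kb * 1000))
    names = list(sizes_bp)
    nbins = [int(-(-sizes_bp[n] // bin_bp)) for n in names]
    return GenomeLattice(names, nbins, bin_size_kb)


def _bin_intervals(
    lattice: GenomeLattice,
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    value: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Aggregate (chrom, start, end, value) intervals into per-bin values.

    mode 'mean': coverage-weighted mean per bin (bedGraph); uncovered bins NaN.
    mode 'coverage': sum of covered bp times value per bin (BED peaks);
    uncovered bins 0.
    """
    bin_bp = int(round(lattice.bin_size_kb * 1000))
    off = lattice.chrom_offsets
    wsum = np.zeros(lattice.n_bins)
    wtot = np.zeros(lattice.n_bins)
    name_to_idx = {n: i for i, n in enumerate(lattice.chrom_names)}
    for c in np.unique(chrom):
        if c not in name_to_idx:
            raise ValueError(f"unknown chromosome {c!r} in input file")
        ci = name_to_idx[c]
        sel = chrom == c
        s, e, v = start[sel], end[sel], value[sel]
        chrom_bp = lattice.chrom_len_bins[ci] * bin_bp
        if (s < 0).any() or (e > chrom_bp).any():
            raise ValueError(f"interval outside chromosome {c!r}")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if mode == "mean" and (s[1:] < e[:-1]).any():
            raise ValueError(f"overlapping bedGraph intervals on {c!r}")
        lo = int(off[ci])
        for si, ei, vi in zip(s, e, v):
            b0, b1 = si // bin_bp, (ei - 1) // bin_bp
            for b in range(b0, b1 + 1):
                ov = min(ei, (b + 1) * bin_bp) - max(si, b * bin_bp)
                # weights in bin units so a fully covered bin has weight
                # exactly 1 and a single full record round-trips bit-exactly
                wsum[lo + b] += (ov / bin_bp) * vi
                wtot[lo + b] += ov / bin_bp
    if mode == "mean":
        with np.errstate(invalid="ignore"):
            out = np.where(wtot > 0, wsum / np.maximum(wtot, 1e-300), np.nan)
    else:
        out = wsum  # covered length per bin, in bin units (times any score)
    return out


def _read_table(path: str | Path, ncols_min: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            rows.append(line)
    if not rows:
        raise ValueError(f"{path}: no data lines")
    df = pd.read_csv(
        _io.StringIO("\n".join(rows)),
        sep=r"\s+",
        header=None,
        float_precision="round_trip",
    )
    if df.shape[1] < ncols_min:
        raise ValueError(f"{path}: expected at least {ncols_min} columns")
    return df


def _parse_wig(path: str | Path):
    """Fixed-step wiggle to interval arrays (0-based half-open)."""
    chroms, starts, ends, vals = [], [], [], []
    chrom, pos, step, span = None, None, None, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wig is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", step))
                continue
            if line.startswith("variableStep"):
                raise ValueError("only fixedStep wiggle is supported")
            if chrom is None:
                raise ValueError("wiggle data before any fixedStep header")
            chroms.append(chrom)
            starts.append(pos)
            ends.append(pos + span)
            vals.append(float(line))
            pos += step
    return (
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(vals, dtype=float),
    )


def read_profile(
    path: str | Path,
    format: str,
    lattice: GenomeLattice,
    kind: str = "generic",
    use_score: bool = False,
) -> Profile:
    """Read a track file into a per-bin :class:`Profile`.

    * ``bedGraph`` — values are averaged into bins, weighting by the covered
      fraction of the bin; bins without any record are missing (NaN).
    * ``bed`` — BED3/BED5 peaks; per-bin value is the summed peak coverage
      (in bin-length units), optionally weighted by the BED5 score
      (``use_score``); uncovered bins are 0.
    * ``wig`` — fixed-step wiggle, aggregated like bedGraph.
    """
    if format in ("bedGraph", "bedgraph"):
        df = _read_table(path, 4)
        vals = _bin_intervals(
            lattice,
            df[0].to_numpy(dtype=object),
            df[1].to_numpy(dtype=np.int64),
            df[2].to_numpy(dtype=np.int64),
            df[3].to_numpy(dtype=float),
            "mean",
        )
    elif format in ("bed", "BED-peak", "bed-peak"):
        df = _read_table(path, 3)
        if use_score:
            if df.shape[1] < 5:
                raise ValueError("use_score requires a BED5 file")
            weights = df[4].to_numpy(dtype=float)
        else:
            weights = np.ones(len(df))
        vals = _bin_intervals(
            lattice,
            df[0].to_numpy(dtype=object),
            df[1].to_numpy(dtype=np.int64),
            df[2].to_numpy(dtype=np.int64),
            weights,
            "coverage",
        )
    elif format == "wig":
        vals = _bin_intervals(lattice, *_parse_wig(path), "mean")
    else:
        raise ValueError(f"unknown format {format!r}")
    return Profile(vals, kind, lattice)


def write_profile(profile: Profile, path: str | Path, name: str | None = None) -> None:
    """Write a profile as 4-column bedGraph (one record per defined bin).

    Values are printed with ``repr`` round-trip precision so that
    read ∘ write is the identity on defined bins.
    """
    lat = profile.lattice
    bin_bp = int(round(lat.bin_size_kb * 1000))
    off = lat.chrom_offsets
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        for c, cname in enumerate(lat.chrom_names):
            lo, hi = int(off[c]), int(off[c + 1])
            vals = profile.values[lo:hi]
            for i in np.flatnonzero(np.isfinite(vals)):
                fh.write(
                    f"{cname}\t{i * bin_bp}\t{(i + 1) * bin_bp}\t{float(vals[i])!r}\n"
                )
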