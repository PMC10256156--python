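"""Synthetic landscapes, perturbations and noisy observation fixtures.

The generator emulates the measured structure of an optimised human
initiation probability landscape: a small fraction of the genome carries
most of the initiation potential (about 80% of the mass on 15-20% of bins,
organised in broad initiation zones a few tens of kb wide, a few per Mb),
on top of a weak floor of dispersed initiation that thins out away from
the zones, the whole modulated by Mb-scale replication-timing domains.
Chromosome gap masks and noisy MRT/RFD observations can be layered on so
the whole pipeline runs without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import GenomeLattice, Profile, ProfilePair, smooth

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_ipls",
    "resample_in_windows",
    "modulate_amplitude",
    "add_observation_noise",
]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic genome and its initiation landscape.

    Defaults give a desk-scale genome: 3 chromosomes totalling 60 Mb, ~3.5
    initiation zones per Mb of mean width 45 kb carrying 80% of the mass,
    over a distance-graded floor, with 3 Mb timing domains.
    """

    n_chrom: int = 3
    chrom_len_mb: tuple[float, ...] = (25.0, 20.0, 15.0)
    bin_size_kb: float = 5.0
    peak_density: float = 3.5  # IZs per Mb
    peak_mass_fraction: float = 0.8
    peak_width_kb_mean: float = 45.0
    peak_width_kb_shape: float = 4.0  # gamma shape for widths
    peak_strength_shape: float = 2.0  # gamma shape for zone amplitudes
    floor_decay_mb: float | None = 1.0  # e-folding of the floor away from zones
    floor_basal: float = 0.15  # basal floor weight far from any zone
    domain_corr_mb: float = 3.0  # correlation length of the timing-domain field
    domain_log_sd: float = 1.0  # log-scale sd of the domain amplitude field
    gap_spec: tuple[tuple[int, float, float], ...] = field(default_factory=tuple)
    # gaps as (chromosome index, start Mb, length Mb)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_len_mb) != self.n_chrom:
            raise ValueError("chrom_len_mb length must equal n_chrom")
        if not 0.0 <= self.peak_mass_fraction <= 1.0:
            raise ValueError("peak_mass_fraction must lie in [0, 1]")
        if any(l <= 0 for l in self.chrom_len_mb):
            raise ValueError("chromosome lengths must be positive")

    def lattice(self) -> GenomeLattice:
        nbins = [int(round(l * 1000 / self.bin_size_kb)) for l in self.chrom_len_mb]
        lat = GenomeLattice(
            [f"chr{i + 1}" for i in range(self.n_chrom)], nbins, self.bin_size_kb
        )
        off = lat.chrom_offsets
        for c, start_mb, len_mb in self.gap_spec:
            a = int(off[c]) + int(round(start_mb * 1000 / self.bin_size_kb))
            b = a + int(round(len_mb * 1000 / self.bin_size_kb))
            lat.mask[a : min(b, int(off[c + 1]))] = True
        return lat


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated IPLS, for recovery tests."""

    iz_bins: np.ndarray  # peak-center bin indices
    iz_mass: np.ndarray  # mass of each peak
    peak_bin_mask: np.ndarray  # bins belonging to some peak's support
    spec: SyntheticSpec


def _domain_field(
    lat: GenomeLattice, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal replication-timing-domain amplitude field, mean ~1."""
    if spec.domain_log_sd <= 0:
        return np.ones(lat.n_bins)
    from scipy.ndimage import gaussian_filter1d

    sigma_bins = spec.domain_corr_mb * 1000.0 / lat.bin_size_kb
    # unit white noise smoothed with a Gaussian kernel of width sigma has
    # marginal variance 1/(2 sigma sqrt(pi)); rescale by the theoretical
    # factor (an empirical per-chromosome sd would blow up on chromosomes
    # not much longer than the correlation length)
    gain = np.sqrt(2.0 * sigma_bins * np.sqrt(np.pi))
    field = np.empty(lat.n_bins)
    off = lat.chrom_offsets
    for c in range(len(lat.chrom_names)):
        lo, hi = int(off[c]), int(off[c + 1])
        white = rng.standard_normal(hi - lo)
        sm = gaussian_filter1d(white, sigma_bins, mode="reflect") * gain
        # timing domains are intra-chromosomal structure: remove the
        # chromosome-level offset so chromosomes stay comparable in mass
        field[lo:hi] = sm - sm.mean()
    return np.exp(spec.domain_log_sd * field)


def generate_ipls(spec: SyntheticSpec) -> tuple[Profile, SyntheticTruth]:
    """Generate a peaky IPLS over a graded floor, with ground truth.

    Peaks are Poisson-placed along each chromosome.  Each initiation zone
    has a gamma-distributed width and amplitude; its mass is amplitude times
    width and is spread over the zone with a flat-top, cosine-tapered shape
    truncated at +/- half the width, so zones are broad and no single bin
    concentrates the zone's mass (initiation zones in OK-seq data are tens
    of kb wide, a few per Mb, and per-bin observed efficiencies stay
    modest).  With the default density and width the peak support covers
    roughly 15-20% of the genome.

    The floor carrying the remaining mass is not strictly uniform unless
    ``floor_decay_mb`` is ``None``: its weight decays exponentially with the
    distance to the nearest zone down to a basal level, emulating the
    progressive depletion of potential origins in late-replicating DNA
    (inferred human landscapes show the mean distance between potential
    origins growing more than tenfold from early- to late-replicating
    regions, while no region is completely devoid of initiation).

    A lognormal amplitude field with Mb-scale correlation (``domain_corr_mb``,
    ``domain_log_sd``) modulates both zone strengths and the floor.  This
    reproduces replication-timing domains: genomic regions rich in strong
    zones replicate reproducibly early, origin-poor regions reproducibly
    late, so the population-average replication timing spans its full range
    instead of every locus averaging to mid-S phase.  Set ``domain_log_sd``
    to 0 for a spatially homogeneous landscape.
    """
    if spec.peak_mass_fraction == 0 and spec.peak_density == 0:
        raise ValueError("zero peaks and zero floor leave nothing to generate")
    rng = np.random.default_rng(spec.seed)
    lat = spec.lattice()
    n = lat.n_bins
    vals = np.zeros(n)
    peak_mask = np.zeros(n, dtype=bool)
    centers: list[int] = []
    masses: list[float] = []
    off = lat.chrom_offsets
    domain = _domain_field(lat, spec, rng)
    for c in range(spec.n_chrom):
        lo, hi = int(off[c]), int(off[c + 1])
        n_peaks = rng.poisson(spec.peak_density * spec.chrom_len_mb[c])
        pos = lo + rng.integers(0, hi - lo, size=n_peaks)
        amplitude = rng.gamma(spec.peak_strength_shape, 1.0, size=n_peaks)
        width_kb = rng.gamma(
            spec.peak_width_kb_shape,
            spec.peak_width_kb_mean / spec.peak_width_kb_shape,
            size=n_peaks,
        )
        # zone mass = amplitude * width * local domain strength: broader
        # zones carry more mass, per-bin intensity stays bounded by the
        # amplitude scale, and zones inside strong timing domains dominate
        strength = amplitude * width_kb / spec.peak_width_kb_mean * domain[pos]
        for p, s, w in zip(pos, strength, width_kb):
            if lat.mask[p]:
                continue
            half = max(1, int(round(w / (2.0 * lat.bin_size_kb))))
            a, b = max(lo, p - half), min(hi, p + half + 1)
            x = np.arange(a, b) - p
            # flat-top zone with cosine-tapered shoulders: initiation density
            # is even across the zone core, giving the quasi-linear RFD
            # ascent that characterises initiation zones
            taper = np.clip((np.abs(x) - 0.5 * half) / (0.5 * half + 1.0), 0.0, 1.0)
            shape = 0.5 * (1.0 + np.cos(np.pi * taper))
            shape[lat.mask[a:b]] = 0.0
            tot = shape.sum()
            if tot <= 0:
                continue
            vals[a:b] += s * shape / tot
            peak_mask[a:b] |= shape > 0
            centers.append(int(p))
            masses.append(float(s))
    open_bins = ~lat.mask
    peak_total = vals.sum()
    if peak_total > 0:
        vals *= spec.peak_mass_fraction / peak_total
    floor = 1.0 - (spec.peak_mass_fraction if peak_total > 0 else 0.0)
    if spec.floor_decay_mb is None or not centers:
        weight = open_bins.astype(float)
    else:
        # floor decays with distance to the nearest zone, within chromosomes
        weight = np.zeros(n)
        centers_arr = np.sort(np.array(centers, dtype=np.int64))
        decay_bins = spec.floor_decay_mb * 1000.0 / lat.bin_size_kb
        for c in range(spec.n_chrom):
            lo, hi = int(off[c]), int(off[c + 1])
            cc = centers_arr[(centers_arr >= lo) & (centers_arr < hi)]
            idx = np.arange(lo, hi)
            if cc.size == 0:
                dist = np.full(hi - lo, np.inf)
            else:
                j = np.clip(np.searchsorted(cc, idx), 1, cc.size - 1)
                dist = np.minimum(np.abs(idx - cc[j - 1]), np.abs(idx - cc[j]))
                dist = np.minimum(dist, np.abs(idx - cc[np.clip(j, 0, cc.size - 1)]))
            w = spec.floor_basal + (1.0 - spec.floor_basal) * np.exp(
                -dist / decay_bins
            )
            weight[lo:hi] = w
        weight *= domain
        weight[~open_bins] = 0.0
    wsum = weight.sum()
    if floor > 0 and wsum > 0:
        vals += floor * weight / wsum
    vals[~open_bins] = 0.0
    vals /= vals.sum()
    profile = Profile(vals, "ipls", lat)
    truth = SyntheticTruth(
        iz_bins=np.array(centers, dtype=np.int64),
        iz_mass=np.array(masses),
        peak_bin_mask=peak_mask,
        spec=spec,
    )
    return profile, truth


def resample_in_windows(
    profile: Profile, window_kb: float = 200.0, rng: np.random.Generator | None = None
) -> Profile:
    """Permute bin values uniformly within non-overlapping windows.

    Windows never span chromosome boundaries; window sums are conserved
    exactly.  Emulates shuffling origin positions at sub-window scale while
    keeping the integrated local initiation strength.
    """
    lat = profile.lattice
    w = window_kb / lat.bin_size_kb
    if w < 1 or abs(w - round(w)) > 1e-9:
        raise ValueError("window_kb must be a multiple of the bin size")
    w = int(round(w))
    rng = rng or np.random.default_rng()
    out = profile.values.copy()
    off = lat.chrom_offsets
    for c in range(len(lat.chrom_names)):
        lo, hi = int(off[c]), int(off[c + 1])
        for a in range(lo, hi, w):
            b = min(a + w, hi)
            out[a:b] = rng.permutation(out[a:b])
    return Profile(out, profile.kind, lat)


def modulate_amplitude(
    profile: Profile, period_mb: float = 25.0, use_two_pi: bool = False
) -> Profile:
    """Divide the signal by ``1.1 + cos(2 x / P)`` (x = bin center).

    The divisor oscillates in [0.1, 2.1], amplifying some regions tenfold
    and halving others, which perturbs broad-scale initiation strength while
    keeping peak positions.  ``use_two_pi`` switches the argument to
    ``2 pi x / P`` so the modulation period is exactly ``period_mb``.
    """
    if np.nanmin(profile.values) < 0:
        raise ValueError("profile must be non-negative")
    lat = profile.lattice
    x_mb = lat.bin_centers_kb() / 1000.0
    factor = 2.0 * np.pi if use_two_pi else 2.0
    div = 1.1 + np.cos(factor * x_mb / period_mb)
    out = profile.values / div
    if profile.kind == "ipls":
        ok = ~lat.mask & np.isfinite(out)
        out = np.where(ok, out, 0.0)
        out /= out.sum()
    return Profile(out, profile.kind, lat)


def add_observation_noise(
    pair: ProfilePair,
    mrt_blur_kb: float = 100.0,
    rfd_sigma: float = 0.0,
    seed: int = 0,
) -> ProfilePair:
    """Emulate experimental resolution and sampling noise on a profile pair.

    MRT is blurred with a running mean of ``mrt_blur_kb`` (Repli-seq-like
    ~100 kb resolution); iid Gaussian noise of sd ``rfd_sigma`` is added to
    RFD and the result clipped to [-1, 1] (OK-seq-like sampling noise).
    """
    if rfd_sigma < 0:
        raise ValueError("rfd_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    mrt = smooth(pair.mrt, mrt_blur_kb)
    rfd_vals = pair.rfd.values + rng.normal(0.0, rfd_sigma, pair.lattice.n_bins)
    rfd_vals = np.clip(rfd_vals, -1.0, 1.0)
    rfd_vals[~np.isfinite(pair.rfd.values)] = np.nan
    rfd = Profile(rfd_vals, "rfd", pair.lattice)
    return ProfilePair(mrt, rfd, mask=pair.mask.copy())
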