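"""Stochastic S-phase simulator.

The model: before S phase, ``N_PO = L/d_PO`` potential origins are drawn
(with replacement) from a normalised initiation probability landscape (IPLS),
so several origins can share one 5 kb bin.  A fixed pool of ``N_F = rho_F*L``
limiting firing factors becomes available progressively with an exponential
characteristic time ``tau``.  Origin firing is a bimolecular reaction between
free factors and unfired origins with rate constant ``kon``, simulated with
an exact Gillespie scheme: the candidate initiation waiting time competes
with the earliest deterministic fork-fork or fork-boundary encounter.  An
initiation engages one factor and emits two diverging forks moving at speed
``v``; a fork merge is a termination that releases its factor; unfired
origins swept by a fork are passivated.  Forks never cross masked regions or
chromosome ends; every two boundary-retired forks release one factor.

``kon`` is parameterised through the genome-size-invariant constant
``kone = kon * L`` so that replication kinetics are preserved when only part
of a genome is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .lattice import GenomeLattice, Profile

__all__ = [
    "SimParams",
    "EffectiveIPLS",
    "ReplicationRecord",
    "rescale_kon",
    "draw_potential_origins",
    "simulate_s_phase",
    "simulate_ensemble",
]


@dataclass
class SimParams:
    """Model parameter vector.

    Attributes
    ----------
    v : fork speed, kb/min.
    kone : genome-size-invariant reaction constant ``kon*L``, kb/min.
    rho_F : firing-factor density, per Mb.
    d_PO : mean distance between potential origins, kb.
    r : uniform (dispersed) initiation fraction of the IPLS, in [0, 1].
    tau : firing-factor activation time constant, min.
    n_sims : ensemble size.
    seed : base RNG seed for the ensemble.
    """

    v: float = 1.5
    kone: float = 8.625
    rho_F: float = 0.56
    d_PO: float = 20.0
    r: float = 0.0
    tau: float = 60.0
    n_sims: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.v, self.kone, self.rho_F, self.d_PO) <= 0:
            raise ValueError("v, kone, rho_F and d_PO must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")

    def kon(self, length_kb: float) -> float:
        return rescale_kon(self.kone, length_kb)

    def n_factors(self, length_kb: float) -> int:
        n = int(round(self.rho_F * length_kb / 1000.0))
        if n < 1:
            raise ValueError("rho_F too small: fewer than one firing factor")
        return n

    def n_potential_origins(self, length_kb: float) -> int:
        n = int(round(length_kb / self.d_PO))
        if n < 1:
            raise ValueError("d_PO too large: fewer than one potential origin")
        return n


def rescale_kon(kone: float, length_kb: float) -> float:
    """Reaction rate ``kon = kone / L`` for a genome of length ``L`` kb."""
    if length_kb <= 0:
        raise ValueError("genome length must be positive")
    return kone / length_kb


@dataclass
class EffectiveIPLS:
    """IPLS decomposed into a structured part and a uniform fraction ``r``.

    The effective landscape is ``(1 - r) * structured + r * uniform`` over
    unmasked bins; it sums to 1.
    """

    structured: Profile
    r: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")

    def effective(self) -> np.ndarray:
        lat = self.structured.lattice
        vals = np.where(
            lat.mask, 0.0, np.nan_to_num(self.structured.values, nan=0.0)
        )
        if vals.min() < 0:
            raise ValueError("IPLS values must be non-negative")
        total = vals.sum()
        if total <= 0 and self.r == 0:
            raise ValueError("all-zero landscape with r = 0")
        structured = vals / total if total > 0 else np.zeros_like(vals)
        n_open = int((~lat.mask).sum())
        uniform = np.where(lat.mask, 0.0, 1.0 / n_open)
        return (1.0 - self.r) * structured + self.r * uniform


@dataclass
class ReplicationRecord:
    """Outcome of one simulated S phase.

    ``rt_min`` is the replication time of each bin (min, NaN where masked);
    ``fork_sign`` is +1/-1 for a right/left fork, 0 where an initiation or a
    termination occurred; ``fired`` flags bins with at least one initiation;
    ``replicated_fraction_at_rt`` is the global replicated fraction at the
    moment each bin replicated; ``f_free_trace`` is a step trace of free
    (activated, unengaged) factors; ``firing_times``/``firing_bins`` list
    the initiation events in time order.
    """

    rt_min: np.ndarray
    fork_sign: np.ndarray
    fired: np.ndarray
    replicated_fraction_at_rt: np.ndarray
    f_free_trace: tuple[np.ndarray, np.ndarray]
    firing_times: np.ndarray
    firing_bins: np.ndarray

    @property
    def fired_bins(self) -> np.ndarray:
        return np.flatnonzero(self.fired)

    @property
    def t100(self) -> float:
        return float(np.nanmax(self.rt_min))


def draw_potential_origins(
    ipls: EffectiveIPLS, n_po: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial draw of ``n_po`` origins over bins of the effective landscape."""
    if n_po < 1:
        raise ValueError("n_po must be at least 1")
    p = ipls.effective()
    return rng.multinomial(n_po, p)


@njit(cache=True)
def _sim_core(
    seg_start,  # int64[:], segment start bin (inclusive)
    seg_stop,  # int64[:], segment stop bin (exclusive)
    seg_of_bin,  # int64[:], segment index per bin (-1 where masked)
    origin_bins,  # int64[:], sorted bins of potential origins (with multiplicity)
    bin_kb,
    v,
    kon,
    tau,
    n_f,
    seed,
):
    np.random.seed(seed)
    n_bins = seg_of_bin.shape[0]
    n_orig = origin_bins.shape[0]

    rt = np.full(n_bins, np.nan)
    sign = np.zeros(n_bins, dtype=np.int8)
    fired = np.zeros(n_bins, dtype=np.bool_)

    total = 0
    for s in range(seg_start.shape[0]):
        total += seg_stop[s] - seg_start[s]

    oalive = np.ones(n_orig, dtype=np.bool_)
    n_alive = n_orig

    max_fire = n_orig + 1
    firing_t = np.empty(max_fire)
    firing_b = np.empty(max_fire, dtype=np.int64)
    n_fire = 0

    max_tr = 4 * n_orig + 4 * n_f + 8
    trace_t = np.empty(max_tr)
    trace_f = np.empty(max_tr, dtype=np.int64)
    n_tr = 0

    # factor activation times: k-th factor (k=0..n_f-1) active from
    # a_k = -tau*ln(1 - k/n_f); all factors active at finite time
    act_times = np.empty(n_f)
    for k in range(n_f):
        act_times[k] = -tau * np.log(1.0 - k / n_f) if tau > 0 else 0.0
    n_act = 0
    engaged = 0
    retired = 0

    # forks kept sorted by position
    max_forks = 2 * n_f + 2
    fpos = np.empty(max_forks)
    fdir = np.empty(max_forks, dtype=np.int8)
    fseg = np.empty(max_forks, dtype=np.int64)
    nf = 0

    n_rep = 0
    t = 0.0

    trace_t[n_tr] = 0.0
    trace_f[n_tr] = 0
    n_tr += 1

    while n_rep < total:
        # immediate activations
        while n_act < n_f and act_times[n_act] <= t:
            n_act += 1
            trace_t[n_tr] = t
            trace_f[n_tr] = n_act - engaged
            n_tr += 1

        free = n_act - engaged
        # candidate initiation time
        if n_alive > 0 and free > 0:
            rate = kon * n_alive * free
            t_a = t + np.random.exponential(1.0 / rate)
        else:
            t_a = np.inf
        # next factor activation
        t_act = act_times[n_act] if n_act < n_f else np.inf
        # earliest fork encounter (merge or boundary)
        t_e = np.inf
        e_kind = 0  # 1 = merge, 2 = boundary
        e_i = -1
        for i in range(nf):
            if fdir[i] > 0:
                tb = t + (seg_stop[fseg[i]] * bin_kb - fpos[i]) / v
            else:
                tb = t + (fpos[i] - seg_start[fseg[i]] * bin_kb) / v
            if tb < t_e:
                t_e, e_kind, e_i = tb, 2, i
            if (
                i + 1 < nf
                and fdir[i] > 0
                and fdir[i + 1] < 0
                and fseg[i] == fseg[i + 1]
            ):
                tm = t + (fpos[i + 1] - fpos[i]) / (2.0 * v)
                if tm < t_e:
                    t_e, e_kind, e_i = tm, 1, i

        t_next = min(t_a, min(t_e, t_act))
        if t_next == np.inf:
            return (rt, sign, fired, firing_t[:n_fire], firing_b[:n_fire],
                    trace_t[:n_tr], trace_f[:n_tr], -1)

        # advance all forks to t_next, painting replicated bins
        dt = t_next - t
        if dt > 0.0:
            for i in range(nf):
                old = fpos[i]
                new = old + fdir[i] * v * dt
                if fdir[i] > 0:
                    b0 = int(np.floor(old / bin_kb - 0.5)) + 1
                    b1 = int(np.floor(new / bin_kb - 0.5 + 1e-12))
                    for b in range(max(b0, seg_start[fseg[i]]),
                                   min(b1, seg_stop[fseg[i]] - 1) + 1):
                        if np.isnan(rt[b]):
                            rt[b] = t + ((b + 0.5) * bin_kb - old) / v
                            sign[b] = 1
                            n_rep += 1
                            lo = np.searchsorted(origin_bins, b)
                            hi = np.searchsorted(origin_bins, b + 1)
                            for k in range(lo, hi):
                                if oalive[k]:
                                    oalive[k] = False
                                    n_alive -= 1
                else:
                    b1 = int(np.floor(old / bin_kb - 0.5 - 1e-12))
                    b0 = int(np.ceil(new / bin_kb - 0.5 - 1e-12))
                    for b in range(max(b0, seg_start[fseg[i]]),
                                   min(b1, seg_stop[fseg[i]] - 1) + 1):
                        if np.isnan(rt[b]):
                            rt[b] = t + (old - (b + 0.5) * bin_kb) / v
                            sign[b] = -1
                            n_rep += 1
                            lo = np.searchsorted(origin_bins, b)
                            hi = np.searchsorted(origin_bins, b + 1)
                            for k in range(lo, hi):
                                if oalive[k]:
                                    oalive[k] = False
                                    n_alive -= 1
                fpos[i] = new
        t = t_next

        if t_act <= min(t_a, t_e):
            n_act += 1
            trace_t[n_tr] = t
            trace_f[n_tr] = n_act - engaged
            n_tr += 1
        elif t_e <= t_a:
            if e_kind == 1:
                # merge: both forks are at the midpoint; termination bin -> 0
                m = fpos[e_i]
                bm = int(m / bin_kb)
                if bm >= seg_stop[fseg[e_i]]:
                    bm = seg_stop[fseg[e_i]] - 1
                sign[bm] = 0
                if np.isnan(rt[bm]):
                    rt[bm] = t
                    n_rep += 1
                    lo = np.searchsorted(origin_bins, bm)
                    hi = np.searchsorted(origin_bins, bm + 1)
                    for k in range(lo, hi):
                        if oalive[k]:
                            oalive[k] = False
                            n_alive -= 1
                for j in range(e_i, nf - 2):
                    fpos[j] = fpos[j + 2]
                    fdir[j] = fdir[j + 2]
                    fseg[j] = fseg[j + 2]
                nf -= 2
                engaged -= 1
                trace_t[n_tr] = t
                trace_f[n_tr] = n_act - engaged
                n_tr += 1
            else:
                # boundary retirement; two retired forks release one factor
                for j in range(e_i, nf - 1):
                    fpos[j] = fpos[j + 1]
                    fdir[j] = fdir[j + 1]
                    fseg[j] = fseg[j + 1]
                nf -= 1
                retired += 1
                if retired == 2:
                    retired = 0
                    engaged -= 1
                    trace_t[n_tr] = t
                    trace_f[n_tr] = n_act - engaged
                    n_tr += 1
        else:
            # initiation: pick an unfired origin uniformly.  Fork sweeps during
            # the time advance may have passivated every remaining origin, in
            # which case the candidate reaction is void and we simply redraw.
            if n_alive == 0:
                continue
            pick = np.random.randint(n_alive)
            oi = -1
            cnt = -1
            for k in range(n_orig):
                if oalive[k]:
                    cnt += 1
                    if cnt == pick:
                        oi = k
                        break
            b = origin_bins[oi]
            seg = seg_of_bin[b]
            pos = (b + 0.5) * bin_kb
            # the origin's bin replicates now; co-binned origins are passivated
            sign[b] = 0
            if np.isnan(rt[b]):
                rt[b] = t
                n_rep += 1
            lo = np.searchsorted(origin_bins, b)
            hi = np.searchsorted(origin_bins, b + 1)
            for k in range(lo, hi):
                if oalive[k]:
                    oalive[k] = False
                    n_alive -= 1
            fired[b] = True
            firing_t[n_fire] = t
            firing_b[n_fire] = b
            n_fire += 1
            engaged += 1
            # insert two diverging forks, keeping position order
            ins = np.searchsorted(fpos[:nf], pos)
            for j in range(nf + 1, ins + 1, -1):
                fpos[j] = fpos[j - 2]
                fdir[j] = fdir[j - 2]
                fseg[j] = fseg[j - 2]
            fpos[ins] = pos
            fdir[ins] = -1
            fseg[ins] = seg
            fpos[ins + 1] = pos
            fdir[ins + 1] = 1
            fseg[ins + 1] = seg
            nf += 2
            trace_t[n_tr] = t
            trace_f[n_tr] = n_act - engaged
            n_tr += 1

    # final trace point: the forks still running when the last bin center
    # replicates all retire deterministically, so every factor ends up free
    trace_t[n_tr] = t
    trace_f[n_tr] = n_f
    n_tr += 1
    return (rt, sign, fired, firing_t[:n_fire], firing_b[:n_fire],
            trace_t[:n_tr], trace_f[:n_tr], 0)


def _segment_arrays(lattice: GenomeLattice):
    segs = lattice.segments()
    if not segs:
        raise ValueError("lattice has no unmasked bins")
    seg_start = np.array([a for a, _ in segs], dtype=np.int64)
    seg_stop = np.array([b for _, b in segs], dtype=np.int64)
    seg_of_bin = np.full(lattice.n_bins, -1, dtype=np.int64)
    for i, (a, b) in enumerate(segs):
        seg_of_bin[a:b] = i
    return seg_start, seg_stop, seg_of_bin


def simulate_s_phase(
    lattice: GenomeLattice,
    ipls: EffectiveIPLS,
    params: SimParams,
    rng: np.random.Generator,
) -> ReplicationRecord:
    """Run one stochastic S phase and return its :class:`ReplicationRecord`.

    Raises ``ValueError`` if a contiguous unmasked segment received no
    potential origin (it could never replicate).
    """
    seg_start, seg_stop, seg_of_bin = _segment_arrays(lattice)
    length_kb = float((~lattice.mask).sum()) * lattice.bin_size_kb
    n_po = params.n_potential_origins(length_kb)
    counts = draw_potential_origins(ipls, n_po, rng)
    origin_bins = np.repeat(
        np.arange(lattice.n_bins, dtype=np.int64), counts
    )
    # every segment needs at least one origin, else it can never replicate
    seg_has = np.zeros(seg_start.shape[0], dtype=bool)
    seg_has[np.unique(seg_of_bin[origin_bins])] = True
    if not seg_has.all():
        missing = int(np.flatnonzero(~seg_has)[0])
        a, b = int(seg_start[missing]), int(seg_stop[missing])
        raise ValueError(
            f"segment bins [{a}, {b}) received no potential origin and "
            "cannot replicate; increase L/d_PO or use r > 0 with more draws"
        )
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    out = _sim_core(
        seg_start,
        seg_stop,
        seg_of_bin,
        origin_bins,
        float(lattice.bin_size_kb),
        float(params.v),
        params.kon(length_kb),
        float(params.tau),
        params.n_factors(length_kb),
        kernel_seed,
    )
    rt, sign, fired, fire_t, fire_b, tr_t, tr_f, status = out
    if status != 0:
        raise RuntimeError("simulation stalled: no feasible event remained")
    rt[lattice.mask] = np.nan
    sign = np.asarray(sign)
    sign[lattice.mask] = 0
    # global replicated fraction at each bin's replication moment
    frac = np.full(lattice.n_bins, np.nan)
    open_bins = np.flatnonzero(~lattice.mask)
    order = np.argsort(rt[open_bins], kind="stable")
    frac[open_bins[order]] = np.arange(open_bins.size) / open_bins.size
    return ReplicationRecord(
        rt_min=rt,
        fork_sign=sign,
        fired=np.asarray(fired),
        replicated_fraction_at_rt=frac,
        f_free_trace=(np.asarray(tr_t), np.asarray(tr_f)),
        firing_times=np.asarray(fire_t),
        firing_bins=np.asarray(fire_b),
    )


def simulate_ensemble(
    lattice: GenomeLattice,
    ipls: EffectiveIPLS,
    params: SimParams,
):
    """Simulate ``params.n_sims`` independent S phases.

    Each simulation index gets its own RNG stream spawned from
    ``params.seed``, so results do not depend on execution order.
    Returns a :class:`replisim.observables.ReplicationEnsemble`.
    """
    from .observables import ReplicationEnsemble

    records = []
    base = np.random.SeedSequence(params.seed)
    for child in base.spawn(params.n_sims):
        rng = np.random.default_rng(child)
        records.append(simulate_s_phase(lattice, ipls, params, rng))
    return ReplicationEnsemble(records=records, lattice=lattice, params=params)
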