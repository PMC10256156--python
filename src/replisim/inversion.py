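"""Iterative inversion of MRT/RFD profiles into an initiation landscape.

The replication model maps an IPLS to MRT and RFD profiles; this module
learns the inverse map.  A regression network is trained on *simulated*
(MRT, RFD) -> IPLS pairs — input: a sliding window of the two profiles
centred on a bin; output: the initiation probability of the centre bin —
and then applied to the experimental profiles to propose an improved IPLS.
Alternating simulation, training, prediction and a grid search over the
global parameters (firing-factor density rho_F, dispersed-initiation
fraction r) improves the landscape over a few iterations; the state with
the best joint MRT+RFD correlation is the optimised landscape I_M.

The initial landscape I_0 is built from the strongest smoothed RFD
increments — initiation zones are exactly the upward RFD shifts, so a flat
RFD profile carries no initialisation signal and is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.neural_network import MLPRegressor

from .lattice import GenomeLattice, Profile, ProfilePair, smooth
from .metrics import score_pair
from .observables import compute_mrt_fractions, compute_rfd
from .simulate import EffectiveIPLS, SimParams, simulate_ensemble

__all__ = [
    "InversionState",
    "InversionResult",
    "InverterModel",
    "init_ipls",
    "train_inverter",
    "apply_inverter",
    "grid_search",
    "iterate_inversion",
]


@dataclass
class InversionState:
    """One iteration of the inversion: landscape, parameters, fit quality."""

    iteration: int
    ipls: Profile
    params: SimParams
    sim_pair: ProfilePair
    scores: tuple[float, float]  # (pcc_mrt, pcc_rfd)

    @property
    def joint_score(self) -> float:
        return float(self.scores[0] + self.scores[1])


@dataclass
class InversionResult:
    """Best state plus the full iteration history."""

    best: InversionState
    states: list[InversionState]


@dataclass
class InverterModel:
    """Trained windowed regressor mapping (MRT, RFD) windows to IPLS values."""

    model: MLPRegressor
    window_bins: int
    rfd_smooth_kb: float
    target_scale: float
    train_chroms: list[str]
    val_chrom: str | None
    test_chrom: str | None
    val_pcc: float = float("nan")


def init_ipls(
    rfd: Profile,
    smooth_kb: float = 50.0,
    keep_top_fraction: float = 0.2,
) -> Profile:
    """Initial landscape I_0 from RFD increments.

    Per-bin RFD increments are smoothed over ``smooth_kb``, negatives are
    clipped, values below the ``1 - keep_top_fraction`` quantile of unmasked
    bins are zeroed, and the result is normalised to sum 1.
    """
    lat = rfd.lattice
    d = np.zeros(lat.n_bins)
    off = lat.chrom_offsets
    for c in range(len(lat.chrom_names)):
        lo, hi = int(off[c]), int(off[c + 1])
        d[lo + 1 : hi] = np.diff(rfd.values[lo:hi])
    sm = smooth(Profile(d, "generic", lat), smooth_kb).values
    sm = np.nan_to_num(sm, nan=0.0).clip(min=0.0)
    open_idx = np.flatnonzero(~lat.mask)
    vals = sm[open_idx]
    if not (vals > 0).any():
        raise ValueError(
            "RFD profile has no positive increments: no initialisation signal"
        )
    k = int(np.ceil(keep_top_fraction * open_idx.size))
    out = np.zeros(lat.n_bins)
    if k < vals.size:
        keep = np.argpartition(vals, -k)[-k:]
        out[open_idx[keep]] = vals[keep]
    else:
        out[open_idx] = vals
    return Profile(out, "generic", lat).normalised()


def _window_features(
    pair: ProfilePair, window_bins: int, rfd_smooth_kb: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin feature matrix of stacked (MRT, smoothed RFD) windows.

    Windows are built per chromosome with reflective padding at the ends.
    Returns (X, covered) where ``covered`` flags bins of chromosomes long
    enough to window (too-short chromosomes are skipped with a warning).
    """
    lat = pair.lattice
    half = window_bins // 2
    mrt = np.nan_to_num(pair.mrt.values, nan=0.0)
    rfd = np.nan_to_num(smooth(pair.rfd, rfd_smooth_kb).values, nan=0.0)
    X = np.zeros((lat.n_bins, 2 * window_bins), dtype=np.float32)
    covered = np.zeros(lat.n_bins, dtype=bool)
    off = lat.chrom_offsets
    for c, name in enumerate(lat.chrom_names):
        lo, hi = int(off[c]), int(off[c + 1])
        n = hi - lo
        if half >= n:
            warnings.warn(
                f"chromosome {name!r} shorter than the window; skipped",
                stacklevel=2,
            )
            continue
        mpad = np.pad(mrt[lo:hi], half, mode="reflect")
        rpad = np.pad(rfd[lo:hi], half, mode="reflect")
        mw = np.lib.stride_tricks.sliding_window_view(mpad, window_bins)
        rw = np.lib.stride_tricks.sliding_window_view(rpad, window_bins)
        X[lo:hi, :window_bins] = mw[:n]
        X[lo:hi, window_bins:] = rw[:n]
        covered[lo:hi] = True
    return X, covered


def _chrom_split(
    lattice: GenomeLattice,
    train_chroms: list[str] | None,
    val_chrom: str | None,
    test_chrom: str | None,
):
    names = lattice.chrom_names
    if train_chroms is None:
        if len(names) < 3:
            raise ValueError(
                "need at least 3 chromosomes for the default train/val/test "
                "split; pass train_chroms explicitly for smaller genomes"
            )
        test_chrom = names[0] if test_chrom is None else test_chrom
        val_chrom = names[1] if val_chrom is None else val_chrom
        train_chroms = [n for n in names if n not in (test_chrom, val_chrom)]
    return train_chroms, val_chrom, test_chrom


def train_inverter(
    sim_pair: ProfilePair,
    target_ipls: Profile,
    r: float,
    seed: int = 0,
    window_bins: int = 401,
    rfd_smooth_kb: float = 50.0,
    hidden_layers: tuple[int, ...] = (128, 64),
    n_augment: int = 3,
    noise_bin_fraction: float = 0.01,
    max_epochs: int = 200,
    alpha: float = 1e-3,
    train_chroms: list[str] | None = None,
    val_chrom: str | None = None,
    test_chrom: str | None = None,
) -> InverterModel:
    """Train the inverse regressor on one simulated (MRT, RFD) -> IPLS pair.

    The regression target is the mixture landscape ``(1-r)*I + r*uniform``
    rescaled by its maximum over the training chromosomes to [0, 1] and
    square-root transformed (the landscape is heavily skewed: most bins are
    near zero and a plain least-squares fit ignores the peaks; predictions
    are squared back on application).  Training rows are augmented with
    ``n_augment`` extra copies whose raw RFD had ``noise_bin_fraction`` of
    its bins replaced by a uniform value in [-1, 1] (robustness to
    experimental noise); targets are never perturbed.
    """
    lat = sim_pair.lattice
    train_chroms, val_chrom, test_chrom = _chrom_split(
        lat, train_chroms, val_chrom, test_chrom
    )
    rng = np.random.default_rng(seed)

    mix = EffectiveIPLS(target_ipls, r).effective()
    train_sel = np.zeros(lat.n_bins, dtype=bool)
    for name in train_chroms:
        train_sel[lat.chrom_slice(name)] = True
    usable = sim_pair.usable
    scale = float(mix[train_sel & usable].max())
    if scale <= 0:
        raise ValueError("target landscape is zero on the training chromosomes")
    y_full = (mix / scale).astype(np.float32)

    X, covered = _window_features(sim_pair, window_bins, rfd_smooth_kb)
    rows = train_sel & usable & covered
    X_train = [X[rows]]
    y_train = [y_full[rows]]
    for _ in range(n_augment):
        noisy_rfd = sim_pair.rfd.values.copy()
        n_noise = int(round(noise_bin_fraction * lat.n_bins))
        idx = rng.choice(lat.n_bins, size=n_noise, replace=False)
        noisy_rfd[idx] = rng.uniform(-1.0, 1.0, size=n_noise)
        noisy_pair = ProfilePair(
            sim_pair.mrt,
            Profile(noisy_rfd, "rfd", lat),
            mask=sim_pair.mask.copy(),
        )
        Xa, _ = _window_features(noisy_pair, window_bins, rfd_smooth_kb)
        X_train.append(Xa[rows])
        y_train.append(y_full[rows])
    Xt = np.concatenate(X_train)
    yt = np.sqrt(np.concatenate(y_train).clip(min=0.0))

    model = MLPRegressor(
        hidden_layer_sizes=hidden_layers,
        activation="relu",
        solver="adam",
        alpha=alpha,
        max_iter=max_epochs,
        early_stopping=False,
        tol=1e-7,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at epoch cap
        model.fit(Xt, yt)

    val_pcc = float("nan")
    if val_chrom is not None:
        vsel = np.zeros(lat.n_bins, dtype=bool)
        vsel[lat.chrom_slice(val_chrom)] = True
        vrows = vsel & usable & covered
        if vrows.sum() > 2:
            pred = model.predict(X[vrows]).clip(min=0.0) ** 2
            from .metrics import pearson

            val_pcc = pearson(pred, y_full[vrows])
    return InverterModel(
        model=model,
        window_bins=window_bins,
        rfd_smooth_kb=rfd_smooth_kb,
        target_scale=scale,
        train_chroms=list(train_chroms),
        val_chrom=val_chrom,
        test_chrom=test_chrom,
        val_pcc=val_pcc,
    )


def apply_inverter(model: InverterModel, pair: ProfilePair) -> Profile:
    """Predict an IPLS for every unmasked bin of ``pair``.

    Predictions are clipped at 0, masked bins are set to 0 and excluded from
    the final normalisation to sum 1.
    """
    lat = pair.lattice
    X, covered = _window_features(pair, model.window_bins, model.rfd_smooth_kb)
    out = np.zeros(lat.n_bins)
    rows = covered & ~lat.mask
    if rows.any():
        pred = model.model.predict(X[rows]).clip(min=0.0) ** 2
        out[rows] = pred * model.target_scale
    return Profile(out, "generic", lat).normalised()


def _subset_pair(
    pair: ProfilePair, ipls: Profile, chroms: list[str]
) -> tuple[ProfilePair, Profile]:
    """Restrict a pair and a landscape to the given chromosomes."""
    lat = pair.lattice
    idx = np.concatenate(
        [np.arange(lat.chrom_slice(n).start, lat.chrom_slice(n).stop) for n in chroms]
    )
    sub = GenomeLattice(
        list(chroms),
        [lat.chrom_slice(n).stop - lat.chrom_slice(n).start for n in chroms],
        lat.bin_size_kb,
        lat.mask[idx].copy(),
    )
    mrt = Profile(pair.mrt.values[idx].copy(), pair.mrt.kind, sub)
    rfd = Profile(pair.rfd.values[idx].copy(), pair.rfd.kind, sub)
    sub_pair = ProfilePair(mrt, rfd, mask=pair.mask[idx].copy())
    sub_ipls = Profile(ipls.values[idx].copy(), "generic", sub).normalised()
    return sub_pair, sub_ipls


def grid_search(
    pair_exp: ProfilePair,
    ipls: Profile,
    rho_f_grid: list[float],
    r_grid: list[float],
    base_params: SimParams | None = None,
    restrict_chroms: list[str] | None = None,
    n_sims: int = 40,
    seed: int = 0,
) -> tuple[SimParams, dict]:
    """Optimise (rho_F, r) by maximising PCC_MRT(10 kb) + PCC_RFD(5 kb).

    Each grid point runs an ensemble of ``n_sims`` simulations with the
    candidate parameters and the given landscape; the optimisation can be
    restricted to a subset of chromosomes to save time.  Failed grid points
    are skipped with a warning.  Returns the winning parameter vector (with
    the base ensemble size restored) and the per-point score table.
    """
    if not rho_f_grid or not r_grid:
        raise ValueError("grids must be non-empty")
    base = base_params or SimParams()
    target_pair, target_ipls = (
        _subset_pair(pair_exp, ipls, restrict_chroms)
        if restrict_chroms
        else (pair_exp, ipls)
    )
    ss = np.random.SeedSequence(seed)
    table: dict[tuple[float, float], tuple[float, float]] = {}
    best_key, best_score = None, -np.inf
    for i, rho in enumerate(rho_f_grid):
        for j, r in enumerate(r_grid):
            params = replace(
                base,
                rho_F=rho,
                r=r,
                n_sims=n_sims,
                seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
            )
            try:
                ens = simulate_ensemble(
                    target_pair.lattice, EffectiveIPLS(target_ipls, r), params
                )
            except (ValueError, RuntimeError) as exc:
                warnings.warn(
                    f"grid point (rho_F={rho}, r={r}) failed: {exc}", stacklevel=2
                )
                continue
            sim_pair = ProfilePair(
                compute_mrt_fractions(ens),
                compute_rfd(ens),
                mask=target_pair.mask.copy(),
            )
            sc = score_pair(sim_pair, target_pair)
            table[(rho, r)] = sc
            if sum(sc) > best_score:
                best_score, best_key = sum(sc), (rho, r)
    if best_key is None:
        raise RuntimeError("every grid point failed")
    best = replace(base, rho_F=best_key[0], r=best_key[1])
    return best, table


def iterate_inversion(
    pair_exp: ProfilePair,
    i0: Profile,
    n_iter: int = 4,
    rho_f_grid: list[float] | None = None,
    r_grid: list[float] | None = None,
    base_params: SimParams | None = None,
    seed: int = 0,
    n_sims: int = 100,
    grid_n_sims: int = 30,
    restrict_chroms: list[str] | None = None,
    train_kwargs: dict | None = None,
) -> InversionResult:
    """Alternate simulation, network training and prediction for ``n_iter`` rounds.

    Round k: grid-search (rho_F, r) given the current landscape I_k, simulate
    an ensemble, score the simulated MRT/RFD against the experimental pair,
    then train the inverter on the simulated pair and apply it to the
    experimental pair to obtain I_{k+1}.  Stops early after two consecutive
    degradations of the joint score.  Returns the best-scoring state
    (optimised landscape I_M) and the full history.
    """
    base = base_params or SimParams()
    rho_f_grid = rho_f_grid or [base.rho_F]
    r_grid = r_grid if r_grid is not None else [base.r]
    if not np.nan_to_num(i0.values, nan=0.0).clip(min=0).sum() > 0:
        raise ValueError("initial landscape is flat/empty")
    ss = np.random.SeedSequence(seed)
    train_kwargs = dict(train_kwargs or {})

    states: list[InversionState] = []
    ipls = i0.normalised()
    degraded = 0
    for it in range(n_iter + 1):
        params, _ = grid_search(
            pair_exp,
            ipls,
            rho_f_grid,
            r_grid,
            base_params=base,
            restrict_chroms=restrict_chroms,
            n_sims=grid_n_sims,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
        )
        params = replace(
            params,
            n_sims=n_sims,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
        )
        ens = simulate_ensemble(
            pair_exp.lattice, EffectiveIPLS(ipls, params.r), params
        )
        sim_pair = ProfilePair(
            compute_mrt_fractions(ens), compute_rfd(ens), mask=pair_exp.mask.copy()
        )
        scores = score_pair(sim_pair, pair_exp)
        state = InversionState(it, ipls, params, sim_pair, scores)
        states.append(state)
        best_so_far = max(states, key=lambda s: s.joint_score)
        if state.joint_score < best_so_far.joint_score:
            degraded += 1
            if degraded >= 2:
                break
        else:
            degraded = 0
        if it == n_iter:
            break
        model = train_inverter(
            sim_pair,
            ipls,
            params.r,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31),
            **train_kwargs,
        )
        ipls = apply_inverter(model, pair_exp)
    best = max(states, key=lambda s: s.joint_score)
    return InversionResult(best=best, states=states)
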