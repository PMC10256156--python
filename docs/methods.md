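# Methods

## Model

S phase is modelled on a genome discretised into 5 kb bins, organised in
chromosomes and optionally interrupted by masked gaps (telomere/centromere
analogues). A simulation receives:

* an **initiation probability landscape** `I(x)` — a non-negative per-bin
  weight normalised to sum 1, decomposable as
  `(1 - r) * I_structured + r * uniform`, with `r` the fraction of fully
  dispersed ("random") initiation;
* `N_PO = L / d_PO` **potential origins**, drawn from `I(x)` with
  replacement before S entry (several origins can share a bin); origins sit
  at bin centers;
* `N_F = rho_F * L` **firing factors**, activated progressively with the
  exponential law `N_F (1 - e^(-t/tau))`;
* a bimolecular **firing reaction** with rate constant `kon`, applied as a
  global propensity `kon * N_PO(t) * N_Ffree(t)`; the firing origin is
  chosen uniformly among unfired origins.

Forks move deterministically at speed `v` in both directions from a fired
origin. A factor is engaged at initiation and recycled when two forks merge
(termination). Forks passivate every unfired origin they sweep and retire
at chromosome/gap boundaries; every two retired forks release one factor,
which conserves the pool without biasing interior kinetics (the model
specification defines release only at mergers; boundary handling is our
choice). The event loop is an exact stochastic simulation: the candidate
initiation waiting time (exponential in the current propensity) competes
with the earliest deterministic fork-fork or fork-boundary encounter and
with the next factor-activation time; the propensity is re-drawn after
every event. If fork sweeps during a time advance passivate the last
remaining origins, the pending initiation is void and is simply re-drawn.
Ties between an encounter and an initiation are resolved for the encounter.

Two discretisation choices matter. First, factor activation uses
`ceil(N_F (1 - e^(-t/tau)))` clipped to `N_F` rather than `floor(...)`:
the floor variant never activates the last factor at finite time, whereas
the ceiling variant starts at 0 and reaches the full pool — which the
free-factor trace invariants (start at 0, end at `N_F`) require. Second,
`kon` is parameterised through the genome-size-invariant constant
`kone = kon * L` (8.625 kb/min by default), so that desk-scale genomes
keep the kinetic regime of a full-genome run (3e-6 /min at 2875 Mb).

The core event loop is JIT-compiled with numba; a 200-simulation ensemble
of a 60 Mb genome runs in roughly a second. Each simulation index owns an
RNG stream spawned from the ensemble seed, so results are independent of
execution order and reproducible bit-for-bit.

### Parameters (defaults)

| parameter | meaning | default | origin of the value |
|---|---|---|---|
| `v` | fork speed | 1.5 kb/min | single-molecule measurements (1–3 kb/min) |
| `kone` | `kon * L` | 8.625 kb/min | keeps the limiting-factor regime at any L |
| `rho_F` | firing factors per Mb | 0.56 | optimum of the K562-style grid search |
| `d_PO` | mean potential-origin spacing | 20 kb | MCM loading estimates (1 per 20–40 kb) |
| `r` | dispersed-initiation fraction | 0 | reference optimum |
| `tau` | factor activation time | 60 min | progressive S-entry activation |
| `n_sims` | ensemble size | 200 | population-average convention |

## Observables

* **RFD**: per bin, `(n_right - n_left) / n_sims`, with initiation and
  termination bins contributing 0 (each bin records one fork sign per
  simulation; the sign is 0 where the bin's replication started or where a
  merge occurred).
* **MRT (fraction units)**: each simulation records, for each bin, the
  global replicated fraction at the moment the bin replicated (a rank, so
  simulation-to-simulation differences in global pace cancel); the [0,1)
  axis is cut into 6 equal compartments and
  `MRT(x) = sum_i p_i(x) * i/6 + 1/12`. Compartment intervals are
  half-open with the last closed.
* **MRT (minutes)**: the ensemble mean of the recorded replication times.
* **OE**: the fraction of simulations in which a bin hosted at least one
  initiation (binary per simulation).
* **T95/T99/T100**: per-simulation times at which 95/99/100% of bins have
  replicated; ensemble medians are reported.
* **I(t)**: origin firing rate per unreplicated length. Firings and
  unreplicated lengths are pooled across the ensemble in 5-minute windows
  before taking the ratio, and windows where less than 1% of the pooled
  genome remains are masked — a per-simulation ratio diverges as its
  denominator vanishes at the very end of S phase, and a rate estimated
  from a vanishing exposure carries no information.
* **RT variability**: per-bin interquartile range of the replication-time
  proxy (true minutes, or replicated fraction), aggregated by MRT decile.
  The replicated-fraction proxy reproduces the bell-shaped profile reported
  for high-resolution Repli-seq; the true-time variability instead grows
  through S phase, and the contrast between the two is the point of the
  diagnostic.

## Analytic origin-strength relations

With `n(x)` potential origins in a bin and the free-factor trace
`F_free(t)`, the probability that the bin has fired by time `t`, ignoring
passivation, is `A_x(t) = 1 - exp(-kon n(x) int_0^t F_free du)` (the trace
integral is evaluated by exact step quadrature). Because a 5 kb bin is
almost always replicated passively, its passivation time is close to its
mean replication time, whence `OE(x) = A_x(MRT_t(x))`. Inverting at
initiation zones, where `OE ~ dRFD/2`:

```
n_e(x)     = -ln(1 - dRFD/2) / (kon int_0^MRT_t F_free du)     (exact)
n_e^a(x)   = -ln(1 - dRFD/2) / (kon MRT T_S [F_free])          (constant F)
n_e^exp(x) ~  dRFD * exp(-6 MRT)                               (empirical)
```

`dRFD` is the first difference of the (optionally smoothed) RFD profile,
negatives zeroed, thresholded to the top 15% of bins. Initiation-zone
calls are local maxima with height >= 0.02 and width >= 4 bins at half
prominence (`scipy.signal.find_peaks` semantics — the width convention of
the peak detector whose parameters the procedure names). The exponent 6 in
the empirical form is exposed as a tunable parameter; it compensates the
late-S increase of free factors that the constant-`F_free` form ignores.

Two accuracy caveats, established by decomposition experiments on
simulated ensembles and worth knowing before interpreting fitted slopes:

1. At a dRFD local maximum, `diff[i] = OE_i + OE_{i-1} - (termination
   density)`: each observed initiation contributes +1 to two consecutive
   bin differences, and passive terminations inside moderate-efficiency
   zones (zones that failed to fire in a simulation and sit near the
   midpoint of their inter-zone gap) depress the upshift. On our synthetic
   ensembles this makes OE exceed `dRFD/2` at peaks by ~10%.
2. Evaluating `A_x` at the *ensemble-mean* replication time with the
   *ensemble-mean* trace under-predicts OE when the per-bin replication
   time disperses across simulations while `F_free(t)` is not constant
   (a Jensen gap: the integral is convex in `t` wherever `F_free` rises).
   Using per-simulation traces and times removes most of the gap. This is
   the mechanism behind the regime sensitivity of the OE-prediction
   proportionality (reported drifts of 0.6–1.7 across `kon`/`d_PO`
   combinations).

## MRT-RFD consistency and fork speed

`MRT_t(x+l) - MRT_t(x) = (l/v) <RFD>` is fitted per scale `l` with a
through-origin least-squares slope (the relation has no intercept);
windows advance one bin at a time and any window touching a masked or
missing bin is excluded. MRT in fraction units is converted to minutes by
multiplying with an assumed S-phase duration; the known sigmoid distortion
of the fraction-time relation is not modelled. On noiseless constructed
pairs the estimator is exact to machine precision and scale-independent.

## Synthetic landscapes

The generator emulates the structure of inferred human initiation
landscapes, anchored to their published summary statistics:

* **zones**: Poisson-placed initiation zones (default 3.5 per Mb), widths
  gamma-distributed around 45 kb, flat-topped with cosine-tapered
  shoulders (initiation density even across the zone core produces the
  quasi-linear RFD ascent that characterises initiation zones); zone mass
  is amplitude x width, amplitudes gamma-distributed. Zones carry 80% of
  the total mass on roughly 15–20% of bins.
* **floor**: the remaining 20% of mass spreads over the whole genome, but
  not uniformly: its weight decays (1 Mb e-folding) with distance from the
  nearest zone to a basal level of 0.15. This reproduces the strong
  depletion of potential origins in late-replicating DNA (mean spacing
  growing from ~2 kb in the earliest regions to several hundred kb in the
  latest) while leaving no region completely devoid of initiation. A
  strictly uniform floor instead floods late-replicating DNA with origins
  and produces a terminal surge of the firing rate per unreplicated length
  that no measured I(t) curve shows.
* **timing domains**: a lognormal amplitude field with 3 Mb correlation
  length (log-sd 1.0, scaled by the theoretical variance of the smoothed
  noise and centred per chromosome) modulates zone strengths and floor.
  Without it every locus averages to mid-S and the simulated MRT never
  leaves [0.15, 0.85]; with it the MRT spans [0.08, 0.90], as experimental
  profiles do.

Perturbation utilities reproduce the two classic in-silico experiments:
permuting bin values within 200 kb windows (destroys positions, keeps
local integrated strength — degrades RFD, not MRT) and dividing the
amplitude by `1.1 + cos(2x/P)` with `P = 25 Mb` (perturbs broad-scale
strength — degrades MRT, not RFD). The modulation argument is `2x/P`
as printed, with a `2*pi*x/P` variant available. Observation noise adds a
100 kb blur to MRT (Repli-seq resolution) and iid Gaussian noise to RFD,
clipped to [-1, 1].

What the generator does *not* emulate: sequence context, transcription
interference, sigmoid fraction-time warping of MRT, read-count noise
models, and cell-line-specific domain geography. Tests passing on these
fixtures therefore validate the machinery and the in-model relations, not
biological conclusions about any particular cell line.

## Landscape inversion

`I_0` is built from the RFD derivative: per-bin increments, 50 kb
smoothing, negatives clipped, top 20% of bins kept, normalised (a flat RFD
carries no initialisation signal and is rejected). Each round then:

1. grid-searches `(rho_F, r)` by maximising the sum of the Pearson
   correlations of simulated vs target MRT (at 10 kb) and RFD (at 5 kb);
2. simulates an ensemble under the winning parameters;
3. trains the inverter on the simulated pair with target
   `(1 - r) * I + r * uniform`;
4. applies it to the target (experimental) pair to obtain the next
   landscape.

The inverter is a scikit-learn multilayer perceptron over flattened
sliding windows (default 401 bins x 2 channels: MRT, and RFD smoothed
over 50 kb), predicting the centre-bin landscape value; reflective padding
at chromosome ends; chromosome-wise train/validation/test split (defaults:
first chromosome test, second validation, configurable for toy genomes).
Targets are rescaled by their maximum over the training chromosomes and
square-root transformed — the landscape is heavily skewed and a plain
least-squares fit ignores the rare strong bins; predictions are squared
back, clipped at zero and renormalised. Training uses a fixed 200-epoch
adam budget with L2 penalty 1e-3: a validation-loss early stop on a random
split (the obvious alternative) halts after a few epochs on this loss
landscape and underfits by a factor of two in held-out correlation.
Robustness augmentation re-windows the pair after replacing 1% of raw RFD
bins with uniform values in [-1, 1]; targets are never perturbed.

Iteration stops after `n_iter` rounds or two consecutive degradations of
the joint score; the best state is returned with the full history. On
closed-loop fixtures (landscape -> simulated "experiment" -> inversion)
the procedure recovers joint correlations above 0.9 (MRT) and 0.9 (RFD)
in three rounds at 60 Mb, selects the generating `(rho_F, r)` from the
grid, and the recovered landscape correlates with the generating truth at
~0.86, improving monotonically over rounds.

## Problem sizes

Default study conditions are desk-scale by design: 60 Mb genomes
(3 chromosomes) for ensemble statistics and inversion, 200 simulations for
population averages, 40-simulation ensembles inside grid searches, and a
201-bin inverter window in the closed-loop tests. These sizes keep the
full test suite in minutes while leaving ~10^2 initiation zones per
genome; all kinetic regimes are preserved through the `kone` rescaling.

## Known limitations

* The OE-vs-`dRFD/2` and OE-vs-`A_x(MRT_t)` proportionality coefficients
  are regime- and landscape-dependent (see the two caveats above); on the
  default synthetic conditions they measure ~1.10 and ~1.4 respectively
  at detected zones, with correlations of ~0.93 and ~0.78–0.90.
* Replication-transcription conflicts, checkpoint signalling, chromatin
  3D structure and sister-chromatid dynamics are out of scope.
* The fraction-to-time conversion of MRT assumes linearity; very early and
  very late S-phase values are therefore slightly distorted.
* Factor handling at boundaries (pairing of retired forks) is a modelling
  choice; it conserves the pool exactly but has no experimental anchor.
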