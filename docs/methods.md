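# Methods

## Model

The simulation advances an ensemble of independent clusters of synapses in
discrete steps of one day. Synaptic weight `W` is dimensionless and stands
in for dendritic spine volume, which empirically tracks postsynaptic
density size, AMPA-receptor count and EPSP amplitude. The modelling
assumptions are:

- **Daily synchronous updates.** All weights update at once, once per
  simulated day, matching the cadence of chronic spine-imaging experiments.
  Update sizes and directions are uncorrelated across synapses and across
  days.
- **Competing multiplicative LTP/LTD.** Each active synapse receives an LTP
  increment and an independent LTD decrement, both proportional to the
  preexisting weight and to a volatility factor
  `VO(W) = v_hi − (v_hi − v_lo)·W/(W + W_med)` that makes small spines
  fluctuate relatively more. LTP additionally carries a saturation bracket
  `1 − k_hi·W/(W + W_hi)` so that very large spines cannot grow without
  bound. The stochastic amplitudes `r1`, `r2` are Gaussian with sd = mean /
  `sd_ratio`; negative draws are clamped to zero per draw, before use.
- **Cluster-level resource competition.** Strong synapses (`W > T_st`,
  strictly) consume shared maintenance resources, so the mean LTP amplitude
  falls linearly with the cluster's strong count: `a1 = x2 − (x2 −
  x1)·N_st/N_cl`. The increment sd tracks this mean at the fixed ratio
  (the `fixed_ltp` variant instead uses a constant mean and sd, which is
  also the configuration whose separate sd parameter motivates sd tracking
  the mean in the standard model).
- **Silencing and regeneration.** An active synapse whose updated weight
  falls below `T_wk` (strictly) is reset to silent at the basal weight
  `W_sil`. A silent synapse regenerates to `W_reset` with daily probability
  `P_ACT = P_bas·N_st/N_cl`, and only if a chain-adjacent synapse is
  strong. Adjacency is a linear, non-periodic chain: synapse `i` neighbours
  `i−1` and `i+1`, endpoints have one neighbour.

### Intra-day ordering

The order of operations within a day is part of the model definition here:
(1) strong flags and `N_st` are snapshotted from the start-of-day state and
used both for the LTP mean and for regeneration gating; (2) all active
synapses update; (3) silencing is applied to the updated weights; (4)
regeneration applies only to synapses that were already silent at day
start. Consequently a synapse can never be silenced and regenerate within
the same day, and a synapse silenced today cannot have gated a neighbour's
regeneration today. This is one self-consistent synchronous semantics; the
qualitative results do not depend on the tie-breaks.

## Parameters

| symbol | default | meaning |
|---|---|---|
| `N_cl` | 10 | synapses per cluster (chain) |
| `W_reset` | 0.4 | weight on regeneration |
| `W_sil` | 0.05 | basal weight of a silent synapse |
| `T_wk` | 0.08 | silencing threshold |
| `T_st` | 0.8 | strong-synapse threshold |
| `v_hi`, `v_lo` | 4.0, 0.2 | volatility bounds at `W=0` and `W≫W_med` |
| `W_med` | 0.4 | volatility half-saturation weight |
| `x1`, `x2` | 0.144, 0.18 | min/max mean LTP amplitude |
| `a2` | 0.16 | mean LTD amplitude |
| `sd_ratio` | 4 | increment mean / sd |
| `k_hi`, `W_hi` | 0.05, 20.0 | LTP saturation parameters |
| `P_bas` | 0.1 | maximal daily regeneration probability |
| `a1_fixed`, `sd1_fixed` | 0.16, 0.04 | `fixed_ltp` variant amplitude |
| `lambda1`, `lambda2` | 1.0, 1.0 | exponential-variant decay rates, in [0.5, 3.0] |

All weights are dimensionless; time is in days. These defaults are the
standard values used by every protocol unless explicitly overridden, and
they place the stationary state in the regime where roughly half the
synapses of a cluster are strong (`a1(N_st) ≈ a2` at `N_st ≈ 5`).

## Random numbers and reproducibility

Each run is driven by one NumPy `Generator` seeded from the run's seed.
Every day the raw draws are generated in a fixed, state-independent order:
for every synapse (cluster-major) a standard-normal pair (LTP then LTD; raw
uniforms in the exponential variant), then one regeneration uniform per
synapse. Draws are made for every synapse whether or not they are used, so
the stream layout never depends on the state; this is what lets the
vectorized ensemble kernel and the naive per-synapse loop consume the same
draws and agree bit for bit (checked in the tests), and makes runs
bit-reproducible given (seed, parameters, sizes).

The initial condition is all synapses active at `W = 1.0`. It is forgotten
by burn-in: runs started from `W = W_reset` give the same stationary
summaries (tested), and summaries at 10,000, 20,000 and 50,000 days agree
within Monte-Carlo error across seeds. Protocols therefore default to a
long (50,000-day) burn-in but are routinely run at 10,000; the acceptance
script and the figure-scale tests use 10,000-day burn-ins with 1,000
clusters and three seeds per stochastic quantity, and 10,000
re-equilibration days after parameter perturbations (measured identical to
5,000 and 20,000).

## Analysis choices

- **Weight histograms** use 80 bins of equal width in natural-log units
  spanning the observed range; counts are conserved by construction.
- **Log-normal fits** default to maximum likelihood (mean and sd of
  `ln W`, active synapses); a least-squares fit of a Gaussian to the binned
  `ln W` histogram is provided for parity with figure-style fits to binned
  curves. The two differ when the sample departs from log-normality (the
  simulated distribution has slightly heavy shoulders, so the histogram
  fit reports a larger sd).
- **Daily-change fits**: the one-day `ΔW` sample of active synapses
  contains a sharp concentration near zero contributed by small synapses
  (for which `ΔW ∝ W` is tiny). The default figure-style fit is a
  least-squares Gaussian on the 80-bin histogram excluding bins with
  |center| ≤ 0.01 over a symmetric range at the 99.9th percentile of
  |ΔW|; this recovers the sd of the broad component (≈ 0.067–0.07 at
  standard parameters) rather than the pooled moment sd (≈ 0.087).
  Moment estimates with and without the exclusion are also reported.
- **ΔW is the pre-silencing increment** of synapses active at day start;
  regeneration jumps are not counted as ΔW. The mean relative daily change
  is `100·mean(|ΔW|/W_pre)` over those synapses (the absolute value is
  required for a nonzero statistic, since signed changes average to ≈ 0 at
  steady state). Sensitivity: including silent synapses (ΔW = 0) lowers
  the figure by the silent fraction, ≈ 10% relative.
- **Decorrelation** uses the product-moment correlation between all
  weights (silent included at `W_sil`) at a steady-state reference day and
  the same synapses later, sampled every 10 days to 1,500 days, fitted by
  nonlinear least squares to `R(t) = exp(−t/τ)`; a variant with additive
  offset `c + (1−c)·exp(−t/τ)` is available behind a flag. A constant
  series is reported as a fit failure rather than a spurious τ.
- **Perturbation response** is the relative change of the mean weight over
  all synapses (silent at `W_sil`) between the equilibrated baseline and
  the re-equilibrated perturbed run continued from the same state with an
  independent stream; the active-only change is reported alongside.
- The piecewise-linear empirical volume-change model (`yasumatsu_c1`,
  `ΔV = −0.16V + 0.01` for `V ≤ 0.25`; `0.12V − 0.06` for `0.25 < V ≤
  0.5`; 0 above) is included as a standalone reference used to motivate
  the one-day step; both branch boundaries are continuous, with `V = 0.25`
  assigned to the first branch and `V = 0.5` to the second.

## What the simulations do and do not show

The generator *is* the model: there is no external data. Runs at the
standard conditions (1,000 clusters × 10 synapses) reproduce the
qualitative phenomenology of chronic spine-imaging experiments: a
stationary, unimodal, heavy-tailed (approximately log-normal) weight
distribution spanning ~5 natural-log units; greater relative volatility of
small spines; a stable strong-synapse count per cluster (N_st in [4, 7]
for ≈ 99% of cluster-days over 2,000 days); slow decorrelation of the
specific weight pattern (τ ≈ 1,000 days at these parameters); and
persistence of an imprinted strong subset at ≈ 1.8× the steady-state mean
700 days after imprinting. None of this validates the model against real
imaging data — no empirical dataset is fitted here.

## Known limitations

- Several externally reported reference values for this model family are
  not reached by the equations as implemented, and the corresponding
  acceptance-style checks fail at their stated tolerances: the measured
  mean relative daily change is ≈ 6.2% (reference 16.5%), the log-normal
  sd ≈ 1.04 (reference 0.9341), the active count ≈ 9,000/10,000
  (reference 9,482), τ ≈ 1,000 days (reference ≈ 500), the 5% LTP-cut
  response ≈ −46% (reference −16%), and the fixed-amplitude variant
  collapses fully after a 2% cut (reference 56% silent). Analytically,
  the reference values are not mutually consistent under these equations:
  the daily-change sd of 0.07 pins the increment sd at mean/4, and under
  that noise level the stated 16.5% daily change (and the buffered
  perturbation responses) cannot arise; with `a1_fixed = a2` the
  fixed-amplitude variant has strictly negative drift at every weight and
  admits only a collapsed steady state. The implementation follows the
  equations; the checks are kept at their stated tolerances and left
  failing.
- Small clusters (`N_cl = 5`) remain unimodal here rather than going
  bimodal.
- No spatial geometry beyond chain adjacency, no explicit mRNA/protein
  resource dynamics, no molecular slot model, and no fitting to empirical
  spine data.
- The exponential-increment variant is numerically unbounded by design;
  with strongly unequal rates weights overflow to astronomically large
  values within a few thousand days (use short horizons).
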