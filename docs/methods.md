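# Methods

## Scope

`gliasim` simulates networks of point neurons and point astrocytes
coupled through tripartite connectivity: chemical synapses between
neurons, glutamatergic neuron-to-astrocyte signalling expressed as
instantaneous IP3 increments, and astrocyte-to-neuron slow inward
currents (SICs).  Execution is single-process on a fixed time grid.

## Astrocyte model

The astrocyte follows the two-variable Li-Rinzel reduction of the De
Young-Keizer IP3-receptor (IP3R) model.  State variables are cytosolic
calcium `ca` (uM), IP3 concentration `ip3` (uM), and the fraction `h`
of IP3Rs not inactivated by calcium.  The calcium balance is

    dca/dt = J_channel - J_pump + J_leak        (+ noise)

with IP3R-gated release from the endoplasmic reticulum (ER),

    J_channel = r_ER_cyt * v_IP3R * (m_inf n_inf h)^3 * (ca_ER - ca),
    m_inf = ip3 / (ip3 + Kd_IP3_1),   n_inf = ca / (ca + Kd_act),

SERCA pump uptake `J_pump = v_SERCA ca^2 / (Km_SERCA^2 + ca^2)` and a
passive leak `J_leak = r_ER_cyt v_L (ca_ER - ca)`.  Total calcium is
conserved: the ER concentration is derived as
`ca_ER = (Ca_tot - ca) / r_ER_cyt` at every step, and after every grid
step `ca` is clamped to `[0, Ca_tot]` and `h` to `[0, 1]`, so the noise
term can never produce a negative concentration.  Gating follows
`dh/dt = alpha_h (1-h) - beta_h h` with
`alpha_h = k_IP3R Kd_inh (ip3 + Kd_IP3_1)/(ip3 + Kd_IP3_2)` and
`beta_h = k_IP3R ca`.

IP3 decays exponentially to its baseline and jumps by
`delta_IP3 * weight` for each presynaptic spike delivered through a
neuron-to-astrocyte (`third_in`) connection:

    dip3/dt = (IP3_0 - ip3) / tau_IP3 + delta_IP3 * J_syn(t).

Increments are applied at the start of the grid step in which the
delayed spike arrives, before the ODE integration; simultaneous arrivals
sum linearly.  Only excitatory input is accepted.

The SIC drive is the Nadkarni-Jung phenomenological expression

    F_SIC = SIC_scale * ln((ca/nM - SIC_th)/nM)   if the log argument > 1,
    F_SIC = 0                                      otherwise,

with the **natural** logarithm.  Internally concentrations are in uM;
`SIC_th` is stored in nM and the uM-to-nM conversion is explicit.
F_SIC is dimensionless, non-negative, continuous and non-decreasing in
calcium; the pA unit enters through the weight of the
astrocyte-to-neuron (`third_out`) connection.

Shipped defaults (`gliasim/data/astrocyte_default.json`) are the
published Li-Rinzel constants (`Ca_tot` 2 uM, `IP3_0` 0.16 uM,
dissociation constants 0.13/0.9434/0.08234/1.049 uM, rates 0.006/ms,
0.0009 uM/ms, 0.00011/ms, `r_ER_cyt` 0.185) with the standard SIC
threshold of 196.69 nM.

A surrogate astrocyte is provided for benchmarking: it has no internal
dynamics, ignores input spikes, and emits a constant, configurable
F_SIC.

## Neuron model

Neurons are adaptive exponential integrate-and-fire (AdEx) cells with
conductance-based alpha synapses and an additive SIC term:

    C_m dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T)
                - w + I_syn + I_SIC + I_noise,
    tau_w dw/dt = a (V - E_L) - w,

with `I_syn = -g_exc (V - E_exc) - g_inh (V - E_inh)`.  On reaching
`V_peak` the reset `V -> V_reset, w -> w + b` applies and `V` is held at
`V_reset` for the refractory time `t_ref`; no two spikes of a cell can
be closer than `t_ref`.  The exponential term is clamped at
`(V - V_T)/Delta_T = 10` so the potential races to `V_peak` at a bounded
rate instead of overflowing; spike detection happens at substep
resolution and the spike time is recorded at the end of the grid step.

Alpha conductances are normalized so that a single spike of weight `w`
(nS) peaks at exactly `w` one synaptic time constant after arrival.

## Numerical integration

Each cell is advanced per grid step with an embedded
Runge-Kutta-Fehlberg 4(5) pair, adaptive substeps bounded above by the
grid step, relative/absolute mixed error control
`|y5 - y4| <= tol (1 + |y5|)` with default `tol = 1e-6`, step-size
update `0.9 err^(-1/5)` limited to [0.1x, 5x], and a hard failure when
the substep underflows below 1e-10 of the grid step.  For neurons, the
alpha-conductance pairs form a linear subsystem and are propagated with
their closed-form solution; the RKF45 pair integrates only (V, w),
sampling the exact conductances at the Fehlberg stage times.  An
all-six-variable RKF45 variant is kept internally and cross-checked in
the test suite.  Conductance values below 1e-12 nS are flushed to zero
(subnormal arithmetic would otherwise dominate run time).  The grid step
is configurable (0.01 / 0.1 / 0.2 ms by convention); experiments use
0.1 ms.

Calcium noise is applied as a per-step additive Gaussian increment of
standard deviation `noise_sd * sqrt(dt)` (Euler-Maruyama convention),
and neuronal current noise is redrawn per step and held constant within
it.

## Connectivity

Primary neuron-to-neuron connections support four rules: pairwise
Bernoulli (one trial per ordered pair, hence no multapses), fixed
in-degree, fixed out-degree, and fixed total number.  Autapses are
excluded by default; multapses default to allowed for the fixed-degree
and fixed-total rules.

The third-factor Bernoulli-with-pool (TBP) rule attaches astrocytes to
primary connections.  Every target neuron owns a fixed pool of
astrocytes: random pools are drawn without replacement from the whole
astrocyte population, block pools tile it deterministically in
ascending-id contiguous blocks (size-1 blocks require the target count
to be a multiple of the astrocyte count; larger blocks require exactly
`S_pool` astrocytes per target, giving disjoint pools).  For each
primary connection with an excitatory source, independently with
probability `p_third_if_primary`, one astrocyte is drawn uniformly from
the target's pool and a `third_in` (source -> astrocyte) plus a
`third_out` (astrocyte -> target) edge are appended.  Repeated selection
of the same astrocyte creates multapses; `third_in` duplicates are not
collapsed.  Generation order is fixed (targets ascending, sources
ascending within a target), so one seed fully determines the graph —
an order-equivalent sequential replacement for buffered parallel
construction.

## Engine

Time advances on a fixed grid; all delays must be positive multiples of
the grid step.  A spike emitted at step k on an edge with delay D grid
steps affects its target exactly at step k + D.  Delayed delivery uses
per-buffer rings for excitatory/inhibitory conductance increments and
astrocytic IP3 weights.  SIC is delivered continuously: each `third_out`
edge contributes `weight * F_SIC` evaluated from its astrocyte's state
the edge's delay earlier, sampled once per grid step (piecewise
constant).  Poisson drive is realized as per-step Poisson counts
delivered as conductance events within the same step.

Randomness is counter-based: every draw is a hash of (master seed, cell
id, stream kind, step, draw index), giving per-cell logical streams that
are independent of evaluation order and of attached recorders, and
byte-identical recordings for equal seeds.

## Benchmark networks

Populations follow a 4:1 excitatory:inhibitory ratio with equally many
astrocytes as neurons; scale 1 means 8,000 + 2,000 neurons and 10,000
astrocytes.  Connectivity: pairwise Bernoulli `p_primary = 0.1` (any of
the four rules can be selected with matched expected connection
counts), TBP with random pools of 10 and attachment probability 0.5 —
giving a mean astrocytic in-degree of 400 at scale 1.  Weak scaling
rescales `p_primary` by 1/scale so expected per-cell degrees are
preserved.  Drive and synaptic parameters (Poisson drive per neuron,
1 nS excitatory and 4 nS inhibitory weights) were selected so that the
default ("sparse") variant shows low-rate asynchronous spiking near
4.7 spikes/s; the "synchronous" variant differs only in the inhibitory
delay and synaptic time constant and shows oscillatory synchrony at a
higher rate; the "surrogate" variant replaces every astrocyte with the
surrogate model, whose constant output is set to the mean F_SIC observed
in the sparse variant so that the firing rate is close to sparse.

## Use-case models

A slice-like circuit of 400 excitatory and 100 inhibitory neurons and
100 astrocytes, pairwise Bernoulli `p_primary = 0.2`, 5 nS synaptic
weights, 1 ms delays, and population Poisson drives of 2700 (exc) and
2500 (inh) events/s.  Four regimes: `ttx` (all neuron-neuron weights
zero, no Poisson drive to neurons, weak current noise; spiking occurs
only through SIC), `block_async` and `block_burst` (block pools of size
one; the 500 targets are interleaved as 4 excitatory + 1 inhibitory per
astrocyte, producing 100 disjoint groups; the neuron-to-astrocyte weight
0.2 vs 0.31 switches between asynchronous activity and network-wide
bursting), and `random_pool` (random pools of 5, attachment probability
0.03, with correspondingly larger third-factor weights).

The five free astrocyte parameters (Poisson input rate, `delta_IP3`,
`Ca_tot`, `IP3_0`, `tau_IP3`) were selected with the shipped
random-sampling scan (`astro_parameter_scan`): a candidate set is
simulated as a single noise-driven astrocyte and accepted when its
calcium transients have a frequency of 0.1–1.5 per minute, durations of
1–20 s, and peaks of 0.2–0.7 uM.  The accepted configuration used in
the experiments sits just below the oscillatory regime of the IP3R
model, so transients are noise-evoked and the cell returns to a fixed
point without input; its total calcium keeps even IP3-saturated
plateaus below 0.7 uM.  In network simulations the astrocytic Poisson
rate is reduced to 70% of the fitted value to compensate for the
additional synaptic glutamate signalling.

Neuron parameters derive from the initial-bursting (excitatory) and
tonic-spiking (inhibitory) AdEx configurations, modified so that (a) a
SIC-sized current step evokes a short burst of a few spikes lasting
about a second (strong spike-triggered adaptation ends the burst and
prevents the SIC feedback loop from self-sustaining), and (b) under the
stated Poisson drives the excitatory population is nearly silent
(~0.1 spikes/s) while the inhibitory population fires at a few
spikes/s.  Per-cell heterogeneity draws the fitted astrocyte parameters
and the neuronal `b` and `V_reset` from truncated Gaussians (5%
relative SD, 10% cutoff).  Initial membrane potentials are spread
uniformly to avoid a synchronized drive-onset volley.

## Analysis

* Mean firing rate: total spike count / (N * window length).
* Spike-count correlation: Pearson r on binned counts, 10 ms
  non-overlapping bins for the benchmark and a 2 s window sliding by
  4 ms for the use case; silent (zero-variance) cells are excluded
  pairwise from the average.
* SIC-gated bursts: spikes closer than 2 s (excitatory) or 400 ms
  (inhibitory) belong to one burst; a burst counts only if it has at
  least 2 spikes (configurable) and starts between a SIC window's onset
  and its offset plus the gap threshold.  SIC windows are zero
  crossings of the recorded summed I_SIC trace, merged below 500 ms.
* Calcium transients: crossings of the SIC trigger level
  (`SIC_th` + 1 nM, in uM), merged below 500 ms, with per-transient
  peak; frequency is count / model time.
* Burst-onset distance: onsets of the shorter list matched to distinct
  onsets of the other; the default greedy matcher (ascending absolute
  difference) and an optimal-assignment matcher coincide for
  well-separated bursts, which is the regime the statistic is used in.
* Group contrasts: two-sample Kolmogorov-Smirnov with Bonferroni
  correction over the four tests per experiment (two measures x two
  contrasts).
* Network-wide bursts (needed for the bursting-regime duration
  statistic) are defined on the population rate in 100 ms bins as
  contiguous regions above twice the median count; the threshold factor
  is configurable.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the
experiments: benchmark dynamics at scale 0.1 (2,000 cells, per-cell
degrees preserved) over 4.5 s of model time after 0.5 s of warm-up;
use-case runs of 90 s (asynchronous), 60 s (TTX) and 120 s (bursting)
after 5 s of warm-up in the test suite, and 60/45/100 s in the
standalone reproduction script; the full-size (scale 1, 20,000 cells)
benchmark graph is built for connectivity statistics but not simulated.  Transient and
burst statistics at these sizes carry sampling error of roughly
+-0.1/min (100 astrocytes x 1 min) and a few hundred ms on mean burst
durations.

## What the synthetic experiments do and do not show

All inputs are generated programmatically: Poisson drives, Gaussian
noise, and the connectivity ensembles defined above.  Passing tests
demonstrate the internal consistency of the framework — conservation
and clamping, delay exactness, reproducibility, the statistical
contracts of the connection rules, and that the fitted models reproduce
the targeted transient statistics and synchrony contrasts.  They do not
validate the biophysical parameters against raw experimental
recordings, model astrocyte morphology or gliotransmitter pathways
beyond glutamate-evoked SICs, or address distributed execution.

## Known limitations

* Single-process only; no MPI/threading.
* SIC is piecewise constant between grid points; sub-grid SIC dynamics
  are not resolved.
* The surrogate-substitution equivalence holds only in the mean-drive
  sense; fluctuations of F_SIC are not emulated.
* Block pools assume ascending-id contiguous blocks; other tilings are
  not provided.
* The use-case network is bistable by construction (a quiescent
  low-rate state coexists with a high-rate state); extreme parameter
  perturbations can flip it.
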