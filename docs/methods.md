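# Methods

## Overview

`lineagesim` simulates cell-viability drug assays at single-cell,
single-lineage resolution.  An in-silico population is first *heterogenized*
(independent stochastic gene-expression runs from one average serum-starved
state) and *asynchronized* (each cell's treated-phase initial condition is
its state at a uniformly random time of a growth-stimulated window).  Drug
treatment is then simulated generation by generation: each living cell runs
for its remaining time, divisions are detected as peaks of a cyclin-B-like
marker, deaths as a cleaved-marker threshold crossing, daughters inherit the
mother's state at division, and the loop ends when a generation produces no
divisions.  Analytics on the recorded lineages cover growth curves and
doubling time, the growth-rate-inhibition (GR) dose-response metric, death
fractions in an observation window, dendrograms and Newick trees, fractional
cycle progress, division-probability-vs-progress curves, and PCA/PLSR on
Gen-1 mother states.

The engine is model-agnostic (see `model_contract.md`).  All desk-scale work
uses the built-in minimal cycle model described next; it is a deliberately
small stand-in for a mechanistic whole-cell model, built so that every piece
of the pipeline has a closed-form or arithmetic oracle.

## The minimal single-cell model

State per cell: cumulative cycle phase `phase`, telegraph gene state
`gene_state` (0/1), transcript count `transcripts`, smoothed expression
activity `E`, three cyclin-like phase markers, a cleaved death-marker
fraction, and (with a drug attached) intracellular drug `D_in`, free target
`T_free` and complex `TD`.

**Phase dynamics.**  `dphase/dt = GF * (a_E + b_E * E) / T0 * S(t)` in
cycles per hour, `T0 = 24 h`, `a_E = b_E = 0.5` so the mean-expression cell
(`E = 1`) cycles at period `T0`.  `GF` is a 0/1 growth-factor switch (off
during heterogenization).  Phase is cumulative, so the completed-cycle count
is recoverable from the state.

**Markers.**  Each marker is a periodic bump
`exp(kappa * (cos(2*pi*(phase - c)) - 1))` with centers
`c = (0.45, 0.70, 0.95)` and `kappa = 10`.  The B-like marker (`c = 0.95`)
is the division marker.  The centers cluster in the second half of the cycle
(cyclin E at G1/S, A through S/G2, B at mitosis) leaving one wide gap after
the B peak; consequently the average of the max-normalized markers has a
single deep trough per cycle, at phase `(0.95 + 1.45)/2 = 1.20`, i.e. 0.20
after the B peak.  This is what makes the trough-to-trough definition of
cycle progress well posed: with near-equally spaced or very narrow bumps the
averaged trace has several indistinguishable minima per cycle and the
progress estimator has no unique cycle anchor.  The within-cycle dips of the
averaged trace sit at ~0.035 of its maximum versus ~1e-5 at the true trough,
so a 5%-of-maximum floor separates them robustly.

**Restriction point.**  The commitment window is the first `R = 0.1` of the
cycle *measured from the trough phase*: a drug rescales the phase speed by
the factor `S` only while `frac(phase - 0.20) < R`; a committed cell
finishes its current cycle at full speed.  Measuring commitment from the
trough (the natural cycle start: early G1, right after cyclin-B decay)
rather than from the arbitrary phase origin makes the threshold coincide
with estimated progress `R` by construction, and gives the
divide-once-then-arrest pattern at saturating dose: a daughter born at the
B peak (progress 0.75 past the trough) is committed only until it crosses
the next trough, then arrests.

**Expression noise.**  The only stochastic element is a telegraph gene:
first-order on/off switching, Poisson transcript births from the active
state and Poisson first-order decay, advanced every 30 s of simulated time
(one uniform draw per gene per step for switching; death draws truncated so
counts stay non-negative).  Defaults: stationary mean 20 transcripts
(`p_on = 1/2`, `k_m/gamma_m = 40`), 30-min transcript lifetime, and a
**24 h switching timescale**.  The slow timescale is a deliberate choice:
expression bursts then persist across a large part of the 72 h assay and are
inherited by daughters (both daughters copy the mother's gene state and
counts), which is the heritable proliferative-capacity heterogeneity the
mother-cell state analysis is designed to expose.  With fast (hours)
switching, expression noise averages out and division counts are governed
almost entirely by initial cycle phase; with the 24 h default, Gen-1
division counts span the low/moderate/high categories and the expression
block (gene state, transcripts, activity) carries the top PLSR loadings.
`E` relaxes toward `transcripts / mean` at `k_E = 0.2 /h`, converting
transcript noise into smooth cycle-speed heterogeneity (~15% period CV).

**Death.**  `d(cleaved)/dt = k_apop * s_tox * D_in`, clipped to [0, 1];
`s_tox` defaults to 0 (the built-in inhibitors are cytostatic in this model,
matching their primarily growth-inhibitory action), so death paths are
exercised with `s_tox > 0` or with synthetic fixtures.

**Integration.**  Hybrid fixed-step scheme: stochastic updates every 30 s;
between them `E` is advanced by its exact exponential relaxation, phase by
an explicit step with the current speed, and the drug subsystem by RK4 with
sub-steps sized so `rate_max * dt < 0.2`.  Because the drug subsystem has no
feedback from the rest of the cell and its reservoir is clamped, it is
frozen once its per-step change falls below 1e-12 relative — after that the
equilibrium values are held exactly.  Output is recorded every 6 min.
Integration is vectorized across all cells of a generation; randomness flows
from a single root seed through named streams per (replicate, stage or
generation), so any run is bit-reproducible from its config.

## Pharmacodynamic modules

Each drug: first-order membrane transport at 0.01 /s against a clamped
extracellular dose (the nuclear compartment of the CDK4/6 inhibitor is
collapsed into the single intracellular compartment — two identical
sequential transport steps would only delay equilibration), mass-action
binding `D + T <-> TD`, and optional bound-complex degradation balanced by
constant synthesis so the total target pool (default 100 nM, a declared
config value) is stationary.  Built-ins: alpelisib Kd 2.4 nM, palbociclib
Kd 1.9 nM, trametinib Kd 0.35 nM (all kon 1e-3 /nM/s), neratinib
irreversible with kon 1e-4 /nM/s; neratinib's multi-receptor binding is
pooled into one target, a noted fidelity limit.  A bound target is inactive;
coupling to the cell model is through the free-target fraction
`f = T_free / (T_free + TD)`, either linearly (`S = f`, default) or through
a normalized Hill function.  Mass conservation (`T_free + TD` constant at
`k_deg = 0`) is exact to rounding because every RK4 stage preserves the sum.

Module behavior is verified against its own printed constants by
simulation: equilibrium titrations return half-occupancy at `koff/kon`
within fractions of a percent, free-target decay under clamped drug excess
is exponential at `kon * D`, and intracellular drug reaches 95% of the
external dose in 5 simulated minutes.

## Event detection

Divisions are `scipy.signal.find_peaks` maxima of the cycle-marker trace
with prominence at least 20% of the trace's own maximum (detection is
therefore invariant to marker rescaling), separation at least `0.25 * T0`,
and an absolute floor of 0.05.  Endpoints are never peaks: a cell born on
the rising flank of an imminent peak (marker already above 80% of maximum)
cannot certify that peak and its first detectable division is one period
later; the test-suite phase oracle models exactly this rule.  Death is the
first linear-interpolated crossing of the cleaved fraction above 1/2
(interpolation keeps the trailing observation window grid-independent).
When both events are detected, the earlier wins; an exact tie counts as
death (conservative).

## Cycle progress and division probability

Each progress marker is normalized by its own observed peak (the reference
peak substitutes when a cell spans less than a full cycle), the markers are
averaged, and per-cycle troughs are the local minima below 5% of the trace
maximum.  Progress at time t is `(t - previous trough)/(next - previous)`;
when a bracketing trough is unobserved, the trough-to-trough period of a
deterministic (noise-free) reference simulation substitutes for the
denominator.  Progress at dose time is evaluated on each cell's Gen-0
trajectory at its asynchronization sample point — i.e. from pre-dose marker
dynamics, where troughs are observable even for cells arrested by the drug.
On noise-free cells the estimate is exact to rounding; with default noise
its error is unbiased with standard deviation ~0.05.

The division-probability curve splits cells into divided/non-divided
groups, estimates each group's progress density with a Gaussian KDE (Scott
bandwidth), and forms `P(divide | bin) = n_d f_d / (n_d f_d + n_n f_n)` on
0.01-wide bins.  Progress is a circular variable (0.99 and 0.01 are
adjacent), so densities are evaluated with wrap-around replicas; without
this, group mass leaks past the 0/1 boundary and biases the 0.5 crossing
near the commitment point.  Groups smaller than 5 fall back to direct
binning (flagged on the returned curve).  At a saturating dose (1000 x Kd,
99.9% occupancy) the Gen-1 curve crosses 0.5 at ~10% progression — the
commitment fraction `R` — with a per-seed spread of about one percentage
point at 500 cells.

## GR dose response

`GR = 2^(log2(x/x0) / log2(x_ctrl/x0)) - 1` from living-cell counts at the
end of the window; each replicate is normalized by its own control
(replicates are independent end to end, so the standard error over
replicates reflects full pipeline variance), and dose comparisons are paired
by reusing one asynchronized Gen-1 pool per replicate across doses (the pool
streams do not depend on dose).  GR at control equals 1 and at cytostasis 0
exactly.  Four-parameter GR curve fitting (GR50/GRmax) is out of scope.

## State analysis

One row per Gen-1 mother (her initial state), response `y` = number of
division events in her lineage subtree; categories low/moderate/high with
half-open boundaries `[0,6)/[6,16)/[16,inf)`.  Columns with zero variance
are dropped before z-scoring (they carry no signal and would divide by
zero); one pooled scaler is fitted across all supplied conditions (a
per-condition option would refit per group; pooled is the default because
projections of treated states onto control-fitted axes must share the
control scaler).  PCA, standardization and PLSR are scikit-learn
(`svd_solver="full"`, `PLSRegression(scale=False)`); loadings are ranked by
absolute value with sign retained, and projection of new conditions applies
the control-fitted scaler and rotation with no refit.

## What the synthetic setting does and does not show

The minimal model reproduces the *algorithmic* behaviors of the pipeline —
asynchronous phase structure, restriction-point gating, cytostatic
dose-response shapes, heritable-capacity loadings — with known ground truth.
It does not emulate receptor-level signaling, pathway crosstalk, drug-
induced apoptosis cascades, cell-cycle checkpoint biology, or realistic
species dimensionality; quantitative dose-response values from a
mechanistic whole-cell model (or experiment) are outside what passing tests
here can certify.  Problem sizes in the test-suite and acceptance runs
(populations of 20-500 cells, 1-5 seeds, 21-point titrations) were chosen as
the smallest sizes at which the respective statistics are stable.

## Numerical choices and degenerate inputs

* Time unit is hours externally; per-second rate constants are converted
  internally (x3600).
* Output grid 6 min; stochastic step 30 s; both configurable.
* A division detected in the final output step spawns daughters censored
  immediately, preserving the census identity.
* Peaks within the separation window keep the higher (earlier on ties).
* Flat marker traces make cycle progress undefined — an error, never a
  fabricated value; the `analyze` command skips the progress curve with a
  warning in that case.
* Zero-variance z-score columns are dropped and recorded on the scaler;
  constant PLSR responses are rejected.
* Titration grids must bracket half-occupancy; irreversible binders have no
  titration Kd.

## Known limitations

Single pooled drug target per model; no spatial effects, contact
inhibition or nutrient depletion; no checkpoint/restart; the divider hook is
the only asymmetric-division mechanism; MPI/cluster execution is out of
scope (cells within a generation are independent, and the per-generation
random streams keep results order-independent, but the shipped runner is
sequential and vectorized rather than parallel).
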