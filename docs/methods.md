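# Methods

## Model overview

`ca1net` models the isolated CA1 area as a network of point neurons inside a
laminar prism (stratum oriens / pyramidale / radiatum / lacunosum-moleculare
stacked along z; longitudinal x, transverse y). One principal type
(pyramidal cells) and eight interneuron classes are wired through a
per-type-pair synapse-budget matrix; 454,700 Poisson stimulating units stand
in for CA3 (204,700) and entorhinal layer III (250,000) afferents. None of
the cells is spontaneously active: all activity is driven through the
stimulating units, so a silent-afferent network is silent.

## Neurons

Each type is an adaptive exponential integrate-and-fire (AdEx) neuron. This
is a deliberate reduction: the reference system pairs one morphologically
detailed pyramidal model with single-compartment interneurons, but the only
printed single-cell contract is a table of whole-cell measurements (resting
potential, input resistance, membrane time constant, rheobase, threshold,
spike latency and width), and AdEx can satisfy that contract at desk scale.
The fit is mostly analytic:

- E_L, R_in, τ_m are taken directly from the targets (C = τ_m g_L).
- V_T = E_L + Δ_T + R_in·I_rheo pins the steady-state rheobase
  g_L (V_T − Δ_T − E_L) to the measured rheobase.
- Δ_T is grid-searched (scripts/fit_cells.py) so that the *measured*
  threshold — the voltage where dV/dt first crosses 20 mV/ms, a standard
  criterion the source does not specify — lands on the target threshold.

Measured passive values come back within 2% (mostly <0.5%), rheobase within
~1%, thresholds within ~1 mV. Two table entries are physiologically
implausible (a pyramidal threshold of "52.0" mV and an O-LM threshold of
"100.2" mV, with matching ~100 ms half-widths) and are treated as printing
errors: those two cells keep the default Δ_T = 2 mV and their
threshold/half-width targets are excluded from strict checks.

Adaptation parameters (a = 0, spike increment b, τ_w) are not constrained by
the table; they encode the qualitative firing profiles (fast-spiking types
adapt weakly; pyramidal, O-LM and the regular-spiking types adapt strongly)
and, for pyramidal cells (b = 80 pA, τ_w = 130 ms), set the post-burst
recovery time that paces the population rhythm. Spike half-width is reported
for completeness but is not meaningful in a point model.

## Synapses

Double-exponential conductances g(t) = ĝ N (e^(−t/τ2) − e^(−t/τ1)), with N
normalizing the peak to ĝ and the closed-form charge ĝ N (τ2 − τ1) ΔV.
Channel families: AMPA (0.5/3 ms, 0 mV), fast GABA-A (0.3/5 ms, −60 mV), a
slower GABA-A used by neurogliaform and ivy outputs (1/11 ms, −60 mV), and
GABA-B (−90 mV). GABA-B kinetics are not printed anywhere; 25/100 ms
rise/decay was chosen within the physiological range during network
calibration (below). Neurogliaform outputs are mixed GABA-A,B synapses; the
packaged conductance ratio makes the charge-matching factor — the scale k
by which the fast GABA-A conductance must grow to carry the GABA-B charge at
a −50 mV reference — come out at ≈300, consistent with the reported
compensation experiment. Paired recordings are simulated under ideal
voltage clamp; trial-to-trial variability enters only through resampling the
synapse zone, whose attenuation factor stands in for dendritic filtering.

## Connectivity

The three-step wiring algorithm per (pre, post) pair:

1. all pre-post distances in the XY plane only;
2. the pair's connection budget (total synapses / synapses-per-connection)
   split into 100 µm radial bins by the Gaussian mass of the presynaptic
   type's axonal bouton profile (largest-remainder rounding, so quotas sum
   exactly to the budget);
3. candidate pairs assigned to their bins; each bin's quota sampled
   uniformly without replacement.

An ordered pair connects at most once, with the pair's fixed 1-10 synapses
per connection. Where a bin holds fewer candidates than its quota, the
deficit moves to the nearest non-exhausted bins, alternating inward/outward
— this preserves the total connection count and distorts the distance
profile minimally; the source does not state its own shortfall rule. Each
projection draws from its own named RNG stream, so perturbing one projection
leaves every other byte-identical. Conduction delays (unspecified in the
source) default to 0.5 ms + distance/(300 µm/ms) and are stored per edge.

Axonal Gaussian parameters (mean, SD, maximum extent per type) exist only as
figures in the source; the packaged triples are documented estimates, fully
configurable, as are the prism dimensions and layer heights (the quantitative
anatomical assessment they derive from is external to the source text).
Interneuron counts per type (5,530 PV+ basket … 8,810 ivy) come from the same
assessment and sum exactly to the printed 27,240.

## Engine

Clock-driven integration at a fixed step (default 0.025 ms): forward update
of the AdEx membrane (exponential term clipped at e^16 for stability),
exact exponential decay of the synaptic rise/decay states, event delivery
with per-edge delays rounded to the step. A per-step pending-event ring
makes replay deterministic for a given (configuration, seed, dt).
Perturbation operators either rewrite edge weights in place and reversibly
(muting, GABA-B removal/compensation) or transform the configuration
(recurrence scaling, the staged interneuron morph), so every perturbed
condition is itself an ordinary, buildable configuration. Network clamp
extracts one cell with its incoming synapses intact and drives every
presynaptic source with a prescribed spike train.

## Analysis pipeline

- **SDF**: 1 ms binned counts convolved with a unit-mass Gaussian kernel.
  The source's "window of 3 ms" is read as kernel SD = 3 ms (truncated at
  ±3 SD), following the SD parameterization of the cited SDF method; the
  kernel is renormalized at the edges so the series always integrates to the
  spike count.
- **Spectra**: one-sided Welch periodogram, Hamming window, 50% overlap;
  segment length (unprinted) defaults to 1024 ms. Band peaks are read in
  theta (5-10 Hz) and gamma (25-80 Hz; low gamma 25-40 Hz).
- **Band filtering**: zero-phase 3rd-order Butterworth, forward-backward —
  preserves peak timing for the phase analysis (filter family unprinted).
- **Spike phases**: troughs of the theta-filtered trace are local minima
  with ≥50 ms separation; phase runs linearly 0→360° between consecutive
  troughs (trough = 0°/360°, peak = 180°); the first 50 ms are cropped.
  "Modulation level" is implemented as the Rayleigh resultant length r, with
  the standard exponential approximation for the Rayleigh p-value.
- **LFP analog**: point-source sum of pyramidal membrane currents weighted
  by inverse distance to the electrode (default 200/500/120 µm), distance
  floored at 10 µm; cells beyond a 100 µm radius are represented by a random
  10% sample scaled by 10 — an unbiased estimator of the exhaustive outer
  sum (verified by Monte-Carlo in the tests).
- **Cross-frequency coupling**: Hilbert phase of the theta-filtered trace
  (shifted so troughs map to 0°) against the Hilbert envelope of the
  gamma-filtered trace, averaged in 20° bins.

## Reduced-scale study conditions and calibration

Dynamics are studied at 1.5% of full scale (~5,100 cells, ~6,800 stimulating
units) with probability-preserving scaling: budgets shrink by fraction²,
weights grow by 1/fraction, so the expected synaptic drive per cell is
conserved — the explicit form of the compensation that small-scale models
otherwise hide in arbitrarily strengthened synapses. Runs last 4,000 ms at
dt = 0.025 ms with 0.65 Hz afferent drive (the reference excitation level).

Per-synapse peak conductances are not printed in the source (they live in an
external appendix). They were set by the procedure the source itself
describes: iterate the afferent and recurrent weights until each cell type
fires at a plausible rate in the driven network and the pyramidal population
sustains a 5-10 Hz rhythm. The resulting values are frozen in the packaged
configuration. Under these conditions the reduced network shows: a global
pyramidal-SDF power peak inside 5-10 Hz for each of three seeds (5.9, 7.8,
9.8 Hz; median 7.8 Hz), collapse of theta (factor 30-300 in power) when all
pyramidal outputs are muted, and a charge-match factor of 299.7 for the
neurogliaform GABA-A compensation.

Theta in the reduced model is coherent locally but drifts in phase along the
10 mm longitudinal axis, so all population spectra are computed from cells
within ±500 µm (longitudinal) of the analysis point — the reduced-scale
analogue of the full-scale analysis' 100 µm electrode radius, which at 1.5%
density would contain too few cells.

## What the reduced scale does and does not show

Passing tests at desk scale establish the arithmetic, census, connectivity,
single-cell and signal-processing contracts exactly, and the *directional*
network results (theta presence at the reference drive; dependence on
pyramidal output). They do not reproduce full-scale quantities: per-type
phase preferences, absolute power values, or the full perturbation table.
Two known reduced-scale departures: interneuron firing rates sit above their
full-scale counterparts for several types, and removing the neurogliaform
GABA-B component does not *reduce* theta power here (the charge-transfer
equality of the compensation is exact regardless). Both reflect the
connectivity-scaling tradeoff — at 1.5% scale each remaining connection is
67× stronger, which coarsens the inhibitory dynamics the full-scale result
depends on.

## Numerical and degenerate-input choices

Rounding in `scale_config` is half-up per type with the total fixed by
adjusting the largest type (deterministic, proportion-preserving); every
type with nonzero full-scale count keeps at least one cell. Lattice
placement picks integer dimensions nearest the layer's aspect ratio with
product ≥ N and takes the first N cell-centred sites (z-major). Bin quotas
use largest-remainder rounding. Welch analysis shortens its segment when a
series is shorter than the default. Rheobase bisection reports NaN when the
maximum sweep current elicits no spike. Empty rasters yield zero SDFs, zero
rates, and an undefined (NaN) per-active-cell rate.
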