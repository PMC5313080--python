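# ca1net

A configurable-scale spiking-network model of the rodent hippocampal CA1
area, together with the oscillation-analysis pipeline used to study it:
spike density functions, Welch periodograms and spectrograms, an
extracellular-potential proxy (LFP analog), trough-referenced spike phases
with Rayleigh statistics, theta-gamma cross-frequency coupling, and a
battery of perturbation experiments (cell-type muting, recurrence scaling,
interneuron homogenization, GABA-B manipulation).

## Who this is for

Researchers studying how theta (5-10 Hz) and gamma (25-80 Hz) rhythms arise
inside the CA1 microcircuit itself, without rhythmic external input. The
packaged configuration describes the full-scale rat CA1: 311,500 pyramidal
cells, eight interneuron classes (PV+ basket, CCK+ basket, axo-axonic,
bistratified, Schaffer-collateral-associated, O-LM, neurogliaform, ivy;
27,240 interneurons in total), and 454,700 Poisson stimulating units standing
in for CA3 and entorhinal layer III afferents, wired through a synapse-budget
matrix totalling ~5.1 billion synapses. The full-scale configuration is
retained as data; simulations run at a user-chosen fraction of that size.

## The model

Cells are adaptive exponential integrate-and-fire neurons,

dV/dt = ( -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T) - w + I_syn ) / C,
dw/dt = (a (V - E_L) - w) / τ_w,   w ← w + b at each spike,

with the passive core (E_L, R_in, τ_m) pinned per type to measured
electrophysiology and V_T placed so the steady-state rheobase
g_L (V_T - Δ_T - E_L) matches the measured rheobase. Synapses are
double-exponential conductances g(t) = ĝ N (e^(-t/τ2) - e^(-t/τ1));
neurogliaform outputs are mixed GABA-A,B synapses (reversals -60 / -90 mV).

Connectivity follows a three-step distance-binned algorithm: XY-plane
distances between all cell pairs, a per-projection connection budget split
into radial bins by the presynaptic type's Gaussian axonal bouton profile,
and uniform sampling without replacement within each bin. Cells sit on
regular 3D lattices filling their laminar volumes inside a
10,000 x 1,000 x 550 µm prism.

Scaling a configuration down (`scale_config`) either preserves per-cell
convergence or — the default — preserves pairwise connection probability
while multiplying synaptic weights by 1/fraction so the expected synaptic
drive per cell is conserved.

## Worked example

Census and single-cell characterization are instant:

```
$ ca1net census | head -4
total_cells     338740
principal_cells 311500
interneurons    27240
afferent_units  454700

$ ca1net characterize --cell-type CCKB
type  rmp_mv  rin_mohm  tau_m_ms  rheobase_pa  threshold_mv  ...
CCKB  -70.6   211.6     22.6      60.6         -39.9         ...
```

The census matches the published cell counts exactly; the characterized
input resistance, membrane time constant and resting potential land within
2% of the measured values they were fit to (rheobase within ~1%).

A reduced-scale oscillation experiment (about 5,100 cells at 1.5% of full
scale, 0.65 Hz tonic afferent drive, 4 s):

```
$ ca1net experiment --entry control --scale 0.015 --seed 1 --duration 4000 \
      --out runs/control
theta_freq_hz   5.859375
theta_power     20830730.9
gamma_freq_hz   28.3203125
gamma_power     254217.9
peak_freq_hz    5.859375
n_spikes        69319
```

The pyramidal spike density function (computed, as in the full-scale
analysis, from cells near the reference electrode) has its global power
peak inside the theta band — a spontaneous theta rhythm arising from tonic,
arrhythmic input (5.9 Hz for this seed; the median over seeds 1-3 is
7.8 Hz). Muting all
pyramidal-cell outputs (`--entry mute:Pyr`) collapses theta power by roughly
two orders of magnitude, reproducing the directional role of recurrent
excitation. Other battery entries (`ca1net experiment --entry list`) cover
the tonic-excitation sweep, per-type muting, pyramidal-recurrence scaling
(0x / 0.5x / 2x), 50% PV+/SOM+ class muting, staged interneuron
homogenization, and GABA-B removal with charge-matched GABA-A compensation.

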