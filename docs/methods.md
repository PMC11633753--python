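# Methods

`glomflow` couples a biophysical model of olfactory receptor neurons (ORNs)
to the calcium-imaging statistics used to characterize glomerular odor
responses, and ships a synthetic cohort generator so the whole analysis
pipeline can be exercised without in vivo data.  This note records the
model, its parameters, the numerical choices, and the places where the
design was genuinely open.

## The biophysical model

### Cell

Each ORN is a chain of four sections with uniform squid-type Hodgkin-Huxley
channels:

| section  | geometry            | nodes |
|----------|---------------------|-------|
| axon     | 1.6 mm x 0.2 um     | 51    |
| soma     | 5 um sphere         | 1     |
| dendrite | 12 um x 0.8 um      | 5     |
| end bulb | 2 um sphere         | 1     |

Membrane: Ra = 180 ohm*cm, Cm = 1 uF/cm2, gNa = 32, gK = 8, g_pas = 0.08
mS/cm2, E_pas = -50 mV.  Spheres are represented as cylinders with length
equal to diameter (area-preserving).  The squid kinetics are used in their
canonical 6.3 C form with E_Na = +50 mV and E_K = -77 mV; the source
material says only "standard Hodgkin-Huxley channels", and these are the
reversals and temperature that phrase denotes in NEURON practice.  Both are
configurable (`MembraneParams`).

The axon is discretized into 51 nodes because its 1.6 mm length is ~8.6
passive length constants (lambda ~ 190 um from the printed parameters);
spike propagation and its failure are the phenomenon of interest, so the
cable must be resolved.  The resting potential is -63.1 mV at every node.

### Receptor input

The odor-evoked receptor conductance is g(t) = m*(a + b - c): a sigmoidal
onset `a`, a post-envelope decay `b`, and a slow adaptation term `c`,
with separate printed constants for a weak and a strong odor concentration.
The printed formulas have lost their typographic grouping; the
reconstruction in `receptor_waveform` was validated by two oracles: `c`
evaluates to ~0 at its window onset, and the total conductance is continuous
at the envelope offset.  Two caveats discovered en route:

* The continuity oracle holds at the 3-s stimulus duration the original
  fits used (offset step < 1% of peak for the weak set, < 0.3% for the
  strong).  For the weak set at much shorter or longer stimuli the fixed
  amplitude of `b` no longer matches `a - c` at the offset (a ~35% step at
  td = 1 s).  This is a property of the published constants, not of the
  reconstruction; the strong set is continuous at any duration because its
  `b` amplitude equals the `a - c` plateau.
* `c(onset)` is -0.0065 rather than 0 for the weak constants; the total
  conductance is floored at zero.

The envelope outlasts the stimulus by the duration multiplier `tx` (weak:
exactly 1; strong: 1.65 + N(0.2, 0.25), clipped at 1, drawn once per neuron
and trial).  The overhang `(tx - 1)*td` is what delays the rebound burst
after strong stimuli, and the clip prevents a Gaussian tail from making the
receptor current end before the odor does.

`m` converts the dimensionless fit units to nS.  It is calibrated in closed
form against the published peak receptor currents (13 pA weak, 96 pA
strong) measured with the membrane held at rest:
`m = I_peak / (g_raw_peak * (E_syn - V_rest))`.  The receptor reversal is
E_syn = 0 mV, consistent with the depolarized reversal of the
ANO2-dominated transduction current.

### Noise and the spontaneous rate

Basal firing is produced by a Gaussian current at the end bulb, mean 0.5 pA,
drawn independently each 0.025-ms step.  The printed noise SD, "0.014",
carries no unit.  Read as pA it moves the membrane by well under a
microvolt and the model is silent forever; read as 0.014 nA -- the value as
typed in NEURON's nA current units, consistent with the mean (0.5 pA =
0.0005 nA) -- it gives a ~2 mV voltage SD and spontaneous axonal firing at
7.2-7.4 Hz, matching the published "~7 Hz".  The package default is
therefore sd = 14 pA per 0.025-ms reference step; at other dt the per-step
SD is scaled by sqrt(dt_ref/dt) so the noise spectral density (the
physically meaningful quantity) is dt-invariant.

### Integration

Voltages advance with a staggered, fixed-step Crank-Nicolson scheme
(gating variables updated by the exponential rule at the current voltage,
then a tridiagonal solve of the trapezoidal cable update) -- the analogue of
NEURON's `secondorder=2` -- at dt = 0.025 ms.  Rate functions are tabulated
on a 0.05 mV grid.  The scheme is second-order accurate and handles the
stiff, low-capacitance end-bulb node implicitly; that matters because the
noise charge is injected exactly there, and a scheme that relaxes the bulb
node to quasi-steady state within a step silently discards most of it (an
early first-order prototype did, and the model then never fired).
Verification: on a single HH compartment driven to repetitive firing the
kernel matches a DOP853 reference integration of the same ODEs to 0.52 mV
(dt = 0.025) and 0.13 mV (dt = 0.0125) over 100 ms, converging at second
order; a noise-free 3-s weak-stimulus trial produces an identical spike
count at dt = 0.025 and 0.0125.

Axonal spikes are upward crossings of -20 mV at the distal axon node with a
2-ms lockout; during depolarizing block the somatic spikelets shrink below
this threshold and are not counted, which is exactly the transmission
failure the detection rule is meant to expose.

### Input resistance

The measured steady-state input resistance of the full model (-1 pA somatic
step, noise off) is **1.85 GOhm**, not the published 4 GOhm.  The analysis
in `isopotential_chord_resistance` shows where the printed figure comes
from: 1/(g_rest * area(soma + dendrite + bulb)) = 4.0 GOhm -- the chord
resistance of the somatic compartments *alone*, with the resting K
conductance but without the axonal load (which halves the result) or the
steady-state linearization of the K channels.  We report the honest
measurement and keep the printed-value assertion in the acceptance suite as
a deliberate red, with this explanation.  Similarly, the published "length
constant of ~740 um" does not follow from the printed passive parameters
(axon ~190 um, dendrite ~370 um); the package computes and reports its own
values.

### The depolarizing-block phenotype

With these ingredients the published population phenotype is reproduced
end-to-end: the weak stimulus (13 pA peak) raises firing above the ~7 Hz
baseline for the entire stimulus; the strong stimulus (96 pA) clamps the
soma near -45 mV, yields a brief onset burst whose spikes shrink as Nav
channels inactivate, silences the axon for the rest of the stimulus
(population PSTH below baseline), and produces a rebound burst once the
conductance envelope -- which outlasts the stimulus by (tx-1)*td -- decays.
Scaling the strong waveform's peak current from 13 to 96 pA moves the
sustained-phase rate below baseline at a single threshold (between ~55 and
~75 pA at the default parameters).  After convolving the 50-ms-bin PSTH
with the GCaMP6f kernel, the strong response's peak is several-fold smaller
than the weak one's (low-pass filtering of the brief burst), and the
adaptation index of the strong proxy exceeds 1 while the weak proxy stays
below 1.

## Population readout

PSTHs use 50-ms bins and divide by neuron count and bin width.  The GCaMP6f
kernel is `g * (t/0.001) * exp(-(t + 0.15)/0.15)` with t in seconds,
truncated at 2 s (>13 decay constants) and peak-normalized (`g` is a free
scale in the source; peak normalization makes the two readings of the
printed kernel expression -- with or without the `t/0.001` prefactor
inside -- numerically identical).  The kernel peaks exactly at t = 0.15 s.

## Imaging statistics

All definitions follow the published ones: dF/F against a 5-s pre-stimulus
baseline; response maps as mean stimulus dF/F per pixel, sigma = 2 px
Gaussian smoothed, zeroed outside segmented glomeruli; the adaptation index
AI = (peak - mean of last 100 ms of stimulus)/peak on a 5-point mean
filtered trace (centered window, shrinking at the edges); SNR = (stimulus
max - 3-s baseline mean)/baseline SD with responsiveness at SNR >= 5
(inclusive); response amplitude as the mean over stimulus + 1 s, normalized
per glomerulus to its maximum across stimuli; percept labels weak (c <=
0.01 % sv) and strong (c >= 0.3 % sv) with the transition range excluded
from classification; a class-balanced linear SVM scored by leave-one-out
weighted F1, with per-glomerulus |coefficient| normalized to the largest;
activation ranks from the first stimulus frame exceeding the baseline by 5
SDs, rank 1 earliest, mean rank across repeats.

Open points resolved as follows (all exposed as parameters):

* "successive concentrations responsive" -> responsive at a rung iff SNR >=
  5 there *and* at the next rung (top rung: own SNR only), which suppresses
  single-rung flickers;
* ties in first-active frame break by larger dF/F at that frame, then by
  glomerulus id (deterministic ranking);
* "within 50% of the boundary concentration" is operationalized on the log
  scale (the stimulus ladder is logarithmic): labeled stimuli are those at
  or beyond each boundary, i.e. the transition range (0.01-0.3 % sv) is
  excluded;
* the classifier internally renormalizes its input by the global maximum,
  making the report exactly invariant to feature rescaling;
* irregular-breathing trials are excluded when > 80% of glomeruli sit below
  -2 baseline SDs simultaneously for >= 0.5 s.

## Synthetic cohorts

The generator emulates the *structure* of the in vivo recordings: per mouse
(default 9), 12 glomeruli, an 8-rung concentration ladder (3e-5 to 10 % sv),
1-3 trials per stimulus at 42 Hz, one primary glomerulus (lowest threshold,
first active at weak concentrations) plus secondaries recruited at higher
concentrations with shorter latencies, iid Gaussian fluorescence noise
(SD 0.05 dF/F), and optional breathing-artifact trials with ground-truth
flags.  Cohort phenotypes: naive -- primary sustained at weak rungs,
deeply adapting in the transition range, block-mode (transient + undershoot
+ rebound) at strong rungs, peak response near 0.01 % sv; associated --
sustained everywhere with the peak-response concentration two decades
higher (near the concentration experienced on food); exposed -- like naive.

Trace templates are closed-form (fast), but their shape constants -- block
peak ratio 0.20, undershoot 0.58 of the block peak, rebound 2.0x the block
peak arriving 1.8 s after the envelope ends, sustained-adaptation plateau
0.35 with tau 5.4 s -- were extracted from the mechanistic backend (the HH
population simulator plus GCaMP kernel, 40 neurons, 3-s stimuli;
`derive_block_parameters` re-derives them).  Secondary-glomerulus latency
distributions are not tabulated in the source material; the generator's
log-linear recruitment rule is labeled an assumption in the ground-truth
JSON.

What passing the recovery tests does and does not show: the pipeline
recovers the generating phenotypes (AI direction, rank structure,
sensitivity shift, classifier accuracy and weight attribution) from data
with realistic noise and trial structure.  It does not validate the
templates against real imaging noise (shot noise, neuropil contamination,
motion, breathing modulation), glomerulus segmentation, or hemodynamic
artifacts -- all out of scope.

## Problem sizes

Routine tests run the simulator at reduced scale: the long-stimulus
phenotype uses 100 neurons and 60-s stimuli; the spontaneous-rate
measurement 20 neurons x 30 s; the block-threshold ladder 20 neurons per
amplitude with 3-s stimuli; cohort recovery uses 2-5 mice.  The published
simulations used 500 neurons; the PSTH and proxy statistics at 100 neurons
are well converged for every assertion made (rates differ from baseline by
multiples, not percentages).

## Known limitations

* Transduction-cascade kinetics (CNG/ANO2 gating, Ca2+ feedback) are not
  modelled; the receptor waveform is phenomenological.
* The weak-set waveform's offset continuity is specific to ~3-s stimuli
  (see above); 60-s weak simulations carry a small (~8% of peak) step at
  the envelope offset inherited from the published constants.
* Channel noise is modelled as white current noise at one site; no
  channel-state stochasticity.
* The printed input resistance and length constant are not reproduced by
  the printed parameters; the discrepancies are quantified above rather
  than patched.
* Percept labels in the generator are assigned from the concentration
  ladder, not from behavior; behavioral assays are out of scope.
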