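# glomflow

Biophysical simulation and imaging-statistics pipeline for
concentration-dependent odor coding in olfactory receptor neurons (ORNs).

Mice can perceive the same odorant as two different smells at low and high
concentration.  The neural correlate is striking: the *primary* glomerulus
(the most sensitive one, first to activate at threshold concentrations)
responds to weak stimuli with sustained activity, but at strong
concentrations its calcium signal collapses within a few hundred
milliseconds, drops *below* baseline, and rebounds only seconds after the
odor ends.  `glomflow` implements the mechanistic explanation --
**depolarizing block**: large receptor currents clamp the tiny,
high-resistance ORN at a depolarized potential, voltage-gated Na⁺ channels
accumulate in the inactivated state, and spike transmission down the axon
fails -- together with the analysis used to quantify it in imaging data.

The package is aimed at computational and systems neuroscientists who want
to simulate ORN populations, forward-model glomerular calcium signals, or
run the corresponding trace statistics (adaptation index, SNR
responsiveness, percept decoding, activation ranking) on their own or on
synthetic data.

## What is inside

* **`receptor_waveform`** -- the odor-evoked receptor conductance
  g(t) = m·(a + b − c): sigmoidal onset *a*, post-envelope decay *b*, slow
  adaptation *c*, with published constants for a weak and a strong
  concentration, and the stochastic duration multiplier t_x by which the
  conductance envelope outlasts the stimulus.
* **`orn_biophysics`** -- a four-section Hodgkin–Huxley ORN (axon 1.6 mm ×
  0.2 µm, soma 5 µm, dendrite 12 µm × 0.8 µm, end bulb 2 µm; g_Na = 32,
  g_K = 8, g_pas = 0.08 mS/cm², E_pas = −50 mV, Ra = 180 Ω·cm), end-bulb
  noise, a staggered Crank–Nicolson cable integrator, spike detection, and
  calibration of the conductance scale against the published peak receptor
  currents (13 pA weak / 96 pA strong).
* **`population_readout`** -- population PSTHs (50-ms bins) and the GCaMP6f
  forward model k(t) ∝ t·exp(−(t+0.15)/0.15 s), i.e. a calcium proxy for
  the summed activity of all ORNs converging on one glomerulus.
* **`imaging_analysis`** -- ΔF/F; response maps; the adaptation index
  AI = (peak − mean of last 100 ms of stimulus)/peak (AI = 1 ⇔ complete
  adaptation, AI > 1 ⇔ activity below baseline); SNR ≥ 5 responsiveness;
  normalized response amplitudes; weak/strong percept labels (≤ 0.01 % and
  ≥ 0.3 % saturated vapor); a class-balanced linear SVM with leave-one-out
  weighted F1 and weight attribution; activation-time ranking.
* **`synthetic_cohort`** -- generator of complete per-mouse trace tables
  (naive / food-associated / exposed cohorts) with ground truth, emulating
  the structure the analysis assumes; template shapes derived from the
  mechanistic simulator.
* **`cli_io` + `glomflow` CLI** -- configs, HDF5/CSV I/O, and the
  subcommands `waveform`, `simulate`, `readout`, `synth`, `analyze`,
  `classify`, `run`.

## Worked example

Thirty model ORNs, 3-s weak and strong stimuli, population PSTH convolved
with the GCaMP6f kernel:

```python
import numpy as np
from glomflow import orn_biophysics as ob, population_readout as pr, imaging_analysis as ia
from glomflow.receptor_waveform import StimulusSpec

cell = ob.build_cell()
print(f"input resistance: {ob.input_resistance(cell):.2f} GOhm")
print(f"spontaneous rate: {ob.spontaneous_rate(cell, duration_ms=10_000, n_neurons=10, seed=0):.1f} Hz")

for intensity in ("weak", "strong"):
    m = ob.calibrate_m(cell, intensity)                      # nS per waveform unit
    stim = StimulusSpec(t0=3000.0, td=3000.0, intensity=intensity, m=m)
    res = ob.integrate(cell, ob.SimConfig(duration=14_000.0, n_neurons=30, seed=1),
                       stimulus=stim)
    p = pr.psth(res.spike_times, window_ms=(0.0, 14_000.0))
    prox = pr.baseline_relative(pr.gcamp_convolve(p), (0.5, 2.9))
    tr = ia.DffTrace(values=prox.signal, frame_rate=20.0, stim_on_s=3.0, stim_off_s=6.0)
    rate = np.mean([np.sum((s >= 3000) & (s < 6000)) / 3.0 for s in res.spike_times])
    print(f"{intensity:>6}: stimulus rate {rate:.1f} Hz, "
          f"AI {ia.adaptation_index(tr).ai:.2f}")
```

prints

```
input resistance: 1.85 GOhm
spontaneous rate: 7.0 Hz
  weak: stimulus rate 54.9 Hz, AI 0.28
strong: stimulus rate 2.0 Hz, AI 1.74
```

The weak stimulus (13 pA peak receptor current) drives sustained firing at
~55 Hz, eight-fold above the ~7 Hz spontaneous rate, and its calcium proxy
adapts only partially (AI 0.28 < 1).  The strong stimulus (96 pA) fires a
brief onset burst and then blocks: 2 Hz average over the stimulus, the
proxy falls 58 units below baseline (its within-stimulus peak, 94, is
five-fold smaller than the weak stimulus's 463 despite the six-fold larger
input), AI 1.74 > 1, and a rebound transient (peak 211) appears seconds
after odor offset once the conductance envelope decays -- the full
signature seen in primary glomeruli in vivo.

The same pipeline runs from the shell:

```bash
glomflow simulate --intensity strong --td-ms 3000 --n 30 --seed 1 --out sim.h5
glomflow readout sim.h5 --bin-ms 50
glomflow run --seed 7 --out results/    # synth -> analyze -> classify
```

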