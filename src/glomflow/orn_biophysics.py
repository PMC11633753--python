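"""Four-compartment Hodgkin-Huxley model of an olfactory receptor neuron.

The cell is a chain of cylindrical sections -- axon (1.6 mm x 0.2 um), soma
(5 um), dendrite (12 um x 0.8 um) and end bulb (2 um) -- with uniform squid
HH channel densities (gNa 32, gK 8, g_pas 0.08 mS/cm2, E_pas -50 mV), axial
resistivity 180 ohm*cm and 1 uF/cm2 membrane capacitance.  The soma and end
bulb are represented as cylinders with length equal to their diameter, which
preserves the spherical surface area.  Receptor input is a conductance point
process at the end-bulb tip with reversal 0 mV (the transduction current is
carried largely by the depolarized-reversal ANO2 chloride conductance), and
a Gaussian noise current at the end bulb mimics spontaneous Nav openings.

The axon is discretized into many nodes (default 51; its length far exceeds
its ~190 um passive length constant), the dendrite into 5.  Node voltages
are advanced with a staggered Crank-Nicolson scheme (see
:mod:`glomflow._hh_kernel`).

Key emergent behaviours: spontaneous axonal firing at ~7 Hz under the
end-bulb noise; sustained firing for weak receptor currents (13 pA peak);
and, for strong receptor currents (96 pA peak), a brief onset burst followed
by depolarizing block -- the soma clamps depolarized, Nav channels
accumulate in the inactivated state and spike transmission down the axon
fails -- with a rebound burst once the conductance envelope decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _hh_kernel as hk
from .receptor_waveform import (
    PiecewiseParams,
    StimulusSpec,
    conductance,
    sample_tx,
    waveform_params,
)

__all__ = [
    "CellMorphology",
    "MembraneParams",
    "NoiseSpec",
    "SimConfig",
    "SimResult",
    "Cell",
    "build_cell",
    "integrate",
    "detect_spikes",
    "input_resistance",
    "isopotential_chord_resistance",
    "spontaneous_rate",
    "calibrate_m",
    "resting_potential",
    "ConfigurationError",
    "IntegrationError",
    "CalibrationError",
    "MeasurementError",
]

UM = 1e-4  # um -> cm


class ConfigurationError(ValueError):
    """Invalid cell or simulation configuration."""


class IntegrationError(RuntimeError):
    """Numerical divergence during integration."""


class CalibrationError(RuntimeError):
    """Receptor-current calibration failed."""


class MeasurementError(RuntimeError):
    """An electrophysiological measurement violated its preconditions."""


@dataclass(frozen=True)
class CellMorphology:
    """Section dimensions (um) and spatial discretization (nodes per section)."""

    axon_length: float = 1600.0
    axon_diam: float = 0.2
    soma_diam: float = 5.0
    dend_length: float = 12.0
    dend_diam: float = 0.8
    bulb_diam: float = 2.0
    n_axon: int = 51
    n_dend: int = 5

    def __post_init__(self) -> None:
        dims = (self.axon_length, self.axon_diam, self.soma_diam,
                self.dend_length, self.dend_diam, self.bulb_diam)
        if any(d <= 0 for d in dims):
            raise ConfigurationError("all morphological dimensions must be positive")
        if self.n_axon < 1 or self.n_dend < 1:
            raise ConfigurationError("node counts must be >= 1")


@dataclass(frozen=True)
class MembraneParams:
    """Electrical parameters; conductances in S/cm2, potentials in mV."""

    Ra: float = 180.0           # ohm*cm
    Cm: float = 1.0e-6          # F/cm2
    gna: float = 32e-3
    gk: float = 8e-3
    gpas: float = 0.08e-3
    e_pas: float = -50.0
    e_na: float = 50.0
    e_k: float = -77.0
    e_syn: float = 0.0          # receptor-conductance reversal

    def __post_init__(self) -> None:
        if min(self.gna, self.gk, self.gpas) < 0:
            raise ConfigurationError("conductance densities must be >= 0")
        if not (self.e_na > self.e_pas > self.e_k):
            raise ConfigurationError("require e_na > e_pas > e_k")


@dataclass(frozen=True)
class NoiseSpec:
    """End-bulb Gaussian current noise, drawn independently each step.

    ``mean`` is the printed 0.5 pA bias.  ``sd`` defaults to 14 pA: the
    printed value "0.014" carries no unit and is read as 0.014 nA, the
    figure as typed in NEURON's nA current units (consistent with the mean,
    0.5 pA = 0.0005 nA).  Read as 0.014 pA the noise moves the membrane by
    well under a microvolt and the cell never fires; at 14 pA per 0.025 ms
    step it produces the stated ~7 Hz spontaneous rate.
    """

    mean: float = 0.5   # pA
    sd: float = 14.0    # pA per reference step (dt = 0.025 ms)
    reference_dt: float = 0.025

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("noise sd must be >= 0")

    def sd_at(self, dt: float) -> float:
        """Per-step SD at another dt, preserving the noise spectral density."""
        return self.sd * float(np.sqrt(self.reference_dt / dt))


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.025             # ms
    duration: float = 1000.0      # ms
    n_neurons: int = 1
    seed: int = 0
    spike_threshold: float = -20.0  # mV, upward crossing at the spike site
    refractory: float = 2.0         # ms lockout
    record_sites: tuple[str, ...] = ()   # subset of ('axon', 'soma', 'bulb')
    record_every: int = 20               # decimation of voltage recordings
    settle: float = 2000.0               # ms discarded before t=0

    def __post_init__(self) -> None:
        if self.dt > 0.05 or self.dt <= 0:
            raise ConfigurationError("dt must be in (0, 0.05] ms")
        if self.n_neurons < 1:
            raise ConfigurationError("n_neurons must be >= 1")


@dataclass
class Cell:
    """Discretized cell: node areas (cm2) and axial couplings (S).

    Node 0 is the distal axon tip; the last node is the end-bulb tip.
    """

    area: np.ndarray
    gax: np.ndarray
    i_axon_distal: int
    i_soma: int
    i_bulb: int
    morph: CellMorphology
    mem: MembraneParams

    @property
    def n_nodes(self) -> int:
        return self.area.size


def build_cell(morph: CellMorphology = CellMorphology(),
               mem: MembraneParams = MembraneParams()) -> Cell:
    """Discretize the morphology into a chain of coupled cylindrical nodes.

    Spherical sections (soma, end bulb) become cylinders of length equal to
    their diameter.  Axial couplings between adjacent nodes combine the two
    half-segment resistances Ra*(L/2)/(pi r^2).
    """
    na, nd = morph.n_axon, morph.n_dend
    L = np.concatenate([
        np.full(na, morph.axon_length / na),
        [morph.soma_diam],
        np.full(nd, morph.dend_length / nd),
        [morph.bulb_diam],
    ]) * UM
    D = np.concatenate([
        np.full(na, morph.axon_diam),
        [morph.soma_diam],
        np.full(nd, morph.dend_diam),
        [morph.bulb_diam],
    ]) * UM
    area = np.pi * D * L
    r_half = mem.Ra * (L / 2.0) / (np.pi * (D / 2.0) ** 2)
    gax = 1.0 / (r_half[:-1] + r_half[1:])
    return Cell(area=area, gax=gax, i_axon_distal=0, i_soma=na,
                i_bulb=len(area) - 1, morph=morph, mem=mem)


@dataclass
class SimResult:
    """Spike times (ms, relative to end of settle) and optional recordings."""

    spike_times: list[np.ndarray]
    t_rec: np.ndarray
    voltage: dict[str, np.ndarray]      # site -> (n_neurons, n_times) mV
    conductance: np.ndarray | None      # (n_neurons, n_times) nS at the bulb
    tx: np.ndarray
    config: SimConfig

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)


_WP_ORDER = ("A_amp", "A_half", "A_slope", "B_amp", "B_shift", "B_window",
             "C_tau", "C_base", "C_offset", "C_amp", "C_onset", "B_slope")


def _pack_wp(p: PiecewiseParams) -> np.ndarray:
    return np.array([getattr(p, k) for k in _WP_ORDER], dtype=float)


def integrate(cell: Cell,
              cfg: SimConfig,
              stimulus: StimulusSpec | None = None,
              noise: NoiseSpec | None = NoiseSpec(),
              tx: np.ndarray | None = None,
              inj_site: str = "soma",
              inj_pa: np.ndarray | float = 0.0,
              v0: float = -65.0) -> SimResult:
    """Advance the population for ``settle + duration`` ms.

    Each neuron gets an independent noise stream and (for strong stimuli) an
    independent envelope duration multiplier ``tx``.  The settle period runs
    with noise but without stimulus or injected current and is discarded;
    stimulus times are relative to the end of the settle period.  Identical
    seed and config give bit-identical results.
    """
    mem, n = cell.mem, cfg.n_neurons
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)

    if stimulus is not None:
        p = waveform_params(stimulus.intensity)
        wp = _pack_wp(p)
        if tx is None:
            tx = np.array([sample_tx(stimulus.intensity, rng) for _ in range(n)])
        m_scale = stimulus.m
        stim_t0, stim_td = stimulus.t0 + cfg.settle, stimulus.td
    else:
        wp = np.zeros(12)
        wp[[2, 5, 6, 11]] = 1.0  # keep divisors nonzero
        tx = np.ones(n) if tx is None else tx
        m_scale, stim_t0, stim_td = 0.0, 0.0, 1.0

    n_steps = int(round((cfg.settle + cfg.duration) / cfg.dt))
    site_map = {"axon": cell.i_axon_distal, "soma": cell.i_soma, "bulb": cell.i_bulb}
    rec_nodes = np.array([site_map[s] for s in cfg.record_sites], dtype=np.int64)

    inj = np.atleast_1d(np.asarray(inj_pa, dtype=float))
    if inj.size > 1:
        pad = int(round(cfg.settle / cfg.dt))
        inj = np.concatenate([np.zeros(pad), inj])
        if inj.size < n_steps:
            inj = np.concatenate([inj, np.zeros(n_steps - inj.size)])
        inj = inj[:n_steps]
    elif inj[0] != 0.0:
        # constant injections also start after the settle period
        trace = np.zeros(n_steps)
        trace[int(round(cfg.settle / cfg.dt)):] = inj[0]
        inj = trace

    noise = noise or NoiseSpec(mean=0.0, sd=0.0)
    max_spikes = max(1000, int(cfg.duration / 1000.0 * 400) + 100)

    spikes, n_spk, vrec, grec, ok = hk.run_population(
        n_steps, cfg.dt, v0,
        cell.area, cell.gax, mem.Cm, mem.gna, mem.gk, mem.gpas,
        mem.e_na, mem.e_k, mem.e_pas,
        hk.gating_tables(cfg.dt),
        cell.i_bulb, wp, stim_t0, stim_td, np.asarray(tx, dtype=float),
        m_scale, mem.e_syn,
        cell.i_bulb, noise.mean, noise.sd_at(cfg.dt),
        site_map[inj_site], inj,
        seeds.astype(np.int64),
        cfg.spike_threshold, cfg.refractory, cell.i_axon_distal,
        max_spikes, rec_nodes, cfg.record_every,
    )
    if not ok:
        raise IntegrationError(
            f"voltage diverged (|V| > 200 mV) at dt={cfg.dt} ms; "
            "reduce dt or the stimulus amplitude")

    spike_times = []
    for i in range(n):
        st = np.sort(spikes[i, :n_spk[i]]) - cfg.settle
        spike_times.append(st[st >= 0.0])  # settle-period spikes are discarded
    t_rec = (np.arange(vrec.shape[2]) * cfg.record_every * cfg.dt - cfg.settle
             if rec_nodes.size else np.empty(0))
    voltage = {s: vrec[:, j, :] for j, s in enumerate(cfg.record_sites)}
    g_ns = grec / hk.NS if (rec_nodes.size and stimulus is not None) else None
    return SimResult(spike_times=spike_times, t_rec=t_rec, voltage=voltage,
                     conductance=g_ns, tx=np.asarray(tx), config=cfg)


def detect_spikes(v: np.ndarray, t: np.ndarray, threshold: float = -20.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times from a voltage trace: upward threshold crossings with a
    refractory lockout.  Shrinking subthreshold spikelets (depolarizing
    block) are not counted."""
    v = np.asarray(v, float)
    idx = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    out = []
    last = -np.inf
    for i in idx:
        if t[i] - last >= refractory:
            out.append(t[i])
            last = t[i]
    return np.asarray(out)


def resting_potential(cell: Cell, settle_ms: float = 2000.0, dt: float = 0.025) -> float:
    """Somatic resting potential with noise and stimulus off."""
    cfg = SimConfig(dt=dt, duration=50.0, n_neurons=1, settle=settle_ms,
                    record_sites=("soma",), record_every=20)
    res = integrate(cell, cfg, noise=None)
    return float(res.voltage["soma"][0, -1])


def input_resistance(cell: Cell, step_pa: float = -1.0, settle_ms: float = 2000.0,
                     step_ms: float = 6000.0, dt: float = 0.025) -> float:
    """Steady-state somatic input resistance, in GOhm.

    Injects a small constant current step at the soma with noise off and
    returns the steady-state voltage deflection over the step amplitude
    (mV/pA = GOhm).  Steps above 1 pA in magnitude, or any step that
    triggers spikes, raise :class:`MeasurementError`.
    """
    if abs(step_pa) > 1.0 or step_pa == 0.0:
        raise MeasurementError("input resistance requires a nonzero step of <= 1 pA")
    cfg = SimConfig(dt=dt, duration=step_ms, n_neurons=1, settle=settle_ms,
                    record_sites=("soma",), record_every=40)
    base = integrate(cell, cfg, noise=None)
    stepped = integrate(cell, cfg, noise=None, inj_site="soma", inj_pa=step_pa)
    if len(stepped.spike_times[0]) > 0:
        raise MeasurementError("current step triggered spikes; use a smaller step")
    dv = stepped.voltage["soma"][0, -1] - base.voltage["soma"][0, -1]
    return float(dv / step_pa)


def isopotential_chord_resistance(cell: Cell, v_rest: float | None = None) -> float:
    """Chord resistance (GOhm) of the isopotential soma-side compartments.

    1 / (g_rest * area(soma + dendrite + bulb)) with all channels at their
    resting activation -- the axon load and the steady-state linearization of
    the K conductance are deliberately ignored.  This analytic figure
    reproduces the published "4 gigohms" to within a few percent, whereas the
    measured steady-state dV/dI of the full cable-discretized cell is roughly
    half of it.
    """
    mem = cell.mem
    if v_rest is None:
        v_rest = resting_potential(cell)
    m, h, n = hk.steady_gates(v_rest)
    g = mem.gpas + mem.gna * m ** 3 * h + mem.gk * n ** 4
    side_area = cell.area[cell.i_soma:].sum()
    return float(1.0 / (g * side_area) / 1e9)


def spontaneous_rate(cell: Cell, noise: NoiseSpec = NoiseSpec(),
                     duration_ms: float = 30_000.0, n_neurons: int = 20,
                     seed: int = 0, dt: float = 0.025) -> float:
    """Mean axonal firing rate (Hz) with no odor stimulus."""
    cfg = SimConfig(dt=dt, duration=duration_ms, n_neurons=n_neurons, seed=seed)
    res = integrate(cell, cfg, noise=noise)
    counts = [len(s) for s in res.spike_times]
    return float(np.mean(counts) / (duration_ms / 1000.0))


def calibrate_m(cell: Cell, intensity: str, target_pa: float | None = None,
                v_rest: float | None = None) -> float:
    """Scale factor m (nS per raw waveform unit) giving the target peak
    receptor current with the membrane held at rest.

    Under voltage clamp at rest the synaptic current is linear in the
    conductance, I_peak = m * g_raw_peak * (E_syn - V_rest), so m follows in
    closed form; the published peaks are 13 pA (weak) and 96 pA (strong).
    """
    targets = {"weak": 13.0, "strong": 96.0}
    if target_pa is None:
        target_pa = targets[intensity]
    if v_rest is None:
        v_rest = resting_potential(cell)
    driving = cell.mem.e_syn - v_rest  # mV; nS * mV = pA
    if driving <= 0:
        raise CalibrationError("receptor reversal must be above rest")
    spec = StimulusSpec(t0=0.0, td=10_000.0, intensity=intensity, tx=1.0, m=1.0)
    t = np.arange(0.0, spec.td, 0.5)
    g_raw_peak = float(conductance(t, spec).max())
    if g_raw_peak <= 0:
        raise CalibrationError("raw waveform has no positive peak")
    return target_pa / (g_raw_peak * driving)
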