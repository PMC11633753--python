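"""Population readouts: PSTH and GCaMP6f calcium proxy.

The glomerular calcium signal reflects the pooled activity of the thousands
of receptor neurons converging on one glomerulus.  The model analogue is a
peristimulus time histogram (50-ms bins) over the simulated population,
convolved with a kernel representing GCaMP6f kinetics,

    k(t) = g * (t / 0.001) * exp(-(t + 0.15) / 0.15),   t >= 0  (seconds),

with the scale g chosen to normalize the kernel peak to 1 (the published g
is a free scaling factor).  The kernel peaks 0.15 s after an impulse and
low-pass filters the spike rate: a brief strong-stimulus onset burst yields
a *smaller* calcium transient than the lower but sustained weak-stimulus
firing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Psth", "GcampKernel", "CalciumProxy", "psth", "gcamp_convolve",
           "baseline_relative"]

PSTH_BIN_MS = 50.0


@dataclass
class Psth:
    """Mean firing rate per bin (Hz), averaged across neurons."""

    edges: np.ndarray      # bin edges, ms
    rate: np.ndarray       # Hz
    n_neurons: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class GcampKernel:
    """GCaMP6f impulse response, sampled at ``dt_s`` and truncated at
    ``t_max_s`` (>13 decay constants; the tail is negligible)."""

    tau_s: float = 0.15
    t_max_s: float = 2.0

    def sample(self, dt_s: float) -> np.ndarray:
        t = np.arange(0.0, self.t_max_s, dt_s)
        k = (t / 0.001) * np.exp(-(t + self.tau_s) / self.tau_s)
        peak = k.max()
        return k / peak if peak > 0 else k

    @property
    def peak_time_s(self) -> float:
        """argmax of t*exp(-t/tau) is exactly tau."""
        return self.tau_s


@dataclass
class CalciumProxy:
    """GCaMP-filtered population rate; arbitrary units on a seconds base."""

    t_s: np.ndarray
    signal: np.ndarray
    baseline: float | None = None


def psth(spike_trains: list[np.ndarray], bin_ms: float = PSTH_BIN_MS,
         window_ms: tuple[float, float] | None = None) -> Psth:
    """Population PSTH: per-bin spike count / (n_neurons * bin width), Hz."""
    if len(spike_trains) == 0:
        raise ValueError("need at least one spike train")
    if window_ms is None:
        t_max = max((s[-1] for s in spike_trains if len(s)), default=bin_ms)
        window_ms = (0.0, np.ceil(t_max / bin_ms) * bin_ms)
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    for s in spike_trains:
        counts += np.histogram(s, bins=edges)[0]
    rate = counts / (len(spike_trains) * bin_ms / 1000.0)
    return Psth(edges=edges, rate=rate, n_neurons=len(spike_trains))


def gcamp_convolve(p: Psth, kernel: GcampKernel = GcampKernel()) -> CalciumProxy:
    """Causal discrete convolution of the PSTH with the GCaMP6f kernel.

    Linear in the input rate; the output at time t depends only on rates at
    times <= t.
    """
    dt_s = (p.edges[1] - p.edges[0]) / 1000.0
    k = kernel.sample(dt_s)
    sig = np.convolve(p.rate, k)[: p.rate.size]
    return CalciumProxy(t_s=p.centers / 1000.0, signal=sig)


def baseline_relative(proxy: CalciumProxy,
                      baseline_window_s: tuple[float, float]) -> CalciumProxy:
    """Subtract the mean over a pre-stimulus window.

    The resulting signal can go negative: during depolarizing block the
    population rate falls below the spontaneous rate and the calcium proxy
    dips below baseline.
    """
    lo, hi = baseline_window_s
    mask = (proxy.t_s >= lo) & (proxy.t_s < hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = float(proxy.signal[mask].mean())
    return CalciumProxy(t_s=proxy.t_s, signal=proxy.signal - base, baseline=base)
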