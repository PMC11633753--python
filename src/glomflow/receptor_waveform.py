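"""Odor-evoked receptor conductance waveforms.

The receptor current of an olfactory receptor neuron (ORN) is modelled as a
conductance g(t) = m * (a(t) + b(t) - c(t)) built from three piecewise
components fitted to suction-electrode recordings of ORN transduction
currents:

* ``a`` -- a sigmoidal rise spanning the odor stimulus (onset kinetics),
* ``b`` -- a sigmoidal decay after the conductance envelope ends,
* ``c`` -- a slow exponential describing transduction adaptation during the
  steady-state phase of the stimulus.

Two printed parameter sets are shipped, one for a weak and one for a strong
odor concentration.  The conductance envelope outlasts the odor stimulus by a
duration multiplier ``tx`` (1 for weak stimuli; random around 1.85 for strong
stimuli), which is the substrate of the delayed rebound firing seen after
strong stimuli.

``m`` is a free scaling factor; it is calibrated against the target peak
receptor current (13 pA weak / 96 pA strong) by
:func:`glomflow.orn_biophysics.calibrate_m`.

All times are in milliseconds; the raw a/b/c components are in the
dimensionless units of the published fits and become Siemens only after
scaling by ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "PiecewiseParams",
    "StimulusSpec",
    "TxRule",
    "WEAK",
    "STRONG",
    "waveform_params",
    "component_a",
    "component_b",
    "component_c",
    "conductance",
    "sample_tx",
    "waveform_table",
]

C_ONSET_MS = 190.0  # adaptation window opens 190 ms after odor onset (both intensities)


@dataclass(frozen=True)
class PiecewiseParams:
    """Constants of the three piecewise conductance components.

    Attributes use the grouping reconstructed from the published formulas:

    * ``a(t) = A_amp / (1 + exp((A_half + t0 - t)/A_slope))`` for
      ``t0 < t < t0 + td*tx``,
    * ``b(t) = B_amp / (1 + exp((t - t_off - B_shift)/B_slope))`` for
      ``t_off < t < t_off + B_window`` where ``t_off = t0 + td*tx``,
    * ``c(t) = C_base - (C_offset + C_amp * exp(-(t - t0 - 190)/C_tau))``
      for ``t0 + 190 < t < t_off``.
    """

    A_amp: float
    A_half: float
    A_slope: float
    B_amp: float
    B_shift: float
    B_slope: float
    B_window: float
    C_base: float
    C_offset: float
    C_amp: float
    C_tau: float
    C_onset: float = C_ONSET_MS

    def __post_init__(self) -> None:
        if min(self.A_slope, self.B_slope, self.C_tau) <= 0:
            raise ValueError("slopes and time constants must be positive")
        if self.B_window <= 0:
            raise ValueError("B_window must be positive")
        if not (self.A_amp >= self.C_base - self.C_offset >= 0):
            raise ValueError("require A_amp >= C_base - C_offset >= 0")


@dataclass(frozen=True)
class TxRule:
    """Duration-multiplier rule: fixed 1 for weak, 1.65 + N(0.2, 0.25) for strong."""

    weak_value: float = 1.0
    strong_base: float = 1.65
    strong_noise_mean: float = 0.2
    strong_noise_sd: float = 0.25


@dataclass
class StimulusSpec:
    """One odor stimulus: onset ``t0`` (ms), duration ``td`` (ms), intensity
    ('weak'|'strong'), duration multiplier ``tx`` and conductance scale ``m``."""

    t0: float
    td: float
    intensity: str = "weak"
    tx: float = 1.0
    m: float = 1.0

    def __post_init__(self) -> None:
        if self.td <= 0:
            raise ValueError("stimulus duration td must be positive")
        if self.tx < 1:
            raise ValueError("tx must be >= 1")
        if self.m <= 0:
            raise ValueError("scaling factor m must be positive")
        if self.intensity not in ("weak", "strong"):
            raise ValueError(f"unknown intensity {self.intensity!r}")

    @property
    def t_off(self) -> float:
        """End of the conductance envelope (start of the b decay), ms."""
        return self.t0 + self.td * self.tx


def _load_param_table() -> dict:
    with resources.files("glomflow.params").joinpath("waveforms.yaml").open() as fh:
        return yaml.safe_load(fh)


_TABLE = _load_param_table()

WEAK = PiecewiseParams(**_TABLE["weak"])
STRONG = PiecewiseParams(**_TABLE["strong"])


def waveform_params(intensity: str) -> PiecewiseParams:
    """Return the published parameter set for 'weak' or 'strong'."""
    try:
        return {"weak": WEAK, "strong": STRONG}[intensity]
    except KeyError:
        raise ValueError(f"unknown intensity {intensity!r}") from None


def component_a(t, spec: StimulusSpec, p: PiecewiseParams | None = None):
    """Stimulus-onset sigmoid; nonzero on t0 < t < t0 + td*tx."""
    p = p or waveform_params(spec.intensity)
    t = np.asarray(t, dtype=float)
    inside = (t > spec.t0) & (t < spec.t_off)
    val = p.A_amp / (1.0 + np.exp((p.A_half + spec.t0 - t) / p.A_slope))
    return np.where(inside, val, 0.0)


def component_b(t, spec: StimulusSpec, p: PiecewiseParams | None = None):
    """Post-envelope decay sigmoid; nonzero on t_off < t < t_off + B_window."""
    p = p or waveform_params(spec.intensity)
    t = np.asarray(t, dtype=float)
    t_off = spec.t_off
    inside = (t > t_off) & (t < t_off + p.B_window)
    val = p.B_amp / (1.0 + np.exp((t - t_off - p.B_shift) / p.B_slope))
    return np.where(inside, val, 0.0)


def component_c(t, spec: StimulusSpec, p: PiecewiseParams | None = None):
    """Steady-state adaptation; nonzero on t0 + C_onset < t < t_off.

    Monotonically increasing toward the asymptote ``C_base - C_offset``; its
    subtraction from ``a`` produces the slow sag of the receptor current during
    a sustained stimulus.
    """
    p = p or waveform_params(spec.intensity)
    t = np.asarray(t, dtype=float)
    inside = (t > spec.t0 + p.C_onset) & (t < spec.t_off)
    with np.errstate(over="ignore"):
        val = p.C_base - (
            p.C_offset + p.C_amp * np.exp(-(t - spec.t0 - p.C_onset) / p.C_tau)
        )
    return np.where(inside, val, 0.0)


def conductance(t, spec: StimulusSpec, p: PiecewiseParams | None = None):
    """Total receptor conductance g(t) = m*(a + b - c), floored at zero.

    The floor removes the small negative excursion of ``a - c`` immediately
    after the adaptation window opens (the published constants make
    ``c(190+) ~ -0.0065`` for the weak set instead of exactly 0).
    """
    p = p or waveform_params(spec.intensity)
    g = component_a(t, spec, p) + component_b(t, spec, p) - component_c(t, spec, p)
    return np.maximum(spec.m * g, 0.0)


def sample_tx(intensity: str, rng: np.random.Generator, rule: TxRule = TxRule()) -> float:
    """Draw the envelope duration multiplier for one neuron and trial.

    Weak stimuli use exactly 1.  Strong stimuli draw
    ``1.65 + N(0.2, 0.25)``, clipped below at 1 so the envelope never ends
    before the stimulus does (the receptor current outlasts the stimulus).
    """
    if intensity == "weak":
        return rule.weak_value
    if intensity == "strong":
        tx = rule.strong_base + rng.normal(rule.strong_noise_mean, rule.strong_noise_sd)
        return max(tx, 1.0)
    raise ValueError(f"unknown intensity {intensity!r}")


def waveform_table(spec: StimulusSpec, dt: float = 1.0, t_max: float | None = None):
    """Sample t, a, b, c, g on a regular grid; returns a dict of arrays."""
    p = waveform_params(spec.intensity)
    if t_max is None:
        t_max = spec.t_off + p.B_window + 100.0
    t = np.arange(0.0, t_max, dt)
    return {
        "t": t,
        "a": component_a(t, spec, p),
        "b": component_b(t, spec, p),
        "c": component_c(t, spec, p),
        "g": conductance(t, spec, p),
    }
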