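"""Synthetic glomerular-imaging cohorts.

Generates complete per-mouse trace tables across an ascending odor
concentration ladder with the statistical structure the analysis pipeline
assumes, so that every stage is testable without in vivo data:

* one *primary* glomerulus per mouse -- most sensitive, first to activate at
  weak concentrations -- plus later-recruited secondary glomeruli,
* naive cohort: the primary responds sustained at weak-percept
  concentrations and switches to a transient/undershoot/rebound (depolarizing
  block) response at strong-percept concentrations,
* associated cohort (odor paired with food): the primary stays sustained
  throughout, with its peak-response concentration shifted about two orders
  of magnitude upward, toward the concentration experienced on food,
* exposed cohort (same odor exposure, no food association): like naive,
* per-frame Gaussian fluorescence noise and, with some probability,
  irregular-breathing artifact trials (a coherent activity drop across all
  glomeruli) with ground-truth flags retained.

Two trace-template backends exist.  The *parametric* backend (default) uses
closed-form response templates whose shape constants -- block peak ratio,
undershoot depth, rebound delay and amplitude, sustained-adaptation plateau
-- were extracted from the *mechanistic* backend (the HH population
simulator convolved with the GCaMP6f kernel; see
:func:`derive_block_parameters`), so the synthetic phenotypes inherit the
model's dynamics while remaining fast enough for routine testing.

Concentrations are handled on a log10 scale internally and reported in %
saturated vapor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imaging_analysis as ia

__all__ = [
    "DEFAULT_LADDER",
    "BLOCK_SHAPE",
    "SUSTAINED_SHAPE",
    "CohortSpec",
    "GlomerulusModel",
    "PerceptDataset",
    "generate_cohort",
    "generate_percept_dataset",
    "inject_artifacts",
    "derive_block_parameters",
]

# Odorant dilution series used throughout, % saturated vapor.
DEFAULT_LADDER = (3e-5, 1e-4, 3e-3, 1e-2, 0.1, 1.0, 3.0, 10.0)

# Template shape constants extracted from the mechanistic backend
# (40-neuron HH population, 3-s stimuli, GCaMP6f kernel; derive_block_parameters).
BLOCK_SHAPE = {
    "peak_ratio": 0.20,       # block peak / sustained peak at matched drive
    "undershoot_frac": 0.58,  # depth below baseline, in units of the block peak
    "rebound_amp_frac": 2.0,  # rebound peak, in units of the block peak
    "rebound_lag_s": 1.8,     # rebound peak delay after the envelope ends
    "tx_mean": 1.85,          # envelope outlasts the stimulus by (tx-1)*td
    "tx_sd": 0.25,
}
SUSTAINED_SHAPE = {
    "plateau_frac": 0.35,     # late-stimulus level / peak (weak percept)
    "tau_adapt_s": 5.4,
    "tau_rise_s": 0.3,
    "tau_decay_s": 0.6,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_mice: int = 9
    cohort: str = "naive"                    # naive | associated | exposed
    ladder: tuple = DEFAULT_LADDER           # % sv, ascending
    n_glomeruli: int = 12
    n_trials: int = 3                        # 1..3 trials per stimulus
    frame_rate: float = 42.0                 # Hz
    noise_sd: float = 0.05                   # dF/F units, per frame
    artifact_prob: float = 0.0
    pre_s: float = 6.0
    stim_s: float = 3.0
    post_s: float = 6.0
    f0: float = 100.0                        # baseline fluorescence, a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if list(self.ladder) != sorted(self.ladder) or len(set(self.ladder)) != len(self.ladder):
            raise ValueError("concentration ladder must be strictly increasing")
        if self.cohort not in ("naive", "associated", "exposed"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact probability must be in [0, 1]")


@dataclass
class GlomerulusModel:
    """Response rules for one glomerulus."""

    glomerulus: int
    role: str                        # primary | secondary
    threshold: float                 # % sv; silent below
    c_peak: float                    # % sv of maximal response amplitude
    amp: float                       # peak dF/F at c_peak (sustained mode)
    latency_s: dict = field(default_factory=dict)      # concentration -> onset latency
    mode: dict = field(default_factory=dict)           # concentration -> response mode
    sigma_log: float = 1.5           # width of the log-Gaussian amplitude curve

    def amplitude(self, c: float) -> float:
        if c < self.threshold:
            return 0.0
        d = np.log10(c) - np.log10(self.c_peak)
        return self.amp * (0.25 + 0.75 * np.exp(-d * d / (2 * self.sigma_log ** 2)))


@dataclass
class PerceptDataset:
    """Per-mouse normalized response matrices with percept labels."""

    responses: dict                  # mouse -> DataFrame (stimuli x glomeruli)
    labels: dict                     # mouse -> Series of 'weak'/'strong'/None
    ground_truth: dict


def _smoothstep(t, start, tau):
    return 1.0 / (1.0 + np.exp(-(t - start) / max(tau / 4.0, 1e-6)))


def _sustained_template(t, on, off, lat, plateau_frac, tau_adapt,
                        tau_rise=SUSTAINED_SHAPE["tau_rise_s"],
                        tau_decay=SUSTAINED_SHAPE["tau_decay_s"]):
    """Saturating rise then slow adaptation toward a plateau; exponential
    indicator decay after stimulus offset.  Peak normalized to ~1."""
    t0 = on + lat
    rise = np.where(t > t0, 1.0 - np.exp(-np.maximum(t - t0, 0) / tau_rise), 0.0)
    adapt = plateau_frac + (1 - plateau_frac) * np.exp(-np.maximum(t - t0, 0) / tau_adapt)
    during = rise * adapt
    v_off = np.interp(off, t, during)
    after = v_off * np.exp(-np.maximum(t - off, 0) / tau_decay)
    return np.where(t < off, during, after)


def _block_template(t, on, off, lat, tx, shape=BLOCK_SHAPE):
    """Transient onset burst, undershoot below baseline lasting through the
    conductance envelope (which outlasts the stimulus by (tx-1)*td), then a
    delayed rebound bump.  Onset peak normalized to 1."""
    t0 = on + lat
    td = off - on
    t_env = off + (tx - 1.0) * td
    x = np.maximum(t - t0, 0)
    a_r, b_d = 0.06, 0.22   # rise and decay time constants, s
    burst = (1.0 - np.exp(-x / a_r)) * np.exp(-x / b_d)
    # analytic peak of (1-e^(-x/a))e^(-x/b) at x* = a*ln((a+b)/a)
    x_pk = a_r * np.log((a_r + b_d) / a_r)
    norm = (1.0 - a_r / (a_r + b_d)) * np.exp(-x_pk / b_d)
    burst = np.where(t > t0, burst / norm, 0.0)
    under = shape["undershoot_frac"] * _smoothstep(t, t0 + 0.45, 0.6) \
        * (1.0 - _smoothstep(t, t_env + 0.6, 1.2))
    t_reb = t_env + shape["rebound_lag_s"]
    rebound = shape["rebound_amp_frac"] * np.exp(-((t - t_reb) ** 2) / (2 * 0.45 ** 2))
    return burst - under + rebound


def _assign_models(spec: CohortSpec, rng: np.random.Generator) -> list[GlomerulusModel]:
    """Glomerulus models for one mouse.  Glomerulus 0 is the primary."""
    ladder = spec.ladder
    assoc = spec.cohort == "associated"
    models = []
    c_peak_primary = 1.0 if assoc else 1e-2
    primary = GlomerulusModel(
        glomerulus=0, role="primary", threshold=ladder[0],
        c_peak=c_peak_primary, amp=1.5 * float(rng.uniform(0.9, 1.1)))
    for c in ladder:
        if assoc:
            primary.mode[c] = "sustained"
        elif c <= ia.WEAK_BOUNDARY:
            primary.mode[c] = "sustained"
        elif c < ia.STRONG_BOUNDARY:
            primary.mode[c] = "adapting"      # transition range: deep adaptation
        else:
            primary.mode[c] = "block"
        # primary activates fast at weak concentrations but lags the
        # recruited secondaries at strong ones; this relative-primacy
        # structure is a property of the input and unaffected by learning
        primary.latency_s[c] = 0.15 if c < ia.STRONG_BOUNDARY else 0.35
    models.append(primary)
    for g in range(1, spec.n_glomeruli):
        thr = 10.0 ** rng.uniform(-2.0, 0.5)
        amp = float(rng.uniform(0.3, 0.9))
        m = GlomerulusModel(glomerulus=g, role="secondary", threshold=thr,
                            c_peak=min(10.0, thr * 10 ** 2.5), amp=amp)
        for c in ladder:
            m.mode[c] = "sustained"
            # recruitment latency shortens with concentration above threshold
            if c >= thr:
                m.latency_s[c] = float(np.clip(
                    0.6 - 0.17 * (np.log10(c) - np.log10(thr)) + rng.normal(0, 0.04),
                    0.12, 1.5))
            else:
                m.latency_s[c] = np.nan
        models.append(m)
    return models


def _trial_trace(t, model: GlomerulusModel, c: float, on: float, off: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Noise-free dF/F template for one glomerulus and trial."""
    a = model.amplitude(c)
    if a <= 0:
        return np.zeros_like(t)
    gain = float(np.exp(rng.normal(0.0, 0.12 if model.role == "primary" else 0.35)))
    mode = model.mode.get(c, "sustained")
    lat = model.latency_s.get(c, 0.3)
    if mode == "sustained":
        shape = _sustained_template(t, on, off, lat,
                                    SUSTAINED_SHAPE["plateau_frac"],
                                    SUSTAINED_SHAPE["tau_adapt_s"])
    elif mode == "adapting":
        shape = _sustained_template(t, on, off, lat, 0.15, 1.5)
    elif mode == "block":
        tx = max(1.0, rng.normal(BLOCK_SHAPE["tx_mean"], BLOCK_SHAPE["tx_sd"]))
        shape = _block_template(t, on, off, lat, tx)
        # the onset burst is drive-saturated: its size scales with the full
        # glomerular gain, not the concentration-tuning curve
        a = model.amp * BLOCK_SHAPE["peak_ratio"]
    else:
        raise ValueError(f"unknown response mode {mode!r}")
    return a * gain * shape


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate the tidy trace table and ground truth for one cohort.

    Returns ``(table, ground_truth)``.  The table has the schema consumed by
    :mod:`glomflow.imaging_analysis` -- columns mouse, glomerulus,
    concentration, trial, frame_time_s, F -- plus stim_on_s/stim_off_s.
    Identical specs (same seed) give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round((spec.pre_s + spec.stim_s + spec.post_s) * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate
    on, off = spec.pre_s, spec.pre_s + spec.stim_s
    frames = pd.DataFrame({"frame_time_s": t})

    chunks = []
    truth: dict = {"cohort": spec.cohort, "seed": spec.seed, "mice": {},
                   "assumptions": {
                       "secondary_latency": "log-linear in concentration above "
                       "threshold; not constrained by measured data",
                   },
                   "template_shapes": {"block": BLOCK_SHAPE,
                                       "sustained": SUSTAINED_SHAPE}}
    for im in range(spec.n_mice):
        mouse = f"m{im}"
        models = _assign_models(spec, rng)
        truth["mice"][mouse] = {
            "glomeruli": [
                {"glomerulus": m.glomerulus, "role": m.role,
                 "threshold": m.threshold, "c_peak": m.c_peak, "amp": m.amp,
                 "modes": {str(k): v for k, v in m.mode.items()}}
                for m in models
            ],
        }
        for c in spec.ladder:
            for trial in range(spec.n_trials):
                for m in models:
                    dffv = _trial_trace(t, m, c, on, off, rng)
                    dffv = dffv + rng.normal(0.0, spec.noise_sd, size=n_frames)
                    chunk = frames.copy()
                    chunk["mouse"] = mouse
                    chunk["glomerulus"] = m.glomerulus
                    chunk["concentration"] = c
                    chunk["trial"] = trial
                    chunk["F"] = spec.f0 * (1.0 + dffv)
                    chunks.append(chunk)
    table = pd.concat(chunks, ignore_index=True)
    table["stim_on_s"] = on
    table["stim_off_s"] = off
    if spec.artifact_prob > 0:
        table, flags = inject_artifacts(table, spec.artifact_prob, rng,
                                        noise_sd=spec.noise_sd, f0=spec.f0)
        truth["artifact_trials"] = flags.to_dict(orient="records")
    else:
        truth["artifact_trials"] = []
    return table, truth


def inject_artifacts(table: pd.DataFrame, probability: float,
                     rng: np.random.Generator, noise_sd: float = 0.05,
                     f0: float = 100.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark random trials with an irregular-breathing artifact.

    During the artifact window (~2 s Gaussian envelope), odor-evoked
    activity in *all* glomeruli is suppressed toward baseline and the trace
    dips below it (depth 4 noise SDs + 0.1 dF/F) -- the signature of a pause
    in inhalation.  Returns the modified table and a ground-truth flag
    table.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    table = table.copy()
    keys = table[["mouse", "concentration", "trial"]].drop_duplicates()
    flags = []
    depth_rel = 4.0 * noise_sd + 0.1  # dF/F units
    for _, key in keys.iterrows():
        hit = bool(rng.random() < probability)
        flags.append({**key.to_dict(), "artifact": hit})
        if not hit:
            continue
        sel = ((table["mouse"] == key["mouse"])
               & (table["concentration"] == key["concentration"])
               & (table["trial"] == key["trial"]))
        tt = table.loc[sel, "frame_time_s"].to_numpy()
        on = table.loc[sel, "stim_on_s"].iloc[0]
        t_max = tt.max()
        center = rng.uniform(on + 0.5, max(on + 0.6, t_max - 2.5))
        env = np.exp(-((tt - center) ** 2) / (2 * 0.7 ** 2))
        dffv = table.loc[sel, "F"].to_numpy() / f0 - 1.0
        dffv = dffv * (1.0 - env) - depth_rel * env
        table.loc[sel, "F"] = f0 * (1.0 + dffv)
    return table, pd.DataFrame(flags)


def generate_percept_dataset(spec: CohortSpec) -> PerceptDataset:
    """Cohort -> per-mouse normalized response matrices with percept labels.

    Runs the real analysis path on the generated tables: dF/F per trace,
    response amplitude over stimulus + 1 s, per-glomerulus normalization to
    the maximum across stimuli, percept labels from the boundary
    concentrations (transition-range stimuli unlabeled).
    """
    table, truth = generate_cohort(spec)
    responses: dict = {}
    labels: dict = {}
    for mouse, mg in table.groupby("mouse"):
        rows = {}
        for (c, trial), gg in mg.groupby(["concentration", "trial"]):
            amps = {}
            for gid, tr in gg.groupby("glomerulus"):
                trace = ia.GlomerulusTrace(
                    F=tr.sort_values("frame_time_s")["F"].to_numpy(),
                    frame_rate=spec.frame_rate, stim_on_s=spec.pre_s,
                    stim_off_s=spec.pre_s + spec.stim_s,
                    glomerulus=int(gid), mouse=mouse, concentration=c,
                    trial=int(trial))
                amps[gid] = ia.response_amplitude(ia.dff(trace))
            rows[(c, trial)] = amps
        mat = pd.DataFrame(rows).T
        mat.index.names = ["concentration", "trial"]
        responses[mouse] = ia.normalize_responses(mat)
        labels[mouse] = ia.label_percepts(
            mat.index.get_level_values("concentration"))
        labels[mouse].index = mat.index
    return PerceptDataset(responses=responses, labels=labels, ground_truth=truth)


def render_movie(table: pd.DataFrame, mouse: str, concentration: float,
                 trial: int, masks: dict, shape: tuple = (48, 48),
                 noise_sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Render a small synthetic fluorescence movie for one trial.

    Each glomerulus paints its fluorescence trace uniformly over its boolean
    mask (``masks``: glomerulus id -> (h, w) array); off-glomerulus pixels
    hold a constant background, and iid Gaussian pixel noise is added.
    Deliberately coarse -- a fixture for the pixelwise response-map path,
    not an emulation of raw sensor data.
    """
    rng = np.random.default_rng(seed)
    sel = table[(table["mouse"] == mouse)
                & (table["concentration"] == concentration)
                & (table["trial"] == trial)]
    if sel.empty:
        raise ValueError("no such trial in the table")
    times = np.sort(sel["frame_time_s"].unique())
    movie = np.full((times.size, *shape), 50.0)
    for gid, g in sel.groupby("glomerulus"):
        if gid not in masks:
            continue
        f = g.sort_values("frame_time_s")["F"].to_numpy()
        movie[:, masks[gid].astype(bool)] = f[:, None]
    movie += rng.normal(0.0, noise_sd, size=movie.shape)
    return movie


def derive_block_parameters(n_neurons: int = 40, td_ms: float = 3000.0,
                            seed: int = 11) -> dict:
    """Re-derive the parametric template constants from the mechanistic
    backend (slow: runs the HH population simulator for a weak and a strong
    trial and measures the convolved calcium proxy)."""
    from . import orn_biophysics as ob
    from . import population_readout as pr
    from .receptor_waveform import StimulusSpec

    cell = ob.build_cell()
    v_rest = ob.resting_potential(cell)
    out = {}
    for intensity in ("weak", "strong"):
        m = ob.calibrate_m(cell, intensity, v_rest=v_rest)
        stim = StimulusSpec(t0=3000.0, td=td_ms, intensity=intensity, m=m)
        cfg = ob.SimConfig(duration=td_ms + 11_000.0, n_neurons=n_neurons, seed=seed)
        res = ob.integrate(cell, cfg, stimulus=stim)
        p = pr.psth(res.spike_times, window_ms=(0.0, td_ms + 11_000.0))
        prox = pr.baseline_relative(pr.gcamp_convolve(p), (0.0, 2.9))
        out[intensity] = (prox, res)
    t = out["strong"][0].t_s
    s = out["strong"][0].signal
    w = out["weak"][0].signal
    stim_win = (t >= 3.0) & (t < 3.0 + td_ms / 1000.0)
    post = t >= 3.0 + td_ms / 1000.0
    peak_s, peak_w = s[stim_win].max(), w[stim_win].max()
    tx_mean = float(out["strong"][1].tx.mean())
    t_env = 3.0 + td_ms / 1000.0 * tx_mean
    t_reb = float(t[post][s[post].argmax()])
    return {
        "peak_ratio": float(peak_s / peak_w),
        "undershoot_frac": float(-s[stim_win].min() / peak_s),
        "rebound_amp_frac": float(s[post].max() / peak_s),
        "rebound_lag_s": t_reb - t_env,
        "tx_mean": tx_mean,
        "tx_sd": float(out["strong"][1].tx.std()),
    }
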