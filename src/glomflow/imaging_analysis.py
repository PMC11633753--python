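"""Glomerular calcium-imaging trace statistics and percept decoding.

Implements the quantities used to characterize glomerular odor responses
across a concentration ladder:

* dF/F normalization against a 5-s pre-stimulus baseline,
* pixelwise response maps (3-s pre-stimulus baseline, sigma=2 Gaussian
  smoothing, zero outside segmented glomeruli),
* the adaptation index AI = (peak - mean of last 100 ms of stimulus)/peak
  on a 5-point mean-filtered trace; AI = 1 is complete adaptation and
  AI > 1 means the response fell below baseline,
* SNR-based responsiveness (SNR >= 5, and the immediately following
  concentration also responsive),
* response amplitudes (mean over stimulus + 1 s) normalized per glomerulus
  to the maximum across stimuli,
* weak/strong percept labels from boundary concentrations (<= 0.01 % and
  >= 0.3 % saturated vapor; the transition range between is unlabeled),
* a class-balanced linear SVM percept classifier with leave-one-out
  weighted F1 and per-glomerulus weight attribution, and
* activation-time ranking (first stimulus frame with SNR >= 5; rank 1 =
  earliest).

Traces travel as tidy :class:`pandas.DataFrame` tables with columns
``mouse, glomerulus, concentration, trial, frame_time_s, F`` (raw
fluorescence) so that synthetic cohorts and file-based data flow through
identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter1d
from sklearn.metrics import f1_score
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import LinearSVC

__all__ = [
    "TRACE_COLUMNS",
    "WEAK_BOUNDARY",
    "STRONG_BOUNDARY",
    "SNR_THRESHOLD",
    "GlomerulusTrace",
    "DffTrace",
    "AdaptationIndexResult",
    "ClassifierReport",
    "ActivationRank",
    "dff",
    "response_map",
    "adaptation_index",
    "snr",
    "responsive",
    "response_amplitude",
    "normalize_responses",
    "label_percepts",
    "fit_percept_classifier",
    "rank_activation",
    "artifact_trials",
    "InvalidBaselineError",
    "UndefinedAIError",
]

TRACE_COLUMNS = ("mouse", "glomerulus", "concentration", "trial", "frame_time_s", "F")

WEAK_BOUNDARY = 0.01    # % saturated vapor; c <= this -> weak percept
STRONG_BOUNDARY = 0.3   # % saturated vapor; c >= this -> strong percept
SNR_THRESHOLD = 5.0     # inclusive


class InvalidBaselineError(ValueError):
    """Baseline fluorescence is nonpositive or missing."""


class UndefinedAIError(ValueError):
    """Adaptation index undefined (nonpositive peak)."""


@dataclass
class GlomerulusTrace:
    """Raw fluorescence of one glomerulus on one trial."""

    F: np.ndarray
    frame_rate: float            # Hz
    stim_on_s: float
    stim_off_s: float
    glomerulus: int = 0
    mouse: str = "m0"
    concentration: float = np.nan   # % saturated vapor
    trial: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if not (0 <= self.stim_on_s < self.stim_off_s <= len(self.F) / self.frame_rate):
            raise ValueError("stimulus window must lie inside the trace")

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(len(self.F)) / self.frame_rate


@dataclass
class DffTrace:
    """dF/F series with the baseline-window definition that produced it."""

    values: np.ndarray
    frame_rate: float
    stim_on_s: float
    stim_off_s: float
    baseline_s: float = 5.0

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


@dataclass
class AdaptationIndexResult:
    ai: float
    peak: float
    tail_mean: float           # mean of last 100 ms of stimulus
    filter_points: int = 5


@dataclass
class ClassifierReport:
    f1: float                           # leave-one-out weighted F1
    weights: pd.Series                  # |coef| per glomerulus, max-normalized
    n_stimuli: int
    glomeruli: tuple = ()


@dataclass
class ActivationRank:
    first_frame_s: dict                 # glomerulus -> activation time (s) or nan
    ranks: dict                         # glomerulus -> integer rank (1 = earliest)


def dff(trace: GlomerulusTrace, baseline_s: float = 5.0) -> DffTrace:
    """(F - F0)/F0 with F0 the mean over ``baseline_s`` seconds immediately
    before stimulus onset."""
    n0 = int(round((trace.stim_on_s - baseline_s) * trace.frame_rate))
    n1 = int(round(trace.stim_on_s * trace.frame_rate))
    if n0 < 0 or n1 <= n0:
        raise InvalidBaselineError(
            f"need {baseline_s} s of pre-stimulus frames before t={trace.stim_on_s} s")
    f0 = float(np.mean(trace.F[n0:n1]))
    if f0 <= 0:
        raise InvalidBaselineError(f"baseline fluorescence F0={f0:.3g} must be positive")
    return DffTrace(values=(trace.F - f0) / f0, frame_rate=trace.frame_rate,
                    stim_on_s=trace.stim_on_s, stim_off_s=trace.stim_off_s,
                    baseline_s=baseline_s)


def response_map(movie: np.ndarray, masks: np.ndarray, frame_rate: float,
                 stim_on_s: float, stim_off_s: float, pre_s: float = 3.0,
                 sigma: float = 2.0) -> np.ndarray:
    """Mean pixelwise dF/F over the stimulus window, Gaussian-smoothed
    (sigma in pixels) and zeroed outside the segmented glomeruli.

    ``movie`` is (frames, h, w); ``masks`` a boolean (h, w) union of
    glomerulus masks (or an integer label image; nonzero = inside).
    """
    masks = np.asarray(masks)
    if not masks.any():
        raise ValueError("empty mask set")
    n_pre0 = int(round((stim_on_s - pre_s) * frame_rate))
    n_on = int(round(stim_on_s * frame_rate))
    n_off = int(round(stim_off_s * frame_rate))
    if n_pre0 < 0 or n_off > movie.shape[0]:
        raise ValueError("movie does not cover the pre-window and stimulus")
    f0 = movie[n_pre0:n_on].mean(axis=0)
    if (f0 <= 0).any():
        raise InvalidBaselineError("nonpositive baseline pixels")
    resp = ((movie[n_on:n_off] - f0) / f0).mean(axis=0)
    smoothed = gaussian_filter(resp, sigma=sigma)
    return np.where(masks.astype(bool), smoothed, 0.0)


def _mean_filter(x: np.ndarray, points: int = 5) -> np.ndarray:
    # centered running mean; the window shrinks at the edges
    return uniform_filter1d(np.asarray(x, float), size=points, mode="nearest")


def adaptation_index(trace: DffTrace, tail_ms: float = 100.0,
                     filter_points: int = 5) -> AdaptationIndexResult:
    """AI = (peak - mean of the last ``tail_ms`` of the stimulus) / peak,
    computed on the 5-point mean-filtered trace.

    The peak is taken over the stimulus window.  AI = 1 iff the tail mean is
    zero (complete adaptation); AI > 1 iff the response ends below baseline.
    """
    v = _mean_filter(trace.values, filter_points)
    t = trace.t_s
    stim = (t >= trace.stim_on_s) & (t < trace.stim_off_s)
    n_tail = max(1, int(round(tail_ms / 1000.0 * trace.frame_rate)))
    if stim.sum() < n_tail:
        raise UndefinedAIError("stimulus window shorter than the tail window")
    peak = float(v[stim].max())
    if peak <= 0:
        raise UndefinedAIError(f"nonpositive peak ({peak:.3g})")
    tail = float(v[stim][-n_tail:].mean())
    return AdaptationIndexResult(ai=(peak - tail) / peak, peak=peak,
                                 tail_mean=tail, filter_points=filter_points)


def snr(trace: DffTrace, pre_s: float = 3.0) -> float:
    """(max over stimulus - baseline mean) / baseline SD, on the dF/F trace.

    The baseline statistics come from the ``pre_s`` seconds immediately
    preceding stimulus onset.  Responsiveness uses SNR >= 5, boundary
    inclusive.
    """
    t = trace.t_s
    pre = (t >= trace.stim_on_s - pre_s) & (t < trace.stim_on_s)
    stim = (t >= trace.stim_on_s) & (t < trace.stim_off_s)
    if not pre.any():
        raise ValueError("no baseline frames")
    sd = float(trace.values[pre].std())
    if sd == 0:
        raise ValueError("baseline window has zero SD")
    return float((trace.values[stim].max() - trace.values[pre].mean()) / sd)


def responsive(snr_by_concentration: dict, threshold: float = SNR_THRESHOLD,
               require_successor: bool = True) -> dict:
    """Responsiveness flags over an ascending concentration ladder.

    A glomerulus is responsive at a concentration iff its SNR meets the
    threshold there and at the next tested concentration; the top rung is
    judged on its own SNR (it has no successor).  This suppresses isolated
    single-concentration flickers.  Set ``require_successor=False`` for the
    plain per-stimulus rule.
    """
    concs = sorted(snr_by_concentration)
    out = {}
    for i, c in enumerate(concs):
        ok = snr_by_concentration[c] >= threshold
        if require_successor and ok and i + 1 < len(concs):
            ok = snr_by_concentration[concs[i + 1]] >= threshold
        out[c] = bool(ok)
    return out


def response_amplitude(trace: DffTrace, post_s: float = 1.0) -> float:
    """Mean dF/F over the stimulus period plus ``post_s`` seconds after odor
    cessation (capturing delayed activation)."""
    t = trace.t_s
    if trace.stim_off_s + post_s > t[-1] + 1.0 / trace.frame_rate:
        raise ValueError("trace ends before stimulus offset + post window")
    win = (t >= trace.stim_on_s) & (t < trace.stim_off_s + post_s)
    return float(trace.values[win].mean())


def normalize_responses(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Normalize each glomerulus column to its maximum across stimuli (rows).

    Rows index stimuli, columns glomeruli.  Columns with nonpositive maxima
    are left unscaled.
    """
    out = amplitudes.copy().astype(float)
    for col in out.columns:
        mx = out[col].max()
        if mx > 0:
            out[col] = out[col] / mx
    return out


def label_percepts(concentrations, weak_boundary: float = WEAK_BOUNDARY,
                   strong_boundary: float = STRONG_BOUNDARY) -> pd.Series:
    """'weak' for c <= 0.01 % sv, 'strong' for c >= 0.3 % sv, otherwise None
    (transition range; excluded from classification)."""
    arr = np.asarray(concentrations, dtype=float)
    index = (concentrations.index if isinstance(concentrations, pd.Series)
             else pd.RangeIndex(len(arr)))
    lab = pd.Series([None] * len(arr), dtype=object, index=index)
    lab[arr <= weak_boundary] = "weak"
    lab[arr >= strong_boundary] = "strong"
    return lab


def fit_percept_classifier(responses: pd.DataFrame, labels,
                           subset=None, C: float = 1.0,
                           seed: int = 0) -> ClassifierReport:
    """Linear max-margin percept classifier with leave-one-out weighted F1.

    ``responses``: stimuli x glomeruli matrix of normalized amplitudes;
    ``labels``: percept label per stimulus ('weak'/'strong'; None rows are
    dropped).  Class imbalance is handled with balanced class weights.  The
    report carries the absolute coefficient per glomerulus normalized to the
    largest (fit on all stimuli), so exactly one glomerulus has weight 1.
    """
    labels = pd.Series(list(labels), index=responses.index)
    keep = labels.notna()
    X_full = responses.loc[keep]
    y = labels[keep].astype(str)
    if y.nunique() < 2:
        raise ValueError("need at least two percept classes to classify")
    if (y.value_counts() < 2).any():
        raise ValueError("need >= 2 stimuli per class for leave-one-out scoring")
    X = X_full[list(subset)] if subset is not None else X_full
    # responses enter max-normalized; re-applying the global normalization
    # here makes the report exactly invariant to feature rescaling
    scale = float(np.abs(X.to_numpy()).max())
    if scale > 0:
        X = X / scale

    def make_clf():
        return LinearSVC(C=C, class_weight="balanced", random_state=seed)

    preds = np.empty(len(y), dtype=object)
    for tr, te in LeaveOneOut().split(X):
        clf = make_clf().fit(X.iloc[tr].to_numpy(), y.iloc[tr])
        preds[te[0]] = clf.predict(X.iloc[te].to_numpy())[0]
    f1 = f1_score(y, preds.astype(str), average="weighted")

    full_fit = make_clf().fit(X.to_numpy(), y)
    w = np.abs(full_fit.coef_[0])
    w = w / w.max() if w.max() > 0 else w
    weights = pd.Series(w, index=X.columns).sort_values(ascending=False)
    return ClassifierReport(f1=float(f1), weights=weights, n_stimuli=len(y),
                            glomeruli=tuple(X.columns))


def rank_activation(traces: dict, pre_s: float = 3.0,
                    threshold: float = SNR_THRESHOLD) -> ActivationRank:
    """Activation order within one trial.

    For each glomerulus, the activation time is the first stimulus frame
    whose dF/F exceeds baseline mean + threshold*baseline SD (the per-frame
    form of the SNR >= 5 rule).  The earliest glomerulus gets rank 1.  Ties
    break by larger dF/F at the tied frame, then by glomerulus id;
    non-activating glomeruli get no rank.
    """
    first: dict = {}
    tiebreak: dict = {}
    for gid, tr in traces.items():
        t = tr.t_s
        pre = (t >= tr.stim_on_s - pre_s) & (t < tr.stim_on_s)
        stim = (t >= tr.stim_on_s) & (t < tr.stim_off_s)
        mu, sd = tr.values[pre].mean(), tr.values[pre].std()
        if sd == 0:
            raise ValueError("baseline window has zero SD")
        hits = np.flatnonzero(tr.values[stim] >= mu + threshold * sd)
        if hits.size:
            idx = np.flatnonzero(stim)[hits[0]]
            first[gid] = float(t[idx])
            tiebreak[gid] = -float(tr.values[idx])
        else:
            first[gid] = np.nan
    order = sorted((first[g], tiebreak[g], g) for g in first if np.isfinite(first[g]))
    ranks = {g: i + 1 for i, (_, _, g) in enumerate(order)}
    return ActivationRank(first_frame_s=first, ranks=ranks)


def artifact_trials(table: pd.DataFrame, drop_sd: float = 2.0,
                    fraction: float = 0.8, min_duration_s: float = 0.5,
                    baseline_s: float = 3.0) -> pd.DataFrame:
    """Flag irregular-breathing trials in a tidy dF/F trace table.

    A trial is flagged when more than ``fraction`` of its glomeruli
    simultaneously sit below -``drop_sd`` baseline SDs for at least
    ``min_duration_s``.  ``table`` needs columns mouse, glomerulus,
    concentration, trial, frame_time_s, dff, stim_on_s.  Returns one row per
    (mouse, concentration, trial) with a boolean ``artifact`` column.
    """
    rows = []
    for (mouse, conc, trial), g in table.groupby(["mouse", "concentration", "trial"]):
        pivot = g.pivot_table(index="frame_time_s", columns="glomerulus", values="dff")
        t = pivot.index.to_numpy()
        on = float(g["stim_on_s"].iloc[0])
        pre = (t >= on - baseline_s) & (t < on)
        arr = pivot.to_numpy()
        mu = arr[pre].mean(axis=0)
        sd = arr[pre].std(axis=0)
        sd[sd == 0] = np.inf
        below = (arr - mu) < -drop_sd * sd
        coherent = below.mean(axis=1) > fraction
        dt = float(np.median(np.diff(t))) if len(t) > 1 else np.inf
        need = max(1, int(round(min_duration_s / dt)))
        run = best = 0
        for c in coherent:
            run = run + 1 if c else 0
            best = max(best, run)
        rows.append({"mouse": mouse, "concentration": conc, "trial": trial,
                     "artifact": bool(best >= need)})
    return pd.DataFrame(rows)
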