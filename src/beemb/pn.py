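"""Projection-neuron signal processing and response-profile classification.

The pipeline starts from extracted glomerular fluorescence time series:
baseline-normalised -dF/F computation, trial averaging, trial-to-trial
stability (Pearson correlations of glomerular response vectors across
repetitions), supervised rule-based classification of response profiles into
the nine recurrent classes, and response-latency measurement with the 1-SD
threshold rule.

Window conventions (half-open, nearest-sample):
    PRE   [-1, 0) s relative to stimulus onset
    ON    [1, 5)  s relative to onset
    POST  [1, 4)  s relative to offset

Detection uses a 2-SD threshold held for >= 250 ms; the 1-SD threshold is
reserved for latency, separating detection robustness from latency
sensitivity.  When the pre-stimulus standard deviation is zero (noiseless
input) an absolute tolerance takes its place and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocol import StimulusProtocol, check_uniform_grid, window_slice
from .stats import safe_pearson
from .types import (
    EXCITATORY_GROUPS,
    INHIBITORY_COMPONENT_GROUPS,
    INHIBITORY_GROUPS,
    SHORT_GROUPS,
    UNRESPONSIVE,
    GlomerularTrace,
    OdorResponseMap,
    polarity_of_group,
)

WINDOWS = {
    "PRE": ("onset", -1.0, 0.0),
    "ON": ("onset", 1.0, 5.0),
    "POST": ("offset", 1.0, 4.0),
}


# ---------------------------------------------------------------------------
# dF/F and averaging
# ---------------------------------------------------------------------------

def compute_dff(raw: GlomerularTrace) -> GlomerularTrace:
    """-dF/F from a raw fluorescence trace.

    Baseline F0 is the mean fluorescence over the second before stimulus
    onset; the output is -(F - F0)/F0 so that fluorescence decreases of the
    Fura-2 sensor (calcium increases) read as positive responses.
    """
    t = raw.time_s
    if t[0] > -1.0 + 1e-9:
        raise ValueError("trace does not cover the 1 s baseline window")
    base = window_slice(t, -1.0, 0.0)
    f0 = float(raw.values[base].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline fluorescence (F0={f0:g})")
    return GlomerularTrace(
        values=-(raw.values - f0) / f0, time_s=t, protocol=raw.protocol,
        bee=raw.bee, odorant=raw.odorant, glomerulus=raw.glomerulus,
        trial=raw.trial, group=raw.group)


def average_trials(traces: Sequence[GlomerularTrace]) -> GlomerularTrace:
    """Pointwise mean across stimulus repetitions (trial id becomes "mean")."""
    if not traces:
        raise ValueError("no trials to average")
    t0 = traces[0]
    for tr in traces[1:]:
        if tr.values.shape != t0.values.shape:
            raise ValueError("trials must share the time grid")
    vals = np.mean([tr.values for tr in traces], axis=0)
    return GlomerularTrace(values=vals, time_s=t0.time_s, protocol=t0.protocol,
                           bee=t0.bee, odorant=t0.odorant,
                           glomerulus=t0.glomerulus, trial="mean",
                           group=t0.group)


def window_vector(response_map: OdorResponseMap, window) -> np.ndarray:
    """Per-glomerulus mean -dF/F over a named or explicit window.

    ``window`` is "PRE" / "ON" / "POST", or a tuple ``(anchor, start, end)``
    with anchor "onset" or "offset" and a half-open [start, end) range.
    """
    if isinstance(window, str):
        try:
            anchor, start, end = WINDOWS[window]
        except KeyError:
            raise ValueError(f"unknown window {window!r}") from None
    else:
        anchor, start, end = window
    shift = response_map.protocol.offset_s if anchor == "offset" else 0.0
    sl = window_slice(response_map.time_s, start + shift, end + shift)
    return response_map.values[:, sl].mean(axis=1)


# ---------------------------------------------------------------------------
# trial-to-trial stability
# ---------------------------------------------------------------------------

@dataclass
class TrialStabilityReport:
    correlations: Dict[str, np.ndarray]  # per comparison, one r per trial pair
    n_missing: Dict[str, int]            # zero-variance pairs, reported not zeroed

    def mean(self, comparison: str) -> float:
        return float(np.nanmean(self.correlations[comparison]))

    def sem(self, comparison: str) -> float:
        r = self.correlations[comparison]
        r = r[~np.isnan(r)]
        return float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan

    def summary(self) -> pd.DataFrame:
        rows = [{"comparison": c, "mean_r": self.mean(c), "sem_r": self.sem(c),
                 "n_pairs": int(np.isfinite(self.correlations[c]).sum()),
                 "n_missing": self.n_missing[c]}
                for c in self.correlations]
        return pd.DataFrame(rows)


def trial_stability(trial_maps: Sequence[OdorResponseMap]) -> TrialStabilityReport:
    """Pearson r between glomerular response vectors across repetitions.

    Within-window comparisons (PRE vs PRE, ON vs ON, POST vs POST) use all
    unordered trial pairs; ON vs POST uses all ordered cross-trial pairs.
    Pairs involving a zero-variance vector are undefined and reported as
    missing, never silently zero.
    """
    if len(trial_maps) < 2:
        raise ValueError("need at least two trials")
    vecs = {w: np.stack([window_vector(m, w) for m in trial_maps])
            for w in ("PRE", "ON", "POST")}
    n = len(trial_maps)
    corr: Dict[str, List[float]] = {}
    for name, w in (("PREvsPRE", "PRE"), ("ONvsON", "ON"), ("POSTvsPOST", "POST")):
        corr[name] = [safe_pearson(vecs[w][i], vecs[w][j])
                      for i in range(n) for j in range(i + 1, n)]
    corr["ONvsPOST"] = [safe_pearson(vecs["ON"][i], vecs["POST"][j])
                        for i in range(n) for j in range(n) if i != j]
    arrays = {k: np.asarray(v) for k, v in corr.items()}
    missing = {k: int(np.isnan(v).sum()) for k, v in arrays.items()}
    return TrialStabilityReport(correlations=arrays, n_missing=missing)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierParams:
    eps_abs: float = 0.02          # absolute threshold floor (-dF/F units)
    detect_sd: float = 2.0         # detection threshold, in pre-stimulus SDs
    latency_sd: float = 1.0        # latency threshold (as printed)
    min_component_s: float = 0.15  # minimum duration of a proper component
    min_event_s: float = 0.06      # minimum duration of a weak (group 9) event
    short_max_s: float = 1.5       # excitation ending earlier than this is "short"
    prolonged_hold_s: float = 1.0  # beyond threshold this long after offset
    sustain_s: float = 0.10        # latency crossings must persist this long


@dataclass
class ResponseClassification:
    group_id: int
    polarity: str
    has_inhibitory_component: bool
    onset_latency_ms: float = np.nan
    termination_latency_ms: float = np.nan
    flags: Tuple[str, ...] = ()


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Start/stop index pairs of contiguous True runs (half-open)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


@dataclass
class _Component:
    sign: int
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _threshold(trace: GlomerularTrace, n_sd: float,
               params: ClassifierParams) -> Tuple[float, float, bool]:
    """(pre-window mean, threshold half-width, eps_used flag).

    The half-width is n_sd pre-stimulus SDs, floored at the absolute
    tolerance ``eps_abs`` so that noiseless input (sd = 0) and vanishing
    noise stay well-defined; the flag marks when the floor took over.
    """
    base = window_slice(trace.time_s, -1.0, 0.0)
    pre = trace.values[base]
    mu, sd = float(pre.mean()), float(pre.std())
    half = n_sd * sd
    if half < params.eps_abs:
        return mu, params.eps_abs, True
    return mu, half, False


def _components(trace: GlomerularTrace, thr_half: float, mu: float,
                min_dur: float) -> List[_Component]:
    t = trace.time_s
    dt = trace.dt
    post_onset = t >= -1e-9
    comps = []
    for sign in (1, -1):
        mask = post_onset & (sign * (trace.values - mu) > thr_half)
        for i0, i1 in _runs(mask):
            if (i1 - i0) * dt >= min_dur:
                comps.append(_Component(sign, t[i0], t[i0] + (i1 - i0) * dt))
    comps.sort(key=lambda c: c.t_start)
    return comps


def classify_profile(trace: GlomerularTrace,
                     params: ClassifierParams = ClassifierParams()
                     ) -> ResponseClassification:
    """Deterministic rule-based classification of a trial-averaged trace.

    Responsiveness requires exceeding the detection threshold for at least
    250 ms contiguously after onset; polarity follows the sign of the first
    such component; short vs sustained excitation splits at a 1.5 s
    termination; prolonged responses stay beyond threshold throughout the
    first second after offset; post-stimulus components decide the remaining
    subgroups.  Weak activity (>=100 ms but never >=250 ms beyond threshold)
    is labelled group 9.
    """
    check_uniform_grid(trace.time_s)
    flags: List[str] = []
    mu, half, eps_used = _threshold(trace, params.detect_sd, params)
    if eps_used:
        flags.append("eps_threshold")
    comps = _components(trace, half, mu, params.min_component_s)
    off = trace.protocol.offset_s

    if not comps:
        events = _components(trace, half, mu, params.min_event_s)
        group = 9 if events else UNRESPONSIVE
        return ResponseClassification(
            group_id=group, polarity="none",
            has_inhibitory_component=group in INHIBITORY_COMPONENT_GROUPS,
            flags=tuple(flags))

    primary = comps[0]
    hold = window_slice(trace.time_s, off, off + params.prolonged_hold_s)
    s = primary.sign
    beyond = s * (trace.values[hold] - mu) > half
    prolonged = bool(beyond.all())
    if s > 0:
        if primary.t_end < params.short_max_s:
            inh_after = any(c.sign < 0 and c.t_start >= primary.t_end - trace.dt
                            for c in comps)
            group = 8 if inh_after else 7
        elif prolonged:
            group = 6
        elif any(c.sign < 0 and c.t_start >= off for c in comps):
            group = 5
        else:
            group = 4
    else:
        # a brief excitatory event truncated by the incoming inhibition
        # (too short to be a full component) marks the excitation-then-
        # inhibited class
        events = _components(trace, half, mu, params.min_event_s)
        exc_before = any(e.sign > 0 and e.t_start < primary.t_start
                         and e.t_start < off for e in events)
        if exc_before:
            group = 8
            s = 1
        elif prolonged:
            group = 2
        elif any(c.sign > 0 and c.t_start >= off for c in comps):
            group = 3
        else:
            group = 1

    direction = "onset_excitatory" if s > 0 else "onset_inhibitory"
    onset = response_latency(trace, direction, params)
    term = LatencyResult(np.nan, ("not_applicable",))
    if group in SHORT_GROUPS:
        term = response_latency(trace, "termination_short", params)
    for extra in onset.flags + term.flags:
        if extra not in flags and extra != "not_applicable":
            flags.append(extra)
    return ResponseClassification(
        group_id=group, polarity=polarity_of_group(group),
        has_inhibitory_component=group in INHIBITORY_COMPONENT_GROUPS,
        onset_latency_ms=onset.latency_ms, termination_latency_ms=term.latency_ms,
        flags=tuple(flags))


# ---------------------------------------------------------------------------
# latency
# ---------------------------------------------------------------------------

@dataclass
class LatencyResult:
    latency_ms: float
    flags: Tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return np.isfinite(self.latency_ms)


def response_latency(trace: GlomerularTrace, direction: str,
                     params: ClassifierParams = ClassifierParams()
                     ) -> LatencyResult:
    """Latency at the 1-SD threshold, in ms relative to stimulus onset.

    Onset latency is the first post-onset timepoint beyond mean_pre +/- 1 SD
    (sustained for ``sustain_s`` to be robust to sample noise); termination
    of short excitation is the first timepoint after the excitatory peak
    where the trace re-enters the +/-1 SD band.
    """
    t = trace.time_s
    dt = trace.dt
    flags: List[str] = []
    mu, half, eps_used = _threshold(trace, params.latency_sd, params)
    if eps_used:
        flags.append("eps_threshold")
    sustain = max(1, int(round(params.sustain_s / dt)))
    post = t >= -1e-9

    if direction in ("onset_excitatory", "onset_inhibitory"):
        sign = 1 if direction == "onset_excitatory" else -1
        mask = post & (sign * (trace.values - mu) > half)
        for i0, i1 in _runs(mask):
            if i1 - i0 >= sustain:
                return LatencyResult(float(t[i0] * 1000.0), tuple(flags))
        flags.append("not_crossed")
        return LatencyResult(np.nan, tuple(flags))

    if direction == "termination_short":
        on = post & (t < trace.protocol.offset_s)
        if not on.any():
            raise ValueError("trace does not cover the stimulation window")
        peak = int(np.flatnonzero(on)[np.argmax(trace.values[on])])
        # excitation has terminated once the trace is no longer above the
        # upper band — it may re-enter the band (group 7) or cross straight
        # through into inhibition (group 8)
        inside = trace.values - mu <= half
        inside[: peak + 1] = False
        for i0, i1 in _runs(inside):
            if i1 - i0 >= sustain:
                return LatencyResult(float(t[i0] * 1000.0), tuple(flags))
        flags.append("not_crossed")
        return LatencyResult(np.nan, tuple(flags))

    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

LATENCY_CATEGORIES = {
    "excitatory_onset": (sorted(EXCITATORY_GROUPS), "onset_latency_ms"),
    "inhibitory_onset": (sorted(INHIBITORY_GROUPS), "onset_latency_ms"),
    "short_termination": (sorted(SHORT_GROUPS), "termination_latency_ms"),
}


@dataclass
class LatencySummary:
    table: pd.DataFrame                 # per category: mean, sd, n
    kruskal: Optional[Tuple[float, float]]  # (H, p) across categories
    pairwise: Optional[pd.DataFrame]    # Tukey-Kramer-style pairwise p-values


def latency_summary(classifications: Sequence[ResponseClassification]
                    ) -> LatencySummary:
    """Per-direction latency statistics with a Kruskal-Wallis omnibus test
    and Tukey-Kramer-corrected pairwise comparisons (scipy ``tukey_hsd``)."""
    samples: Dict[str, np.ndarray] = {}
    rows = []
    for name, (groups, attr) in LATENCY_CATEGORIES.items():
        vals = np.array([getattr(c, attr) for c in classifications
                         if c.group_id in groups and np.isfinite(getattr(c, attr))])
        samples[name] = vals
        rows.append({"category": name,
                     "mean_ms": float(vals.mean()) if len(vals) else np.nan,
                     "sd_ms": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                     "n": len(vals)})
    table = pd.DataFrame(rows)
    present = {k: v for k, v in samples.items() if len(v) > 1}
    if len(present) < 2:
        return LatencySummary(table=table, kruskal=None, pairwise=None)
    names = list(present)
    h, p = sps.kruskal(*present.values())
    hsd = sps.tukey_hsd(*present.values())
    pair_rows = [
        {"a": names[i], "b": names[j], "p": float(hsd.pvalue[i, j])}
        for i in range(len(names)) for j in range(i + 1, len(names))
    ]
    return LatencySummary(table=table, kruskal=(float(h), float(p)),
                          pairwise=pd.DataFrame(pair_rows))


def classify_map(response_map: OdorResponseMap,
                 params: ClassifierParams = ClassifierParams()) -> pd.DataFrame:
    """Classification table, one row per glomerulus of a trial-averaged map."""
    rows = []
    for i in range(response_map.n_glomeruli):
        c = classify_profile(response_map.row(i), params)
        rows.append({
            "bee": response_map.bee, "odorant": response_map.odorant,
            "glomerulus": i, "group": c.group_id, "polarity": c.polarity,
            "has_inhibitory_component": c.has_inhibitory_component,
            "onset_latency_ms": c.onset_latency_ms,
            "termination_latency_ms": c.termination_latency_ms,
            "true_group": (None if response_map.groups is None
                           else int(response_map.groups[i])),
            "flags": ";".join(c.flags),
        })
    return pd.DataFrame(rows)
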