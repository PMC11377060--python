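"""Synthetic glomerular calcium datasets.

The generator emulates the statistical structure of fast calcium-imaging
recordings from the honey bee antennal lobe: ~25 glomeruli per animal, three
odorants, 20 trials on a 5 s ON / 25 s OFF schedule at ~127 Hz, and a
taxonomy of nine recurrent response-profile classes plus flat unresponsive
traces.  Profile shapes are parametric (difference-of-exponential kinetics
gated by onset/offset events); latencies follow the distributions measured
for excitatory onsets (313 +/- 22 ms), inhibitory onsets (351 +/- 47 ms) and
short-excitation terminations (346 +/- 47 ms).

Response groups
---------------
1  inhibition for the whole stimulation, terminating after offset
2  prolonged inhibition outlasting the stimulus
3  inhibition followed by post-stimulus excitation
4  excitation for the whole stimulation
5  excitation followed by post-stimulus inhibition
6  prolonged excitation outlasting the stimulus
7  short phasic excitation with prompt termination
8  short phasic excitation followed by inhibition
9  weak, unclassifiable activity (sub-threshold blips)
0  unresponsive (flat)
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .protocol import StimulusProtocol, window_slice
from .types import (
    ALL_GROUPS,
    EXCITATORY_GROUPS,
    INHIBITORY_GROUPS,
    SHORT_GROUPS,
    UNRESPONSIVE,
    GlomerularTrace,
    OdorResponseMap,
    polarity_of_group,
)

#: fixed composition of a "balanced" artificial odorant: per-group profile
#: counts for groups 1..9 plus unresponsive rows (32 profiles in total)
BALANCED_COMPOSITION: Dict[int, int] = {
    1: 5, 2: 3, 3: 3, 4: 7, 5: 1, 6: 2, 7: 2, 8: 1, 9: 4, UNRESPONSIVE: 4,
}

#: order in which groups are laid out inside assembled maps (keeps row
#: identity aligned across maps that share a composition, which is what makes
#: across-map response-vector correlations meaningful)
GROUP_ORDER: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, UNRESPONSIVE)


def default_group_proportions() -> np.ndarray:
    """Population frequencies of the ten labels, ordered as GROUP_ORDER.

    48% of recorded traces are excitatory, 37% inhibitory and 15%
    non-responsive; the excitatory/inhibitory mass is split across subgroups
    in the ratios of the balanced-odorant composition, and the non-responsive
    mass evenly between weak-irregular (group 9) and flat traces.
    """
    inh = 0.37 * np.array([5, 3, 3]) / 11.0
    exc = 0.48 * np.array([7, 1, 2, 2, 1]) / 13.0
    p = np.concatenate([inh, exc, [0.075, 0.075]])
    return p / p.sum()


@dataclass
class ResponseTemplate:
    """Parametric description of one glomerulus's noiseless response."""

    group_id: int
    amplitude: float = 0.2           # signed, -dF/F units; sign must match polarity
    onset_latency_ms: float = 313.0
    termination_latency_ms: Optional[float] = None  # groups 7/8, from stim onset
    post_latency_ms: float = 350.0   # post-component onset after stimulus offset
    post_duration_s: float = 2.0
    post_amplitude_scale: float = 0.7
    prolong_s: float = 2.5           # drive extension past offset for groups 2/6
    rise_tau_s: float = 0.03
    decay_tau_s: float = 0.3
    term_fall_s: float = 0.25        # calcium decay after short-excitation drive ends
    inhibition_rise_tau_s: float = 0.30  # slow build-up of group-8 inhibition
    adapt_tau_s: float = 1.2         # within-stimulus phasic-tonic time constant
    tonic_fraction: float = 0.55     # steady-state level relative to the peak

    def __post_init__(self) -> None:
        g = self.group_id
        if g not in ALL_GROUPS:
            raise ValueError(f"unknown group id {g}")
        pol = polarity_of_group(g)
        if g == UNRESPONSIVE:
            if self.amplitude != 0:
                raise ValueError("unresponsive templates must have amplitude 0")
        elif self.amplitude == 0:
            raise ValueError(f"group {g} template requires nonzero amplitude")
        elif pol == "inhibitory" and self.amplitude > 0:
            raise ValueError(f"group {g} is inhibitory: amplitude must be negative")
        elif pol == "excitatory" and self.amplitude < 0:
            raise ValueError(f"group {g} is excitatory: amplitude must be positive")
        if self.onset_latency_ms < 0:
            raise ValueError("onset_latency_ms must be non-negative")
        if g in SHORT_GROUPS:
            if self.termination_latency_ms is None:
                raise ValueError(f"group {g} requires termination_latency_ms")
            if self.termination_latency_ms <= self.onset_latency_ms:
                raise ValueError("termination must follow onset")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("kinetic time constants must be positive")

    @property
    def polarity(self) -> str:
        return polarity_of_group(self.group_id)


@dataclass
class GeneratorConfig:
    group_proportions: np.ndarray = field(default_factory=default_group_proportions)
    excitatory_onset_ms: Tuple[float, float] = (313.0, 22.0)
    inhibitory_onset_ms: Tuple[float, float] = (351.0, 47.0)
    short_termination_ms: Tuple[float, float] = (346.0, 47.0)
    amplitude_mean: float = 0.2
    amplitude_sd: float = 0.05
    amplitude_min: float = 0.10
    group9_amplitude: float = 0.06
    noise_sd: float = 0.05           # white sample noise, -dF/F units
    drift_sd: float = 0.01           # slow OU baseline drift amplitude
    drift_tau_s: float = 1.0
    latency_jitter: bool = True      # per-trial onset jitter, sd = group latency sd
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.group_proportions, dtype=float)
        if p.shape != (10,):
            raise ValueError("group_proportions must have 10 entries "
                             "(groups 1..9 then unresponsive)")
        if np.any(p < 0):
            raise ValueError("group_proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1 within 1e-9")
        for name in ("excitatory_onset_ms", "inhibitory_onset_ms",
                     "short_termination_ms"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise levels must be >= 0")
        self.group_proportions = p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_proportions"] = list(map(float, self.group_proportions))
        return d


# ---------------------------------------------------------------------------
# profile synthesis
# ---------------------------------------------------------------------------

def _component(time_s: np.ndarray, amp: float, t_start: float, t_end: float,
               rise_tau: float, decay_tau: float, fall: str = "exp") -> np.ndarray:
    """One gated transient: saturating rise on [t_start, t_end), then decay.

    The rise is shifted by one sample so the first grid point at/after
    t_start is already nonzero (deviation begins exactly at the gate).
    ``fall="linear"`` ramps to zero across the last ``decay_tau`` seconds of
    the gate and is used for sharply terminating short excitation.
    """
    x = np.zeros_like(time_s)
    dt = time_s[1] - time_s[0]
    tol = 1e-9
    if fall == "exp":
        on = (time_s >= t_start - tol) & (time_s < t_end - tol)
        x[on] = amp * (1.0 - np.exp(-(time_s[on] - t_start + dt) / rise_tau))
        level = amp * (1.0 - np.exp(-(max(t_end - t_start, dt)) / rise_tau))
        after = time_s >= t_end - tol
        x[after] = level * np.exp(-(time_s[after] - t_end) / decay_tau)
    elif fall == "linear":
        t_fall = max(t_end - decay_tau, t_start)
        on = (time_s >= t_start - tol) & (time_s < t_fall - tol)
        x[on] = amp * (1.0 - np.exp(-(time_s[on] - t_start + dt) / rise_tau))
        level = amp * (1.0 - np.exp(-(max(t_fall - t_start, dt)) / rise_tau))
        ramp = (time_s >= t_fall - tol) & (time_s < t_end - tol)
        x[ramp] = level * (t_end - time_s[ramp]) / max(t_end - t_fall, dt)
    else:  # pragma: no cover - internal misuse
        raise ValueError(f"unknown fall mode {fall!r}")
    return x


def make_profile(template: ResponseTemplate, protocol: StimulusProtocol,
                 seed: Optional[int] = None) -> GlomerularTrace:
    """Noiseless -dF/F trace for one template.

    The trace is exactly zero throughout the pre-stimulus window and deviates
    from zero no earlier than stimulus onset + onset latency.  ``seed`` is
    accepted for interface symmetry; profile synthesis is deterministic.
    """
    t = protocol.times()
    g = template.group_id
    A = abs(template.amplitude)
    on = template.onset_latency_ms / 1000.0
    off = protocol.stim_duration_s
    x = np.zeros_like(t)

    def exc(a, t0, t1, fall="exp", decay=None):
        return _component(t, a, t0, t1, template.rise_tau_s,
                          template.decay_tau_s if decay is None else decay, fall)

    def fading(comp):
        """Phasic-tonic adaptation: the response peaks early and relaxes
        toward a tonic plateau while the stimulus lasts."""
        m = np.ones_like(t)
        late = t >= on
        m[late] = template.tonic_fraction + (1 - template.tonic_fraction) * \
            np.exp(-(t[late] - on) / template.adapt_tau_s)
        return comp * m

    def deepening(comp):
        """Inhibition builds up gradually toward its full depth."""
        m = np.ones_like(t)
        late = t >= on
        m[late] = 1 - (1 - template.tonic_fraction) * \
            np.exp(-(t[late] - on) / template.adapt_tau_s)
        return comp * m

    post_on = off + template.post_latency_ms / 1000.0
    post_off = post_on + template.post_duration_s
    post_amp = A * template.post_amplitude_scale
    if g == UNRESPONSIVE:
        pass
    elif g == 1:
        x -= deepening(exc(A, on, off))
    elif g == 2:
        x -= deepening(exc(A, on, off + template.prolong_s))
    elif g == 3:
        x -= deepening(exc(A, on, off))
        x += exc(post_amp, post_on, post_off)
    elif g == 4:
        x += fading(exc(A, on, off))
    elif g == 5:
        x += fading(exc(A, on, off))
        x -= exc(post_amp, post_on, post_off)
    elif g == 6:
        x += fading(exc(A, on, off + template.prolong_s))
    elif g in SHORT_GROUPS:
        # the drive ends at the configured termination; the measured calcium
        # signal then decays with term_fall_s
        term = template.termination_latency_ms / 1000.0
        x += exc(A, on, term, decay=template.term_fall_s)
        if g == 8:
            # lateral inhibition builds up with calcium-like slow kinetics
            x -= _component(t, A * 0.8, term, off,
                            template.inhibition_rise_tau_s,
                            template.decay_tau_s)
    elif g == 9:
        # brief alternating blips too short to count as proper components
        for sign, t0 in ((1.0, on + 0.5), (-1.0, on + 2.2)):
            x += sign * _component(t, A, t0, t0 + 0.10, template.rise_tau_s,
                                   0.04, fall="linear")
    return GlomerularTrace(values=x, time_s=t, protocol=protocol,
                           trial="mean", group=g)


# ---------------------------------------------------------------------------
# template and noise draws
# ---------------------------------------------------------------------------

def draw_template(group_id: int, config: GeneratorConfig,
                  rng: np.random.Generator) -> ResponseTemplate:
    """Draw a random template for one group under the configured statistics."""
    if group_id == UNRESPONSIVE:
        return ResponseTemplate(group_id=group_id, amplitude=0.0)
    if group_id in INHIBITORY_GROUPS:
        mu, sd = config.inhibitory_onset_ms
    else:
        mu, sd = config.excitatory_onset_ms
    onset = max(0.0, rng.normal(mu, sd))
    if group_id == 9:
        amp = config.group9_amplitude
    else:
        amp = float(np.clip(rng.normal(config.amplitude_mean, config.amplitude_sd),
                            config.amplitude_min, 2 * config.amplitude_mean))
    if polarity_of_group(group_id) == "inhibitory":
        amp = -amp
    term = None
    if group_id in SHORT_GROUPS:
        tmu, tsd = config.short_termination_ms
        term = max(onset + 30.0, rng.normal(tmu, tsd))
    # heterogeneous within-stimulus dynamics across glomeruli: adaptation
    # speed and tonic level vary, so the population vector rotates during
    # the stimulation instead of merely scaling
    return ResponseTemplate(group_id=group_id, amplitude=amp,
                            onset_latency_ms=onset, termination_latency_ms=term,
                            adapt_tau_s=float(rng.uniform(0.6, 2.5)),
                            tonic_fraction=float(rng.uniform(0.3, 0.8)))


def _ou_drift(n: int, dt: float, sd: float, tau: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path emulating slow baseline drift."""
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    innov = rng.normal(0.0, sd * np.sqrt(1 - a * a), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    x, _ = lfilter([1.0], [1.0, -a], innov, zi=np.zeros(1))
    return x


def _jittered(template: ResponseTemplate, config: GeneratorConfig,
              rng: np.random.Generator) -> ResponseTemplate:
    """Per-trial copy of a template with onset/termination jitter."""
    if not config.latency_jitter or template.group_id == UNRESPONSIVE:
        return template
    if template.group_id in INHIBITORY_GROUPS:
        sd = config.inhibitory_onset_ms[1]
    else:
        sd = config.excitatory_onset_ms[1]
    onset = max(0.0, template.onset_latency_ms + rng.normal(0.0, sd))
    term = template.termination_latency_ms
    if term is not None:
        term = max(onset + 30.0,
                   term + rng.normal(0.0, config.short_termination_ms[1]))
    return ResponseTemplate(
        group_id=template.group_id, amplitude=template.amplitude,
        onset_latency_ms=onset, termination_latency_ms=term,
        post_latency_ms=template.post_latency_ms,
        post_duration_s=template.post_duration_s,
        post_amplitude_scale=template.post_amplitude_scale,
        prolong_s=template.prolong_s, rise_tau_s=template.rise_tau_s,
        decay_tau_s=template.decay_tau_s, term_fall_s=template.term_fall_s)


def _add_noise(mean_values: np.ndarray, protocol: StimulusProtocol,
               config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Trial realisation: mean + OU drift + white noise, re-baselined.

    The baseline second before onset is subtracted, mirroring the dF/F
    normalisation applied to real recordings.
    """
    n = mean_values.shape[-1]
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
    drift = _ou_drift(n, protocol.dt, config.drift_sd, config.drift_tau_s, rng)
    x = mean_values + noise + drift
    base = window_slice(protocol.times(), -1.0, 0.0)
    return x - x[base].mean()


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """One synthetic animal: odorants x glomeruli x trials x time."""

    traces: np.ndarray        # (n_odorants, n_glomeruli, n_trials, T)
    mean: np.ndarray          # (n_odorants, n_glomeruli, T) noiseless profiles
    groups: np.ndarray        # (n_odorants, n_glomeruli) ground-truth labels
    onset_ms: np.ndarray      # configured onset latencies (NaN if none)
    termination_ms: np.ndarray
    protocol: StimulusProtocol
    config: GeneratorConfig
    bee: str = "bee00"

    @property
    def n_odorants(self) -> int:
        return self.traces.shape[0]

    @property
    def odorant_names(self) -> List[str]:
        return [f"od{i:02d}" for i in range(self.n_odorants)]

    def map_mean(self, odorant: int) -> OdorResponseMap:
        return OdorResponseMap(
            values=self.mean[odorant], time_s=self.protocol.times(),
            protocol=self.protocol, odorant=self.odorant_names[odorant],
            bee=self.bee, trial="mean", groups=self.groups[odorant])

    def map_trial(self, odorant: int, trial: int) -> OdorResponseMap:
        return OdorResponseMap(
            values=np.asarray(self.traces[odorant, :, trial], dtype=float),
            time_s=self.protocol.times(), protocol=self.protocol,
            odorant=self.odorant_names[odorant], bee=self.bee, trial=trial,
            groups=self.groups[odorant])

    def trial_maps(self, odorant: int,
                   trials: Optional[Sequence[int]] = None) -> List[OdorResponseMap]:
        idx = range(self.traces.shape[2]) if trials is None else trials
        return [self.map_trial(odorant, j) for j in idx]

    def trial_average_map(self, odorant: int,
                          trials: Optional[Sequence[int]] = None) -> OdorResponseMap:
        idx = list(range(self.traces.shape[2])) if trials is None else list(trials)
        vals = np.asarray(self.traces[odorant][:, idx], dtype=float).mean(axis=1)
        return OdorResponseMap(
            values=vals, time_s=self.protocol.times(), protocol=self.protocol,
            odorant=self.odorant_names[odorant], bee=self.bee, trial="mean",
            groups=self.groups[odorant])


def make_dataset(config: GeneratorConfig, protocol: StimulusProtocol,
                 n_glomeruli: int = 25, n_odorants: int = 3,
                 bee: str = "bee00") -> SyntheticDataset:
    """Generate one animal's dataset with ground-truth labels and latencies."""
    if n_glomeruli < 1 or n_odorants < 1:
        raise ValueError("n_glomeruli and n_odorants must be >= 1")
    rng = np.random.default_rng(config.seed)
    T = protocol.n_samples
    n_tr = protocol.n_trials
    traces = np.empty((n_odorants, n_glomeruli, n_tr, T), dtype=np.float32)
    mean = np.empty((n_odorants, n_glomeruli, T))
    groups = np.empty((n_odorants, n_glomeruli), dtype=int)
    onset = np.full((n_odorants, n_glomeruli), np.nan)
    term = np.full((n_odorants, n_glomeruli), np.nan)
    labels = list(GROUP_ORDER)
    for o in range(n_odorants):
        drawn = rng.choice(labels, size=n_glomeruli, p=config.group_proportions)
        for g_i, grp in enumerate(drawn):
            tpl = draw_template(int(grp), config, rng)
            groups[o, g_i] = tpl.group_id
            if tpl.group_id != UNRESPONSIVE:
                onset[o, g_i] = tpl.onset_latency_ms
            if tpl.termination_latency_ms is not None:
                term[o, g_i] = tpl.termination_latency_ms
            mean[o, g_i] = make_profile(tpl, protocol).values
            for j in range(n_tr):
                jt = _jittered(tpl, config, rng)
                base = (mean[o, g_i] if jt is tpl
                        else make_profile(jt, protocol).values)
                traces[o, g_i, j] = _add_noise(base, protocol, config, rng)
    return SyntheticDataset(traces=traces, mean=mean, groups=groups,
                            onset_ms=onset, termination_ms=term,
                            protocol=protocol, config=config, bee=bee)


def make_experiment(config: GeneratorConfig, protocol: StimulusProtocol,
                    n_bees: int = 8, n_glomeruli: int = 25,
                    n_odorants: int = 3) -> List[SyntheticDataset]:
    """Multi-animal battery; per-bee seeds derive from the master seed."""
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=n_bees)
    out = []
    for b, s in enumerate(seeds):
        cfg = GeneratorConfig(**{**config.to_dict(), "seed": int(s)})
        cfg.group_proportions = config.group_proportions
        out.append(make_dataset(cfg, protocol, n_glomeruli, n_odorants,
                                bee=f"bee{b:02d}"))
    return out


# ---------------------------------------------------------------------------
# profile database and artificial odorants
# ---------------------------------------------------------------------------

@dataclass
class ProfileDatabase:
    """Pool of labelled noiseless glomerular profiles to subsample from."""

    values: np.ndarray    # (n_profiles, T)
    groups: np.ndarray    # (n_profiles,)
    protocol: StimulusProtocol

    def pool(self, group_id: int) -> np.ndarray:
        return np.flatnonzero(self.groups == group_id)

    def proportions(self) -> np.ndarray:
        counts = np.array([(self.groups == g).sum() for g in GROUP_ORDER], float)
        return counts / counts.sum()


def make_profile_database(config: GeneratorConfig, protocol: StimulusProtocol,
                          n_per_group: int = 30,
                          seed: Optional[int] = None) -> ProfileDatabase:
    """Draw ``n_per_group`` random templates per label and synthesise them."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    vals, grps = [], []
    for g in GROUP_ORDER:
        for _ in range(n_per_group):
            tpl = draw_template(g, config, rng)
            vals.append(make_profile(tpl, protocol).values)
            grps.append(g)
    return ProfileDatabase(values=np.stack(vals), groups=np.array(grps),
                           protocol=protocol)


def _counts_from_proportions(proportions: np.ndarray, n_profiles: int) -> Dict[int, int]:
    """Largest-remainder apportionment of n_profiles across the ten labels."""
    p = np.asarray(proportions, dtype=float)
    if p.shape != (10,) or np.any(p < 0):
        raise ValueError("proportions must be a non-negative 10-vector")
    p = p / p.sum()
    raw = p * n_profiles
    base = np.floor(raw).astype(int)
    rem = n_profiles - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return {g: int(c) for g, c in zip(GROUP_ORDER, base)}


def _assemble_with_counts(db: ProfileDatabase, counts: Dict[int, int],
                          n_odorants: int, rng: np.random.Generator,
                          name_prefix: str = "odor") -> List[OdorResponseMap]:
    maps = []
    for g, c in counts.items():
        if c > 0 and len(db.pool(g)) == 0:
            raise ValueError(f"profile database has no profiles for group {g} "
                             f"(requested {c})")
    for m in range(n_odorants):
        rows, row_groups = [], []
        for g in GROUP_ORDER:
            c = counts.get(g, 0)
            if c == 0:
                continue
            pool = db.pool(g)
            replace = len(pool) < c  # without replacement within a map if possible
            sel = rng.choice(pool, size=c, replace=replace)
            rows.append(db.values[sel])
            row_groups.extend([g] * c)
        maps.append(OdorResponseMap(
            values=np.concatenate(rows, axis=0), time_s=db.protocol.times(),
            protocol=db.protocol, odorant=f"{name_prefix}{m:03d}",
            groups=np.array(row_groups)))
    return maps


def assemble_artificial_odorants(db: ProfileDatabase, n_odorants: int,
                                 n_profiles: int,
                                 proportions: Optional[np.ndarray] = None,
                                 seed: int = 0) -> List[OdorResponseMap]:
    """Subsample the profile database into artificial odorant response maps.

    Each map holds exactly ``n_profiles`` rows with a fixed per-group
    composition implied by ``proportions`` (database proportions by default),
    rows ordered by group so that maps sharing a composition are row-aligned.
    """
    if n_profiles < 1 or n_odorants < 1:
        raise ValueError("n_odorants and n_profiles must be >= 1")
    if proportions is None:
        proportions = db.proportions()
    counts = _counts_from_proportions(proportions, n_profiles)
    rng = np.random.default_rng(seed)
    return _assemble_with_counts(db, counts, n_odorants, rng)


def make_balanced_odorants(db: ProfileDatabase, n_odorants: int = 16,
                           seed: int = 0) -> List[OdorResponseMap]:
    """Artificial odorants with the fixed 32-profile balanced composition."""
    rng = np.random.default_rng(seed)
    return _assemble_with_counts(db, BALANCED_COMPOSITION, n_odorants, rng,
                                 name_prefix="balanced")


def ablate_groups(response_map: OdorResponseMap,
                  groups_to_remove: Sequence[int]) -> OdorResponseMap:
    """Replace the rows of the named groups with flat zero traces.

    Map dimensions and row indexing are preserved so downstream PN wiring is
    unaffected; only the signal content of the removed groups disappears.
    """
    if response_map.groups is None:
        raise ValueError("map rows carry no group labels")
    remove = set(int(g) for g in groups_to_remove)
    unknown = remove - ALL_GROUPS
    if unknown:
        raise ValueError(f"unknown group id(s): {sorted(unknown)}")
    out = response_map.copy()
    mask = np.isin(out.groups, sorted(remove))
    out.values[mask] = 0.0
    return out


def make_noisy_trials(response_map: OdorResponseMap, n_trials: int,
                      config: GeneratorConfig, seed: int = 0) -> List[OdorResponseMap]:
    """Trial realisations of an assembled map (noise + small onset jitter).

    Jitter is applied as an integer-sample shift with edge padding (profiles
    here are stored arrays, not templates), white noise and OU drift as in
    :func:`make_dataset`.
    """
    rng = np.random.default_rng(seed)
    protocol = response_map.protocol
    dt = protocol.dt
    out = []
    for j in range(n_trials):
        vals = np.empty_like(response_map.values)
        for i in range(response_map.n_glomeruli):
            row = response_map.values[i]
            if config.latency_jitter and response_map.groups is not None \
                    and response_map.groups[i] != UNRESPONSIVE:
                g = int(response_map.groups[i])
                sd = (config.inhibitory_onset_ms[1] if g in INHIBITORY_GROUPS
                      else config.excitatory_onset_ms[1])
                shift = int(round(rng.normal(0.0, sd) / 1000.0 / dt))
                row = shift_trace(row, shift)
            vals[i] = _add_noise(row, protocol, config, rng)
        out.append(OdorResponseMap(
            values=vals, time_s=response_map.time_s, protocol=protocol,
            odorant=response_map.odorant, bee=response_map.bee, trial=j,
            groups=None if response_map.groups is None
            else response_map.groups.copy()))
    return out


def shift_trace(values: np.ndarray, shift: int) -> np.ndarray:
    """Shift a trace by ``shift`` samples, padding with the edge value."""
    if shift == 0:
        return values.copy()
    out = np.empty_like(values)
    if shift > 0:
        out[shift:] = values[:-shift]
        out[:shift] = values[0]
    else:
        out[:shift] = values[-shift:]
        out[shift:] = values[-1]
    return out
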