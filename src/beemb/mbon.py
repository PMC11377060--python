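"""KC-to-MBON plasticity and conditioning-protocol battery.

A single appetitive mushroom-body output neuron (MBON) receives binary
synapses from all KCs, initialised to 1 (broad tuning: it responds to any
stimulus).  Learning is a synaptic-plasticity-threshold (spt) rule: during
a 3 s learning window (the US/reward analogue), any KC that fires at least
``spt`` times has its output synapse switched from 1 to 0.  With the 50 ms
model step, spt = 15 requires at least 750 ms of cumulative activation
inside the window.

Four conditioning protocols differ only in the inter-stimulus interval
(ISI), the delay from CS onset to US onset, for a 5 s CS and 3 s US:
backward (-2 s), early (+1 s), delay (+4 s) and trace (+7 s).

The MBON readout is an AP-probability time course: at each timestep, the
fraction of currently firing KCs whose synapse is still intact, averaged
over replicate networks and test trials.  It is 1 everywhere for an
untrained MBON and drops where the active population overlaps the depressed
one; 1 minus its mean over the CS window is the learned-response score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mb import (
    MB_DT,
    KCSpikeRaster,
    MBConfig,
    MBNetwork,
    PNInput,
    build_network,
    expand_and_resample,
    kc_rasters,
    replicate_seeds,
)
from .stats import kruskal_test, wilcoxon_signed_rank
from .synthetic import (
    GeneratorConfig,
    ProfileDatabase,
    SyntheticDataset,
    ablate_groups,
    make_balanced_odorants,
    make_noisy_trials,
)
from .types import OdorResponseMap

CS_WINDOW_S = (0.0, 5.0)


@dataclass(frozen=True)
class ConditioningProtocol:
    name: str
    isi_s: float
    us_duration_s: float = 3.0

    @property
    def window(self) -> Tuple[float, float]:
        """Learning window [isi, isi + US duration) on the 20 Hz grid."""
        return (self.isi_s, self.isi_s + self.us_duration_s)


PROTOCOLS: Dict[str, ConditioningProtocol] = {
    "backward": ConditioningProtocol("backward", -2.0),
    "early": ConditioningProtocol("early", 1.0),
    "delay": ConditioningProtocol("delay", 4.0),
    "trace": ConditioningProtocol("trace", 7.0),
}


def min_active_time_ms(spt: int) -> float:
    """Minimum cumulative activation implied by an spt value at 50 ms steps."""
    return spt * MB_DT * 1000.0


@dataclass
class MBONModel:
    """Binary KC-to-MBON weight vector with a synaptic plasticity threshold."""

    weights: np.ndarray
    spt: int = 15

    @classmethod
    def untrained(cls, n_kc: int, spt: int = 15) -> "MBONModel":
        if spt < 1:
            raise ValueError("spt must be a positive integer")
        return cls(weights=np.ones(n_kc), spt=spt)


def train(mbon: MBONModel, raster: KCSpikeRaster,
          protocol: ConditioningProtocol) -> MBONModel:
    """Apply the spt rule over the protocol's learning window.

    KCs firing >= spt times inside the window lose their output synapse;
    no weight ever increases.  Raises if the raster does not cover the
    learning window.
    """
    lo, hi = protocol.window
    t = raster.time_s
    if t[0] > lo + 1e-9 or t[-1] + MB_DT < hi - 1e-9:
        raise ValueError(
            f"learning window [{lo}, {hi}) s outside raster coverage "
            f"[{t[0]:.2f}, {t[-1] + MB_DT:.2f}) s")
    mask = (t >= lo - 1e-9) & (t < hi - 1e-9)
    counts = raster.activity[:, mask].sum(axis=1)
    new_w = np.where(counts >= mbon.spt, 0.0, mbon.weights)
    return MBONModel(weights=new_w, spt=mbon.spt)


def ap_probability(mbon: MBONModel, raster: KCSpikeRaster) -> np.ndarray:
    """Per-timestep fraction of firing KCs with an intact MBON synapse.

    NaN where no KC fires (undefined, flagged by NaN).  Identically 1 for
    an untrained MBON.
    """
    act = raster.activity.astype(float)
    n_active = act.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (mbon.weights @ act) / n_active
    return np.where(n_active > 0, p, np.nan)


def learned_latency(ap_trace: np.ndarray, time_s: np.ndarray,
                    onset_s: float = 0.0) -> float:
    """Latency (ms after CS onset) to 90% of the maximal probability drop.

    With p_min the minimum AP probability after onset, the threshold is
    1 - 0.9*(1 - p_min); the latency is the first timepoint at or below it.
    NaN for a flat trace (nothing learned).
    """
    t = np.asarray(time_s)
    p = np.asarray(ap_trace, dtype=float)
    after = t >= onset_s - 1e-9
    p_after = p[after]
    if not np.isfinite(p_after).any():
        return np.nan
    p_min = np.nanmin(p_after)
    if p_min >= 1.0 - 1e-9:
        return np.nan
    thr = 1.0 - 0.9 * (1.0 - p_min)
    hit = np.flatnonzero(after & (p <= thr + 1e-12))
    return float((t[hit[0]] - onset_s) * 1000.0)


# ---------------------------------------------------------------------------
# protocol battery
# ---------------------------------------------------------------------------

@dataclass
class ConditioningInput:
    """One bee/odorant-role combination ready for training and testing.

    Training uses the mean response to the first CS stimulations; memory is
    tested against later, unseen repetitions of the CS and of a novel
    odorant (NOd).
    """

    train_cs: OdorResponseMap
    test_cs: List[OdorResponseMap]
    test_nod: List[OdorResponseMap]
    label: str = ""

    @property
    def n_glomeruli(self) -> int:
        return self.train_cs.n_glomeruli


def conditioning_inputs_from_dataset(ds: SyntheticDataset,
                                     odorants: Tuple[int, int] = (0, 1),
                                     n_train: int = 5, n_test: int = 5
                                     ) -> List[ConditioningInput]:
    """Both CS/NOd role assignments of an odorant pair from one animal."""
    out = []
    for cs, nod in (odorants, odorants[::-1]):
        out.append(ConditioningInput(
            train_cs=ds.trial_average_map(cs, range(n_train)),
            test_cs=ds.trial_maps(cs, range(n_train, n_train + n_test)),
            test_nod=ds.trial_maps(nod, range(n_train, n_train + n_test)),
            label=f"{ds.bee}:cs={ds.odorant_names[cs]}"))
    return out


def conditioning_inputs_from_maps(maps: Sequence[OdorResponseMap],
                                  gen_config: GeneratorConfig,
                                  n_train: int = 5, n_test: int = 5,
                                  seed: int = 0) -> List[ConditioningInput]:
    """Pair up assembled odorant maps (2j, 2j+1) in both CS/NOd roles.

    Trials are noisy realisations of each map; training uses the average of
    the first ``n_train`` trials, testing the next ``n_test``.
    """
    if len(maps) % 2:
        raise ValueError("need an even number of maps to form CS/NOd pairs")
    rng = np.random.default_rng(seed)
    trials = []
    for m in maps:
        tr = make_noisy_trials(m, n_train + n_test, gen_config,
                               seed=int(rng.integers(0, 2**31 - 1)))
        mean_train = m.copy()
        mean_train.values = np.mean([t.values for t in tr[:n_train]], axis=0)
        mean_train.trial = "mean"
        trials.append((mean_train, tr[n_train:]))
    out = []
    for j in range(0, len(maps), 2):
        for a, b in ((j, j + 1), (j + 1, j)):
            out.append(ConditioningInput(
                train_cs=trials[a][0], test_cs=trials[a][1],
                test_nod=trials[b][1],
                label=f"pair{j // 2}:cs={maps[a].odorant}"))
    return out


@dataclass
class ProtocolOutcome:
    protocol: str
    label: str
    ap_cs: np.ndarray
    ap_nod: np.ndarray
    time_s: np.ndarray
    response_score_cs: float
    response_score_nod: float
    latency_ms: float
    p_min: float
    t_min_s: float


@dataclass
class ProtocolBattery:
    outcomes: List[ProtocolOutcome]

    def records(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "protocol": o.protocol, "input": o.label,
            "score_cs": o.response_score_cs, "score_nod": o.response_score_nod,
            "latency_ms": o.latency_ms, "p_min": o.p_min, "t_min_s": o.t_min_s,
        } for o in self.outcomes])

    def scores(self, protocol: str) -> Tuple[np.ndarray, np.ndarray]:
        cs = [o.response_score_cs for o in self.outcomes if o.protocol == protocol]
        nod = [o.response_score_nod for o in self.outcomes if o.protocol == protocol]
        return np.asarray(cs), np.asarray(nod)

    def latencies(self, protocol: str) -> np.ndarray:
        return np.asarray([o.latency_ms for o in self.outcomes
                           if o.protocol == protocol])

    def kruskal_cs_vs_nod(self, protocol: str) -> Tuple[float, float]:
        cs, nod = self.scores(protocol)
        return kruskal_test(cs, nod)

    def mean_ap(self, protocol: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        sel = [o for o in self.outcomes if o.protocol == protocol]
        t = sel[0].time_s
        return (t, np.nanmean([o.ap_cs for o in sel], axis=0),
                np.nanmean([o.ap_nod for o in sel], axis=0))


def _score(ap: np.ndarray, time_s: np.ndarray) -> float:
    mask = (time_s >= CS_WINDOW_S[0] - 1e-9) & (time_s < CS_WINDOW_S[1] - 1e-9)
    return float(1.0 - np.nanmean(ap[mask]))


def evaluate_protocols(inputs: Sequence[ConditioningInput],
                       protocols: Optional[Sequence[ConditioningProtocol]] = None,
                       config: MBConfig = MBConfig(), spt: int = 15,
                       seed: int = 0, n_replicates: int = 1
                       ) -> ProtocolBattery:
    """Train and test an MBON per input and protocol.

    Each input gets its own replicate network(s); the same networks produce
    the training raster (mean of the early CS repetitions) and the test
    rasters (fresh later trials), and AP probability is averaged over
    networks and test trials.
    """
    if protocols is None:
        protocols = list(PROTOCOLS.values())
    outcomes: List[ProtocolOutcome] = []
    master = np.random.default_rng(seed)
    for inp in inputs:
        inp_seed = int(master.integers(0, 2**31 - 1))
        pn_all = [expand_and_resample(m, config)
                  for m in [inp.train_cs, *inp.test_cs, *inp.test_nod]]
        t20 = pn_all[0].time_s
        n_cs = len(inp.test_cs)
        acc: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = \
            {p.name: [] for p in protocols}
        for s in replicate_seeds(inp_seed, n_replicates):
            net = build_network(inp.n_glomeruli, config, int(s))
            rasters = kc_rasters(pn_all, net)
            train_raster, test_rasters = rasters[0], rasters[1:]
            for proto in protocols:
                mbon = train(MBONModel.untrained(config.n_kc, spt),
                             train_raster, proto)
                ap_cs = np.nanmean(
                    [ap_probability(mbon, r) for r in test_rasters[:n_cs]], axis=0)
                ap_nod = np.nanmean(
                    [ap_probability(mbon, r) for r in test_rasters[n_cs:]], axis=0)
                acc[proto.name].append((ap_cs, ap_nod))
        for proto in protocols:
            ap_cs = np.nanmean([a for a, _ in acc[proto.name]], axis=0)
            ap_nod = np.nanmean([b for _, b in acc[proto.name]], axis=0)
            after = t20 >= -1e-9
            p_min = float(np.nanmin(ap_cs[after]))
            t_min = float(t20[after][np.nanargmin(ap_cs[after])])
            outcomes.append(ProtocolOutcome(
                protocol=proto.name, label=inp.label, ap_cs=ap_cs,
                ap_nod=ap_nod, time_s=t20,
                response_score_cs=_score(ap_cs, t20),
                response_score_nod=_score(ap_nod, t20),
                latency_ms=learned_latency(ap_cs, t20), p_min=p_min,
                t_min_s=t_min))
    return ProtocolBattery(outcomes=outcomes)


# ---------------------------------------------------------------------------
# ablation experiment
# ---------------------------------------------------------------------------

ABLATION_VARIANTS: Dict[str, Tuple[int, ...]] = {
    "none": (),
    "no_stable_excitatory": (4, 5, 6),
    "no_inhibitory": (1, 2, 3),
    "no_short_excitatory": (7, 8),
    "no_inhibitory_no_short": (1, 2, 3, 7, 8),
}


@dataclass
class AblationResult:
    p_values: Dict[str, np.ndarray]        # variant -> Wilcoxon p per repeat
    latency_medians: pd.DataFrame          # per variant/protocol/repeat

    def fraction_significant(self, variant: str, alpha: float = 0.05) -> float:
        return float((self.p_values[variant] < alpha).mean())


def ablation_experiment(db: ProfileDatabase, gen_config: GeneratorConfig,
                        variants: Optional[Dict[str, Tuple[int, ...]]] = None,
                        n_repeats: int = 100, n_odorants: int = 16,
                        config: MBConfig = MBConfig(), spt: int = 15,
                        seed: int = 0, n_replicates: int = 1
                        ) -> AblationResult:
    """Group-removal experiment on balanced artificial odorants.

    Per repeat: assemble ``n_odorants`` balanced odorants, generate their
    trials, then for every removal variant zero out the targeted response
    groups, run early and delay conditioning, and test the paired
    early-vs-delay latency difference (Wilcoxon signed-rank).  Repeats with
    identical seeds reproduce identical p-value vectors.
    """
    if variants is None:
        variants = ABLATION_VARIANTS
    protos = [PROTOCOLS["early"], PROTOCOLS["delay"]]
    rng = np.random.default_rng(seed)
    p_values = {v: np.empty(n_repeats) for v in variants}
    rows = []
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        maps = make_balanced_odorants(db, n_odorants, seed=rep_seed)
        base_inputs = conditioning_inputs_from_maps(
            maps, gen_config, seed=rep_seed + 1)
        for vname, remove in variants.items():
            if remove:
                inputs = [ConditioningInput(
                    train_cs=ablate_groups(i.train_cs, remove),
                    test_cs=[ablate_groups(m, remove) for m in i.test_cs],
                    test_nod=[ablate_groups(m, remove) for m in i.test_nod],
                    label=i.label) for i in base_inputs]
            else:
                inputs = base_inputs
            battery = evaluate_protocols(inputs, protos, config, spt,
                                         seed=rep_seed + 2,
                                         n_replicates=n_replicates)
            lat_e = battery.latencies("early")
            lat_d = battery.latencies("delay")
            ok = np.isfinite(lat_e) & np.isfinite(lat_d)
            if ok.sum() >= 2:
                _, p = wilcoxon_signed_rank(lat_e[ok], lat_d[ok])
            else:
                p = np.nan
            p_values[vname][rep] = p
            rows.append({"variant": vname, "repeat": rep,
                         "median_latency_early_ms": float(np.nanmedian(lat_e)),
                         "median_latency_delay_ms": float(np.nanmedian(lat_d)),
                         "n_defined_pairs": int(ok.sum()), "wilcoxon_p": p})
    return AblationResult(p_values=p_values, latency_medians=pd.DataFrame(rows))
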