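"""Kenyon-cell population dynamics and coding-space geometry.

Quantifies what the mushroom-body transform does to the odour code:
turnover of the active KC set between adjacent 50 ms timesteps, cumulative
recruitment of distinct KCs from stimulus onset, correlation structure
across timepoints, PCA trajectories of odorant representations, and the
pattern-separation (decorrelation) experiment on batteries of artificially
assembled similar odorants.

Turnover is defined as the newly-recruited fraction of the currently active
set, |A(t+1) \\ A(t)| / |A(t+1)|: 0 for perfect stability, 1 for complete
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA

from .mb import MBConfig, PNInput, build_network, expand_and_resample, kc_rasters
from .pn import window_vector
from .stats import pairwise_pearson, student_t
from .synthetic import ProfileDatabase, assemble_artificial_odorants
from .types import OdorResponseMap

TURNOVER_WINDOWS = {
    "pre_stim": (None, 0.0),
    "on_0_5s": (0.0, 5.0),
    "off_5_10s": (5.0, 10.0),
    "off_10_15s": (10.0, 15.0),
}


@dataclass
class TurnoverSeries:
    values: np.ndarray   # one entry per adjacent timestep pair, NaN if undefined
    time_s: np.ndarray   # time of the later step of each pair

    def window_means(self) -> Dict[str, float]:
        out = {}
        for name, (lo, hi) in TURNOVER_WINDOWS.items():
            mask = self.time_s < hi if lo is None else \
                (self.time_s >= lo) & (self.time_s < hi)
            vals = self.values[mask]
            out[name] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        return out


def turnover_rate(activity: np.ndarray, time_s: np.ndarray) -> TurnoverSeries:
    """Fraction of newly recruited cells among those active at each step."""
    act = np.asarray(activity, dtype=bool)
    if act.shape[1] < 2:
        raise ValueError("need at least two timesteps")
    new = (act[:, 1:] & ~act[:, :-1]).sum(axis=0).astype(float)
    cur = act[:, 1:].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(cur > 0, new / cur, np.nan)
    return TurnoverSeries(values=vals, time_s=np.asarray(time_s)[1:])


def cumulative_recruitment(activity: np.ndarray, time_s: np.ndarray,
                           from_s: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Running count of distinct cells active since ``from_s`` (onset)."""
    act = np.asarray(activity, dtype=bool)
    t = np.asarray(time_s)
    i0 = int(np.searchsorted(t, from_s - 1e-9))
    if i0 >= act.shape[1]:
        raise ValueError("start time beyond the raster")
    seen = np.maximum.accumulate(act[:, i0:], axis=1)
    return seen.sum(axis=0), t[i0:]


def timepoint_correlation(population: np.ndarray) -> np.ndarray:
    """Pearson r between population vectors at all timepoint pairs.

    Zero-variance timepoints yield NaN rows/columns (undefined, flagged by
    NaN rather than silently zero).
    """
    pop = np.asarray(population, dtype=float)
    constant = pop.max(axis=0) == pop.min(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(pop, rowvar=False)
    c[constant, :] = np.nan
    c[:, constant] = np.nan
    return c


@dataclass
class TrajectoryPCA:
    coordinates: List[np.ndarray]       # per odorant, (T, n_components)
    explained_variance_ratio: np.ndarray
    time_s: np.ndarray

    def separation_score(self) -> float:
        """Between-odorant centroid spread over mean within-odorant spread."""
        cents = np.stack([c.mean(axis=0) for c in self.coordinates])
        between = np.linalg.norm(cents - cents.mean(axis=0), axis=1).mean()
        within = np.mean([np.linalg.norm(c - c.mean(axis=0), axis=1).mean()
                          for c in self.coordinates])
        return float(between / within) if within > 0 else np.inf


def odor_trajectories_pca(populations: Sequence[np.ndarray], time_s: np.ndarray,
                          n_components: int = 3) -> TrajectoryPCA:
    """PCA of odorant trajectories in a population space.

    ``populations`` holds one (cells x T) matrix per odorant on a common
    time grid; timepoints of all odorants are pooled, mean-centred and
    decomposed (covariance PCA, no scaling).
    """
    X = np.concatenate([np.asarray(p, float).T for p in populations], axis=0)
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    Z = pca.fit_transform(X)
    T = len(time_s)
    coords = [Z[i * T:(i + 1) * T] for i in range(len(populations))]
    return TrajectoryPCA(coordinates=coords,
                         explained_variance_ratio=pca.explained_variance_ratio_,
                         time_s=np.asarray(time_s))


# ---------------------------------------------------------------------------
# decorrelation experiment
# ---------------------------------------------------------------------------

@dataclass
class DecorrelationResult:
    r_pn: np.ndarray
    r_kc: np.ndarray
    t_stat: float
    p_value: float
    n_pairs: int
    n_excluded: int

    @property
    def pn_mean(self) -> float:
        return float(np.nanmean(self.r_pn))

    @property
    def pn_sd(self) -> float:
        return float(np.nanstd(self.r_pn, ddof=1))

    @property
    def kc_mean(self) -> float:
        return float(np.nanmean(self.r_kc))

    @property
    def kc_sd(self) -> float:
        return float(np.nanstd(self.r_kc, ddof=1))


def kc_response_vectors(maps: Sequence[OdorResponseMap],
                        config: MBConfig, seed: int, n_replicates: int,
                        window: Tuple[float, float] = (1.0, 4.0)
                        ) -> np.ndarray:
    """Replicate-mean KC firing probability per odorant over the ON window.

    All odorants pass through the same replicate networks (the comparison
    across odorants requires a common KC identity).
    Returns (n_odorants, n_kc).
    """
    n_glom = maps[0].n_glomeruli
    inputs = [expand_and_resample(m, config) for m in maps]
    t20 = inputs[0].time_s
    wmask = (t20 >= window[0] - 1e-9) & (t20 < window[1] - 1e-9)
    win_inputs = [PNInput(activity=p.activity[:, wmask], time_s=t20[wmask])
                  for p in inputs]
    from .mb import replicate_seeds
    acc = np.zeros((len(maps), config.n_kc))
    for s in replicate_seeds(seed, n_replicates):
        net = build_network(n_glom, config, int(s))
        for i, r in enumerate(kc_rasters(win_inputs, net)):
            acc[i] += r.activity.mean(axis=1)
    return acc / n_replicates


def decorrelation_experiment(db: ProfileDatabase, n_odorants: int = 100,
                             n_profiles: int = 30,
                             proportions: Optional[np.ndarray] = None,
                             config: MBConfig = MBConfig(), seed: int = 0,
                             n_replicates: int = 10,
                             window: Tuple[float, float] = (1.0, 4.0)
                             ) -> DecorrelationResult:
    """Pattern separation on a battery of similar artificial odorants.

    Builds ``n_odorants`` maps of ``n_profiles`` subsampled glomerular
    responses with a constant type composition, computes pairwise Pearson
    correlations of the ON-window response vectors in PN space and in the
    modelled KC space, and compares the two distributions with a Student's
    t test.  All unordered pairs are considered; undefined pairs are
    excluded and counted.
    """
    maps = assemble_artificial_odorants(db, n_odorants, n_profiles,
                                        proportions, seed=seed)
    anchor_window = ("onset", window[0], window[1])
    pn_vecs = np.stack([window_vector(m, anchor_window) for m in maps])
    r_pn = pairwise_pearson(pn_vecs)
    kc_vecs = kc_response_vectors(maps, config, seed=seed + 1,
                                  n_replicates=n_replicates, window=window)
    r_kc = pairwise_pearson(kc_vecs)
    ok = np.isfinite(r_pn) & np.isfinite(r_kc)
    t_stat, p = student_t(r_pn[ok], r_kc[ok])
    return DecorrelationResult(
        r_pn=r_pn[ok], r_kc=r_kc[ok], t_stat=t_stat, p_value=p,
        n_pairs=len(r_pn), n_excluded=int((~ok).sum()))
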