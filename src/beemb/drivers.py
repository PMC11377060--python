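"""End-to-end reproduction drivers.

Each driver runs one full analysis arm on synthetic data and returns the
tables the corresponding figure-level analysis rests on:

``run_profile_analysis``  response-profile classification, frequencies,
                          latency statistics and trial stability
``run_coding_analysis``   KC turnover, cumulative recruitment, timepoint
                          correlations, PCA separation and decorrelation
``run_learning_analysis`` conditioning-protocol battery (backward / early /
                          delay / trace) with scores and learned latencies
``run_ablation_analysis`` group-removal experiment with the p-value
                          distribution over repeats

``reproduce(figure_id, ...)`` dispatches by analysis name and writes the
tables as CSV/JSON into an output directory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import kc as kc_mod
from . import mbon as mbon_mod
from . import pn as pn_mod
from .io import RunConfig
from .mb import simulate
from .protocol import StimulusProtocol
from .synthetic import (
    GeneratorConfig,
    make_dataset,
    make_experiment,
    make_profile_database,
)
from .types import INHIBITORY_COMPONENT_GROUPS, UNRESPONSIVE

#: protocol with enough pre-stimulus coverage for the backward learning
#: window (US onset at -2 s) and a 15 s post-onset tail
CONDITIONING_PROTOCOL = StimulusProtocol(pre_window_s=2.0, record_window_s=19.0)


def run_profile_analysis(cfg: RunConfig, n_bees: int = 8) -> Dict[str, pd.DataFrame]:
    """Classify all synthetic glomerular responses and summarise them."""
    gen = _seeded(cfg.generator, cfg.seed_for("profiles"))
    bees = make_experiment(gen, cfg.protocol, n_bees=n_bees)
    tables, stab_rows, classifications = [], [], []
    for ds in bees:
        for o in range(ds.n_odorants):
            avg = ds.trial_average_map(o)
            tables.append(pn_mod.classify_map(avg))
            for i in range(avg.n_glomeruli):
                classifications.append(pn_mod.classify_profile(avg.row(i)))
            rep = pn_mod.trial_stability(ds.trial_maps(o))
            s = rep.summary()
            s.insert(0, "odorant", ds.odorant_names[o])
            s.insert(0, "bee", ds.bee)
            stab_rows.append(s)
    table = pd.concat(tables, ignore_index=True)
    n = len(table)
    freq = pd.DataFrame([{
        "excitatory_pct": 100 * (table["polarity"] == "excitatory").mean(),
        "inhibitory_pct": 100 * (table["polarity"] == "inhibitory").mean(),
        "unresponsive_pct": 100 * (table["polarity"] == "none").mean(),
        "inhibitory_component_pct":
            100 * table["has_inhibitory_component"].mean(),
        "accuracy_vs_truth": float((table["group"] == table["true_group"]).mean()),
        "n": n,
    }])
    summ = pn_mod.latency_summary(classifications)
    lat = summ.table.copy()
    if summ.kruskal is not None:
        lat.attrs["kruskal_H"], lat.attrs["kruskal_p"] = summ.kruskal
    return {"classification": table, "frequencies": freq, "latency": lat,
            "latency_pairwise": summ.pairwise if summ.pairwise is not None
            else pd.DataFrame(),
            "stability": pd.concat(stab_rows, ignore_index=True)}


def run_coding_analysis(cfg: RunConfig, n_bees: int = 8,
                        n_replicates: int = 10,
                        decorr_odorants: int = 100,
                        decorr_profiles: int = 30) -> Dict[str, pd.DataFrame]:
    """KC-space dynamics and the PN-vs-KC decorrelation experiment."""
    gen = _seeded(cfg.generator, cfg.seed_for("coding"))
    bees = make_experiment(gen, cfg.protocol, n_bees=n_bees)
    turn_rows, recr_rows, pca_rows = [], [], []
    for b, ds in enumerate(bees):
        kc_pops, pn_pops, t20 = [], [], None
        for o in range(ds.n_odorants):
            avg = ds.trial_average_map(o)
            rasters = simulate(avg, cfg.mb, seed=cfg.seed_for("mb", ds.bee, str(o)),
                               n_replicates=n_replicates)
            t20 = rasters[0].time_s
            series = [kc_mod.turnover_rate(r.activity, t20) for r in rasters]
            mean_vals = np.nanmean([s.values for s in series], axis=0)
            wm = kc_mod.TurnoverSeries(mean_vals, t20[1:]).window_means()
            turn_rows.append({"bee": ds.bee, "odorant": ds.odorant_names[o], **wm})
            counts = np.mean([kc_mod.cumulative_recruitment(r.activity, t20)[0]
                              for r in rasters], axis=0)
            recr_rows.append({"bee": ds.bee, "odorant": ds.odorant_names[o],
                              "recruited_at_offset": float(
                                  counts[np.searchsorted(t20[t20 >= -1e-9], 5.0)]),
                              "recruited_final": float(counts[-1])})
            kc_pops.append(np.mean([r.activity for r in rasters], axis=0))
            pn_pops.append(kc_mod.expand_and_resample(avg, cfg.mb).activity)
        win = (t20 >= -1e-9) & (t20 < 10.0)
        pn_pca = kc_mod.odor_trajectories_pca([p[:, win] for p in pn_pops],
                                              t20[win])
        kc_pca = kc_mod.odor_trajectories_pca([p[:, win] for p in kc_pops],
                                              t20[win])
        pca_rows.append({"bee": ds.bee,
                         "pn_separation": pn_pca.separation_score(),
                         "kc_separation": kc_pca.separation_score()})
    db = make_profile_database(gen, cfg.protocol, n_per_group=30,
                               seed=cfg.seed_for("profile_db"))
    dec = kc_mod.decorrelation_experiment(
        db, n_odorants=decorr_odorants, n_profiles=decorr_profiles,
        config=cfg.mb, seed=cfg.seed_for("decorrelation"),
        n_replicates=n_replicates)
    dec_df = pd.DataFrame([{
        "pn_mean_r": dec.pn_mean, "pn_sd_r": dec.pn_sd,
        "kc_mean_r": dec.kc_mean, "kc_sd_r": dec.kc_sd,
        "t_stat": dec.t_stat, "p_value": dec.p_value,
        "n_pairs": dec.n_pairs, "n_excluded": dec.n_excluded}])
    return {"turnover": pd.DataFrame(turn_rows),
            "recruitment": pd.DataFrame(recr_rows),
            "pca_separation": pd.DataFrame(pca_rows),
            "decorrelation": dec_df}


def run_learning_analysis(cfg: RunConfig, n_bees: int = 8,
                          n_replicates: int = 1) -> Dict[str, pd.DataFrame]:
    """Conditioning battery: 2 odorant-role assignments per animal."""
    gen = _seeded(cfg.generator, cfg.seed_for("learning"))
    bees = make_experiment(gen, CONDITIONING_PROTOCOL, n_bees=n_bees,
                           n_odorants=2)
    inputs = [ci for ds in bees
              for ci in mbon_mod.conditioning_inputs_from_dataset(ds)]
    battery = mbon_mod.evaluate_protocols(
        inputs, config=cfg.mb, spt=cfg.spt,
        seed=cfg.seed_for("battery"), n_replicates=n_replicates)
    stats_rows = []
    for name in mbon_mod.PROTOCOLS:
        cs, nod = battery.scores(name)
        h, p = battery.kruskal_cs_vs_nod(name)
        lat = battery.latencies(name)
        stats_rows.append({
            "protocol": name, "mean_score_cs": float(cs.mean()),
            "mean_score_nod": float(nod.mean()), "kruskal_H": h,
            "kruskal_p": p, "median_latency_ms": float(np.nanmedian(lat)),
            "n": len(cs)})
    from .stats import bartlett_test, wilcoxon_signed_rank
    lat_e, lat_d = battery.latencies("early"), battery.latencies("delay")
    ok = np.isfinite(lat_e) & np.isfinite(lat_d)
    _, p_w = wilcoxon_signed_rank(lat_e[ok], lat_d[ok])
    _, p_b = bartlett_test(lat_e[ok], lat_d[ok])
    tests = pd.DataFrame([{"comparison": "early_vs_delay_latency",
                           "wilcoxon_p": p_w, "bartlett_p": p_b,
                           "n": int(ok.sum())}])
    return {"battery": battery.records(),
            "protocol_stats": pd.DataFrame(stats_rows),
            "latency_tests": tests,
            "_battery_object": battery}


def run_ablation_analysis(cfg: RunConfig, n_repeats: int = 100
                          ) -> Dict[str, pd.DataFrame]:
    """Group-removal experiment over balanced artificial odorants."""
    gen = _seeded(cfg.generator, cfg.seed_for("ablation"))
    proto = StimulusProtocol(pre_window_s=1.0, record_window_s=15.0)
    db = make_profile_database(gen, proto, n_per_group=30,
                               seed=cfg.seed_for("ablation_db"))
    res = mbon_mod.ablation_experiment(
        db, gen, n_repeats=n_repeats, config=cfg.mb, spt=cfg.spt,
        seed=cfg.seed_for("ablation_runs"))
    summary = pd.DataFrame([{
        "variant": v, "fraction_p_below_0.05": res.fraction_significant(v),
        "median_p": float(np.nanmedian(res.p_values[v])),
        "n_repeats": n_repeats} for v in res.p_values])
    return {"ablation_summary": summary, "ablation_detail": res.latency_medians}


FIGURE_DRIVERS = {
    "fig2": run_profile_analysis,
    "fig4": run_coding_analysis,
    "fig5": run_learning_analysis,
    "fig6": run_ablation_analysis,
}


def reproduce(figure_id: str, cfg: Optional[RunConfig] = None,
              output_dir=None, **kwargs) -> Dict[str, pd.DataFrame]:
    """One-command driver: run an analysis arm and write its tables."""
    if figure_id not in FIGURE_DRIVERS:
        raise ValueError(f"unknown figure id {figure_id!r}; "
                         f"known: {sorted(FIGURE_DRIVERS)}")
    cfg = cfg or RunConfig()
    out = FIGURE_DRIVERS[figure_id](cfg, **kwargs)
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"figure": figure_id, "master_seed": cfg.master_seed,
                    "tables": []}
        for name, df in out.items():
            if name.startswith("_"):
                continue
            p = outdir / f"{figure_id}_{name}.csv"
            df.to_csv(p, index=False)
            manifest["tables"].append(p.name)
        (outdir / f"{figure_id}_manifest.json").write_text(
            json.dumps(manifest, indent=2))
    return out


def _seeded(gen: GeneratorConfig, seed: int) -> GeneratorConfig:
    d = gen.to_dict()
    d["seed"] = seed
    return GeneratorConfig(**d)
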