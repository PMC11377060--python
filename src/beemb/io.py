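"""Configuration, seed derivation and dataset file I/O.

Datasets travel as long-form CSV (columns bee, odorant, glomerulus, trial,
time_s, dff) with a JSON sidecar holding the protocol, generator config,
seed and ground-truth labels.  A best-effort adapter stub for the publicly
deposited recordings (Dryad, doi:10.5061/dryad.qbzkh18sc) is feature-probed
rather than assumed, since the deposit's file layout is not documented
here: ``probe_schema`` reports what a file contains, and the loader only
accepts files that already match the long-form dialect.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .mb import MBConfig
from .protocol import StimulusProtocol
from .synthetic import GeneratorConfig, SyntheticDataset

REQUIRED_COLUMNS = ["bee", "odorant", "glomerulus", "trial", "time_s", "dff"]


def derive_seed(master_seed: int, *path: str) -> int:
    """Deterministic child seed (< 2**31) for a named operation path."""
    crc = zlib.crc32("/".join(path).encode())
    ss = np.random.SeedSequence([int(master_seed), crc])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """All module configs plus the master seed; JSON round-trippable."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    mb: MBConfig = field(default_factory=MBConfig)
    spt: int = 15
    master_seed: int = 0
    output_dir: str = "results"

    def seed_for(self, *path: str) -> int:
        return derive_seed(self.master_seed, *path)

    def to_json(self) -> str:
        return json.dumps({
            "generator": self.generator.to_dict(),
            "protocol": self.protocol.to_dict(),
            "mb": self.mb.to_dict(),
            "spt": self.spt,
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        return cls(generator=GeneratorConfig(**d["generator"]),
                   protocol=StimulusProtocol(**d["protocol"]),
                   mb=MBConfig(**d["mb"]), spt=d["spt"],
                   master_seed=d["master_seed"], output_dir=d["output_dir"])


# ---------------------------------------------------------------------------
# dataset round trip
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, csv_path, sidecar_path=None,
                  decimate: int = 1) -> None:
    """Long-form CSV plus JSON sidecar (protocol, config, labels).

    ``decimate`` keeps every n-th sample for compact exports; the sidecar
    records the factor so a round trip stays self-describing.
    """
    t = ds.protocol.times()[::decimate]
    frames = []
    for o, name in enumerate(ds.odorant_names):
        for g in range(ds.traces.shape[1]):
            for j in range(ds.traces.shape[2]):
                frames.append(pd.DataFrame({
                    "bee": ds.bee, "odorant": name, "glomerulus": g,
                    "trial": j, "time_s": t,
                    "dff": ds.traces[o, g, j, ::decimate].astype(float)}))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        sidecar = {
            "bee": ds.bee,
            "protocol": ds.protocol.to_dict(),
            "generator": ds.config.to_dict(),
            "seed": ds.config.seed,
            "decimate": decimate,
            "groups": ds.groups.tolist(),
            "onset_ms": np.where(np.isfinite(ds.onset_ms),
                                 ds.onset_ms, None).tolist(),
            "termination_ms": np.where(np.isfinite(ds.termination_ms),
                                       ds.termination_ms, None).tolist(),
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


@dataclass
class LoadedDataset:
    """Trial-resolved glomerular dataset reconstructed from long CSV."""

    traces: Dict[str, Dict[str, np.ndarray]]  # bee -> odorant -> (G, N, T)
    time_s: np.ndarray
    metadata: dict = field(default_factory=dict)


def probe_schema(path) -> List[str]:
    """Report the column names of a tabular file without interpreting it."""
    head = pd.read_csv(path, nrows=5)
    return list(head.columns)


def load_dataset(path, dialect: str = "long_csv",
                 sidecar_path=None) -> LoadedDataset:
    """Load a trial-resolved glomerular dataset.

    ``long_csv`` is the package's native dialect.  The ``dryad`` dialect is
    best-effort: it accepts deposits only if they already follow the long
    schema, and otherwise raises with the observed columns so the caller can
    write an explicit adapter.
    """
    if dialect not in ("long_csv", "dryad"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty file: missing required columns "
                         f"{REQUIRED_COLUMNS}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        msg = f"schema mismatch: missing columns {missing}"
        if dialect == "dryad":
            msg += (f"; observed columns {list(df.columns)} — the deposit "
                    "layout is not the long-form dialect, adapt it explicitly")
        raise ValueError(msg)
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    traces: Dict[str, Dict[str, np.ndarray]] = {}
    time_ref: Optional[np.ndarray] = None
    for (bee, od), sub in df.groupby(["bee", "odorant"], sort=True):
        gloms = sorted(sub["glomerulus"].unique())
        trials = sorted(sub["trial"].unique())
        lengths = sub.groupby(["glomerulus", "trial"]).size()
        if lengths.nunique() > 1:
            bad = lengths.idxmin()
            raise ValueError(
                f"truncated trial: bee={bee} odorant={od} "
                f"glomerulus={bad[0]} trial={bad[1]}")
        T = int(lengths.iloc[0])
        arr = np.full((len(gloms), len(trials), T), np.nan)
        for (g, j), grp in sub.groupby(["glomerulus", "trial"]):
            grp = grp.sort_values("time_s")
            arr[gloms.index(g), trials.index(j)] = grp["dff"].to_numpy()
            if time_ref is None:
                time_ref = grp["time_s"].to_numpy()
        traces.setdefault(str(bee), {})[str(od)] = arr
    meta = {"extra_columns": extra}
    if sidecar_path is not None:
        meta["sidecar"] = json.loads(Path(sidecar_path).read_text())
    return LoadedDataset(traces=traces, time_s=time_ref, metadata=meta)
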