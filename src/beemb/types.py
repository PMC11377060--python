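"""Core containers shared across modules.

``GlomerularTrace`` is the atomic unit of the projection-neuron analyses: one
glomerulus's -dF/F time series (fluorescence decreases of the Fura-2 sensor
are sign-flipped, so calcium increases read as positive responses).
``OdorResponseMap`` stacks the traces of all glomeruli recorded for one
odorant; it is the input the mushroom-body model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .protocol import StimulusProtocol, check_uniform_grid

#: label used for flat, non-responding glomeruli (distinct from group 9,
#: which shows weak unclassifiable activity)
UNRESPONSIVE = 0

#: response groups carrying an inhibitory component at some point of the trace
INHIBITORY_COMPONENT_GROUPS = frozenset({1, 2, 3, 5, 7, 8})

EXCITATORY_GROUPS = frozenset({4, 5, 6, 7, 8})
INHIBITORY_GROUPS = frozenset({1, 2, 3})
SHORT_GROUPS = frozenset({7, 8})
ALL_GROUPS = frozenset(range(10))  # 0 = unresponsive, 1..9


def polarity_of_group(group_id: int) -> str:
    if group_id in INHIBITORY_GROUPS:
        return "inhibitory"
    if group_id in EXCITATORY_GROUPS:
        return "excitatory"
    return "none"  # unresponsive and group 9 map to non-responsive


@dataclass
class GlomerularTrace:
    values: np.ndarray
    time_s: np.ndarray
    protocol: StimulusProtocol
    bee: Optional[str] = None
    odorant: Optional[str] = None
    glomerulus: Optional[int] = None
    trial: Optional[object] = None  # trial index or "mean"
    group: Optional[int] = None  # ground-truth or assigned response group

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.values.shape != self.time_s.shape:
            raise ValueError("values and time_s must have equal length")
        check_uniform_grid(self.time_s)

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])


@dataclass
class OdorResponseMap:
    """Glomeruli x time matrix of -dF/F for one odorant (trial or mean)."""

    values: np.ndarray  # (n_glomeruli, n_samples)
    time_s: np.ndarray
    protocol: StimulusProtocol
    odorant: Optional[str] = None
    bee: Optional[str] = None
    trial: Optional[object] = None
    groups: Optional[np.ndarray] = None  # per-row response group labels

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.values.shape[1] != self.time_s.shape[0]:
            raise ValueError("map columns must match time grid length")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=int)
            if self.groups.shape[0] != self.values.shape[0]:
                raise ValueError("one group label per glomerulus row required")
        check_uniform_grid(self.time_s)

    @property
    def n_glomeruli(self) -> int:
        return self.values.shape[0]

    def row(self, i: int) -> GlomerularTrace:
        return GlomerularTrace(
            values=self.values[i],
            time_s=self.time_s,
            protocol=self.protocol,
            odorant=self.odorant,
            bee=self.bee,
            glomerulus=i,
            trial=self.trial,
            group=None if self.groups is None else int(self.groups[i]),
        )

    def copy(self) -> "OdorResponseMap":
        return OdorResponseMap(
            values=self.values.copy(),
            time_s=self.time_s.copy(),
            protocol=self.protocol,
            odorant=self.odorant,
            bee=self.bee,
            trial=self.trial,
            groups=None if self.groups is None else self.groups.copy(),
        )


def stack_traces(traces: Sequence[GlomerularTrace]) -> OdorResponseMap:
    """Stack single-glomerulus traces (same grid) into a response map."""
    if not traces:
        raise ValueError("no traces to stack")
    t0 = traces[0]
    for tr in traces[1:]:
        if tr.values.shape != t0.values.shape or not np.allclose(tr.time_s, t0.time_s):
            raise ValueError("traces must share the time grid")
    groups = None
    if all(tr.group is not None for tr in traces):
        groups = np.array([tr.group for tr in traces])
    return OdorResponseMap(
        values=np.stack([tr.values for tr in traces]),
        time_s=t0.time_s,
        protocol=t0.protocol,
        odorant=t0.odorant,
        bee=t0.bee,
        trial=t0.trial,
        groups=groups,
    )
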