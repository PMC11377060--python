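"""Stimulus protocol: timing of odorant delivery and recording.

All times are expressed relative to stimulus onset (t = 0).  A trace spans
``[-pre_window_s, record_window_s - pre_window_s)`` sampled at
``sampling_rate_hz``; the odorant is ON during ``[0, stim_duration_s)``.
The default values mirror a fast calcium-imaging session in the honey bee
antennal lobe: ~127 Hz acquisition, 5 s odour pulses separated by 25 s of
clean air, 20 repetitions per odorant.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

#: rate at which the mushroom-body model integrates its input (Hz)
MB_RATE_HZ = 20.0


@dataclass(frozen=True)
class StimulusProtocol:
    sampling_rate_hz: float = 127.0
    stim_duration_s: float = 5.0
    n_trials: int = 20
    pre_window_s: float = 1.0
    record_window_s: float = 21.0  # total trace duration, pre window included

    def __post_init__(self) -> None:
        if self.sampling_rate_hz < 2 * MB_RATE_HZ:
            raise ValueError(
                f"sampling_rate_hz must be >= {2 * MB_RATE_HZ} Hz to allow "
                f"resampling at the {MB_RATE_HZ} Hz model rate"
            )
        if self.stim_duration_s <= 0:
            raise ValueError("stim_duration_s must be positive")
        if self.pre_window_s <= 0:
            raise ValueError("pre_window_s must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.record_window_s <= self.pre_window_s + self.stim_duration_s:
            raise ValueError("record_window_s must cover pre window and stimulus")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def n_samples(self) -> int:
        return int(round(self.record_window_s * self.sampling_rate_hz))

    @property
    def offset_s(self) -> float:
        """Time of stimulus offset (s, relative to onset)."""
        return self.stim_duration_s

    def times(self) -> np.ndarray:
        return -self.pre_window_s + np.arange(self.n_samples) * self.dt

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)


def window_slice(time_s: np.ndarray, start: float, end: float) -> slice:
    """Half-open [start, end) window on a uniform time grid.

    Bounds are aligned to the nearest sample, so off-grid window edges map
    deterministically onto grid points.
    """
    dt = time_s[1] - time_s[0]
    i0 = int(round((start - time_s[0]) / dt))
    i1 = int(round((end - time_s[0]) / dt))
    i0 = max(i0, 0)
    i1 = min(i1, len(time_s))
    if i1 <= i0:
        raise ValueError(f"window [{start}, {end}) does not overlap the time grid")
    return slice(i0, i1)


def check_uniform_grid(time_s: np.ndarray, rtol: float = 1e-6) -> float:
    """Return the grid step, raising if the grid is not uniform."""
    steps = np.diff(time_s)
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=rtol, atol=0):
        raise ValueError("time grid is not uniform")
    return float(dt)
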