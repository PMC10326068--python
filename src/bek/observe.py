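"""Observation layer: frame-sampled fluorescence and length traces.

Emulates intensity read-out at the barbed end of a filament imaged at a
fixed frame interval.  A frame reports the protein content of the state
occupying the *majority* of that frame interval, so sub-frame excursions
can vanish — measured single-frame dwells are lower bounds, as in real
frame-limited single-molecule data.  Fluorescence is one unit per
unbleached fluorophore plus Gaussian noise; photobleaching is a single
irreversible exponential-time event per fluorophore, with a fresh
molecule (fresh fluorophores) assumed for each continuous presence
episode.  The length channel integrates the per-state elongation velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RateSet
from .simulate import StateTrajectory
from .states import PROTEIN_STATES, STATE_INDEX, STATE_ORDER

__all__ = ["ChannelTrace", "render_trace", "presence_ground_truth", "CHANNELS"]

CHANNELS = ("actin", "formin", "CP", "twinfilin", "length")


@dataclass
class ChannelTrace:
    """Frame-sampled time series for one filament and one channel.

    ``values[k]`` is the read-out for frame k, covering
    ``[t0 + k*dt, t0 + (k+1)*dt)``; intensities are in arbitrary units
    (1 per fluorophore), length in µm.
    """

    filament_id: int
    channel: str
    frame_interval: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def frame_times(self) -> np.ndarray:
        return self.t0 + self.frame_interval * np.arange(self.n_frames)


def _n_frames(traj: StateTrajectory, frame_interval: float, t0: float) -> int:
    return int(np.floor((traj.t_end - t0) / frame_interval)) + 1


def _dominant_states(traj: StateTrajectory, frame_interval: float, t0: float) -> np.ndarray:
    """Index (into STATE_ORDER) of the state occupying most of each frame.

    Ties break toward the lower state index; frames beyond the trajectory
    support keep the last state.
    """
    n = _n_frames(traj, frame_interval, t0)
    occ = np.zeros((n, len(STATE_ORDER)))
    frames_lo = t0 + frame_interval * np.arange(n)
    frames_hi = frames_lo + frame_interval
    for state, start, end in traj.sojourns():
        if end <= start:
            continue
        overlap = np.clip(np.minimum(frames_hi, end) - np.maximum(frames_lo, start), 0.0, None)
        occ[:, STATE_INDEX[state]] += overlap
    # beyond t_end: extend the final state so trailing frames are defined
    last_state = traj.segments[-1][0]
    empty = occ.sum(axis=1) == 0
    occ[empty, STATE_INDEX[last_state]] = 1.0
    return np.argmax(occ, axis=1)


def presence_ground_truth(
    traj: StateTrajectory, protein: str, frame_interval: float, t0: float = 0.0
) -> np.ndarray:
    """Binary per-frame occupancy of *protein*, majority-of-frame rule."""
    members = PROTEIN_STATES.get(protein)
    if members is None:
        raise ValueError(f"unknown protein {protein!r}")
    dom = _dominant_states(traj, frame_interval, t0)
    member_idx = np.array([STATE_ORDER[i] in members for i in range(len(STATE_ORDER))])
    return member_idx[dom].astype(np.int8)


def _episodes(present: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) frame ranges of consecutive presence."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], present, [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def render_trace(
    traj: StateTrajectory,
    channel: str,
    frame_interval: float,
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    seed=None,
    n_fluorophores: int = 1,
    rates: RateSet | None = None,
    t0: float = 0.0,
) -> ChannelTrace:
    """Render one channel of a trajectory as a frame-sampled trace.

    Intensity channels report (number of unbleached fluorophores of the
    molecule present in the frame's majority state) + Gaussian noise.  The
    ``length`` channel integrates the per-state velocity from *rates*
    (required for that channel) and is sampled at frame start times.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if noise_sd < 0 or bleach_rate < 0:
        raise ValueError("noise_sd and bleach_rate must be non-negative")
    rng = np.random.default_rng(seed)

    if channel == "length":
        if rates is None:
            raise ValueError("rates (for per-state velocities) required for length channel")
        n = _n_frames(traj, frame_interval, t0)
        times = t0 + frame_interval * np.arange(n)
        knots_t = [0.0]
        knots_len = [0.0]
        length = 0.0
        for state, start, end in traj.sojourns():
            length += rates.velocity(state) * (end - start)
            knots_t.append(end)
            knots_len.append(length)
        values = np.interp(times, knots_t, knots_len)
    else:
        present = presence_ground_truth(traj, channel, frame_interval, t0)
        values = present.astype(float) * n_fluorophores
        if bleach_rate > 0:
            values = np.zeros(len(present))
            for start, end in _episodes(present):
                bleach_t = rng.exponential(1.0 / bleach_rate, size=n_fluorophores)
                elapsed = frame_interval * np.arange(end - start)
                values[start:end] = (elapsed[:, None] < bleach_t[None, :]).sum(axis=1)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return ChannelTrace(
        filament_id=traj.filament_id,
        channel=channel,
        frame_interval=frame_interval,
        values=values,
        t0=t0,
    )
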