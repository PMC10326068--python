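"""Gillespie simulation of per-filament barbed-end trajectories.

A trajectory is an exact realization of the continuous-time Markov chain
defined by :func:`bek.model.build_transition_table`: sojourn times are
exponential with the state's total exit propensity and the next state is
chosen with probability proportional to the edge propensity.  A cohort is
a set of independent filaments started in the same state, mirroring the
microfluidics experiments in which a population of pre-formed complexes is
switched into a new solution at t = 0 and watched for a fixed window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import RateSet, Transition, build_transition_table
from .states import ABSORBING_STATES, BarbedState

__all__ = [
    "StateTrajectory",
    "simulate_trajectory",
    "simulate_cohort",
    "extract_event",
    "count_twinfilin_visits",
    "EVENT_TABLE_COLUMNS",
]

EVENT_TABLE_COLUMNS = [
    "filament_id",
    "t_event",
    "outcome",
    "censored",
    "conc_C_uM",
    "conc_T_uM",
    "seed",
]


@dataclass
class StateTrajectory:
    """Piecewise-constant state sequence for one filament.

    ``segments`` is an ordered list of ``(state, entry_time)`` with strictly
    increasing entry times starting at 0; the last segment extends to
    ``t_end`` (the observation window) or is an absorbing state entered
    before it.
    """

    filament_id: int
    segments: list[tuple[BarbedState, float]]
    t_end: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("trajectory must have at least one segment")
        if self.segments[0][1] != 0.0:
            raise ValueError("first segment must enter at time 0")
        times = [t for _, t in self.segments]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("entry times must be strictly increasing")

    def state_at(self, t: float) -> BarbedState:
        """State occupied at time ``t`` (right-continuous)."""
        state = self.segments[0][0]
        for s, entry in self.segments:
            if entry > t:
                break
            state = s
        return state

    def sojourns(self) -> list[tuple[BarbedState, float, float]]:
        """List of ``(state, start, end)`` with the final segment clipped to t_end."""
        out = []
        for i, (s, entry) in enumerate(self.segments):
            end = self.segments[i + 1][1] if i + 1 < len(self.segments) else self.t_end
            out.append((s, entry, min(end, self.t_end)))
        return out


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _exit_tables(table: list[Transition]):
    """Per-state (total rate, cumulative probabilities, transitions)."""
    per_state: dict[BarbedState, list[Transition]] = {}
    for tr in table:
        per_state.setdefault(tr.source, []).append(tr)
    compiled = {}
    for state, trs in per_state.items():
        props = np.array([t.propensity for t in trs], dtype=float)
        total = props.sum()
        cum = np.cumsum(props) / total if total > 0 else None
        compiled[state] = (total, cum, trs)
    return compiled


def simulate_trajectory(
    rates: RateSet,
    initial_state: BarbedState,
    t_max: float,
    seed,
) -> StateTrajectory:
    """Exact stochastic simulation of one filament up to ``t_max`` seconds.

    ``seed`` may be an integer, a :class:`numpy.random.SeedSequence` or a
    ``Generator``; identical seeds give identical trajectories.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    initial_state = BarbedState(initial_state)
    rng = _rng_from(seed)
    compiled = _exit_tables(build_transition_table(rates))

    segments: list[tuple[BarbedState, float]] = [(initial_state, 0.0)]
    t = 0.0
    state = initial_state
    while True:
        if state in ABSORBING_STATES:
            break
        total, cum, trs = compiled.get(state, (0.0, None, []))
        if total <= 0.0:
            break  # effectively absorbing under these rates
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        state = trs[int(np.searchsorted(cum, rng.random(), side="right"))].target
        segments.append((state, t))
    return StateTrajectory(filament_id=0, segments=segments, t_end=t_max)


# Which reached state terminates observation of the initial complex, and
# which protein's departure it records.  "to_BF" = CP departed first,
# "to_BC" = formin departed first (filament lost from view).
_TERMINAL = {
    BarbedState.BFC: {BarbedState.BF: "to_BF", BarbedState.DETACHED: "to_BC"},
    BarbedState.BF: {BarbedState.DETACHED: "to_BC"},
    BarbedState.BC: {BarbedState.B: "to_BF", BarbedState.UNCAPPED_DEPOL: "to_BF"},
    BarbedState.B: {},
}


def extract_event(traj: StateTrajectory, initial_state: BarbedState, window: float):
    """First resolution of the initial complex within the window.

    Returns ``(t_event, outcome)`` where outcome is ``to_BF`` (CP left
    first), ``to_BC`` (formin left first) or ``censored`` with
    ``t_event = nan``.
    """
    terminal = _TERMINAL.get(BarbedState(initial_state))
    if terminal is None:
        raise ValueError(f"no event semantics for initial state {initial_state}")
    for state, entry in traj.segments[1:]:
        if entry > window:
            break
        if state in terminal:
            return entry, terminal[state]
    return float("nan"), "censored"


def simulate_cohort(
    rates: RateSet,
    n_filaments: int,
    initial_state: BarbedState,
    window: float,
    seed: int,
) -> tuple[list[StateTrajectory], pd.DataFrame]:
    """Simulate ``n_filaments`` independent filaments and tabulate events.

    Per-filament randomness comes from ``SeedSequence(seed, spawn_key=(i,))``
    so the cohort is reproducible and independent of simulation order.
    The event table records, per filament, the first resolution of the
    initial complex (see :func:`extract_event`) or censoring at ``window``.
    """
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    initial_state = BarbedState(initial_state)
    trajectories = []
    rows = []
    for i in range(n_filaments):
        ss = np.random.SeedSequence(seed, spawn_key=(i,))
        traj = simulate_trajectory(rates, initial_state, window, np.random.default_rng(ss))
        traj.filament_id = i
        trajectories.append(traj)
        t_event, outcome = extract_event(traj, initial_state, window)
        rows.append((i, t_event, outcome, outcome == "censored",
                     rates.conc_C, rates.conc_T, seed))
    events = pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)
    return trajectories, events


def count_twinfilin_visits(traj: StateTrajectory):
    """Twinfilin visits (BCT/BFCT sojourns) before CP loss, from the trajectory.

    Ground-truth counterpart of the trace-based visit counting: returns
    ``(n_visits, t_uncap, resolved)`` where ``t_uncap`` is the time CP
    departed (entry into B, BF after a trimeric state, or UNCAPPED_DEPOL)
    and ``n_visits`` counts twinfilin sojourns started up to that moment.
    Unresolved (censored) trajectories report all observed visits.
    """
    n_visits = 0
    prev = traj.segments[0][0]
    for state, entry in traj.segments[1:]:
        if state in (BarbedState.BCT, BarbedState.BFCT):
            n_visits += 1
        cp_lost = state is BarbedState.UNCAPPED_DEPOL or (
            state in (BarbedState.B, BarbedState.BF)
            and prev in (BarbedState.BC, BarbedState.BCT, BarbedState.BFC, BarbedState.BFCT)
        )
        if cp_lost:
            return n_visits, entry, True
        prev = state
    return n_visits, float("nan"), False
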