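"""Reusable in-silico experiments over the simulator and inference layers.

These functions reproduce, on synthetic cohorts, the designs of the
underlying bench experiments: decision-complex dissociation under a flow
window, the single-molecule uncapping assay (twinfilin visits at a capped
end until depolymerization starts), and a self-calibration experiment for
the parametric-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dwell import (
    binarize_trace,
    detect_depolymerization_onset,
    dwell_summary,
    estimate_uncap_probability,
    visits_until_uncapping,
)
from .model import RateSet
from .observe import render_trace
from .simulate import StateTrajectory, count_twinfilin_visits, simulate_cohort, simulate_trajectory
from .survival import (
    RateFit,
    RouteDecomposition,
    bootstrap_rate_ci,
    decompose_routes,
    fit_single_exponential,
    survival_curve,
)

__all__ = ["run_bfc_cohort", "run_uncapping_assay", "bootstrap_coverage",
           "BfcCohortResult", "UncappingAssayResult"]


@dataclass
class BfcCohortResult:
    events: pd.DataFrame
    fit: RateFit
    decomposition: RouteDecomposition

    @property
    def bf_route_fraction(self) -> float:
        d = self.decomposition
        return d.n_bf / (d.n_bf + d.n_bc)


def run_bfc_cohort(
    rates: RateSet,
    n_filaments: int,
    window: float,
    seed: int,
    grid_dt: float | None = 5.0,
    bootstrap_reps: int = 0,
    ci_level: float = 0.65,
) -> BfcCohortResult:
    """Decision-complex dissociation experiment: simulate, fit, decompose.

    The survival curve is evaluated on a regular grid at ``grid_dt``
    spacing (the acquisition-like convention) unless ``grid_dt`` is None.
    Set ``bootstrap_reps`` > 0 to attach a bootstrap CI to the fit.
    """
    _, events = simulate_cohort(rates, n_filaments, "BFC", window, seed)
    grid = np.arange(grid_dt, window + 1e-9, grid_dt) if grid_dt else None
    fit = fit_single_exponential(survival_curve(events, grid=grid))
    if bootstrap_reps and fit.rate > 0:
        ci = bootstrap_rate_ci(fit.rate, n=n_filaments, window=window,
                               reps=bootstrap_reps, level=ci_level,
                               seed=seed + 1, grid=grid)
        fit.ci_low, fit.ci_high, fit.sd, fit.ci_level = ci.ci_low, ci.ci_high, ci.sd, ci_level
    decomp = decompose_routes(events, grid=grid)
    return BfcCohortResult(events=events, fit=fit, decomposition=decomp)


def _clipped(traj: StateTrajectory, t_end: float) -> StateTrajectory:
    segs = [(s, t) for s, t in traj.segments if t < t_end]
    return StateTrajectory(filament_id=traj.filament_id, segments=segs, t_end=t_end)


@dataclass
class UncappingAssayResult:
    """Per-filament visit statistics plus pooled dwell summary."""

    records: pd.DataFrame
    dwell_durations: np.ndarray
    frame_interval: float
    uncap_probability: float = float("nan")
    uncap_probability_ci: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def mean_visits_true(self) -> float:
        r = self.records[self.records["resolved"]]
        return float(r["n_visits_true"].mean())

    @property
    def mean_visits_traced(self) -> float:
        r = self.records[self.records["resolved_trace"]]
        return float(r["n_visits_trace"].mean())


def run_uncapping_assay(
    rates: RateSet,
    n_filaments: int,
    window: float,
    seed: int,
    frame_interval: float = 0.2,
    noise_sd: float = 0.0,
    render_tail: float = 10.0,
) -> UncappingAssayResult:
    """Single-molecule uncapping assay on capped (BC) filament ends.

    For each filament: simulate the visit process, record the true visit
    count and uncapping time from the trajectory, then render twinfilin
    and length traces (clipped shortly after uncapping), detect the onset
    of depolymerization from the length channel, and count visits from
    the binarized twinfilin trace.  Dwell durations are pooled from the
    trace intervals, as they would be measured.
    """
    rows = []
    dwells: list[np.ndarray] = []
    visit_records = []
    for i in range(n_filaments):
        ss = np.random.SeedSequence(seed, spawn_key=(i,))
        traj = simulate_trajectory(rates, "BC", window, np.random.default_rng(ss))
        traj.filament_id = i
        n_true, t_uncap_true, resolved = count_twinfilin_visits(traj)

        t_render = min(window, t_uncap_true + render_tail) if resolved else window
        clip = _clipped(traj, t_render)
        obs_seed = np.random.SeedSequence(seed, spawn_key=(i, 1))
        tw = render_trace(clip, "twinfilin", frame_interval, noise_sd=noise_sd,
                          seed=obs_seed, rates=rates)
        ln = render_trace(clip, "length", frame_interval, noise_sd=noise_sd,
                          seed=obs_seed, rates=rates)
        iv = binarize_trace(tw, threshold=0.5 if noise_sd == 0 else "auto")
        onset = detect_depolymerization_onset(ln)
        rec = visits_until_uncapping(iv, onset)
        if iv.intervals:
            dwells.append(iv.durations())
        visit_records.append(rec)
        rows.append((i, n_true, t_uncap_true, resolved,
                     rec.n_visits, rec.t_uncap, rec.resolved))

    records = pd.DataFrame(rows, columns=[
        "filament_id", "n_visits_true", "t_uncap_true", "resolved",
        "n_visits_trace", "t_uncap_trace", "resolved_trace",
    ])
    durations = np.concatenate(dwells) if dwells else np.array([])
    result = UncappingAssayResult(records=records, dwell_durations=durations,
                                  frame_interval=frame_interval)
    resolved_recs = [r for r in visit_records if r.resolved and r.n_visits >= 1]
    if resolved_recs:
        p, ci = estimate_uncap_probability(resolved_recs, seed=seed + 1)
        result.uncap_probability = p
        result.uncap_probability_ci = ci
    return result


def bootstrap_coverage(
    rate: float,
    n: int,
    window: float,
    n_cohorts: int,
    seed: int,
    reps: int = 1000,
    level: float = 0.65,
    grid_dt: float | None = 5.0,
) -> float:
    """Empirical coverage of the bootstrap CI over synthetic cohorts.

    Draws ``n_cohorts`` cohorts of ``n`` exponential lifetimes at the true
    ``rate`` (censored at ``window``), fits each, attaches a bootstrap CI,
    and returns the fraction of intervals containing the true rate.
    """
    grid = np.arange(grid_dt, window + 1e-9, grid_dt) if grid_dt else None
    rng = np.random.default_rng(seed)
    covered = 0
    for c in range(n_cohorts):
        life = rng.exponential(1.0 / rate, n)
        censored = life > window
        events = pd.DataFrame({
            "filament_id": np.arange(n),
            "t_event": np.where(censored, np.nan, life),
            "outcome": np.where(censored, "censored", "to_BF"),
            "censored": censored,
            "conc_C_uM": 0.0, "conc_T_uM": 0.0, "seed": seed,
        })
        fit = fit_single_exponential(survival_curve(events, grid=grid))
        if fit.rate <= 0:
            continue
        ci = bootstrap_rate_ci(fit.rate, n=n, window=window, reps=reps,
                               level=level, seed=int(rng.integers(2**31)), grid=grid)
        covered += ci.ci_low <= rate <= ci.ci_high
    return covered / n_cohorts
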