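"""Kinetic model of barbed-end regulation by formin, CP and twinfilin.

Two layers coexist:

* the coarse two-route decision-complex model, in which a barbed end bound
  simultaneously by formin and CP (state BFC) resolves by first-order loss
  of CP (BFC -> BF + C, rate ``k'_-C``) or of formin (BFC -> BC + F, rate
  ``k'_-F``), giving single-exponential decay of the surviving BFC fraction
  with observed rate ``k_-BFC = k'_-C + k'_-F`` and closed-form occupancy
  fractions for the three states; and

* the mechanistic visit model, in which twinfilin transiently joins capped
  ends (BC -> BCT, BFC -> BFCT) and each departure removes CP with a fixed
  per-visit probability.  With the twinfilin concentration set to zero the
  transition table reduces exactly to the two-route model, and under
  twinfilin the effective CP-loss rate is an emergent quantity.

Rates are stored as first-order propensities; bimolecular association
steps are pre-multiplied by the (constant, per experimental phase)
concentration when the transition table is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .states import ABSORBING_STATES, BarbedState

__all__ = [
    "RateSet",
    "OccupancyFractions",
    "Transition",
    "bfc_survival",
    "occupancy_fractions",
    "route_fraction_bf",
    "build_transition_table",
]


DEFAULT_VELOCITIES = {
    # µm/s; positive = elongation.  Magnitudes are configuration values for
    # the synthetic observation layer, not measured quantities.
    "B": 0.02,
    "BF": 0.1,
    "BC": 0.0,
    "BCT": 0.0,
    "BFC": 0.0,
    "BFCT": 0.0,
    "DETACHED": 0.0,
    "UNCAPPED_DEPOL": -0.05,
}


class RateSet(BaseModel):
    """All kinetic parameters of the barbed-end state model.

    First-order rates are in s^-1, bimolecular on-rates in µM^-1 s^-1,
    concentrations in µM, per-visit uncapping probabilities dimensionless.
    Defaults describe the control decision-complex condition (mean BFC
    lifetime 149 s splitting 42%/58% into BF/BC) with twinfilin parameters
    from the single-molecule visit statistics (1.9 s dwell at plain capped
    ends, 1.4 s at decision complexes, ~1/31 per-visit uncapping at capped
    ends, certain uncapping per visit at decision complexes).
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    k_minus_F: float = Field(default=1.0 / 2100.0, ge=0)
    k_minus_C: float = Field(default=1.0 / 1800.0, ge=0)
    kprime_minus_F: float = Field(default=(1.0 / 149.0) * (42.0 / 72.0), ge=0)
    kprime_minus_C: float = Field(default=(1.0 / 149.0) * (30.0 / 72.0), ge=0)
    k_on_C: float = Field(default=10.0, ge=0)
    k_on_T: float = Field(default=1.08, ge=0)
    k_minus_T: float = Field(default=1.0 / 1.9, ge=0)
    k_minus_T_BFCT: float = Field(default=1.0 / 1.4, ge=0)
    p_uncap_BCT: float = Field(default=1.0 / 30.9, ge=0, le=1)
    p_uncap_BFCT: float = Field(default=1.0, ge=0, le=1)
    # Formin loss from the trimeric complex was never observed (n = 8);
    # kept as an explicit, default-zero escape hatch.
    k_minus_F_BFCT: float = Field(default=0.0, ge=0)
    conc_C: float = Field(default=0.0, ge=0)
    conc_T: float = Field(default=0.0, ge=0)
    velocities: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_VELOCITIES))

    @field_validator("velocities")
    @classmethod
    def _velocity_keys_are_states(cls, v: dict[str, float]) -> dict[str, float]:
        labels = {s.value for s in BarbedState}
        unknown = set(v) - labels
        if unknown:
            raise ValueError(f"velocities has unknown state labels: {sorted(unknown)}")
        out = {s.value: 0.0 for s in BarbedState}
        out.update(v)
        return out

    def velocity(self, state: BarbedState) -> float:
        return self.velocities.get(state.value, 0.0)


@dataclass(frozen=True)
class OccupancyFractions:
    """Closed-form occupancy of the two-route model at time(s) ``t``.

    ``frac_bfc + frac_bf + frac_bc == 1`` to numerical tolerance.
    ``degenerate`` flags the case of both route rates zero (all mass
    remains in BFC).
    """

    t: np.ndarray
    frac_bfc: np.ndarray
    frac_bf: np.ndarray
    frac_bc: np.ndarray
    degenerate: bool = False


def _check_nonnegative(**kwargs: object) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be non-negative")


def bfc_survival(t, kprime_minus_C: float, kprime_minus_F: float):
    """Surviving fraction of decision complexes, exp(-(k'_-C + k'_-F) t).

    Accepts scalar or array ``t``; returns the same shape.
    """
    _check_nonnegative(t=t, kprime_minus_C=kprime_minus_C, kprime_minus_F=kprime_minus_F)
    t = np.asarray(t, dtype=float)
    out = np.exp(-(kprime_minus_C + kprime_minus_F) * t)
    return out if out.ndim else float(out)


def occupancy_fractions(t, kprime_minus_C: float, kprime_minus_F: float) -> OccupancyFractions:
    """Fractions of an initial BFC cohort found in BFC, BF and BC at time t.

    The surviving fraction decays exponentially with the total route rate,
    and the dissociated mass splits between BF and BC in proportion to the
    route rates.  If both route rates are zero the split is undefined and
    all mass stays in BFC (``degenerate=True`` with a warning).
    """
    _check_nonnegative(t=t, kprime_minus_C=kprime_minus_C, kprime_minus_F=kprime_minus_F)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    ktot = kprime_minus_C + kprime_minus_F
    if ktot == 0.0:
        if np.any(t > 0):
            warnings.warn(
                "both route rates are zero: occupancy stays in BFC", stacklevel=2
            )
        ones = np.ones_like(t)
        zeros = np.zeros_like(t)
        return OccupancyFractions(t=t, frac_bfc=ones, frac_bf=zeros, frac_bc=zeros,
                                  degenerate=True)
    decay = np.exp(-ktot * t)
    dissociated = -np.expm1(-ktot * t)  # 1 - exp(-ktot t), accurate for small t
    return OccupancyFractions(
        t=t,
        frac_bfc=decay,
        frac_bf=(kprime_minus_C / ktot) * dissociated,
        frac_bc=(kprime_minus_F / ktot) * dissociated,
    )


def route_fraction_bf(kprime_minus_C: float, kprime_minus_F: float) -> float:
    """Asymptotic fraction of decision complexes resolving to BF (CP leaves).

    Equals ``k'_-C / (k'_-C + k'_-F)``; the complement is the BC fraction.
    """
    _check_nonnegative(kprime_minus_C=kprime_minus_C, kprime_minus_F=kprime_minus_F)
    ktot = kprime_minus_C + kprime_minus_F
    if ktot == 0.0:
        raise ValueError("route fraction undefined when both route rates are zero")
    return kprime_minus_C / ktot


@dataclass(frozen=True)
class Transition:
    """One directed edge of the state model with its pseudo-first-order propensity."""

    source: BarbedState
    target: BarbedState
    propensity: float
    tag: str


def build_transition_table(rates: RateSet) -> list[Transition]:
    """Full propensity table of the mechanistic model.

    Bimolecular steps appear pre-multiplied by concentration.  Twinfilin
    departure from a trimeric/capped-ternary state branches according to
    the per-visit uncapping probability; CP and twinfilin leaving a
    decision complex together is a single BFCT -> BF event.  Formin loss
    from BFC is observationally a transition to BC followed by immediate
    filament loss, hence the DETACHED target with tag ``formin_loss``.
    Absorbing states have no outgoing edges.
    """
    r = rates
    S = BarbedState
    table = [
        Transition(S.BF, S.BFC, r.k_on_C * r.conc_C, "cp_arrival"),
        Transition(S.BF, S.DETACHED, r.k_minus_F, "formin_loss"),
        Transition(S.BFC, S.BF, r.kprime_minus_C, "cp_loss"),
        Transition(S.BFC, S.DETACHED, r.kprime_minus_F, "formin_loss"),
        Transition(S.BFC, S.BFCT, r.k_on_T * r.conc_T, "twinfilin_arrival"),
        Transition(S.BFCT, S.BFC, r.k_minus_T_BFCT * (1.0 - r.p_uncap_BFCT),
                   "twinfilin_departure"),
        Transition(S.BFCT, S.BF, r.k_minus_T_BFCT * r.p_uncap_BFCT, "cp_loss"),
        Transition(S.BFCT, S.BCT, r.k_minus_F_BFCT, "formin_loss"),
        Transition(S.B, S.BC, r.k_on_C * r.conc_C, "cp_arrival"),
        Transition(S.BC, S.BCT, r.k_on_T * r.conc_T, "twinfilin_arrival"),
        Transition(S.BC, S.B, r.k_minus_C, "cp_loss"),
        Transition(S.BCT, S.BC, r.k_minus_T * (1.0 - r.p_uncap_BCT),
                   "twinfilin_departure"),
        Transition(S.BCT, S.UNCAPPED_DEPOL, r.k_minus_T * r.p_uncap_BCT, "cp_loss"),
    ]
    assert all(t.source not in ABSORBING_STATES for t in table)
    return table


def total_exit_rate(table: Iterable[Transition], state: BarbedState) -> float:
    """Sum of outgoing propensities of *state* in a transition table."""
    return float(sum(t.propensity for t in table if t.source is state))
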