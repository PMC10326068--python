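"""Barbed-end occupancy states and protein membership.

The observable unit is a single actin-filament barbed end (B) that can be
bound by formin (F), capping protein (C) and twinfilin (T) in the
combinations below.  ``DETACHED`` (filament lost from the field of view
after formin departure) and ``UNCAPPED_DEPOL`` (bare end undergoing
twinfilin-driven depolymerization) are absorbing for the observation model.
"""

from __future__ import annotations

from enum import Enum


class BarbedState(str, Enum):
    """Occupancy state of one filament barbed end."""

    B = "B"
    BF = "BF"
    BC = "BC"
    BCT = "BCT"
    BFC = "BFC"
    BFCT = "BFCT"
    DETACHED = "DETACHED"
    UNCAPPED_DEPOL = "UNCAPPED_DEPOL"


#: States from which no transition leaves (observationally terminal).
ABSORBING_STATES = frozenset({BarbedState.DETACHED, BarbedState.UNCAPPED_DEPOL})

#: Which protein is present in which state. "actin" marks filament
#: visibility (everything except a detached filament).
PROTEIN_STATES = {
    "actin": frozenset(
        {
            BarbedState.B,
            BarbedState.BF,
            BarbedState.BC,
            BarbedState.BCT,
            BarbedState.BFC,
            BarbedState.BFCT,
            BarbedState.UNCAPPED_DEPOL,
        }
    ),
    "formin": frozenset({BarbedState.BF, BarbedState.BFC, BarbedState.BFCT}),
    "CP": frozenset(
        {BarbedState.BC, BarbedState.BCT, BarbedState.BFC, BarbedState.BFCT}
    ),
    "twinfilin": frozenset({BarbedState.BCT, BarbedState.BFCT}),
}

#: Fixed ordering used for array indexing and tie-breaking.
STATE_ORDER = tuple(BarbedState)
STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}


def protein_in_state(protein: str, state: BarbedState) -> bool:
    """Whether *protein* ("actin", "formin", "CP", "twinfilin") occupies *state*."""
    try:
        members = PROTEIN_STATES[protein]
    except KeyError as exc:
        raise ValueError(f"unknown protein/channel {protein!r}") from exc
    return state in members
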