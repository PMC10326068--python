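import numpy as np
import pytest

from bek import BarbedState, RateSet, StateTrajectory


@pytest.fixture
def symmetric_bfc_rates() -> RateSet:
    """Decision-complex-only model with equal route rates (no twinfilin)."""
    return RateSet(kprime_minus_C=0.05, kprime_minus_F=0.05, conc_C=0.0, conc_T=0.0)


@pytest.fixture
def uncapping_rates() -> RateSet:
    """Capped-end model with twinfilin visits and per-visit uncapping."""
    return RateSet(
        conc_T=0.015,
        k_on_T=5.0,
        k_minus_T=1.0 / 1.9,
        p_uncap_BCT=1.0 / 31.0,
        k_minus_C=0.0,
        k_on_C=0.0,
        conc_C=0.0,
    )


def make_trajectory(segments, t_end, filament_id=0) -> StateTrajectory:
    """Build a trajectory from (state-label, entry-time) pairs."""
    segs = [(BarbedState(s), float(t)) for s, t in segments]
    return StateTrajectory(filament_id=filament_id, segments=segs, t_end=float(t_end))
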