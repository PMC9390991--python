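"""Diel light/temperature forcing for hypocotyl growth experiments.

The experimental timeline mirrors the standard seedling protocol: imbibed
seeds receive a 4-h white-light pulse to synchronize germination, followed by
20 h of darkness (both at 22 °C), after which plates are moved to their growth
regime — a square-wave photoperiod at a constant temperature — for a fixed
number of days.  Time ``t`` is measured in hours from the start of the growth
phase, so the synchronization prelude occupies ``t in [-24, 0)``.

Light is a binary square wave: within each 24-h growth-phase cycle the lights
are on during ``[0, photoperiod_h)`` (dawn anchored at the cycle start) and
off during ``[photoperiod_h, 24)``.  ``photoperiod_h = 0`` encodes continuous
darkness (DD) and ``photoperiod_h = 24`` continuous white light (LL/CWL).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

__all__ = [
    "EnvironmentRegime",
    "light_at",
    "temperature_at",
    "transition_times",
    "PRELUDE_START_H",
    "PRELUDE_LIGHT_H",
    "PRELUDE_TEMPERATURE_C",
]

#: Hours before growth-phase start at which the prelude begins.
PRELUDE_START_H = -24.0
#: Duration of the germination-synchronizing light pulse (hours).
PRELUDE_LIGHT_H = 4.0
#: Temperature held throughout the prelude (°C).
PRELUDE_TEMPERATURE_C = 22.0


@dataclass(frozen=True)
class EnvironmentRegime:
    """A photoperiod/temperature schedule for the growth phase.

    Parameters
    ----------
    photoperiod_h
        Hours of light per 24-h cycle, in ``[0, 24]``.
    temperature_C
        Constant temperature during the growth phase (°C).
    duration_days
        Length of the growth phase in days.
    sync_prelude
        Whether the 4-h light + 20-h dark synchronization prelude at 22 °C
        precedes the growth phase.
    """

    photoperiod_h: float
    temperature_C: float
    duration_days: float = 5.0
    sync_prelude: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod_h <= 24.0:
            raise ValueError(
                f"photoperiod_h must lie in [0, 24], got {self.photoperiod_h}"
            )
        if self.duration_days <= 0:
            raise ValueError(f"duration_days must be > 0, got {self.duration_days}")

    @property
    def start_h(self) -> float:
        """First modeled instant (h)."""
        return PRELUDE_START_H if self.sync_prelude else 0.0

    @property
    def end_h(self) -> float:
        """End of the growth phase (h)."""
        return 24.0 * self.duration_days

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "EnvironmentRegime":
        return cls(**json.loads(text))


def _check_time(t: float, regime: EnvironmentRegime) -> None:
    if t < regime.start_h:
        raise ValueError(
            f"t={t} h precedes the modeled timeline (starts at {regime.start_h} h)"
        )


def light_at(t: float, regime: EnvironmentRegime) -> int:
    """Light state (1 = on, 0 = off) at time ``t`` hours.

    Prelude (``t < 0``, when enabled): lights on during ``[-24, -20)``.
    Growth phase: on during ``[0, photoperiod_h)`` of each 24-h cycle
    (half-open window; the dusk instant itself is dark).
    """
    _check_time(t, regime)
    if t < 0.0:
        return 1 if t < PRELUDE_START_H + PRELUDE_LIGHT_H else 0
    tau = t % 24.0
    return 1 if tau < regime.photoperiod_h else 0


def temperature_at(t: float, regime: EnvironmentRegime) -> float:
    """Temperature (°C) at time ``t``: 22 °C during the prelude, the regime
    temperature from ``t = 0`` on (plate transfer is a step, not a ramp)."""
    _check_time(t, regime)
    return PRELUDE_TEMPERATURE_C if t < 0.0 else regime.temperature_C


def transition_times(regime: EnvironmentRegime, horizon: float) -> list[float]:
    """All instants in ``[start, horizon)`` where L(t) or T(t) is discontinuous.

    Returned sorted ascending without duplicates.  The timeline start is not a
    transition; the half-open convention means an event exactly at ``horizon``
    is excluded.
    """
    if horizon <= regime.start_h:
        raise ValueError(f"horizon must exceed {regime.start_h}, got {horizon}")
    D = regime.photoperiod_h
    events: set[float] = set()
    if regime.sync_prelude:
        events.add(PRELUDE_START_H + PRELUDE_LIGHT_H)  # lights off in prelude
        # t = 0: light switches on iff the growth phase starts lit; the
        # temperature steps iff the regime differs from the prelude's 22 °C.
        if D > 0.0 or regime.temperature_C != PRELUDE_TEMPERATURE_C:
            events.add(0.0)
    if 0.0 < D < 24.0:
        k = 0
        while True:
            dawn = 24.0 * k
            dusk = dawn + D
            if dawn >= horizon and dusk >= horizon:
                break
            if k >= 1:
                events.add(dawn)
            events.add(dusk)
            k += 1
    return sorted(e for e in events if regime.start_h < e < horizon)
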