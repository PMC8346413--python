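"""Endurance-time and comfort-time metrics from a simulated trajectory.

The thermal performance of a cold-weather ensemble is expressed as the time
from exposure start until a physiological safety threshold is crossed:

* functional (body) time — reported core temperature reaches 36 C (mild
  hypothermia warning);
* hand / foot endurance — hand / foot skin temperature reaches 5 C (the
  model's hand and foot skin nodes stand for finger and toe);
* exposed-skin endurance — the earliest 5 C crossing among regions with no
  clothing cover;
* comfort time — regional skin wettedness reaches 0.5 (underwear getting
  uncomfortably wet).

Crossings are located by linear interpolation between output samples; a
time beyond the evaluation horizon is reported as the BEYOND_HORIZON
sentinel (infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clothing import REGIONS, RegionalInsulation
from .errors import InputError, ValidationError
from .model import SimulationResult
from .params import SEGMENT_REGION, SEGMENTS, SKIN

#: Sentinel for "threshold never crossed within the horizon".
BEYOND_HORIZON = math.inf

#: Severity order used to break ties among limiting factors.
_PRIORITY = ("functional", "hand", "foot", "exposed_skin", "comfort")


@dataclass(frozen=True)
class Criteria:
    """Physiological thresholds for cold-injury prevention."""

    core_limit: float = 36.0         # C, mild hypothermia
    extremity_limit: float = 5.0     # C, finger/toe/exposed skin
    wettedness_limit: float = 0.5
    horizon: float = 480.0           # min

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in
                   (self.core_limit, self.extremity_limit, self.wettedness_limit)):
            raise ValidationError("criteria limits must be finite")
        if self.horizon <= 0:
            raise ValidationError("horizon must be positive")


@dataclass(frozen=True)
class EnduranceReport:
    """The five guidance times (minutes, or BEYOND_HORIZON) plus the limiter."""

    functional_time: float
    hand_endurance: float
    foot_endurance: float
    exposed_skin_endurance: float
    comfort_time: float
    horizon: float
    limiting_factor: str | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "limiting_factor", self._limiter())

    def _times(self) -> dict[str, float]:
        return {
            "functional": self.functional_time,
            "hand": self.hand_endurance,
            "foot": self.foot_endurance,
            "exposed_skin": self.exposed_skin_endurance,
            "comfort": self.comfort_time,
        }

    def _limiter(self) -> str | None:
        finite = {k: v for k, v in self._times().items() if math.isfinite(v)}
        if not finite:
            return None
        best = min(finite.values())
        for name in _PRIORITY:  # severity order breaks ties
            if name in finite and finite[name] == best:
                return name
        return None

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {
            k: (round(v, 1) if math.isfinite(v) else "beyond_horizon")
            for k, v in self._times().items()
        }
        out["limiting_factor"] = self.limiting_factor or "none"
        out["horizon_min"] = self.horizon
        return out

    def format_minutes(self, value: float) -> str:
        return f"{value:.1f}" if math.isfinite(value) else f"> {self.horizon:.0f} (beyond horizon)"


def first_crossing(times: Sequence[float], values: Sequence[float],
                   threshold: float, direction: str = "falling") -> float:
    """Minutes to the first threshold crossing, linearly interpolated.

    Returns 0.0 if the first sample already violates the threshold and
    BEYOND_HORIZON if the series never crosses.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0 or v.size == 0:
        raise InputError("empty series")
    if t.size != v.size:
        raise InputError(f"times ({t.size}) and values ({v.size}) differ in length")
    if not np.all(np.isfinite(v)):
        raise InputError("series contains non-finite values")
    if direction == "rising":
        return first_crossing(t, -v, -threshold, "falling")
    if direction != "falling":
        raise InputError(f"direction must be 'falling' or 'rising', got {direction!r}")

    if v[0] < threshold:
        return 0.0
    below = v < threshold
    if not below.any():
        return BEYOND_HORIZON
    i = int(np.argmax(below))  # first sample strictly below
    t0, t1 = t[i - 1], t[i]
    v0, v1 = v[i - 1], v[i]
    if v0 == v1:  # flat segment at the threshold; crossing at its start
        return float(t0)
    return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))


def endurance_report(result: SimulationResult, insulation: RegionalInsulation,
                     criteria: Criteria | None = None) -> EnduranceReport:
    """Apply the physiological criteria to a simulated trajectory."""
    criteria = criteria or Criteria()
    times = result.times
    if times[-1] < criteria.horizon - 1e-9:
        raise InputError(
            f"simulation covers {times[-1]:.0f} min but the horizon is "
            f"{criteria.horizon:.0f} min; run a longer simulation")
    mask = times <= criteria.horizon + 1e-9
    t = times[mask]

    def cross(series: np.ndarray, threshold: float, direction: str = "falling") -> float:
        return first_crossing(t, series[mask], threshold, direction)

    functional = cross(result.core, criteria.core_limit)
    hand = cross(result.series("hand", "skin"), criteria.extremity_limit)
    foot = cross(result.series("foot", "skin"), criteria.extremity_limit)

    exposed = BEYOND_HORIZON
    for i, seg in enumerate(SEGMENTS):
        region = SEGMENT_REGION[seg]
        if not insulation.covered[region]:
            exposed = min(exposed, cross(result.temps[:, i, SKIN],
                                         criteria.extremity_limit))

    comfort = cross(result.wettedness.max(axis=1), criteria.wettedness_limit,
                    direction="rising")

    return EnduranceReport(
        functional_time=functional, hand_endurance=hand, foot_endurance=foot,
        exposed_skin_endurance=exposed, comfort_time=comfort,
        horizon=criteria.horizon)
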