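"""Oscillating temperature/density schedules for nanoreactor sampling.

Both the temperature and the density program follow the same functional
form: a linear ramp from ``start`` to ``end`` over the full schedule
duration plus a squared-sine oscillation,

    v(t) = start + (t / t_max) * (end - start) + amp * sin²(t / t_per)

with the sine argument in radians.  Random nanoreactor simulations draw
each coefficient uniformly from a :class:`SchedulePolicy` range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Densities below this value (g/cc) are clamped before use: the sampled
#: training data is not trustworthy in the near-gas-phase limit and zero or
#: negative densities are unphysical.
DENSITY_FLOOR = 0.05


@dataclass(frozen=True)
class ScheduleParams:
    """Coefficients of one oscillating schedule (temperature K or density g/cc)."""

    start: float
    end: float
    amp: float
    t_per: float  # period scale, fs (sin argument is t/t_per radians)
    t_max: float  # total schedule duration, fs

    def __post_init__(self) -> None:
        if self.t_per <= 0 or self.t_max <= 0:
            raise ValueError("t_per and t_max must be positive")
        if self.amp < 0:
            raise ValueError("amp must be non-negative")
        if self.start <= 0 or self.end <= 0:
            raise ValueError("start/end must be positive (T in K, density in g/cc)")


def oscillating_value(t: float, p: ScheduleParams) -> float:
    """Evaluate the schedule at time ``t`` (fs); ``t`` must lie in [0, t_max]."""
    if not (0.0 <= t <= p.t_max):
        raise ValueError(f"t={t} outside schedule range [0, {p.t_max}]")
    return p.start + (t / p.t_max) * (p.end - p.start) + p.amp * math.sin(t / p.t_per) ** 2


def density_at(t: float, p: ScheduleParams) -> float:
    """Density schedule value with the low-density clamp applied."""
    return max(oscillating_value(t, p), DENSITY_FLOOR)


@dataclass(frozen=True)
class SchedulePolicy:
    """Per-parameter uniform ranges for random schedule draws.

    Defaults straddle the case-study conditions (temperatures of a few
    hundred to a few thousand K, condensed-phase densities); they are
    declared configuration, not inferred values.  Density *starts* stay at
    or below 1.0 g/cc so freshly packed boxes are geometrically feasible
    under the 2 Å molecule-separation rule; higher condensed-phase
    densities are reached dynamically through the ramp and oscillation.
    """

    t_start_range: tuple[float, float] = (300.0, 3000.0)
    t_end_range: tuple[float, float] = (300.0, 3000.0)
    t_amp_range: tuple[float, float] = (0.0, 1000.0)
    rho_start_range: tuple[float, float] = (0.3, 1.0)
    rho_end_range: tuple[float, float] = (0.3, 2.0)
    rho_amp_range: tuple[float, float] = (0.0, 0.5)
    t_per_range: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self) -> None:
        for name in (
            "t_start_range",
            "t_end_range",
            "t_amp_range",
            "rho_start_range",
            "rho_end_range",
            "rho_amp_range",
            "t_per_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")


def draw_schedule(
    policy: SchedulePolicy, rng: np.random.Generator, t_max: float
) -> tuple[ScheduleParams, ScheduleParams]:
    """Draw a (temperature, density) schedule pair sharing ``t_max``."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    temp = ScheduleParams(
        start=rng.uniform(*policy.t_start_range),
        end=rng.uniform(*policy.t_end_range),
        amp=rng.uniform(*policy.t_amp_range),
        t_per=rng.uniform(*policy.t_per_range),
        t_max=t_max,
    )
    dens = ScheduleParams(
        start=rng.uniform(*policy.rho_start_range),
        end=rng.uniform(*policy.rho_end_range),
        amp=rng.uniform(*policy.rho_amp_range),
        t_per=rng.uniform(*policy.t_per_range),
        t_max=t_max,
    )
    return temp, dens


def schedule_to_dict(p: ScheduleParams) -> dict[str, float]:
    return {"start": p.start, "end": p.end, "amp": p.amp, "t_per": p.t_per, "t_max": p.t_max}


def schedule_from_dict(d: dict[str, float]) -> ScheduleParams:
    return ScheduleParams(**{k: float(d[k]) for k in ("start", "end", "amp", "t_per", "t_max")})
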