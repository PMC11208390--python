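"""Counts -> activity self-calibration and the time-integrated activity map.

For microspheres permanently trapped in tissue only physical decay matters,
so the number of decays in a voxel over all time is

    TIA = integral_0^inf A(t) dt = A(0) / lambda = A(T) e^(lambda T) / lambda

with ``A(T)`` the voxel activity at acquisition time ``T`` and ``lambda``
the physical decay constant (ln 2 / t_half).  Other isotopes are supported
by swapping :class:`DecayParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ROLE_ACTIVITY, ROLE_TIA, VoxelGrid
from .physics import Y90_HALF_LIFE_H

_SECONDS_PER_HOUR = 3600.0


def decay_constant(half_life_h: float) -> float:
    """Decay constant in 1/s from a half-life in hours."""
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    return float(np.log(2.0) / (half_life_h * _SECONDS_PER_HOUR))


@dataclass(frozen=True)
class DecayParams:
    """Physical decay data of the isotope (half-life in hours)."""

    half_life_h: float = Y90_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")

    @property
    def decay_constant_per_s(self) -> float:
        return decay_constant(self.half_life_h)


@dataclass(frozen=True)
class CalibrationContext:
    """Administered activity (Bq) and the administration-to-acquisition
    interval (hours) used for self-calibration."""

    administered_bq: float
    interval_h: float = 0.0

    def __post_init__(self) -> None:
        if self.administered_bq <= 0:
            raise ValueError("administered activity must be positive")
        if self.interval_h < 0:
            raise ValueError("interval must be >= 0")


def self_calibrate(counts: VoxelGrid, ctx: CalibrationContext,
                   decay: DecayParams = DecayParams()) -> VoxelGrid:
    """Convert a counts image to activity (Bq) by self-calibration.

    The calibration factor is the administered activity, decay-corrected to
    the acquisition start time, divided by the total counts; voxel activity
    is counts times that factor, so the calibrated image integrates exactly
    to the decay-corrected therapy activity.
    """
    total = float(counts.values.sum())
    if total <= 0:
        raise ValueError("counts grid sums to zero; cannot self-calibrate")
    lam = decay.decay_constant_per_s
    a_at_t = ctx.administered_bq * np.exp(-lam * ctx.interval_h * _SECONDS_PER_HOUR)
    return counts.with_values(counts.values * (a_at_t / total), ROLE_ACTIVITY)


def tia_map(activity: VoxelGrid, interval_h: float = 0.0,
            decay: DecayParams = DecayParams()) -> VoxelGrid:
    """Time-integrated activity (decays) from an activity map at time T.

    Per voxel ``TIA = A(T) e^(lambda T) / lambda`` with lambda in 1/s and A
    in Bq, i.e. the decays accumulated from administration to infinity under
    pure physical decay.
    """
    if interval_h < 0:
        raise ValueError("interval must be >= 0")
    if np.any(activity.values < 0):
        raise ValueError("activity must be non-negative")
    lam = decay.decay_constant_per_s
    factor = np.exp(lam * interval_h * _SECONDS_PER_HOUR) / lam
    return activity.with_values(activity.values * factor, ROLE_TIA)
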