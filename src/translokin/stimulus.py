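"""Piecewise-constant stimulation profiles and per-region exposure schedules.

A stimulation profile is the input concentration ``C(t)`` seen by one region
of a tissue explant: a square wave (or a constant) of dexamethasone (DEX)
concentration in µM, held piecewise constant between breakpoints. Profiles
use the right-open interval convention ``[t_i, t_{i+1})`` so that sampling is
single-valued at every breakpoint; a profile built from period/duty-cycle
parameters always starts in the ON phase.

The laminar-interface position in a co-flow channel follows the flow-rate
split between the DEX and carrier (DFA) streams: for equal-viscosity,
equal-height streams the interface sits at ``width * Q_dex / Q_total`` from
the DEX-side wall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidArgumentError, OutOfRangeError

__all__ = [
    "StimulusProfile",
    "RegionSchedule",
    "make_continuous",
    "make_periodic",
    "sample",
    "interface_position",
]


@dataclass(frozen=True)
class StimulusProfile:
    """A piecewise-constant concentration profile C(t).

    Parameters
    ----------
    breakpoints
        Strictly increasing times in minutes, starting at 0 and ending at
        the total duration. There is one more breakpoint than there are
        levels.
    levels
        Concentration (µM) on each interval ``[breakpoints[i],
        breakpoints[i+1])``. Nonnegative.
    """

    breakpoints: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        if bp.size < 2:
            raise InvalidArgumentError("need at least two breakpoints")
        if bp[0] != 0.0:
            raise InvalidArgumentError("breakpoints must start at 0")
        if np.any(np.diff(bp) <= 0):
            raise InvalidArgumentError("breakpoints must be strictly increasing")
        if lv.size != bp.size - 1:
            raise InvalidArgumentError(
                f"{lv.size} levels for {bp.size - 1} intervals"
            )
        if np.any(lv < 0):
            raise InvalidArgumentError("concentration levels must be nonnegative")
        object.__setattr__(self, "breakpoints", tuple(float(t) for t in bp))
        object.__setattr__(self, "levels", tuple(float(c) for c in lv))

    @property
    def duration(self) -> float:
        """Total profile duration in minutes."""
        return self.breakpoints[-1]

    def sample(self, t: float | np.ndarray) -> float | np.ndarray:
        """Concentration at time ``t`` (right-open interval convention).

        ``t == duration`` returns the final level; times outside
        ``[0, duration]`` raise :class:`OutOfRangeError`.
        """
        arr = np.asarray(t, dtype=float)
        if np.any(arr < 0) or np.any(arr > self.duration):
            raise OutOfRangeError(
                f"sample time outside [0, {self.duration}] min"
            )
        bp = np.asarray(self.breakpoints)
        idx = np.searchsorted(bp, arr, side="right") - 1
        idx = np.clip(idx, 0, len(self.levels) - 1)
        out = np.asarray(self.levels)[idx]
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out

    def time_average(self) -> float:
        """Duration-weighted mean concentration (exact, closed form)."""
        widths = np.diff(self.breakpoints)
        return float(np.dot(widths, self.levels) / self.duration)

    def scaled(self, factor: float) -> "StimulusProfile":
        """Profile with every level multiplied by ``factor`` (≥ 0)."""
        if factor < 0:
            raise InvalidArgumentError("scale factor must be nonnegative")
        return StimulusProfile(self.breakpoints, tuple(c * factor for c in self.levels))

    def to_json(self) -> str:
        return json.dumps(
            {
                "breakpoints": list(self.breakpoints),
                "levels": list(self.levels),
                "duration": self.duration,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusProfile":
        obj = json.loads(text)
        prof = cls(tuple(obj["breakpoints"]), tuple(obj["levels"]))
        if "duration" in obj and not np.isclose(obj["duration"], prof.duration):
            raise InvalidArgumentError("stated duration disagrees with breakpoints")
        return prof


def make_continuous(c0: float, duration: float) -> StimulusProfile:
    """Constant-concentration profile: continuous stimulation (CS).

    ``c0 = 0`` yields the no-stimulation (NS) profile.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if c0 < 0:
        raise InvalidArgumentError("concentration must be nonnegative")
    return StimulusProfile((0.0, float(duration)), (float(c0),))


def make_periodic(
    c0: float, period: float, duty: float, duration: float
) -> StimulusProfile:
    """Square-wave profile: periodic stimulation (PS) starting in the ON phase.

    The region sees ``c0`` for the first ``duty * period`` of each period and
    0 for the remainder. Over an integer number of periods the ON fraction of
    total time is exactly ``duty``. ``duty`` of 0 or 1 degenerates to a
    constant profile.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if period <= 0:
        raise InvalidArgumentError("period must be positive")
    if not 0.0 <= duty <= 1.0:
        raise InvalidArgumentError("duty cycle must lie in [0, 1]")
    if c0 < 0:
        raise InvalidArgumentError("concentration must be nonnegative")
    if duty == 0.0 or c0 == 0.0:
        return make_continuous(0.0, duration)
    if duty == 1.0:
        return make_continuous(c0, duration)

    breakpoints: list[float] = [0.0]
    levels: list[float] = []
    t = 0.0
    on = duty * period
    while t < duration - 1e-12:
        t_on_end = min(t + on, duration)
        breakpoints.append(t_on_end)
        levels.append(c0)
        if t_on_end >= duration - 1e-12:
            break
        t_off_end = min(t + period, duration)
        breakpoints.append(t_off_end)
        levels.append(0.0)
        t = t + period
    breakpoints[-1] = float(duration)
    return StimulusProfile(tuple(breakpoints), tuple(levels))


def sample(profile: StimulusProfile, t: float | np.ndarray) -> float | np.ndarray:
    """Functional alias for :meth:`StimulusProfile.sample`."""
    return profile.sample(t)


def interface_position(q_dex: float, q_total: float, width: float) -> float:
    """Lateral laminar-interface position from the flow-rate split.

    For two co-flowing streams of equal viscosity and height, the interface
    sits at ``width * q_dex / q_total`` measured from the DEX-side wall
    (µm for ``width`` in µm; flow rates in any common unit). An equal split
    puts the interface mid-channel, exposing half the explant.
    """
    if q_total <= 0:
        raise InvalidArgumentError("total flow rate must be positive")
    if q_dex < 0 or q_dex > q_total:
        raise InvalidArgumentError("require 0 <= q_dex <= q_total")
    if width <= 0:
        raise InvalidArgumentError("channel width must be positive")
    return width * q_dex / q_total


REGION_LABELS = ("CS", "PS", "NS")


@dataclass(frozen=True)
class RegionSchedule:
    """Exposure schedule of one explant split into stimulation regions.

    Maps region labels (conventionally CS = continuous stimulation,
    PS = periodic, NS = none) to their concentration profiles, with an
    optional piecewise-constant schedule of the laminar-interface lateral
    position over time. Invariants enforced on the conventional labels:
    CS is constant at its amplitude, NS is identically zero.
    """

    profiles: Mapping[str, StimulusProfile]
    interface_schedule: StimulusProfile | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise InvalidArgumentError("schedule needs at least one region")
        for label, prof in self.profiles.items():
            if label == "CS" and len(set(prof.levels)) != 1:
                raise InvalidArgumentError("CS profile must be constant")
            if label == "NS" and any(c != 0 for c in prof.levels):
                raise InvalidArgumentError("NS profile must be identically zero")
        object.__setattr__(self, "profiles", dict(self.profiles))

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.profiles)

    @property
    def duration(self) -> float:
        return max(p.duration for p in self.profiles.values())

    def __getitem__(self, label: str) -> StimulusProfile:
        try:
            return self.profiles[label]
        except KeyError:
            raise InvalidArgumentError(f"unknown region label {label!r}") from None

    @classmethod
    def three_region(
        cls, c0: float, period: float, duty: float, duration: float
    ) -> "RegionSchedule":
        """The canonical CS / PS / NS split of a single explant."""
        return cls(
            {
                "CS": make_continuous(c0, duration),
                "PS": make_periodic(c0, period, duty, duration),
                "NS": make_continuous(0.0, duration),
            }
        )


def parse_stim_shorthand(text: str) -> StimulusProfile:
    """Parse CLI shorthand like ``periodic:C0=25,T=10,duty=0.5,dur=120``.

    Supported kinds: ``continuous:C0=...,dur=...`` and
    ``periodic:C0=...,T=...,duty=...,dur=...``.
    """
    try:
        kind, _, rest = text.partition(":")
        kv = dict(item.split("=") for item in rest.split(",") if item)
        params = {k.strip(): float(v) for k, v in kv.items()}
    except (ValueError, AttributeError) as exc:
        raise InvalidArgumentError(f"cannot parse stimulus shorthand {text!r}") from exc
    if kind == "continuous":
        return make_continuous(params["C0"], params["dur"])
    if kind == "periodic":
        return make_periodic(params["C0"], params["T"], params["duty"], params["dur"])
    raise InvalidArgumentError(f"unknown stimulus kind {kind!r}")
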