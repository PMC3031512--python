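"""First-order kinetic model of reporter nuclear accumulation.

The state variable is the normalized intensity-ratio differential

    y(t) = R(t)/R(0) - 1,

where R is the nuclear-to-cytoplasm fluorescence intensity ratio. y obeys

    tau * dy/dt + y = K * C(t),        y(0) = 0,

with C(t) the stimulating hormone concentration (µM), ``tau`` the single
transport time constant (min; import and export are assumed symmetric) and
``K`` the steady-state gain of y per unit concentration (per µM). Under a
concentration step C the solution is the saturating exponential
``y = K*C*(1 - exp(-t/tau))``.

Because C(t) is piecewise constant, the exact solution is available on every
interval: within an interval at level C_i,

    y(t0 + dt) = K*C_i + (y(t0) - K*C_i) * exp(-dt/tau).

Simulation uses this exponential update exclusively, so results are
deterministic and free of step-size error; generic ODE integrators appear
only as independent test oracles.

In the frequency domain the model is the low-pass filter
``G(s) = K / (tau*s + 1)``. Two corner-frequency conventions are exposed:
the "standard" engineering convention 1/(2*pi*tau) in cycle/min, and a
a "natural" convention that labels omega_c = 1/tau directly in cycle/min
(for tau = 16.6 min this reads 0.06 cycle/min, i.e. 16.6 min/cycle); the
matching transfer-magnitude mode replaces 2*pi*f*tau by f*tau. Both are
computed and labelled rather than silently picking one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .stimulus import StimulusProfile

__all__ = [
    "TranslocationModel",
    "ResponseTrace",
    "FrequencyResponse",
    "step_response",
    "simulate",
    "transfer_magnitude",
    "corner_frequency",
    "half_time",
    "frequency_response",
    "steady_state_ripple",
]

Convention = Literal["natural", "standard"]


@dataclass(frozen=True)
class TranslocationModel:
    """Parameters of the first-order translocation model.

    Parameters
    ----------
    tau
        Time constant in minutes (> 0). Governs both nuclear import and, by
        the symmetric-transport assumption, export.
    k
        Steady-state gain of the normalized intensity-ratio differential per
        µM of stimulus (> 0).
    tau_export
        Optional distinct export time constant (min), applied on intervals
        where y relaxes downward. Defaults to ``tau`` (symmetric transport).
    """

    tau: float
    k: float
    tau_export: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InvalidArgumentError("tau must be positive")
        if self.k <= 0:
            raise InvalidArgumentError("K must be positive")
        if self.tau_export is not None and self.tau_export <= 0:
            raise InvalidArgumentError("tau_export must be positive")

    @property
    def export_tau(self) -> float:
        return self.tau if self.tau_export is None else self.tau_export

    def to_json_dict(self) -> dict:
        return {"tau_min": self.tau, "K_per_uM": self.k}

    @classmethod
    def from_json_dict(cls, obj: dict) -> "TranslocationModel":
        return cls(tau=obj["tau_min"], k=obj["K_per_uM"])


@dataclass(frozen=True)
class ResponseTrace:
    """A simulated or measured response y(t) started at rest (y(0) = 0)."""

    times: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape:
            raise InvalidArgumentError("times and y must have equal length")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise InvalidArgumentError("times must be sorted")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "y", y)

    @property
    def r_norm(self) -> np.ndarray:
        """Normalized intensity ratio, y + 1."""
        return self.y + 1.0

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "y": self.y, "R_norm": self.r_norm}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseTrace":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["y"].to_numpy())


def step_response(
    model: TranslocationModel, c: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form response to a concentration step of height ``c`` µM.

    y(t) = K*C*(1 - exp(-t/tau)); zero at t = 0, asymptote K*C.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise InvalidArgumentError("time must be nonnegative")
    if c < 0:
        raise InvalidArgumentError("concentration must be nonnegative")
    out = model.k * c * (1.0 - np.exp(-arr / model.tau))
    return float(out) if arr.ndim == 0 else out


def simulate(
    model: TranslocationModel,
    profile: StimulusProfile,
    sample_times: Sequence[float] | np.ndarray,
) -> ResponseTrace:
    """Exact solution of the model under a piecewise-constant input.

    Propagates y across each constant-concentration interval with the exact
    exponential update and reads out at ``sample_times`` (sorted, within
    [0, duration]). An empty ``sample_times`` yields an empty trace.
    """
    ts = np.asarray(sample_times, dtype=float)
    if ts.size == 0:
        return ResponseTrace(np.empty(0), np.empty(0))
    if np.any(np.diff(ts) < 0):
        raise InvalidArgumentError("sample_times must be sorted")
    if ts[0] < 0 or ts[-1] > profile.duration + 1e-9:
        raise InvalidArgumentError("sample_times must lie within [0, duration]")

    bp = np.asarray(profile.breakpoints)
    levels = np.asarray(profile.levels)
    out = np.empty_like(ts)
    y = 0.0
    j = 0  # cursor into ts
    for i in range(levels.size):
        t0, t1 = bp[i], bp[i + 1]
        target = model.k * levels[i]
        tau = model.tau if target >= y else model.export_tau
        # read out samples falling in [t0, t1); the final time t == duration
        # belongs to the last interval
        last = i == levels.size - 1
        while j < ts.size and (ts[j] < t1 or (last and ts[j] <= t1 + 1e-9)):
            out[j] = target + (y - target) * math.exp(-(ts[j] - t0) / tau)
            j += 1
        y = target + (y - target) * math.exp(-(t1 - t0) / tau)
    return ResponseTrace(ts, out)


def transfer_magnitude(
    model: TranslocationModel,
    f: float | np.ndarray,
    convention: Convention = "standard",
) -> float | np.ndarray:
    """Magnitude of the transfer function at frequency ``f`` (cycle/min).

    ``standard``: |G(j*2*pi*f)| = K / sqrt(1 + (2*pi*f*tau)^2).
    ``natural``: the plotting convention with f*tau in place of 2*pi*f*tau,
    under which the magnitude reaches K/sqrt(2) at f = 1/tau.
    """
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0):
        raise InvalidArgumentError("frequency must be nonnegative")
    if convention == "standard":
        omega_tau = 2.0 * np.pi * arr * model.tau
    elif convention == "natural":
        omega_tau = arr * model.tau
    else:
        raise InvalidArgumentError(f"unknown convention {convention!r}")
    out = model.k / np.sqrt(1.0 + omega_tau**2)
    return float(out) if arr.ndim == 0 else out


def corner_frequency(
    model: TranslocationModel, convention: Convention = "natural"
) -> float:
    """Low-pass cutoff in cycle/min.

    ``natural`` labels omega_c = 1/tau directly in cycle/min (0.06 for
    tau = 16.6 min, equivalently tau min/cycle); ``standard`` is the -3 dB
    frequency 1/(2*pi*tau).
    """
    if convention == "natural":
        return 1.0 / model.tau
    if convention == "standard":
        return 1.0 / (2.0 * np.pi * model.tau)
    raise InvalidArgumentError(f"unknown convention {convention!r}")


def half_time(model: TranslocationModel) -> float:
    """Time (min) for the step response to reach half its steady state: tau*ln 2."""
    return model.tau * math.log(2.0)


@dataclass(frozen=True)
class FrequencyResponse:
    """Tabulated |G(f)| with the cutoff in both labelling conventions."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    corner_frequency: float  # natural labelling, 1/tau cycle/min
    corner_frequency_standard: float  # 1/(2*pi*tau) cycle/min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f_cycle_per_min": self.frequencies, "magnitude": self.magnitudes}
        )


def frequency_response(
    model: TranslocationModel,
    frequencies: Sequence[float] | np.ndarray,
    convention: Convention = "standard",
) -> FrequencyResponse:
    freqs = np.asarray(frequencies, dtype=float)
    mags = transfer_magnitude(model, freqs, convention=convention)
    return FrequencyResponse(
        frequencies=freqs,
        magnitudes=np.asarray(mags),
        corner_frequency=corner_frequency(model, "natural"),
        corner_frequency_standard=corner_frequency(model, "standard"),
    )


def steady_state_ripple(
    model: TranslocationModel, c0: float, period: float, duty: float
) -> float:
    """Peak-to-trough ripple of y in the periodic steady state.

    For a square wave of amplitude ``c0``, period ``T`` and duty ``d`` the
    limit cycle oscillates between

        y_max = K*C0 * (1 - exp(-d*T/tau)) / (1 - exp(-T/tau))
        y_min = y_max * exp(-(1-d)*T/tau)

    so the ripple is
    K*C0 * (1 - exp(-d*T/tau)) * (1 - exp(-(1-d)*T/tau)) / (1 - exp(-T/tau)).
    Monotone increasing in T; vanishes as T/tau -> 0.
    """
    if period <= 0:
        raise InvalidArgumentError("period must be positive")
    if not 0.0 <= duty <= 1.0:
        raise InvalidArgumentError("duty must lie in [0, 1]")
    if duty in (0.0, 1.0):
        return 0.0
    a = duty * period / model.tau
    b = (1.0 - duty) * period / model.tau
    return (
        model.k
        * c0
        * (1.0 - math.exp(-a))
        * (1.0 - math.exp(-b))
        / (1.0 - math.exp(-(a + b)))
    )
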