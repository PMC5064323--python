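"""Retinal drive for fixation and microsaccade protocols.

A trial has three phases:

1. a dark settling period of ``settle_ms`` before ``t = 0`` (no drive), so
   the network starts each trial from its quiescent state;
2. fixation onset at ``t = 0``: a Gaussian bump of optical strength appears,
   centered on the fixation position ``x_f``;
3. microsaccades: each event at time ``t_n`` instantaneously displaces the
   bump by its signed magnitude ``M_n`` along the ring.

Displacements accumulate and the bump center is always wrapped back onto
``[-L, L)``, consistent with the periodic boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .params import LayerGeometry, ModelParams, circular_distance, wrap_position

__all__ = [
    "MicrosaccadeCommand",
    "StimulusProtocol",
    "stimulus_profile",
    "drive_at_time",
    "center_at_time",
    "single_microsaccade_protocol",
]


@dataclass(frozen=True)
class MicrosaccadeCommand:
    """One microsaccade: onset time ``t`` (ms) and signed magnitude ``M``."""

    t: float
    M: float


@dataclass(frozen=True)
class StimulusProtocol:
    """Fixation position, microsaccade events, and trial timing.

    ``settle_ms`` is the dark period simulated before the fixation onset at
    ``t = 0``; ``duration_ms`` is the simulated time after onset.  Event
    times are relative to fixation onset.
    """

    x_f: float = 0.0
    events: tuple[MicrosaccadeCommand, ...] = field(default_factory=tuple)
    settle_ms: float = 500.0
    duration_ms: float = 3000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.t for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration_ms):
            raise ValueError("event times must lie within [0, duration_ms]")
        if self.settle_ms < 0 or self.duration_ms <= 0:
            raise ValueError("settle_ms must be >= 0 and duration_ms > 0")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "x_f": self.x_f,
            "settle_ms": self.settle_ms,
            "duration_ms": self.duration_ms,
            "events": [{"t": e.t, "M": e.M} for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        events = tuple(MicrosaccadeCommand(float(e["t"]), float(e["M"]))
                       for e in d.get("events", []))
        return cls(x_f=float(d.get("x_f", 0.0)), events=events,
                   settle_ms=float(d.get("settle_ms", 500.0)),
                   duration_ms=float(d.get("duration_ms", 3000.0)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stimulus_profile(center: float, params: ModelParams,
                     geometry: LayerGeometry) -> np.ndarray:
    """Gaussian optical-strength profile of the fixated dot.

    ``O_k = A exp(-d(x_k, center)^2 / (2 sigma_O^2))`` with ``d`` the
    circular distance.  Strictly positive everywhere, peak value ``A`` at
    the center.
    """
    d = circular_distance(geometry.positions_retina,
                          wrap_position(center, params.L), params.L)
    return params.A * np.exp(-d ** 2 / (2.0 * params.sigma_O ** 2))


def center_at_time(t: float, protocol: StimulusProtocol, L: float) -> float:
    """Stimulus center at time ``t``: fixation plus accumulated displacements.

    Events are applied at ``t >= t_event`` (the displacement is instantaneous
    at the event time); the result is wrapped onto the ring.
    """
    c = protocol.x_f + sum(e.M for e in protocol.events if e.t <= t)
    return float(wrap_position(c, L))


def drive_at_time(t: float, protocol: StimulusProtocol, params: ModelParams,
                  geometry: LayerGeometry) -> np.ndarray:
    """Retinal input vector ``O_k`` at time ``t`` (ms, relative to onset).

    Zero during the dark settling period (``t < 0``); afterwards a Gaussian
    bump whose center follows the microsaccade sequence piecewise constantly.
    """
    if t < 0:
        return np.zeros(params.N)
    return stimulus_profile(center_at_time(t, protocol, params.L),
                            params, geometry)


def single_microsaccade_protocol(M: float, TI: float, params: ModelParams,
                                 x_f: float = 0.0, post_ms: float = 2000.0,
                                 settle_ms: float = 500.0) -> StimulusProtocol:
    """Fixation onset at ``t = 0`` and one microsaccade at ``t = TI``.

    The trial continues for ``post_ms`` after the event (default 2000 ms,
    ten STD recovery time constants, so the response has decayed back to
    the fixation steady state by the end of the trace).
    """
    if TI <= 0:
        raise ValueError("TI must be strictly positive")
    if abs(M) >= 2 * params.L:
        raise ValueError("|M| must be smaller than the ring circumference")
    events = (MicrosaccadeCommand(t=float(TI), M=float(M)),)
    return StimulusProtocol(x_f=x_f, events=events, settle_ms=settle_ms,
                            duration_ms=float(TI) + float(post_ms))
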