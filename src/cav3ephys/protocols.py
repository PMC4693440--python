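"""Voltage-clamp command protocols.

A protocol is a per-sweep sequence of constant-voltage segments; one segment's
level varies across sweeps (the step family).  Two concrete protocols are
provided:

* activation: holding -60 mV -> hyperpolarizing prepulse -100 mV -> test steps
  (-90 .. +30 mV, 10 mV increments by default);
* steady-state inactivation: holding -60 mV -> incremental prepulses
  (-120 .. -40 mV) -> fixed test step to -30 mV.

The prepulse duration defaults to 300 ms; 500 ms is equally supported via the
``prepulse_ms`` argument (both durations appear in published descriptions of
this protocol family and the package asserts neither).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Segment",
    "VoltageProtocol",
    "activation_protocol",
    "inactivation_protocol",
]

DEFAULT_SAMPLING_HZ = 20_000.0


@dataclass(frozen=True)
class Segment:
    level_mv: float
    duration_ms: float

    def __post_init__(self) -> None:
        if not (self.duration_ms > 0):
            raise ValueError(f"segment duration must be > 0 ms, got {self.duration_ms}")
        if not np.isfinite(self.level_mv):
            raise ValueError("segment level must be finite")


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant command with one sweep-varying segment.

    ``segments`` holds the template (the varying segment's level is a
    placeholder); ``sweep_segment_index`` says which segment varies and
    ``sweep_levels_mv`` lists its per-sweep values.
    """

    segments: tuple[Segment, ...]
    sweep_segment_index: int
    sweep_levels_mv: tuple[float, ...]
    sampling_rate_hz: float = DEFAULT_SAMPLING_HZ
    label: str = "protocol"

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol needs at least one segment")
        if not (0 <= self.sweep_segment_index < len(self.segments)):
            raise ValueError(
                f"sweep_segment_index {self.sweep_segment_index} does not index a segment"
            )
        if len(self.sweep_levels_mv) == 0:
            raise ValueError("sweep level list is empty")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling rate must be > 0 Hz")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_levels_mv)

    def sweep_segments(self, sweep_id: int) -> tuple[Segment, ...]:
        """Concrete segments of one sweep with the varying level substituted."""
        level = self.sweep_levels_mv[sweep_id]
        return tuple(
            Segment(level, s.duration_ms) if i == self.sweep_segment_index else s
            for i, s in enumerate(self.segments)
        )

    def segment_sample_count(self, segment: Segment) -> int:
        # round(duration * rate); timestamps are left-aligned at segment start
        return int(round(segment.duration_ms * self.sampling_rate_hz / 1000.0))

    def samples_per_sweep(self) -> int:
        return sum(self.segment_sample_count(s) for s in self.segments)

    def segment_bounds_ms(self) -> list[tuple[float, float]]:
        """(start, end) time in ms of each segment within a sweep."""
        bounds, t = [], 0.0
        for s in self.segments:
            bounds.append((t, t + s.duration_ms))
            t += s.duration_ms
        return bounds

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "sampling_rate_hz": self.sampling_rate_hz,
            "sweep_segment_index": self.sweep_segment_index,
            "sweep_levels_mv": list(self.sweep_levels_mv),
            "segments": [{"level_mv": s.level_mv, "duration_ms": s.duration_ms} for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            segments=tuple(Segment(s["level_mv"], s["duration_ms"]) for s in d["segments"]),
            sweep_segment_index=int(d["sweep_segment_index"]),
            sweep_levels_mv=tuple(float(v) for v in d["sweep_levels_mv"]),
            sampling_rate_hz=float(d["sampling_rate_hz"]),
            label=str(d["label"]),
        )


def _default_steps(start: float, stop: float, inc: float = 10.0) -> tuple[float, ...]:
    n = int(round((stop - start) / inc)) + 1
    return tuple(start + i * inc for i in range(n))


def activation_protocol(
    holding_mv: float = -60.0,
    prepulse_mv: float = -100.0,
    prepulse_ms: float = 300.0,
    step_levels_mv=None,
    step_ms: float = 150.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_HZ,
    holding_ms: float = 20.0,
) -> VoltageProtocol:
    """Activation (I–V) protocol: holding -> hyperpolarizing prepulse -> step.

    The prepulse to -100 mV removes resting inactivation so the test steps
    probe activation.  Defaults: steps -90..+30 mV in 10 mV increments,
    150 ms test step, 20 kHz sampling.
    """
    if step_levels_mv is None:
        step_levels_mv = _default_steps(-90.0, 30.0)
    step_levels_mv = tuple(float(v) for v in step_levels_mv)
    if len(step_levels_mv) == 0:
        raise ValueError("step level list is empty")
    return VoltageProtocol(
        segments=(
            Segment(holding_mv, holding_ms),
            Segment(prepulse_mv, prepulse_ms),
            Segment(step_levels_mv[0], step_ms),
        ),
        sweep_segment_index=2,
        sweep_levels_mv=step_levels_mv,
        sampling_rate_hz=sampling_rate_hz,
        label="activation",
    )


def inactivation_protocol(
    holding_mv: float = -60.0,
    prepulse_levels_mv=None,
    prepulse_ms: float = 300.0,
    test_mv: float = -30.0,
    test_ms: float = 150.0,
    sampling_rate_hz: float = DEFAULT_SAMPLING_HZ,
    holding_ms: float = 20.0,
) -> VoltageProtocol:
    """Steady-state inactivation protocol: incremental prepulses, fixed test step.

    Each sweep conditions the channel at one prepulse level (default
    -120..-40 mV, 300 ms) and then reads out availability with a step to
    -30 mV.
    """
    if prepulse_levels_mv is None:
        prepulse_levels_mv = _default_steps(-120.0, -40.0)
    prepulse_levels_mv = tuple(float(v) for v in prepulse_levels_mv)
    if len(prepulse_levels_mv) == 0:
        raise ValueError("prepulse level list is empty")
    return VoltageProtocol(
        segments=(
            Segment(holding_mv, holding_ms),
            Segment(prepulse_levels_mv[0], prepulse_ms),
            Segment(test_mv, test_ms),
        ),
        sweep_segment_index=1,
        sweep_levels_mv=prepulse_levels_mv,
        sampling_rate_hz=sampling_rate_hz,
        label="inactivation",
    )
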