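"""Piecewise-constant stimulation protocols.

Amplitudes are current densities in uA/cm2, depolarizing positive.
Time is in ms from protocol onset; gaps between segments carry zero
current.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Segment:
    t_start: float
    t_end: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("segment requires t_start < t_end")
        if not abs(self.amplitude) < 1e6:
            raise ValueError("segment amplitude must be finite")


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered list of non-overlapping constant-current segments."""

    duration: float
    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("protocol duration must be positive")
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError("protocol segments overlap")
        object.__setattr__(self, "segments", segs)

    def amplitude(self, t: float) -> float:
        """Stimulus density at time t (zero outside all segments)."""
        for s in self.segments:
            if s.t_start <= t < s.t_end:
                return s.amplitude
        return 0.0

    def piecewise(self) -> list[tuple[float, float, float]]:
        """(t0, t1, amplitude) pieces covering [0, duration] without gaps."""
        pieces: list[tuple[float, float, float]] = []
        t = 0.0
        for s in self.segments:
            if s.t_start >= self.duration:
                break
            if s.t_start > t:
                pieces.append((t, s.t_start, 0.0))
            pieces.append((s.t_start, min(s.t_end, self.duration), s.amplitude))
            t = min(s.t_end, self.duration)
        if t < self.duration:
            pieces.append((t, self.duration, 0.0))
        return pieces

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "amplitude": s.amplitude}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            duration=float(d["duration"]),
            segments=tuple(
                Segment(float(s["t_start"]), float(s["t_end"]), float(s["amplitude"]))
                for s in d.get("segments", [])
            ),
        )


def constant(amplitude: float, duration: float) -> StimulusProtocol:
    """A constant current over the whole protocol."""
    return StimulusProtocol(duration, (Segment(0.0, duration, amplitude),))


def step(
    amplitude: float, t_on: float, t_off: float, duration: float
) -> StimulusProtocol:
    """A single current step between t_on and t_off, zero elsewhere."""
    return StimulusProtocol(duration, (Segment(t_on, t_off, amplitude),))


def zero(duration: float) -> StimulusProtocol:
    """No stimulation."""
    return StimulusProtocol(duration)
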