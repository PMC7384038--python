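"""Actinic-light protocols for fluctuating-light (FL) measurements.

A protocol is an ordered list of constant-intensity segments plus a
saturating-pulse cadence.  The standard FL protocol steps a dark-acclimated
leaf through four phases — very low light (VLL), first low light (LL1),
high light (HL) and a second low light (LL2) — with saturating pulses every
30 s to read F' and Fm'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LightSegment",
    "LightProtocol",
    "fl_protocol",
    "dirk_protocol",
]


@dataclass(frozen=True)
class LightSegment:
    """One constant-intensity stretch of a light protocol.

    Parameters
    ----------
    label : str
        Segment name (e.g. ``"VLL"``, ``"LL1"``, ``"HL"``, ``"LL2"``).
    intensity : float
        Actinic intensity in umol photons m-2 s-1 (0 for darkness).
    duration : float
        Segment duration in seconds.
    """

    label: str
    intensity: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"segment {self.label!r}: duration must be > 0")
        if self.intensity < 0:
            raise ValueError(f"segment {self.label!r}: intensity must be >= 0")


@dataclass(frozen=True)
class LightProtocol:
    """Ordered light segments with a saturating-pulse cadence.

    Pulses are applied at integer multiples of ``pulse_interval`` starting
    at ``pulse_interval`` (a pulse falling exactly on a segment boundary
    belongs to the segment it terminates).
    """

    segments: tuple[LightSegment, ...]
    pulse_interval: float = 30.0
    pulse_intensity: float = 8000.0

    def __post_init__(self) -> None:
        segs = tuple(
            s if isinstance(s, LightSegment) else LightSegment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        labels = [s.label for s in segs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"segment labels must be unique, got {labels}")
        if self.pulse_interval <= 0:
            raise ValueError("pulse_interval must be > 0")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def boundaries(self) -> np.ndarray:
        """Cumulative segment end times, prefixed with 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def segment_at(self, t: float) -> LightSegment:
        """Segment containing time ``t`` (boundaries belong to the earlier segment)."""
        if t < 0 or t > self.total_duration:
            raise ValueError(f"t={t} outside protocol range [0, {self.total_duration}]")
        bounds = self.boundaries()
        for seg, start, end in zip(self.segments, bounds[:-1], bounds[1:]):
            if (t > start or t == 0) and t <= end:
                return seg
        return self.segments[-1]  # t == 0 edge handled above

    def segment_start(self, label: str) -> float:
        bounds = self.boundaries()
        for seg, start in zip(self.segments, bounds[:-1]):
            if seg.label == label:
                return float(start)
        raise KeyError(f"no segment labeled {label!r}; have {self.labels}")

    def segment_end(self, label: str) -> float:
        return self.segment_start(label) + next(
            s.duration for s in self.segments if s.label == label
        )

    def intensity_at(self, t: float) -> float:
        return self.segment_at(t).intensity

    def pulse_times(self) -> np.ndarray:
        """Saturating-pulse times: k * pulse_interval, k = 1 .. floor(T/dt)."""
        n = int(np.floor(self.total_duration / self.pulse_interval))
        return self.pulse_interval * np.arange(1, n + 1)

    def to_dict(self) -> dict:
        return {
            "pulse_interval": self.pulse_interval,
            "pulse_intensity": self.pulse_intensity,
            "segments": [
                {"label": s.label, "intensity": s.intensity, "duration": s.duration}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightProtocol":
        return cls(
            segments=tuple(
                LightSegment(s["label"], float(s["intensity"]), float(s["duration"]))
                for s in d["segments"]
            ),
            pulse_interval=float(d.get("pulse_interval", 30.0)),
            pulse_intensity=float(d.get("pulse_intensity", 8000.0)),
        )


def fl_protocol(ll2_duration: float = 1800.0) -> LightProtocol:
    """Standard four-phase FL protocol.

    VLL 57 umol m-2 s-1 for 10 min, LL1 166 for 10 min, HL 1466 for 3.5 min,
    then LL2 at 166 prolonged until NPQ reaches steady state (default 30 min).
    Saturating pulses every 30 s at 8000 umol m-2 s-1.
    """
    return LightProtocol(
        segments=(
            LightSegment("VLL", 57.0, 600.0),
            LightSegment("LL1", 166.0, 600.0),
            LightSegment("HL", 1466.0, 210.0),
            LightSegment("LL2", 166.0, ll2_duration),
        )
    )


def dirk_protocol(ll2_duration: float = 300.0, dark_duration: float = 30.0) -> LightProtocol:
    """Electrochromic-shift (DIRK) protocol.

    LL1 166 for 10 min, HL 1287 for 3.5 min, LL2 166 for 5 min, then 30 s of
    darkness for the dark-interval relaxation.  The protocol clock starts at
    LL1 onset, so the LL2 window spans 810-1110 s.  Note the HL intensity here
    (1287) differs from the fluorescence FL protocol (1466); both presets are
    kept as measured conventions.
    """
    return LightProtocol(
        segments=(
            LightSegment("LL1", 166.0, 600.0),
            LightSegment("HL", 1287.0, 210.0),
            LightSegment("LL2", 166.0, ll2_duration),
            LightSegment("DARK", 0.0, dark_duration),
        )
    )
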