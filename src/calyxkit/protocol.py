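"""Auditory two-burst stimulus protocol.

The in vivo recordings pair juxtacellular sweeps with a wide-band-noise
stimulus: a silent lead-in, two noise bursts separated by a variable gap,
and silence to the end of the sweep.  Only the burst *timing* matters for
the analyses here (the acoustic waveform itself is never synthesized), so
the protocol is a pure timing descriptor.

All times are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["StimulusProtocol", "make_stimulus_protocol"]

#: default inter-burst gaps (ms), one sweep condition per gap
DEFAULT_INTERVALS = (40.0, 80.0, 160.0, 320.0, 640.0, 1280.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing of the two-noise-burst stimulation protocol.

    Attributes
    ----------
    pre_silence
        Silent lead-in before the first burst, ms.
    burst_duration
        Duration of each of the two bursts, ms.
    inter_burst_intervals
        Gap between burst 1 offset and burst 2 onset, ms; one condition
        per listed gap.
    sweep_duration
        Total sweep length, ms.
    level
        Nominal sound level, dB SPL (metadata only).
    """

    pre_silence: float = 200.0
    burst_duration: float = 400.0
    inter_burst_intervals: tuple[float, ...] = DEFAULT_INTERVALS
    sweep_duration: float = 4000.0
    level: float = 80.0

    def __post_init__(self) -> None:
        for name in ("pre_silence", "burst_duration", "sweep_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        ivals = tuple(float(v) for v in self.inter_burst_intervals)
        if not ivals:
            raise ValueError("inter_burst_intervals must not be empty")
        if any(v <= 0 for v in ivals):
            raise ValueError(f"inter_burst_intervals must be > 0, got {ivals}")
        object.__setattr__(self, "inter_burst_intervals", ivals)
        if self.pre_silence + 2 * self.burst_duration + max(ivals) >= self.sweep_duration:
            raise ValueError(
                "sweep_duration too short: pre_silence + 2*burst_duration + "
                "max(inter_burst_intervals) must fit inside the sweep"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.inter_burst_intervals)

    def burst_windows(self, interval: float) -> list[tuple[float, float]]:
        """(onset, offset) of the two bursts, ms, for one gap condition."""
        on1 = self.pre_silence
        off1 = on1 + self.burst_duration
        on2 = off1 + float(interval)
        return [(on1, off1), (on2, on2 + self.burst_duration)]

    def to_dict(self) -> dict:
        return {
            "pre_silence": self.pre_silence,
            "burst_duration": self.burst_duration,
            "inter_burst_intervals": list(self.inter_burst_intervals),
            "sweep_duration": self.sweep_duration,
            "level": self.level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        d = dict(d)
        if "inter_burst_intervals" in d:
            d["inter_burst_intervals"] = tuple(d["inter_burst_intervals"])
        return cls(**d)


def make_stimulus_protocol(**overrides) -> StimulusProtocol:
    """Build a :class:`StimulusProtocol` with the standard two-burst defaults.

    Any field may be overridden by keyword; ``intervals`` is accepted as an
    alias for ``inter_burst_intervals``.  Invalid overrides raise
    ``ValueError``/``TypeError`` naming the offending field.
    """
    if "intervals" in overrides:
        overrides["inter_burst_intervals"] = tuple(overrides.pop("intervals"))
    valid = set(StimulusProtocol.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise TypeError(f"unknown protocol field(s): {sorted(unknown)}")
    return StimulusProtocol(**overrides)
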