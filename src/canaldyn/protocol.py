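"""Drifting-grating stimulation protocol and its sample-index geometry.

The experiment presents a block of equally spaced grating directions, each
shown for a fixed on-period followed by a gray gap, and repeats the block
as trials separated by gray inter-trial intervals after an initial gray
lead-in.  Every downstream analysis (trial averaging, responsiveness
filtering, per-direction amplitude extraction) indexes the ΔF/F timeline
through this object, so all window arithmetic lives here.

Sample indexing is 0-based with half-open ``[start, end)`` windows so that
consecutive windows tile the timeline without overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Sequence


def _to_samples(seconds: float, rate_hz: float) -> int:
    """Convert a duration to a sample count, requiring near-integer results."""
    x = seconds * rate_hz
    n = int(round(x))
    if abs(x - n) > 1e-9:
        raise ValueError(
            f"duration {seconds} s at {rate_hz} Hz is not an integer number of samples"
        )
    return n


@dataclass(frozen=True)
class StimulusProtocol:
    """Timeline of a repeated direction-sequence grating protocol.

    Parameters
    ----------
    directions_deg : tuple of float
        Stimulus motion directions in degrees, strictly increasing, equally
        spaced, in [0, 360).
    stim_duration_s : float
        Seconds each grating is on.
    gap_duration_s : float
        Seconds of neutral gray between directions (within a trial).
    n_trials : int
        Number of repetitions of the full direction sequence.
    inter_trial_gap_s : float
        Seconds of gray following each trial.
    lead_in_s : float
        Seconds of gray before the first trial.
    sample_rate_hz : float
        Imaging rate in samples per second.
    stim_first : bool
        If True (default) the grating precedes the gray gap within each
        direction slot; if False the gap comes first.
    """

    directions_deg: tuple[float, ...]
    stim_duration_s: float
    gap_duration_s: float
    n_trials: int
    inter_trial_gap_s: float
    lead_in_s: float
    sample_rate_hz: float
    stim_first: bool = field(default=True)

    def __post_init__(self) -> None:
        dirs = tuple(float(d) for d in self.directions_deg)
        if len(dirs) < 1:
            raise ValueError("at least one stimulus direction is required")
        if any(d < 0 or d >= 360 for d in dirs):
            raise ValueError("directions must lie in [0, 360)")
        if len(dirs) > 1:
            steps = [b - a for a, b in zip(dirs, dirs[1:])]
            if any(s <= 0 for s in steps):
                raise ValueError("directions must be strictly increasing")
            if any(abs(s - steps[0]) > 1e-9 for s in steps):
                raise ValueError("directions must be equally spaced")
        object.__setattr__(self, "directions_deg", dirs)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("stim_duration_s", "gap_duration_s", "inter_trial_gap_s", "lead_in_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # ---- durations -------------------------------------------------------

    @property
    def n_directions(self) -> int:
        return len(self.directions_deg)

    @property
    def slot_duration_s(self) -> float:
        """One direction slot: grating plus its gray gap."""
        return self.stim_duration_s + self.gap_duration_s

    @property
    def trial_duration_s(self) -> float:
        return self.n_directions * self.slot_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.lead_in_s + self.n_trials * (self.trial_duration_s + self.inter_trial_gap_s)

    # ---- sample counts ---------------------------------------------------

    @property
    def stim_samples(self) -> int:
        return _to_samples(self.stim_duration_s, self.sample_rate_hz)

    @property
    def gap_samples(self) -> int:
        return _to_samples(self.gap_duration_s, self.sample_rate_hz)

    @property
    def slot_samples(self) -> int:
        return self.stim_samples + self.gap_samples

    @property
    def trial_samples(self) -> int:
        return self.n_directions * self.slot_samples

    @property
    def total_samples(self) -> int:
        return _to_samples(self.total_duration_s, self.sample_rate_hz)

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        d = dict(d)
        d["directions_deg"] = tuple(d["directions_deg"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "StimulusProtocol":
        return cls.from_dict(json.loads(s))


def build_protocol(
    directions_count: int,
    stim_s: float,
    gap_s: float,
    n_trials: int,
    inter_trial_s: float,
    lead_in_s: float,
    rate_hz: float,
    stim_first: bool = True,
) -> StimulusProtocol:
    """Construct a protocol with ``directions_count`` equally spaced directions.

    Directions are 0, 360/n, 2*360/n, ... degrees.
    """
    if directions_count < 1:
        raise ValueError("directions_count must be >= 1")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    step = 360.0 / directions_count
    directions = tuple(i * step for i in range(directions_count))
    return StimulusProtocol(
        directions_deg=directions,
        stim_duration_s=stim_s,
        gap_duration_s=gap_s,
        n_trials=n_trials,
        inter_trial_gap_s=inter_trial_s,
        lead_in_s=lead_in_s,
        sample_rate_hz=rate_hz,
        stim_first=stim_first,
    )


def default_protocol() -> StimulusProtocol:
    """The 12-direction protocol: 5 s on / 10 s off at 30° steps, 3 trials,
    50 s between trials, 45 s gray lead-in, imaged at 1 Hz (735 s total)."""
    return build_protocol(12, 5.0, 10.0, 3, 50.0, 45.0, 1.0)


def trial_windows(p: StimulusProtocol) -> list[tuple[int, int, int]]:
    """Half-open sample windows ``(trial_index, start, end)`` for each trial."""
    lead = _to_samples(p.lead_in_s, p.sample_rate_hz)
    iti = _to_samples(p.inter_trial_gap_s, p.sample_rate_hz)
    out = []
    for i in range(p.n_trials):
        start = lead + i * (p.trial_samples + iti)
        out.append((i, start, start + p.trial_samples))
    return out


def stimulus_window(p: StimulusProtocol, direction_index: int) -> tuple[int, int]:
    """Within-trial half-open sample offsets of the grating for one direction."""
    if not (0 <= direction_index < p.n_directions):
        raise IndexError(f"direction_index {direction_index} out of range [0, {p.n_directions})")
    start = direction_index * p.slot_samples
    if not p.stim_first:
        start += p.gap_samples
    return (start, start + p.stim_samples)


def gap_window(p: StimulusProtocol, direction_index: int) -> tuple[int, int]:
    """Within-trial half-open offsets of the gray gap in one direction slot."""
    if not (0 <= direction_index < p.n_directions):
        raise IndexError(f"direction_index {direction_index} out of range [0, {p.n_directions})")
    start = direction_index * p.slot_samples
    if p.stim_first:
        start += p.stim_samples
    return (start, start + p.gap_samples)
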