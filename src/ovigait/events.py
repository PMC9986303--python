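"""Gait-event detection by hoof-marker velocity threshold.

Stance is the set of frames where the sagittal-plane speed of the hoof
(distal phalange) marker falls below a threshold — the hoof is effectively
stationary while load-bearing — and swing is its complement.  The default
threshold of 0.05 m/s is the value commonly used with this detection scheme
in overland gait work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trial, ValidationError
from .markers import limb_marker
from .preprocess import differentiate


@dataclass(frozen=True)
class EventSpec:
    """Detector settings: speed threshold (m/s) and debounce duration (s)."""

    speed_threshold: float = 0.05
    min_phase_duration: float = 0.1

    def validate(self, sample_rate: float) -> None:
        if self.speed_threshold <= 0:
            raise ValidationError("speed_threshold must be positive")
        if self.min_phase_duration * sample_rate < 2:
            raise ValidationError("min_phase_duration must span at least 2 frames")


@dataclass(frozen=True)
class GaitCycle:
    """One strike-to-strike cycle of a limb (stance first, then swing)."""

    limb: str
    foot_strike: int
    toe_off: int
    next_foot_strike: int

    def __post_init__(self) -> None:
        if not self.foot_strike < self.toe_off < self.next_foot_strike:
            raise ValidationError(
                f"cycle frames must be ordered strike < toe-off < next strike, got "
                f"{self.foot_strike}, {self.toe_off}, {self.next_foot_strike}"
            )

    @property
    def stance_frames(self) -> slice:
        return slice(self.foot_strike, self.toe_off)

    @property
    def swing_frames(self) -> slice:
        return slice(self.toe_off, self.next_foot_strike)

    @property
    def n_stance(self) -> int:
        return self.toe_off - self.foot_strike

    @property
    def n_swing(self) -> int:
        return self.next_foot_strike - self.toe_off

    @property
    def n_stride(self) -> int:
        return self.next_foot_strike - self.foot_strike


def sagittal_speed(velocity: np.ndarray, axes) -> np.ndarray:
    """Speed in the progression-vertical plane, m/s."""
    p, v = axes.sagittal
    return np.hypot(velocity[:, p], velocity[:, v])


def stance_mask(
    velocity: np.ndarray, spec: EventSpec, sample_rate: float, axes
) -> np.ndarray:
    """Debounced boolean stance mask from a hoof velocity series."""
    if len(velocity) == 0:
        raise ValidationError("empty velocity series")
    spec.validate(sample_rate)
    mask = sagittal_speed(velocity, axes) < spec.speed_threshold
    return _debounce(mask, int(round(spec.min_phase_duration * sample_rate)))


def _debounce(mask: np.ndarray, min_frames: int) -> np.ndarray:
    """Merge runs shorter than min_frames into the longer adjacent phase."""
    mask = mask.copy()
    while True:
        runs = _runs(mask)
        if len(runs) <= 1:
            return mask
        # find the shortest offending interior-mergeable run
        candidates = [
            (length, i) for i, (start, length, val) in enumerate(runs)
            if length < min_frames
        ]
        if not candidates:
            return mask
        _, i = min(candidates)
        start, length, val = runs[i]
        left_len = runs[i - 1][1] if i > 0 else -1
        right_len = runs[i + 1][1] if i < len(runs) - 1 else -1
        if left_len < 0 and right_len < 0:
            return mask
        mask[start:start + length] = not val
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """(start, length, value) runs of a boolean series."""
    n = len(mask)
    edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [n]))
    return [
        (int(bounds[k]), int(bounds[k + 1] - bounds[k]), bool(mask[bounds[k]]))
        for k in range(len(bounds) - 1)
    ]


def detect_phases(
    hoof_velocity: np.ndarray,
    spec: EventSpec = EventSpec(),
    sample_rate: float = 200.0,
    axes=None,
) -> list[tuple[int, int]]:
    """Ordered (foot_strike, toe_off) event pairs from a hoof velocity series.

    Foot strike is a swing-to-stance transition, toe-off the converse; the
    leading and trailing partial phases of the trial never generate events.
    An all-stance series (static hoof) yields no events.
    """
    if axes is None:
        from .io import AxesConvention

        axes = AxesConvention()
    mask = stance_mask(hoof_velocity, spec, sample_rate, axes)
    strikes = list(np.flatnonzero(~mask[:-1] & mask[1:]) + 1)
    events = []
    for s in strikes:
        # toe-off: first stance->swing transition after this strike
        after = np.flatnonzero(mask[s:-1] & ~mask[s + 1:])
        if after.size:
            events.append((int(s), int(s + after[0] + 1)))
    return events


def extract_cycle(
    events: list[tuple[int, int]],
    trial: Trial,
    limb: str,
    volume_centre: float,
) -> GaitCycle:
    """The one complete cycle whose mid-cycle hoof position is most central.

    ``volume_centre`` is a progression-axis coordinate in metres; of all
    complete (strike, toe-off, next strike) triples, the cycle whose
    mid-cycle hoof position lies nearest is returned (ties toward the
    earlier cycle).
    """
    if len(events) < 2:
        raise ValidationError(f"{limb}: no complete gait cycle in trial")
    hoof = trial.marker(limb_marker("DPHAL", limb))
    y = hoof.positions[:, trial.axes.progression] / 1000.0  # m
    best: tuple[float, GaitCycle] | None = None
    for (s0, t0), (s1, _) in zip(events[:-1], events[1:]):
        cyc = GaitCycle(limb, s0, t0, s1)
        mid_y = float(y[(s0 + s1) // 2])
        d = abs(mid_y - volume_centre)
        if best is None or d < best[0] - 1e-12:
            best = (d, cyc)
    assert best is not None
    return best[1]


def detect_trial_events(
    trial: Trial, spec: EventSpec = EventSpec(), limbs=("FL_L", "FL_R", "HL_L", "HL_R")
) -> dict[str, list[tuple[int, int]]]:
    """Run phase detection on every requested limb's hoof marker."""
    out = {}
    for limb in limbs:
        hoof = trial.marker(limb_marker("DPHAL", limb))
        vel = differentiate(hoof, trial.sample_rate)
        out[limb] = detect_phases(vel, spec, trial.sample_rate, trial.axes)
    return out
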