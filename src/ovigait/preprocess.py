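"""Trajectory conditioning: gap filling, zero-lag low-pass filtering, differentiation.

The conditioning chain mirrors standard optical motion-capture practice:
occlusion gaps are filled first (spline interpolation, or a phase-matched
"cyclic" copy for periodic limb markers), then each coordinate is low-pass
filtered with a zero-lag (forward-backward) Butterworth filter, and
velocities are obtained by central differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .io import MarkerTrajectory, Trial, ValidationError


class GapFillError(ValueError):
    """Raised when a trajectory cannot be gap-filled."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag Butterworth low-pass design.

    ``cutoff`` is the single-pass -3 dB frequency; the forward-backward
    application squares the magnitude response, so the combined -3 dB point
    sits slightly below ``cutoff`` (documented, matching common
    biomechanics/Vicon practice of quoting the single-pass design cutoff).
    """

    order: int = 4
    cutoff: float = 10.0
    zero_lag: bool = True

    def validate(self, sample_rate: float) -> None:
        if self.order < 2 or self.order % 2:
            raise ValidationError("filter order must be even and >= 2")
        if not 0 < self.cutoff < sample_rate / 2:
            raise ValidationError(
                f"cutoff must lie in (0, {sample_rate / 2}) Hz, got {self.cutoff}"
            )


@dataclass(frozen=True)
class GapReport:
    """Occlusion runs found in one trajectory: (start, length) pairs."""

    filled: tuple[tuple[int, int], ...]
    unfilled: tuple[tuple[int, int], ...]


def _occlusion_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(
    traj: MarkerTrajectory,
    method: str = "spline",
    max_gap: int = 20,
    donor: MarkerTrajectory | None = None,
    period: int | None = None,
) -> tuple[MarkerTrajectory, GapReport]:
    """Fill occlusion runs of at most ``max_gap`` frames.

    spline: cubic interpolation through the flanking visible frames.
    cyclic: copy the displacement pattern of the same gait-cycle phase one
    period away (or the donor marker's shape), linearly offset-matched at the
    gap edges so the fill joins the flanking samples exactly.  The period is
    estimated by autocorrelation when not given.

    Longer runs are left occluded and reported.  Visible frames are never
    altered.
    """
    mask = traj.occluded
    n = traj.n_frames
    if mask.all():
        raise GapFillError(f"{traj.label}: all frames occluded, unfillable")
    if mask.sum() == 0:
        return traj.copy(), GapReport((), ())
    if int(np.sum(~mask)) < 2:
        raise GapFillError(f"{traj.label}: fewer than 2 visible frames")

    out = traj.positions.copy()
    new_mask = mask.copy()
    filled, unfilled = [], []
    visible = np.flatnonzero(~mask)

    if method == "cyclic" and donor is None and period is None:
        period = _estimate_period(traj)

    for start, length in _occlusion_runs(mask):
        if length > max_gap:
            unfilled.append((start, length))
            continue
        idx = np.arange(start, start + length)
        if method == "spline":
            out[idx] = _spline_fill(out, visible, idx)
        elif method == "cyclic":
            out[idx] = _cyclic_fill(out, mask, idx, donor=donor, period=period)
        else:
            raise ValueError(f"unknown gap-fill method {method!r}")
        new_mask[idx] = False
        filled.append((start, length))
    return (
        MarkerTrajectory(traj.label, out, new_mask),
        GapReport(tuple(filled), tuple(unfilled)),
    )


def _spline_fill(pos: np.ndarray, visible: np.ndarray, idx: np.ndarray) -> np.ndarray:
    spline = CubicSpline(visible, pos[visible], axis=0)
    return spline(idx)


def _estimate_period(traj: MarkerTrajectory) -> int:
    """Dominant period (frames) of the visible signal via autocorrelation."""
    mask = traj.occluded
    pos = traj.positions.copy()
    visible = np.flatnonzero(~mask)
    if mask.any():  # interpolate through gaps before autocorrelating
        pos[mask] = _spline_fill(pos, visible, np.flatnonzero(mask))
    x = pos - pos.mean(axis=0)
    # detrend the progression drift; use the coordinate with most periodic power
    n = len(x)
    t = np.arange(n)
    best_lag, best_val = None, -np.inf
    for c in range(3):
        y = x[:, c] - np.polyval(np.polyfit(t, x[:, c], 1), t)
        ac = np.correlate(y, y, mode="full")[n - 1:]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        # first local maximum after the central peak decays
        lags = np.flatnonzero((ac[1:-1] > ac[:-2]) & (ac[1:-1] >= ac[2:])) + 1
        lags = lags[lags >= 4]
        if lags.size and ac[lags[0]] > best_val:
            best_lag, best_val = int(lags[0]), float(ac[lags[0]])
    if best_lag is None:
        raise GapFillError(f"{traj.label}: cannot estimate a cycle period for cyclic fill")
    return best_lag


def _cyclic_fill(
    pos: np.ndarray,
    mask: np.ndarray,
    idx: np.ndarray,
    donor: MarkerTrajectory | None,
    period: int | None,
) -> np.ndarray:
    n = len(pos)
    start, stop = idx[0], idx[-1] + 1
    if donor is not None:
        shape = donor.positions
        src = idx
    else:
        if period is None:
            raise GapFillError("cyclic fill needs a donor or a resolvable period")
        # nearest complete cycle: one period earlier if visible, else later
        for shift in (-period, period, -2 * period, 2 * period):
            src = idx + shift
            if src[0] >= 0 and src[-1] < n and not mask[src].any():
                break
        else:
            raise GapFillError("no complete flanking cycle for cyclic fill")
        shape = pos
    seg = shape[src].astype(float)
    # offset-match linearly so the fill meets the flanking visible samples
    left = start - 1
    right = stop
    err_l = pos[left] - _shape_at(shape, src[0] - 1, seg, 0) if left >= 0 else 0.0
    err_r = pos[right] - _shape_at(shape, src[-1] + 1, seg, -1) if right < n else 0.0
    if left < 0:
        err_l = err_r
    if right >= n:
        err_r = err_l
    w = np.linspace(0, 1, len(idx) + 2)[1:-1][:, None]
    return seg + (1 - w) * err_l + w * err_r


def _shape_at(shape: np.ndarray, i: int, seg: np.ndarray, fallback: int) -> np.ndarray:
    if 0 <= i < len(shape):
        return shape[i]
    return seg[fallback]


def lowpass(
    traj: MarkerTrajectory, spec: FilterSpec = FilterSpec(), sample_rate: float = 200.0
) -> MarkerTrajectory:
    """Zero-lag Butterworth low-pass of each coordinate.

    Requires a gap-free trajectory (fill first).  Endpoints are handled by
    reflective padding of length 3x the filter order.
    """
    spec.validate(sample_rate)
    if traj.occluded.any():
        raise ValidationError(f"{traj.label}: occluded frames remain; fill gaps first")
    if traj.n_frames < 3 * spec.order:
        raise ValidationError(f"{traj.label}: too few frames for order-{spec.order} filter")
    b, a = signal.butter(spec.order, spec.cutoff, btype="low", fs=sample_rate)
    if spec.zero_lag:
        out = signal.filtfilt(b, a, traj.positions, axis=0,
                              padtype="odd", padlen=3 * spec.order)
    else:
        out = signal.lfilter(b, a, traj.positions, axis=0)
    return MarkerTrajectory(traj.label, out, traj.occluded.copy())


def differentiate(traj: MarkerTrajectory, sample_rate: float = 200.0) -> np.ndarray:
    """Per-frame velocity 3-vectors in m/s (central differences, one-sided ends)."""
    if traj.occluded.any():
        raise ValidationError(f"{traj.label}: cannot differentiate with occlusions")
    if traj.n_frames < 2:
        raise ValidationError("need at least 2 frames")
    vel_mm = np.gradient(traj.positions, axis=0) * sample_rate  # mm/s
    return vel_mm / 1000.0


def preprocess_trial(
    trial: Trial,
    spec: FilterSpec = FilterSpec(),
    method: str = "spline",
    max_gap: int = 20,
) -> tuple[Trial, dict[str, GapReport]]:
    """Fill gaps then low-pass filter every marker; returns the gap report."""
    reports: dict[str, GapReport] = {}
    markers = {}
    for label, traj in trial.markers.items():
        filled, rep = fill_gaps(traj, method=method, max_gap=max_gap)
        reports[label] = rep
        if filled.occluded.any():
            warnings.warn(
                f"{label}: {len(rep.unfilled)} gap(s) exceed max_gap={max_gap}; "
                "trial flagged, marker left partially occluded"
            )
            markers[label] = filled
        else:
            markers[label] = lowpass(filled, spec, trial.sample_rate)
    return replace(trial, markers=markers), reports
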