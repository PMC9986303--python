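"""Synthetic quadruped walking trials and cohorts with known ground truth.

The generator emulates overland walking passes of a four-limbed walker as
captured by an optical system: trunk/head markers advance at the designed
velocity, each hoof alternates between an exactly stationary stance and a
smooth lift-and-advance swing, and every limb's marker chain is constructed
so that the planar joint angles computed downstream reproduce the designed
per-phase angle waveforms.  Post-stroke deficits (slowed walking, lowered
head, prolonged phases, reduced fetlock excursion, left-right asymmetry)
are injectable as a :class:`StrokeEffect`.

Two consistency contracts shape the construction.  First, the hoof's swing
advance carries a small instantaneous lift-off/touch-down speed (twice the
standard detection threshold), which makes threshold-based stance/swing
detection frame-accurate through the zero-lag conditioning filter.  Second,
the limb-chain marker placement is calibrated against the conditioning
filter's periodic response so that the *filtered* joint angles reproduce
the designed per-phase extremes; this holds for waveforms whose
phase-boundary value lies within both phases' ranges (as for any
physiological joint), up to roughly 90-degree per-phase excursions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    AxesConvention, MarkerTrajectory, StudyTable, Trial, ValidationError,
)
from .markers import LIMBS, limb_marker

FS_DEFAULT = 200.0


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointWaveform:
    """Per-phase angle extremes (degrees) of one joint over the gait cycle.

    Within each phase the angle leaves the phase-boundary value (the stance
    mid-range), visits the phase minimum then the phase maximum at the
    interior third-points, and returns, with smooth easing between knots.
    Designs whose boundary value lies inside both phases' ranges (true of
    any physiological joint) are reproduced exactly by the generator's
    filter calibration.
    """

    stance_min: float
    stance_max: float
    swing_min: float
    swing_max: float

    @property
    def boundary(self) -> float:
        return 0.5 * (self.stance_min + self.stance_max)

    def __call__(self, u: np.ndarray, duty: float) -> np.ndarray:
        """Angle at cycle phase u in [0, 1) (stance first) for a given duty."""
        u = np.asarray(u, dtype=float)
        c = self.boundary
        out = np.empty_like(u)
        st = u < duty
        out[st] = _eased_knots(u[st] / duty, (c, self.stance_min, self.stance_max, c))
        sw = ~st
        out[sw] = _eased_knots(
            (u[sw] - duty) / (1.0 - duty), (c, self.swing_min, self.swing_max, c)
        )
        return out


def _eased_knots(u: np.ndarray, knots) -> np.ndarray:
    """Error-function-eased interpolation through equally spaced knot values.

    The easing is effectively C-infinity at the knots
    (endpoint derivatives are suppressed by exp(-1/(8 sigma^2))), so the
    waveform's spectrum decays fast enough for the limb-chain filter
    pre-compensation to reproduce it through the conditioning stage.
    """
    from scipy.special import erf

    k = len(knots) - 1
    seg = np.clip((u * k).astype(int), 0, k - 1)
    local = u * k - seg
    a = np.asarray(knots, dtype=float)[seg]
    b = np.asarray(knots, dtype=float)[seg + 1]
    sigma = 0.16
    lo = erf(-0.5 / (sigma * np.sqrt(2)))
    w = (erf((local - 0.5) / (sigma * np.sqrt(2))) - lo) / (-2 * lo)
    return a + (b - a) * w


#: Default joint waveforms (degrees).  Stifle per-phase extremes follow the
#: healthy left-hindlimb walking values reported for this protocol; the
#: remaining joints are plausible ovine walking ranges.
DEFAULT_WAVEFORMS: dict[str, JointWaveform] = {
    "stifle": JointWaveform(-69, -45, -81, -35),
    "tarsus": JointWaveform(-40, -22, -52, -18),
    "fetlock_hind": JointWaveform(-38, -12, -45, -8),
    "fetlock_fore": JointWaveform(-35, -10, -42, -6),
    "carpus": JointWaveform(-12, -4, -65, -8),
    "elbow": JointWaveform(-45, -25, -55, -20),
}

#: Idealized segment lengths (m).  Only relative marker placement matters for
#: the planar angles; these set a plausible ovine scale.
DEFAULT_SEGMENTS: dict[str, float] = {
    "fore_humerus": 0.18, "fore_forearm": 0.20, "fore_carpus_gap": 0.03,
    "fore_cannon": 0.18, "fore_pastern": 0.05, "fore_hoof": 0.04,
    "hind_femur": 0.20, "hind_stifle_gap": 0.03, "hind_tibia_upper": 0.10,
    "hind_tibia_lower": 0.12, "hind_tarsus_gap": 0.04,
    "hind_cannon": 0.16, "hind_pastern": 0.05, "hind_hoof": 0.04,
}

#: Lateral-sequence walk: each limb's foot-strike phase as a cycle fraction.
LATERAL_SEQUENCE = {"HL_L": 0.0, "FL_L": 0.25, "HL_R": 0.5, "FL_R": 0.75}


@dataclass(frozen=True)
class GaitDesign:
    """Designed walking pattern of one animal.

    Defaults encode the healthy baseline of the study protocol: forward
    velocity 1.28 m/s, 0.77 s cycles with 0.41 s forelimb / 0.43 s hindlimb
    stance, stride length velocity x cycle (~0.99 m), head carried ~3 cm to
    the right of T1.
    """

    forward_velocity: float = 1.28          # m/s
    cycle_duration: float = 0.77            # s
    duty_factor: float = 0.41 / 0.77        # forelimb stance fraction
    duty_factor_hind: float | None = 0.43 / 0.77
    limb_duty: Mapping[str, float] | None = None  # per-limb overrides
    stride_length: float | None = None      # m; None -> velocity * cycle
    hoof_lift_height: float = 0.05          # m
    hoof_lateral_sweep: float = 1.5         # cm, swing-phase x excursion
    hoof_contact_speed: float = 0.10        # m/s at lift-off/touch-down; twice
                                            # the default detection threshold
    phase_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(LATERAL_SEQUENCE))
    joint_waveforms: Mapping[str, JointWaveform] = field(
        default_factory=lambda: dict(DEFAULT_WAVEFORMS))
    limb_waveforms: Mapping[str, Mapping[str, JointWaveform]] = field(
        default_factory=dict)  # per-limb overrides
    segments: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS))
    withers_height: float = 0.80            # m, T1 above ground
    head_above_T1: float = 20.0             # cm
    T1_above_T13: float = 5.0               # cm
    T13_above_L7: float = 3.0               # cm
    head_lateral_offset: float = 3.0        # cm, + = right
    trunk_osc_amplitude: float = 1.0        # cm, vertical, 2 per cycle
    stance_width_fore: float = 0.24         # m between left and right hooves
    stance_width_hind: float = 0.30         # m

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0:
            raise ValidationError("cycle_duration must be positive")
        duties = [self.duty_factor, self.duty_factor_hind or self.duty_factor]
        if self.limb_duty:
            duties += list(self.limb_duty.values())
        for d in duties:
            if not 0 < d < 1:
                raise ValidationError("duty factors must lie in (0, 1)")
        if self.forward_velocity < 0:
            raise ValidationError("forward_velocity must be non-negative")
        if self.stride_length is not None:
            auto = self.forward_velocity * self.cycle_duration
            if abs(self.stride_length - auto) > 1e-9:
                raise ValidationError(
                    f"stride_length {self.stride_length} inconsistent with "
                    f"velocity x cycle = {auto}"
                )

    @property
    def stride(self) -> float:
        return (self.stride_length if self.stride_length is not None
                else self.forward_velocity * self.cycle_duration)

    def duty(self, limb: str) -> float:
        if self.limb_duty is not None and limb in self.limb_duty:
            return self.limb_duty[limb]
        if limb.startswith("HL") and self.duty_factor_hind is not None:
            return self.duty_factor_hind
        return self.duty_factor

    def waveform(self, limb: str, joint: str) -> JointWaveform:
        override = self.limb_waveforms.get(limb, {})
        if joint in override:
            return override[joint]
        return self.joint_waveforms[joint]


def _per_limb(value, limb: str) -> float:
    if isinstance(value, Mapping):
        return float(value.get(limb, 0.0))
    return float(value)


@dataclass(frozen=True)
class StrokeEffect:
    """Injectable post-stroke gait deficit.

    Duration deltas may be scalars (applied to every limb) or per-limb
    mappings for left-right asymmetry.  Applying the zero effect returns
    the design unchanged.
    """

    delta_velocity: float = 0.0             # m/s
    delta_head_vertical: float = 0.0        # cm, change in head-above-T1
    delta_stance: float | Mapping = 0.0     # s
    delta_swing: float | Mapping = 0.0      # s
    delta_fetlock_swing_range: float | Mapping = 0.0  # deg (negative = reduced)

    def is_zero(self) -> bool:
        vals = [self.delta_velocity, self.delta_head_vertical]
        for v in (self.delta_stance, self.delta_swing, self.delta_fetlock_swing_range):
            vals.extend(v.values() if isinstance(v, Mapping) else [v])
        return all(v == 0 for v in vals)

    def stance_delta(self, limb: str) -> float:
        return _per_limb(self.delta_stance, limb)

    def swing_delta(self, limb: str) -> float:
        return _per_limb(self.delta_swing, limb)

    def apply(self, design: GaitDesign) -> GaitDesign:
        if self.is_zero():
            return design
        # per-limb target durations
        stance = {l: design.duty(l) * design.cycle_duration + self.stance_delta(l)
                  for l in LIMBS}
        swing = {l: (1 - design.duty(l)) * design.cycle_duration + self.swing_delta(l)
                 for l in LIMBS}
        cycles = {l: stance[l] + swing[l] for l in LIMBS}
        # limbs must share one cycle duration to stay phase-locked; use the
        # mean and fold any per-limb imbalance into per-limb duty factors
        new_cycle = float(np.mean(list(cycles.values())))
        limb_duty = {l: stance[l] / new_cycle for l in LIMBS}
        duty_fore = np.mean([limb_duty[l] for l in ("FL_L", "FL_R")])
        duty_hind = np.mean([limb_duty[l] for l in ("HL_L", "HL_R")])
        limb_wf: dict[str, dict[str, JointWaveform]] = {
            l: dict(design.limb_waveforms.get(l, {})) for l in LIMBS
        }
        for limb in LIMBS:
            d_range = _per_limb(self.delta_fetlock_swing_range, limb)
            if d_range:
                joint = "fetlock_fore" if limb.startswith("FL") else "fetlock_hind"
                wf = design.waveform(limb, joint)
                new_min = min(wf.swing_max - 1e-6,
                              wf.swing_min - d_range)  # negative delta raises min
                limb_wf[limb][joint] = replace(wf, swing_min=new_min)
        return replace(
            design,
            forward_velocity=max(design.forward_velocity + self.delta_velocity, 0.0),
            cycle_duration=new_cycle,
            duty_factor=float(duty_fore),
            duty_factor_hind=float(duty_hind),
            limb_duty=limb_duty,
            stride_length=None,
            head_above_T1=design.head_above_T1 + self.delta_head_vertical,
            limb_waveforms={l: wf for l, wf in limb_wf.items() if wf},
        )


#: The study's 3-day post-stroke deficit point estimates as a named preset:
#: velocity -0.28 m/s, head-to-T1 vertical -8.21 cm, stance/swing duration
#: increases per limb, and reduced fetlock swing range with mild
#: hindlimb asymmetry.
POST_STROKE_DAY3 = StrokeEffect(
    delta_velocity=-0.28,
    delta_head_vertical=-8.21,
    delta_stance={"FL_L": 0.13, "FL_R": 0.14, "HL_L": 0.13, "HL_R": 0.12},
    delta_swing={"FL_L": 0.02, "FL_R": 0.02, "HL_L": 0.03, "HL_R": 0.03},
    delta_fetlock_swing_range={"FL_L": -3.9, "FL_R": -3.31,
                               "HL_L": -8.34, "HL_R": -8.19},
)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections: white noise, skin artifact, occlusions."""

    white_sd: float = 0.5                 # mm
    skin_artifact_amplitude: float = 1.0  # mm
    skin_artifact_frequency: float = 3.0  # Hz
    occlusion_rate: float = 0.002         # per marker-frame gap-start probability
    mean_gap_length: float = 5.0          # frames
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("white_sd", "skin_artifact_amplitude", "skin_artifact_frequency",
                  "occlusion_rate", "mean_gap_length"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be non-negative")

    def is_silent(self) -> bool:
        return (self.white_sd == 0 and self.skin_artifact_amplitude == 0
                and self.occlusion_rate == 0)


ZERO_NOISE = NoiseModel(white_sd=0.0, skin_artifact_amplitude=0.0,
                        occlusion_rate=0.0)


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def _dir(psi: np.ndarray) -> np.ndarray:
    """Distal-pointing unit vector in the (y, z) plane at angle psi from
    straight down; psi follows the joint-angle sign convention."""
    return np.stack([np.sin(psi), -np.cos(psi)], axis=-1)


def _hoof_path(t, phase, duty, cycle, stride, lift_m, sweep_cm, y0, x0,
               contact_speed):
    """Hoof (x, y, z) in metres: stationary stance, smooth advance in swing.

    The swing velocity profile is ``v_b + (V - v_b) sin^2(pi tau)``: a small
    instantaneous lift-off/touch-down speed ``v_b`` plus a band-limited
    advance.  A zero-phase low-pass filter halves a velocity step at the
    step instant, so with ``v_b`` set to twice the detection threshold the
    filtered sagittal speed crosses the threshold at the true phase
    boundary, making threshold-based stance/swing detection frame-accurate.
    """
    T_sw = cycle * (1.0 - duty)
    mean_v = stride / T_sw
    v_b = min(contact_speed, mean_v)
    V = 2.0 * mean_v - v_b  # so the profile integrates to one stride
    s = t / cycle - phase
    k = np.floor(s)
    u = s - k
    in_swing = u >= duty
    tau = np.where(in_swing, (u - duty) / (1.0 - duty), 0.0)
    adv = T_sw * (v_b * tau + (V - v_b) * (tau / 2.0 - np.sin(2 * np.pi * tau) / (4 * np.pi)))
    y = y0 + k * stride + np.where(in_swing, adv, 0.0)
    z = np.where(in_swing, lift_m * 0.5 * (1 - np.cos(2 * np.pi * tau)), 0.0)
    x = x0 + np.where(in_swing, (sweep_cm / 100.0) * np.sin(np.pi * tau), 0.0)
    return x, y, z, u


_GRID = 1024  # periodic design grid (one gait cycle)


def _filter_response(freqs_hz: np.ndarray, conditioning, sample_rate: float) -> np.ndarray:
    """Squared magnitude response of the zero-lag conditioning filter."""
    from scipy import signal as _sig

    b, a = _sig.butter(conditioning.order, conditioning.cutoff,
                       btype="low", fs=sample_rate)
    w, h = _sig.freqz(b, a, worN=freqs_hz, fs=sample_rate)
    return np.abs(h) ** 2


def _periodic_filter(v: np.ndarray, resp: np.ndarray) -> np.ndarray:
    """Apply the zero-lag filter's periodic steady-state response."""
    V = np.fft.rfft(v, axis=0)
    return np.fft.irfft(V * resp[:, None], len(v), axis=0)


def _predistort_levels(psi_targets: list[np.ndarray], cycle: float,
                       conditioning, sample_rate: float,
                       tol_deg: float = 0.01, max_iter: int = 40):
    """Pre-distort each chain level's angle series for the conditioning filter.

    A planar joint angle is the difference of the polar angles of its two
    segment vectors, so it suffices that every filtered level vector points
    along its target angle.  The fixed-point update adds the residual angle
    error to the pre-distorted series; the filter is close to identity over
    the band-limited targets, so a handful of iterations converge far below
    the 0.5 degree consistency contract.
    """
    freqs = np.arange(_GRID // 2 + 1) / cycle
    resp = _filter_response(np.minimum(freqs, 0.49 * sample_rate),
                            conditioning, sample_rate)
    # the update only acts where the filter retains authority; error content
    # in heavily attenuated harmonics is uncontrollable by a bounded
    # pre-distortion and must not accumulate
    h_ctrl = int(np.max(np.flatnonzero(resp >= 0.05), initial=2))
    out = []
    tol = np.deg2rad(tol_deg)
    for target in psi_targets:
        psi = target.copy()
        for _ in range(max_iter):
            f = _periodic_filter(_dir(psi), resp)
            ang = np.arctan2(f[:, 0], -f[:, 1])
            err = np.unwrap(target - ang)
            err -= np.round(np.mean(err) / (2 * np.pi)) * 2 * np.pi
            err_b = _bandlimit(err, h_ctrl)
            psi = psi + err_b
            if np.max(np.abs(err_b)) < tol:
                break
        out.append(psi)
    return out


def _realized_angles(psi_levels, base_psi, resp) -> list[np.ndarray]:
    """Joint-angle series (degrees) the conditioned pipeline will report for a
    set of pre-distorted chain levels, from the periodic filter model."""
    angs = [np.full(_GRID, base_psi)]
    for p in psi_levels:
        f = _periodic_filter(_dir(p), resp)
        angs.append(np.unwrap(np.arctan2(f[:, 0], -f[:, 1])))
    return [np.degrees(b - a) for a, b in zip(angs[:-1], angs[1:])]


def _bandlimit(theta: np.ndarray, h_max: int) -> np.ndarray:
    X = np.fft.rfft(theta)
    X[h_max + 1:] = 0.0
    return np.fft.irfft(X, len(theta))


_BUMPS: np.ndarray | None = None


def _bump_matrix() -> np.ndarray:
    """Periodic Gaussian bumps (one per grid point) for extreme restoration."""
    global _BUMPS
    if _BUMPS is None:
        grid_u = np.arange(_GRID) / _GRID
        dist = grid_u[None, :] - grid_u[:, None]
        dist = np.minimum(np.abs(dist), 1 - np.abs(dist))
        _BUMPS = np.exp(-0.5 * (dist / 0.035) ** 2)  # sigma 3.5% of a cycle
    return _BUMPS


@lru_cache(maxsize=512)
def _chain_psi_levels(
    waveforms: tuple[JointWaveform, ...],
    duty: float,
    cycle: float,
    base_psi_deg: float,
    cond_key: tuple | None,
    sample_rate: float,
) -> tuple[np.ndarray, ...]:
    """Pre-distorted chain-level angle series (radians) over one gait cycle.

    Each level's angle is the base segment orientation plus the cumulative
    joint waveforms.  With a conditioning filter two nested loops tune the
    chain: the inner loop pre-distorts each level for the filter's periodic
    response, and the outer loop nudges the band-limited designed waveforms
    with Gaussian bumps at the per-phase extreme locations until the
    *realized* (filtered) joint-angle extremes match the design.
    """
    from .preprocess import FilterSpec

    base_psi = np.deg2rad(base_psi_deg)
    grid_u = np.arange(_GRID) / _GRID
    if cond_key is None:
        psi = np.full(_GRID, base_psi)
        levels = []
        for wf in waveforms:
            psi = psi + np.deg2rad(wf(grid_u, duty))
            levels.append(psi)
        return tuple(levels)

    conditioning = FilterSpec(order=cond_key[0], cutoff=cond_key[1])
    h_keep = max(int(1.55 * conditioning.cutoff * cycle), 2)
    thetas = [_bandlimit(wf(grid_u, duty), h_keep) for wf in waveforms]
    flat = [np.ptp(wf(grid_u, duty)) < 1e-9 for wf in waveforms]
    stance = grid_u < duty
    bumps = _bump_matrix()
    freqs = np.arange(_GRID // 2 + 1) / cycle
    resp = _filter_response(np.minimum(freqs, 0.49 * sample_rate),
                            conditioning, sample_rate)
    best: tuple[float, list[np.ndarray]] | None = None
    for _outer in range(12):
        targets = []
        psi = np.full(_GRID, base_psi)
        for th in thetas:
            psi = psi + np.deg2rad(th)
            targets.append(psi.copy())
        pre = _predistort_levels(targets, cycle, conditioning, sample_rate)
        realized = _realized_angles(pre, base_psi, resp)
        worst = 0.0
        for j, wf in enumerate(waveforms):
            if flat[j]:
                continue
            for mask, target, pick in (
                (stance, wf.stance_min, np.argmin),
                (stance, wf.stance_max, np.argmax),
                (~stance, wf.swing_min, np.argmin),
                (~stance, wf.swing_max, np.argmax),
            ):
                idx = np.flatnonzero(mask)
                at = idx[pick(realized[j][idx])]
                err = target - realized[j][at]
                worst = max(worst, abs(err))
                thetas[j] = thetas[j] + err * bumps[at]
        if best is None or worst < best[0]:
            best = (worst, pre)
        if worst < 0.03:
            break
        thetas = [_bandlimit(th, h_keep) for th in thetas]
    return tuple(best[1])


def _eval_dir(psi_grid: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Periodic cubic-spline evaluation of a level's direction vector."""
    from scipy.interpolate import CubicSpline

    v = _dir(psi_grid)
    x = np.arange(_GRID + 1) / _GRID
    cs = CubicSpline(x, np.vstack([v, v[:1]]), axis=0, bc_type="periodic")
    return cs(np.mod(u, 1.0))


def _limb_chain(limb, design, t, hoof_xyz, u, conditioning, sample_rate):
    """All marker positions (m) of one limb, built distal-to-proximal so the
    hoof follows its designed path and every joint angle is exact after the
    standard conditioning filter."""
    seg = design.segments
    duty = design.duty(limb)
    fore = limb.startswith("FL")
    joints = ("elbow", "carpus", "fetlock_fore") if fore else \
             ("stifle", "tarsus", "fetlock_hind")
    base_psi_deg = 20.0 if fore else 45.0
    cond_key = None if conditioning is None else (conditioning.order,
                                                  conditioning.cutoff)
    psi_levels = _chain_psi_levels(
        tuple(design.waveform(limb, j) for j in joints),
        duty, design.cycle_duration, base_psi_deg, cond_key, sample_rate,
    )
    levels = [np.full(_GRID, np.deg2rad(base_psi_deg))] + list(psi_levels)
    dirs = [_eval_dir(p, u) for p in levels]  # (n, 2) sagittal directions
    hoof = np.stack(hoof_xyz, axis=-1)  # (n, 3) in m, axes (x, y, z)

    def up(pos, level, length):
        d = dirs[level]
        out = pos.copy()
        out[:, 1] -= length * d[:, 0]
        out[:, 2] -= length * d[:, 1]
        return out

    m: dict[str, np.ndarray] = {}
    if fore:
        m["DPHAL"] = hoof
        m["PHAL"] = up(hoof, 3, seg["fore_hoof"])
        m["PPHAL"] = up(m["PHAL"], 3, seg["fore_pastern"])
        m["METAR"] = up(m["PPHAL"], 2, seg["fore_cannon"])
        m["ULNA"] = up(m["METAR"], 1, seg["fore_carpus_gap"])
        m["LEPIRAD"] = up(m["ULNA"], 1, seg["fore_forearm"])
        m["GTUB"] = up(m["LEPIRAD"], 0, seg["fore_humerus"])
    else:
        m["DPHAL"] = hoof
        m["PHAL"] = up(hoof, 3, seg["hind_hoof"])
        m["PPHAL"] = up(m["PHAL"], 3, seg["hind_pastern"])
        m["FTAR"] = up(m["PPHAL"], 2, seg["hind_cannon"])
        m["LMAL"] = up(m["FTAR"], 1, seg["hind_tarsus_gap"])
        m["TIB"] = up(m["LMAL"], 1, seg["hind_tibia_lower"])
        m["LTIB"] = up(m["TIB"], 1, seg["hind_tibia_upper"])
        m["LEPI"] = up(m["LTIB"], 0, seg["hind_stifle_gap"])
        m["GTROC"] = up(m["LEPI"], 0, seg["hind_femur"])
        calc = m["LMAL"].copy()
        calc[:, 1] -= 0.04
        calc[:, 2] += 0.03
        m["CALC"] = calc
    return {limb_marker(name, limb): pos for name, pos in m.items()}


def generate_trial(
    design: GaitDesign = GaitDesign(),
    effect: StrokeEffect | None = None,
    noise: NoiseModel = ZERO_NOISE,
    n_cycles: int = 5,
    sample_rate: float = FS_DEFAULT,
    animal_id: str = "sim",
    session: str = "B1",
    conditioning=None,
) -> Trial:
    """One synthetic walking pass containing all 42 markers.

    With zero noise the hoof markers are exactly stationary in stance, the
    trunk advances at the designed velocity, and the planar joint angles
    computed by the kinematics module reproduce the designed waveforms.
    A zero-velocity design produces a fully static trial.

    ``conditioning`` is the :class:`~ovigait.preprocess.FilterSpec` of the
    downstream conditioning stage (default: the standard 4th-order 10 Hz
    zero-lag filter); the limb-chain marker placement is pre-compensated
    for its response so the *filtered* joint angles reproduce the designed
    waveforms.  Pass ``conditioning=False`` to disable compensation.
    """
    from .preprocess import FilterSpec

    if conditioning is None:
        conditioning = FilterSpec()
    elif conditioning is False:
        conditioning = None
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    if effect is not None:
        design = effect.apply(design)
    C = design.cycle_duration
    v = design.forward_velocity
    stride = design.stride
    static = v == 0.0
    n = int(round((n_cycles + 1) * C * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    ax = AxesConvention()
    markers: dict[str, np.ndarray] = {}

    # trunk and head (metres)
    h_t1 = design.withers_height
    osc = (design.trunk_osc_amplitude / 100.0) * np.sin(4 * np.pi * t / C)
    if static:
        osc = np.zeros_like(t)
    y_t1 = 1.0 + v * t
    t1 = np.stack([np.zeros_like(t), y_t1, h_t1 + osc], axis=-1)
    head = t1.copy()
    head[:, 0] += design.head_lateral_offset / 100.0
    head[:, 1] += 0.25
    head[:, 2] += design.head_above_T1 / 100.0
    t13 = t1.copy()
    t13[:, 1] -= 0.25
    t13[:, 2] -= design.T1_above_T13 / 100.0
    l7 = t13.copy()
    l7[:, 1] -= 0.20
    l7[:, 2] -= design.T13_above_L7 / 100.0
    markers.update({"HEAD": head, "T1": t1, "T13": t13, "L7": l7})
    for side, sign in (("L", -1.0), ("R", 1.0)):
        ilium = l7.copy()
        ilium[:, 0] += sign * 0.08
        ilium[:, 1] -= 0.05
        ilium[:, 2] -= 0.02
        markers[f"ILIUM_HL_{side}"] = ilium
        ischtub = l7.copy()
        ischtub[:, 0] += sign * 0.07
        ischtub[:, 1] -= 0.15
        ischtub[:, 2] -= 0.05
        markers[f"ISCHTUB_HL_{side}"] = ischtub

    for limb in LIMBS:
        fore = limb.startswith("FL")
        width = design.stance_width_fore if fore else design.stance_width_hind
        x0 = (width / 2.0) * (1.0 if limb.endswith("_R") else -1.0)
        y0 = 1.0 + (0.45 if fore else -0.45)
        if static:
            x, y, z = (np.full_like(t, x0), np.full_like(t, y0), np.zeros_like(t))
            u = np.zeros_like(t)
        else:
            x, y, z, u = _hoof_path(
                t, design.phase_offsets[limb], design.duty(limb), C, stride,
                design.hoof_lift_height, design.hoof_lateral_sweep, y0, x0,
                design.hoof_contact_speed,
            )
        markers.update(_limb_chain(limb, design, t, (x, y, z), u,
                                   conditioning, sample_rate))

    rng = np.random.default_rng(noise.seed)
    out: dict[str, MarkerTrajectory] = {}
    for label, pos_m in markers.items():
        pos = pos_m * 1000.0  # mm
        occ = np.zeros(n, dtype=bool)
        if noise.skin_artifact_amplitude > 0:
            phases = rng.uniform(0, 2 * np.pi, size=3)
            wob = noise.skin_artifact_amplitude * np.sin(
                2 * np.pi * noise.skin_artifact_frequency * t[:, None] + phases
            )
            pos = pos + wob
        if noise.white_sd > 0:
            pos = pos + rng.normal(0.0, noise.white_sd, size=pos.shape)
        if noise.occlusion_rate > 0:
            starts = np.flatnonzero(rng.random(n) < noise.occlusion_rate)
            for s in starts:
                length = 1 + rng.geometric(1.0 / max(noise.mean_gap_length, 1.0))
                occ[s:s + length] = True
            # keep the trajectory fillable
            if occ.all():
                occ[:2] = False
        p = pos.copy()
        p[occ] = np.nan
        out[label] = MarkerTrajectory(label, p, occ)
    return Trial(animal_id=animal_id, session=session, sample_rate=sample_rate,
                 markers=out, axes=ax)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetweenAnimalSD:
    """Between-animal dispersion of the designed gait parameters.

    These are free parameters of the simulator (the study does not decompose
    its inter-trial variability into within/between parts); defaults are
    plausible for a habituated flock.
    """

    velocity: float = 0.12        # m/s
    stance: float = 0.03          # s
    swing: float = 0.015          # s
    head_height: float = 2.0      # cm
    fetlock_range: float = 3.0    # deg


@dataclass(frozen=True)
class ResidualSD:
    """Trial-to-trial measurement dispersion of the derived measures."""

    velocity: float = 0.08        # m/s
    stance: float = 0.03          # s
    swing: float = 0.015          # s
    head_height: float = 1.0      # cm
    fetlock_range: float = 2.0    # deg


@dataclass
class Cohort:
    """Simulated study: ground truth + measured tables, scores, volumes."""

    ground_truth: StudyTable
    measured: StudyTable
    trial_level: pd.DataFrame          # per-trial values incl. 'trial' column
    neuroscores: pd.DataFrame          # tidy score-sheet rows
    infarct_volumes: pd.Series         # cm^3 per animal
    trials: dict = field(default_factory=dict)  # (animal, session, i) -> Trial


def _session_design(base: GaitDesign, re_draw: dict, effect: StrokeEffect | None,
                    post: bool) -> GaitDesign:
    animal_effect = StrokeEffect(
        delta_velocity=re_draw["velocity"],
        delta_head_vertical=re_draw["head_height"],
        delta_stance=re_draw["stance"],
        delta_swing=re_draw["swing"],
        delta_fetlock_swing_range=re_draw["fetlock_range"],
    )
    design = animal_effect.apply(base)
    if post and effect is not None:
        design = effect.apply(design)
    return design


def generate_cohort(
    n_animals: int,
    sessions=("B1", "B2", "B3", "D3"),
    design: GaitDesign = GaitDesign(),
    effect_post: StrokeEffect | None = POST_STROKE_DAY3,
    between_animal_sd: BetweenAnimalSD = BetweenAnimalSD(),
    residual_sd: ResidualSD = ResidualSD(),
    noise: NoiseModel = ZERO_NOISE,
    n_trials: int = 5,
    trajectories: bool = False,
    n_cycles: int = 5,
    neuroscore_post_total: float = 7.0,
    seed: int = 0,
) -> Cohort:
    """Multi-session cohort with per-animal random effects drawn once.

    Sessions starting with "B" are baseline, "D" post-stroke; post sessions
    get ``effect_post`` applied on top of the animal's own design.  The
    measured study table is the per-session mean of ``n_trials`` noisy trial
    values (matching the protocol of averaging the reconstructed trials);
    the per-trial draws are kept in ``trial_level``.  With
    ``trajectories=True`` full 42-marker trials are also rendered.
    """
    sessions = list(sessions)
    baselines = [s for s in sessions if s.startswith("B")]
    posts = [s for s in sessions if not s.startswith("B")]
    if not baselines:
        raise ValidationError("cohort needs at least one baseline session")
    if not posts and effect_post is not None and not effect_post.is_zero():
        raise ValidationError("a post-stroke effect needs a post session")
    has_dispersion = any(
        getattr(between_animal_sd, f) > 0
        for f in ("velocity", "stance", "swing", "head_height", "fetlock_range")
    )
    if n_animals < 2 and has_dispersion:
        raise ValidationError("between-animal dispersion needs >= 2 animals")
    rng = np.random.default_rng(seed)

    gt_rows, trial_rows = [], []
    score_rows = []
    infarcts = {}
    trials = {}
    for a in range(n_animals):
        animal = f"A{a + 1:02d}"
        re_draw = {
            "velocity": rng.normal(0, between_animal_sd.velocity),
            "stance": rng.normal(0, between_animal_sd.stance),
            "swing": rng.normal(0, between_animal_sd.swing),
            "head_height": rng.normal(0, between_animal_sd.head_height),
            "fetlock_range": rng.normal(0, between_animal_sd.fetlock_range),
        }
        infarcts[animal] = float(np.exp(rng.normal(np.log(2.7), 1.1)))
        base_left_post = rng.uniform(2.0, 4.5)
        for session in sessions:
            post = session in posts
            sdesign = _session_design(design, re_draw, effect_post, post)
            _designed_rows(gt_rows, animal, session, sdesign)
            for i in range(n_trials):
                _trial_rows(trial_rows, animal, session, i, sdesign,
                            residual_sd, rng)
                if trajectories:
                    tr_noise = replace(noise, seed=int(rng.integers(2 ** 31)))
                    trials[(animal, session, i)] = generate_trial(
                        sdesign, None, tr_noise, n_cycles=n_cycles,
                        animal_id=animal, session=session,
                    )
            score_rows.extend(
                _score_sheet_rows(animal, session, post, rng,
                                  neuroscore_post_total, base_left_post)
            )

    trial_df = pd.DataFrame(trial_rows)
    measured = (
        trial_df.groupby(["animal", "session", "limb", "measure", "units"],
                         sort=False, dropna=False)["value"]
        .mean().reset_index()
    )[["animal", "session", "limb", "measure", "value", "units"]]
    return Cohort(
        ground_truth=StudyTable.from_rows(gt_rows),
        measured=StudyTable(measured),
        trial_level=trial_df,
        neuroscores=pd.DataFrame(
            score_rows, columns=["animal", "session", "criterion",
                                 "component", "value"]),
        infarct_volumes=pd.Series(infarcts, name="infarct_volume_cm3"),
        trials=trials,
    )


def _designed_rows(rows, animal, session, d: GaitDesign) -> None:
    rows.append((animal, session, "", "mean_forward_velocity",
                 d.forward_velocity, "m/s"))
    rows.append((animal, session, "", "head_to_T1_vertical",
                 d.head_above_T1, "cm"))
    for limb in LIMBS:
        duty = d.duty(limb)
        rows.append((animal, session, limb, "stance_duration",
                     duty * d.cycle_duration, "s"))
        rows.append((animal, session, limb, "swing_duration",
                     (1 - duty) * d.cycle_duration, "s"))
        rows.append((animal, session, limb, "stride_duration",
                     d.cycle_duration, "s"))
        joint = "fetlock_fore" if limb.startswith("FL") else "fetlock_hind"
        wf = d.waveform(limb, joint)
        rows.append((animal, session, limb, f"{joint}_range_swing",
                     wf.swing_max - wf.swing_min, "deg"))


def _trial_rows(rows, animal, session, i, d: GaitDesign,
                res: ResidualSD, rng) -> None:
    def add(limb, measure, value, units):
        rows.append({"animal": animal, "session": session, "trial": i,
                     "limb": limb, "measure": measure, "value": value,
                     "units": units})

    add("", "mean_forward_velocity",
        d.forward_velocity + rng.normal(0, res.velocity), "m/s")
    add("", "head_to_T1_vertical",
        d.head_above_T1 + rng.normal(0, res.head_height), "cm")
    for limb in LIMBS:
        duty = d.duty(limb)
        stance = duty * d.cycle_duration + rng.normal(0, res.stance)
        swing = (1 - duty) * d.cycle_duration + rng.normal(0, res.swing)
        add(limb, "stance_duration", stance, "s")
        add(limb, "swing_duration", swing, "s")
        add(limb, "stride_duration", stance + swing, "s")
        joint = "fetlock_fore" if limb.startswith("FL") else "fetlock_hind"
        wf = d.waveform(limb, joint)
        add(limb, f"{joint}_range_swing",
            wf.swing_max - wf.swing_min + rng.normal(0, res.fetlock_range), "deg")


def _score_sheet_rows(animal, session, post, rng, post_total, base_left) -> list:
    """Tidy rubric score-sheet rows for one animal-session.

    Baselines are near-zero with occasional minor postural quarter-points;
    post-stroke sheets encode a designed deficit whose total sits close to
    ``post_total`` above baseline (apathy, mild behavioural signs, left-
    dominant postural deficit, wheelbarrow drift).
    """
    rows = []

    def add(crit, comp, val):
        rows.append((animal, session, crit, comp, float(val)))

    for crit in (1, 2, 3, 4, 5, 6, 10):
        add(crit, "base", 0.0)
    for side in ("left", "right"):
        add(7, f"base_{side}", 0.0)
        add(8, f"base_{side}", 0.0)
    for limb in ("FL_L", "FL_R", "HL_L", "HL_R"):
        add(9, f"base_{limb}", 0.0)

    def setv(crit, comp, val):
        for j, (a, s, c, cm, v) in enumerate(rows):
            if c == crit and cm == comp:
                rows[j] = (a, s, c, cm, float(val))
                return
        add(crit, comp, val)

    if not post:
        # occasional minor postural variation
        if rng.random() < 0.4:
            side = "left" if rng.random() < 0.5 else "right"
            setv(7, f"base_{side}", 1.0)
        if rng.random() < 0.3:
            limb = ["FL_L", "FL_R"][int(rng.random() < 0.5)]
            setv(9, f"drag_{limb}", 0.25)
    else:
        setv(1, "base", 1.0)                       # apathetic
        behav = rng.integers(0, 3)
        if behav >= 1:
            setv(4, "base", 1.0)
        if behav >= 2:
            setv(5, "base", 1.0)
        setv(7, "base_left", round(base_left * 0.6))
        setv(7, "knuckling_FL_L", 0.25)
        setv(8, "base_left", 1.0)
        setv(9, "base_FL_L", 1.0)
        setv(9, "drag_FL_L", 0.25)
        setv(7, "base_right", 1.0 if rng.random() < 0.5 else 0.0)
        setv(10, "base", 1.0)                      # drifting to side
    return rows
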