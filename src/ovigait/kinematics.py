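"""Global and limb-specific kinematic outcome measures.

Global parameters are whole-trial means of trunk/head marker relations
(forward velocity of T1, vertical and lateral offsets along the spine).
Limb parameters are computed within one extracted gait cycle per limb:
phase durations and ratios, stride length, hoof path measures, and per-joint
sagittal-plane angle summaries restricted to stance and to swing.

Angle convention: both joint vectors are projected onto the sagittal
(progression, vertical) plane; the angle is the signed rotation from the
proximal to the distal vector, zero when the distal segment continues the
proximal segment in a straight line (full extension) and negative for
flexion.  Positive rotation is counter-clockwise when the plane is viewed
with the progression axis rightward and the vertical axis upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import GaitCycle, stance_mask, EventSpec
from .io import StudyTable, Trial, ValidationError
from .markers import JOINTS, joints_for_limb, limb_marker
from .preprocess import differentiate

MM_TO_CM = 0.1

#: Contralateral partner of each limb.
CONTRA = {"FL_L": "FL_R", "FL_R": "FL_L", "HL_L": "HL_R", "HL_R": "HL_L"}


@dataclass(frozen=True)
class GlobalParameters:
    """Whole-trial posture and progression measures."""

    mean_forward_velocity: float  # m/s, mean T1 progression velocity
    head_to_T1_vertical: float    # cm, mean z(HEAD) - z(T1)
    head_to_T1_lateral: float     # cm, mean x(HEAD) - x(T1), + = right
    T1_to_T13_vertical: float     # cm
    T13_to_L7_vertical: float     # cm

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_forward_velocity": self.mean_forward_velocity,
            "head_to_T1_vertical": self.head_to_T1_vertical,
            "head_to_T1_lateral": self.head_to_T1_lateral,
            "T1_to_T13_vertical": self.T1_to_T13_vertical,
            "T13_to_L7_vertical": self.T13_to_L7_vertical,
        }


GLOBAL_UNITS = {
    "mean_forward_velocity": "m/s",
    "head_to_T1_vertical": "cm",
    "head_to_T1_lateral": "cm",
    "T1_to_T13_vertical": "cm",
    "T13_to_L7_vertical": "cm",
}


@dataclass
class LimbParameters:
    """Per-cycle kinematic outcome measures of one limb."""

    limb: str
    stance_duration: float        # s
    swing_duration: float         # s
    stride_duration: float        # s
    stance_to_stride: float
    swing_to_stride: float
    stance_to_swing: float
    stride_length: float          # cm
    hoof_height_range_swing: float    # cm
    hoof_lateral_deviation: float     # cm, swing-phase x-range
    hoof_forward_swing_velocity: float   # m/s, mean |v_y| over swing
    hoof_vertical_swing_velocity: float  # m/s, mean |v_z| over swing
    inter_limb_stance_distance: float | None  # cm, mean planar L-R distance in double stance
    joint_angles: dict[str, dict[str, float]] = field(default_factory=dict)
    # joint_angles[joint]["{min|max|range}_{stance|swing}"] in degrees

    def as_dict(self) -> dict[str, float]:
        d = {
            "stance_duration": self.stance_duration,
            "swing_duration": self.swing_duration,
            "stride_duration": self.stride_duration,
            "stance_to_stride": self.stance_to_stride,
            "swing_to_stride": self.swing_to_stride,
            "stance_to_swing": self.stance_to_swing,
            "stride_length": self.stride_length,
            "hoof_height_range_swing": self.hoof_height_range_swing,
            "hoof_lateral_deviation": self.hoof_lateral_deviation,
            "hoof_forward_swing_velocity": self.hoof_forward_swing_velocity,
            "hoof_vertical_swing_velocity": self.hoof_vertical_swing_velocity,
        }
        if self.inter_limb_stance_distance is not None:
            d["inter_limb_stance_distance"] = self.inter_limb_stance_distance
        for joint, summ in self.joint_angles.items():
            for k, v in summ.items():
                d[f"{joint}_{k}"] = v
        return d


def limb_measure_units(name: str) -> str:
    if name.endswith("duration"):
        return "s"
    if "velocity" in name:
        return "m/s"
    if name.startswith(("stance_to", "swing_to")):
        return "ratio"
    if any(name.startswith(j) for j in JOINTS):
        return "deg"
    return "cm"


def global_parameters(trial: Trial) -> GlobalParameters:
    """Whole-trial means; requires preprocessed HEAD, T1, T13, L7."""
    trial.require("HEAD", "T1", "T13", "L7")
    ax = trial.axes
    t1 = trial.marker("T1")
    vel = differentiate(t1, trial.sample_rate)
    head = trial.marker("HEAD").positions
    t1p = t1.positions
    t13 = trial.marker("T13").positions
    l7 = trial.marker("L7").positions
    return GlobalParameters(
        mean_forward_velocity=float(np.mean(vel[:, ax.progression])),
        head_to_T1_vertical=float(np.mean(head[:, ax.vertical] - t1p[:, ax.vertical])) * MM_TO_CM,
        head_to_T1_lateral=float(np.mean(head[:, ax.lateral] - t1p[:, ax.lateral])) * MM_TO_CM,
        T1_to_T13_vertical=float(np.mean(t1p[:, ax.vertical] - t13[:, ax.vertical])) * MM_TO_CM,
        T13_to_L7_vertical=float(np.mean(t13[:, ax.vertical] - l7[:, ax.vertical])) * MM_TO_CM,
    )


def joint_angle_series(trial: Trial, joint: str, limb: str) -> np.ndarray:
    """Signed sagittal-plane joint angle per frame, degrees (NaN where degenerate).

    Frames where either projected vector is shorter than 1 mm are flagged as
    missing (NaN) and excluded from downstream min/max summaries.
    """
    jdef = JOINTS[joint] if isinstance(joint, str) else joint
    p1, p2, d1, d2 = jdef.marker_labels(limb)
    trial.require(p1, p2, d1, d2)
    yz = list(trial.axes.sagittal)
    prox = trial.marker(p2).positions[:, yz] - trial.marker(p1).positions[:, yz]
    dist = trial.marker(d2).positions[:, yz] - trial.marker(d1).positions[:, yz]
    np_len = np.linalg.norm(prox, axis=1)
    nd_len = np.linalg.norm(dist, axis=1)
    cross = prox[:, 0] * dist[:, 1] - prox[:, 1] * dist[:, 0]
    dot = prox[:, 0] * dist[:, 0] + prox[:, 1] * dist[:, 1]
    ang = np.degrees(np.arctan2(cross, dot))
    ang[(np_len < 1.0) | (nd_len < 1.0)] = np.nan
    return ang


def _phase_summary(angles: np.ndarray, frames: slice) -> dict[str, float]:
    seg = angles[frames]
    seg = seg[np.isfinite(seg)]
    if seg.size == 0:
        return {"min": np.nan, "max": np.nan, "range": np.nan}
    return {
        "min": float(seg.min()),
        "max": float(seg.max()),
        "range": float(seg.max() - seg.min()),
    }


def limb_parameters(
    trial: Trial,
    cycle: GaitCycle,
    contra_stance: np.ndarray | None = None,
    event_spec: EventSpec = EventSpec(),
) -> LimbParameters:
    """All per-cycle outcome measures for one limb.

    ``contra_stance`` is the contralateral limb's full-trial stance mask;
    when omitted it is detected from that limb's hoof marker if present, and
    the inter-limb distance is reported as missing if the marker is absent.
    """
    limb = cycle.limb
    rate = trial.sample_rate
    ax = trial.axes
    hoof_label = limb_marker("DPHAL", limb)
    hoof = trial.marker(hoof_label)
    pos = hoof.positions
    vel = differentiate(hoof, rate)

    stance_s = cycle.n_stance / rate
    swing_s = cycle.n_swing / rate
    stride_s = cycle.n_stride / rate
    sw = cycle.swing_frames

    y = pos[:, ax.progression]
    stride_len_cm = float(y[cycle.next_foot_strike] - y[cycle.foot_strike]) * MM_TO_CM
    z_sw = pos[sw, ax.vertical]
    x_sw = pos[sw, ax.lateral]
    hoof_height_range = float(z_sw.max() - z_sw.min()) * MM_TO_CM
    lateral_dev = float(x_sw.max() - x_sw.min()) * MM_TO_CM
    v_fwd = float(np.mean(np.abs(vel[sw, ax.progression])))
    v_vert = float(np.mean(np.abs(vel[sw, ax.vertical])))

    inter_limb = _inter_limb_distance(trial, cycle, contra_stance, event_spec)

    joint_angles: dict[str, dict[str, float]] = {}
    for joint in joints_for_limb(limb):
        labels = JOINTS[joint].marker_labels(limb)
        if not all(lab in trial.markers for lab in labels):
            continue
        ang = joint_angle_series(trial, joint, limb)
        st_summ = _phase_summary(ang, cycle.stance_frames)
        sw_summ = _phase_summary(ang, cycle.swing_frames)
        joint_angles[joint] = {
            "min_stance": st_summ["min"], "max_stance": st_summ["max"],
            "range_stance": st_summ["range"],
            "min_swing": sw_summ["min"], "max_swing": sw_summ["max"],
            "range_swing": sw_summ["range"],
        }

    return LimbParameters(
        limb=limb,
        stance_duration=stance_s,
        swing_duration=swing_s,
        stride_duration=stride_s,
        stance_to_stride=stance_s / stride_s,
        swing_to_stride=swing_s / stride_s,
        stance_to_swing=stance_s / swing_s,
        stride_length=stride_len_cm,
        hoof_height_range_swing=hoof_height_range,
        hoof_lateral_deviation=lateral_dev,
        hoof_forward_swing_velocity=v_fwd,
        hoof_vertical_swing_velocity=v_vert,
        inter_limb_stance_distance=inter_limb,
        joint_angles=joint_angles,
    )


def _inter_limb_distance(
    trial: Trial,
    cycle: GaitCycle,
    contra_stance: np.ndarray | None,
    event_spec: EventSpec,
) -> float | None:
    """Mean ground-plane distance between the limb pair's hooves in double stance, cm."""
    limb = cycle.limb
    contra = CONTRA[limb]
    contra_label = limb_marker("DPHAL", contra)
    if contra_label not in trial.markers:
        return None
    ax = trial.axes
    hoof = trial.marker(limb_marker("DPHAL", limb)).positions
    other = trial.marker(contra_label).positions
    if contra_stance is None:
        vel = differentiate(trial.marker(contra_label), trial.sample_rate)
        contra_stance = stance_mask(vel, event_spec, trial.sample_rate, ax)
    both = np.zeros(len(hoof), dtype=bool)
    both[cycle.stance_frames] = True
    both &= contra_stance
    if not both.any():
        return None
    plane = [ax.lateral, ax.progression]
    d = np.linalg.norm(hoof[np.ix_(both, plane)] - other[np.ix_(both, plane)], axis=1)
    return float(np.mean(d)) * MM_TO_CM


def trial_study_rows(
    trial: Trial,
    cycles: dict[str, GaitCycle],
    event_spec: EventSpec = EventSpec(),
) -> StudyTable:
    """Global + per-limb measures of one trial as long-format StudyTable rows."""
    rows = []
    gp = global_parameters(trial)
    for name, value in gp.as_dict().items():
        rows.append((trial.animal_id, trial.session, "", name, value, GLOBAL_UNITS[name]))
    for limb, cycle in cycles.items():
        lp = limb_parameters(trial, cycle, event_spec=event_spec)
        for name, value in lp.as_dict().items():
            rows.append(
                (trial.animal_id, trial.session, limb, name, value, limb_measure_units(name))
            )
    return StudyTable.from_rows(rows)
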