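import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import ovigait as og
from ovigait.events import GaitCycle
from ovigait.io import ValidationError
from ovigait.kinematics import joint_angle_series, limb_parameters

from conftest import make_marker, static_global_trial

FS = 200.0


class TestGlobalParameters:
    def test_static_trial_offsets(self):
        gp = og.global_parameters(static_global_trial(head_dz=100.0, head_dx=30.0))
        assert gp.mean_forward_velocity == pytest.approx(0.0, abs=1e-12)
        assert gp.head_to_T1_vertical == pytest.approx(10.0)
        assert gp.head_to_T1_lateral == pytest.approx(3.0)

    def test_synthetic_velocity_matches_design(self, conditioned_trial,
                                               healthy_design):
        gp = og.global_parameters(conditioned_trial)
        assert gp.mean_forward_velocity == pytest.approx(
            healthy_design.forward_velocity, abs=0.01)
        assert gp.head_to_T1_lateral == pytest.approx(
            healthy_design.head_lateral_offset, abs=0.1)
        assert gp.head_to_T1_vertical == pytest.approx(
            healthy_design.head_above_T1, abs=0.1)

    def test_missing_marker_rejected(self):
        trial = static_global_trial()
        del trial.markers["L7"]
        with pytest.raises(ValidationError, match="L7"):
            og.global_parameters(trial)


def chain_trial(prox_angle_deg, dist_angle_deg, n=10):
    """Fetlock chain (METAR-PPHAL-PHAL) with given absolute segment angles."""
    def seg_dir(deg):
        r = np.deg2rad(deg)
        return np.array([0.0, np.sin(r), -np.cos(r)])

    metar = np.zeros(3)
    pphal = metar + 100.0 * seg_dir(prox_angle_deg)
    phal = pphal + 50.0 * seg_dir(dist_angle_deg)
    markers = {}
    for name, p in (("METAR_FL_L", metar), ("PPHAL_FL_L", pphal),
                    ("PHAL_FL_L", phal)):
        markers[name] = make_marker(name, np.tile(p, (n, 1)))
    return og.Trial(animal_id="toy", session="B1", markers=markers)


class TestJointAngles:
    def test_collinear_markers_zero_degrees(self):
        ang = joint_angle_series(chain_trial(10.0, 10.0), "fetlock_fore", "FL_L")
        np.testing.assert_allclose(ang, 0.0, atol=1e-9)

    def test_ninety_degree_flexion_is_negative(self):
        ang = joint_angle_series(chain_trial(10.0, -80.0), "fetlock_fore", "FL_L")
        np.testing.assert_allclose(ang, -90.0, atol=1e-9)

    def test_degenerate_vector_flagged_missing(self):
        trial = chain_trial(10.0, 10.0)
        # collapse the distal segment below the 1 mm floor at one frame
        trial.markers["PHAL_FL_L"].positions[3] = \
            trial.markers["PPHAL_FL_L"].positions[3] + [0, 0.1, 0.1]
        ang = joint_angle_series(trial, "fetlock_fore", "FL_L")
        assert np.isnan(ang[3]) and np.isfinite(ang[2])

    def test_stifle_swing_extremes_recovered(self, conditioned_trial,
                                             trial_events, healthy_design):
        # designed stifle excursion -81 to -35 degrees in swing
        cyc = og.extract_cycle(trial_events["HL_L"], conditioned_trial, "HL_L",
                               volume_centre=3.0)
        ang = joint_angle_series(conditioned_trial, "stifle", "HL_L")
        sw = ang[cyc.swing_frames]
        wf = healthy_design.joint_waveforms["stifle"]
        assert np.nanmin(sw) == pytest.approx(wf.swing_min, abs=0.5)
        assert np.nanmax(sw) == pytest.approx(wf.swing_max, abs=0.5)

    def test_all_default_waveforms_recovered_within_half_degree(
            self, conditioned_trial, trial_events, healthy_design):
        for limb, joints in (("FL_L", ("fetlock_fore", "carpus", "elbow")),
                             ("HL_R", ("fetlock_hind", "tarsus", "stifle"))):
            cyc = og.extract_cycle(trial_events[limb], conditioned_trial, limb,
                                   volume_centre=3.0)
            for joint in joints:
                wf = healthy_design.joint_waveforms[joint]
                ang = joint_angle_series(conditioned_trial, joint, limb)
                st, sw = ang[cyc.stance_frames], ang[cyc.swing_frames]
                for got, want in ((np.nanmin(st), wf.stance_min),
                                  (np.nanmax(st), wf.stance_max),
                                  (np.nanmin(sw), wf.swing_min),
                                  (np.nanmax(sw), wf.swing_max)):
                    assert got == pytest.approx(want, abs=0.5), (limb, joint)

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(st.floats(-120, 30), st.floats(10, 60), st.floats(2, 40),
           st.floats(2, 40))
    def test_any_physiological_waveform_recovered(self, smin, srange, down, up):
        # values within +-120 deg; boundary value inside the swing range,
        # as for any joint moving continuously through the cycle
        smax = min(smin + srange, 120.0)
        c = 0.5 * (smin + smax)
        wf = og.JointWaveform(smin, smax, max(c - down, -120.0),
                              min(c + up, 120.0))
        design = og.GaitDesign()
        design = replace(design,
                         joint_waveforms={**design.joint_waveforms,
                                          "carpus": wf})
        trial = og.generate_trial(design, n_cycles=4)
        cond, _ = og.preprocess_trial(trial)
        events = og.detect_trial_events(cond, limbs=("FL_L",))
        cyc = og.extract_cycle(events["FL_L"], cond, "FL_L", 3.0)
        ang = joint_angle_series(cond, "carpus", "FL_L")
        st, sw = ang[cyc.stance_frames], ang[cyc.swing_frames]
        assert np.nanmin(st) == pytest.approx(wf.stance_min, abs=0.5)
        assert np.nanmax(st) == pytest.approx(wf.stance_max, abs=0.5)
        assert np.nanmin(sw) == pytest.approx(wf.swing_min, abs=0.5)
        assert np.nanmax(sw) == pytest.approx(wf.swing_max, abs=0.5)


class TestLimbParameters:
    def test_frame_arithmetic(self):
        # 82 stance + 72 swing frames at 200 Hz
        n = 400
        pos = np.zeros((n, 3))
        pos[:, 1] = np.linspace(0, 1000.0, n)
        trial = og.Trial(animal_id="x", session="B1", markers={
            "DPHAL_FL_L": make_marker("DPHAL_FL_L", pos)})
        cyc = GaitCycle("FL_L", 100, 182, 254)
        lp = limb_parameters(trial, cyc)
        assert lp.stance_duration == pytest.approx(0.41)
        assert lp.swing_duration == pytest.approx(0.36)
        assert lp.stride_duration == pytest.approx(0.77)
        assert lp.stance_to_stride == pytest.approx(82 / 154)
        assert lp.stance_to_stride + lp.swing_to_stride == pytest.approx(1.0,
                                                                         abs=1e-12)
        assert lp.stance_to_swing == pytest.approx(
            lp.stance_to_stride / lp.swing_to_stride, abs=1e-9)

    def test_hoof_lifted_five_cm(self):
        n = 300
        pos = np.zeros((n, 3))
        pos[150, 2] = 50.0  # 5 cm spike mid-swing
        trial = og.Trial(animal_id="x", session="B1", markers={
            "DPHAL_FL_L": make_marker("DPHAL_FL_L", pos)})
        lp = limb_parameters(trial, GaitCycle("FL_L", 50, 120, 250))
        assert lp.hoof_height_range_swing == pytest.approx(5.0)

    def test_synthetic_stride_length(self, conditioned_trial, forelimb_cycle,
                                     healthy_design):
        lp = limb_parameters(conditioned_trial, forelimb_cycle)
        assert lp.stride_length == pytest.approx(
            healthy_design.stride * 100, abs=0.1)

    def test_rigid_translation_invariance(self, conditioned_trial,
                                          forelimb_cycle):
        shifted = conditioned_trial.map_markers(
            lambda m: og.MarkerTrajectory(m.label,
                                          m.positions + [500.0, -200.0, 80.0],
                                          m.occluded.copy()))
        a = limb_parameters(conditioned_trial, forelimb_cycle).as_dict()
        b = limb_parameters(shifted, forelimb_cycle).as_dict()
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-9), key

    def test_stride_length_scales_with_velocity(self, healthy_design):
        doubled = replace(healthy_design, forward_velocity=2.56)
        lengths = []
        for design in (healthy_design, doubled):
            trial = og.generate_trial(design, n_cycles=4)
            cond, _ = og.preprocess_trial(trial)
            events = og.detect_trial_events(cond, limbs=("FL_L",))
            hoof = cond.marker("DPHAL_FL_L")
            centre = float(np.mean(hoof.positions[:, 1])) / 1000
            cyc = og.extract_cycle(events["FL_L"], cond, "FL_L", centre)
            lengths.append(limb_parameters(cond, cyc).stride_length)
        assert lengths[1] == pytest.approx(2 * lengths[0], rel=0.01)

    def test_contralateral_absent_only_drops_interlimb_distance(
            self, conditioned_trial, forelimb_cycle):
        solo = og.Trial(
            animal_id="x", session="B1", sample_rate=FS,
            markers={k: v for k, v in conditioned_trial.markers.items()
                     if not k.endswith("_FL_R")})
        lp = limb_parameters(solo, forelimb_cycle)
        assert lp.inter_limb_stance_distance is None
        assert np.isfinite(lp.stride_length)
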