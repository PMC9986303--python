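import numpy as np
import pytest
from dataclasses import replace

import ovigait as og
from ovigait.io import ValidationError
from ovigait.neuroscore import load_score_sheets


class TestGenerateTrial:
    def test_same_seed_bit_identical(self, tmp_path):
        noise = og.NoiseModel(seed=42)
        a = og.generate_trial(noise=noise, n_cycles=3)
        b = og.generate_trial(noise=noise, n_cycles=3)
        og.write_trial(a, tmp_path / "a.tsv")
        og.write_trial(b, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_different_seed_differs(self):
        a = og.generate_trial(noise=og.NoiseModel(seed=1), n_cycles=2)
        b = og.generate_trial(noise=og.NoiseModel(seed=2), n_cycles=2)
        assert not np.array_equal(a.marker("T1").positions,
                                  b.marker("T1").positions)

    def test_zero_velocity_design_is_static(self):
        design = replace(og.GaitDesign(), forward_velocity=0.0)
        trial = og.generate_trial(design, n_cycles=3)
        for m in trial.markers.values():
            assert np.ptp(m.positions, axis=0).max() < 1e-9
        cond, _ = og.preprocess_trial(trial)
        assert og.detect_trial_events(cond)["FL_L"] == []

    def test_hoof_exactly_stationary_in_stance(self, healthy_trial,
                                               healthy_design):
        hoof = healthy_trial.marker("DPHAL_FL_L").positions
        d = healthy_design
        t = healthy_trial.times
        u = (t / d.cycle_duration - d.phase_offsets["FL_L"]) % 1.0
        stance = u < d.duty("FL_L")
        # within each stance the hoof must not move at all
        dy = np.abs(np.diff(hoof[:, 1]))
        interior = stance[:-1] & stance[1:]
        assert dy[interior].max() < 1e-9

    def test_all_42_markers_present(self, healthy_trial):
        assert og.validate_marker_set(healthy_trial, "full").passed
        assert len(healthy_trial.markers) == 42

    def test_occlusion_noise_produces_gaps(self):
        noise = og.NoiseModel(white_sd=0.3, occlusion_rate=0.01, seed=7)
        trial = og.generate_trial(noise=noise, n_cycles=3)
        assert any(m.occluded.any() for m in trial.markers.values())

    def test_invalid_design_rejected(self):
        with pytest.raises(ValidationError):
            og.GaitDesign(cycle_duration=-1.0)
        with pytest.raises(ValidationError):
            og.GaitDesign(duty_factor=1.5)
        with pytest.raises(ValidationError):
            og.GaitDesign(stride_length=2.0)  # inconsistent with v * cycle


class TestStrokeEffect:
    def test_zero_effect_leaves_design_unchanged(self, healthy_design):
        assert og.StrokeEffect().apply(healthy_design) == healthy_design

    def test_preset_shifts_velocity_and_head(self, healthy_design):
        post = og.POST_STROKE_DAY3.apply(healthy_design)
        assert post.forward_velocity == pytest.approx(1.0)
        assert post.head_above_T1 == pytest.approx(20.0 - 8.21)

    def test_per_limb_stance_deltas_preserved(self, healthy_design):
        post = og.POST_STROKE_DAY3.apply(healthy_design)
        for limb, delta in og.POST_STROKE_DAY3.delta_stance.items():
            designed = healthy_design.duty(limb) * healthy_design.cycle_duration
            assert post.duty(limb) * post.cycle_duration == pytest.approx(
                designed + delta, abs=1e-9)

    def test_monotonic_stance_prolongation(self):
        """Larger injected stance deltas yield strictly longer measured stance."""
        measured = []
        for delta in (0.0, 0.06, 0.13):
            effect = og.StrokeEffect(delta_stance=delta)
            trial = og.generate_trial(og.GaitDesign(), effect, n_cycles=4)
            cond, _ = og.preprocess_trial(trial)
            events = og.detect_trial_events(cond, limbs=("FL_L",))["FL_L"]
            measured.append(np.mean([t - s for s, t in events[:-1]]))
        assert measured[0] < measured[1] < measured[2]


class TestGenerateCohort:
    def test_single_animal_with_dispersion_rejected(self):
        with pytest.raises(ValidationError, match="2 animals"):
            og.generate_cohort(n_animals=1, seed=0)

    def test_no_baseline_rejected(self):
        with pytest.raises(ValidationError, match="baseline"):
            og.generate_cohort(n_animals=4, sessions=("D3",), seed=0)

    def test_effect_without_post_session_rejected(self):
        with pytest.raises(ValidationError, match="post"):
            og.generate_cohort(n_animals=4, sessions=("B1", "B2"), seed=0)

    def test_baseline_only_cohort_without_effect(self):
        cohort = og.generate_cohort(n_animals=4, sessions=("B1", "B2", "B3"),
                                    effect_post=None, seed=0)
        assert set(cohort.measured.df["session"]) == {"B1", "B2", "B3"}

    def test_random_effects_shared_across_sessions(self):
        cohort = og.generate_cohort(n_animals=6, effect_post=None,
                                    residual_sd=og.ResidualSD(0, 0, 0, 0, 0),
                                    seed=5)
        df = cohort.measured.df
        vel = df[df["measure"] == "mean_forward_velocity"]
        for _, grp in vel.groupby("animal"):
            assert grp["value"].std() < 1e-12  # identical across sessions

    def test_score_sheets_validate_against_rubric(self):
        cohort = og.generate_cohort(n_animals=4, seed=11)
        scores = load_score_sheets(cohort.neuroscores)
        assert len(scores) == 4 * 4
        post_totals = [s.total for s in scores if s.session == "D3"]
        base_totals = [s.total for s in scores if s.session != "D3"]
        assert np.mean(post_totals) > np.mean(base_totals)

    def test_ground_truth_records_designed_values(self):
        cohort = og.generate_cohort(
            n_animals=2, between_animal_sd=og.BetweenAnimalSD(0, 0, 0, 0, 0),
            seed=0)
        gt = cohort.ground_truth.df
        base = gt[(gt["session"] == "B1") & (gt["limb"] == "FL_L")
                  & (gt["measure"] == "stance_duration")]
        assert base["value"].iloc[0] == pytest.approx(0.41)
        post = gt[(gt["session"] == "D3") & (gt["limb"] == "FL_L")
                  & (gt["measure"] == "stance_duration")]
        assert post["value"].iloc[0] == pytest.approx(0.54)

    def test_trajectories_mode_renders_trials(self):
        cohort = og.generate_cohort(
            n_animals=2, sessions=("B1", "D3"), n_trials=1,
            trajectories=True, n_cycles=3, seed=3)
        assert len(cohort.trials) == 4
        trial = cohort.trials[("A01", "B1", 0)]
        assert og.validate_marker_set(trial, "full").passed

    def test_seed_determinism(self):
        a = og.generate_cohort(n_animals=3, seed=9)
        b = og.generate_cohort(n_animals=3, seed=9)
        assert a.measured.df["value"].equals(b.measured.df["value"])
        assert a.infarct_volumes.equals(b.infarct_volumes)
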