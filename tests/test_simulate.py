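"""Synthetic gaze generator: determinism, structure, and ground-truth contracts."""

import numpy as np
import pytest

from gazeseq import (
    AttentionModel,
    ExperimentDesign,
    StimulusMeta,
    TrialTimeline,
    detect_fixations,
    scanpath_string,
    similarity_ratio,
    simulate_experiment,
    simulate_trial,
)
from gazeseq.presets import default_study


def test_same_seed_bit_identical(timeline, abc_stimulus, geometry):
    model = AttentionModel(adherence=0.7)
    r1, g1 = simulate_trial(timeline, model, abc_stimulus, geometry, seed=99)
    r2, g2 = simulate_trial(timeline, model, abc_stimulus, geometry, seed=99)
    assert np.array_equal(r1.time_ms, r2.time_ms)
    assert np.array_equal(r1.x_px, r2.x_px)
    assert np.array_equal(r1.y_px, r2.y_px)
    assert g1.visits == g2.visits
    r3, _ = simulate_trial(timeline, model, abc_stimulus, geometry, seed=100)
    assert not np.array_equal(r1.x_px, r3.x_px)


def test_noiseless_full_adherence_visits_intended(timeline, abc_stimulus, geometry,
                                                  noiseless_model):
    _, gt = simulate_trial(timeline, noiseless_model, abc_stimulus, geometry, seed=1)
    assert "".join(gt.visits) == abc_stimulus.aois.intended_sequence


def test_sampling_grid_and_epochs(timeline, abc_stimulus, geometry, noiseless_model):
    rec, gt = simulate_trial(timeline, noiseless_model, abc_stimulus, geometry, seed=2)
    dt = 1000.0 / rec.sampling_rate
    assert np.allclose(np.diff(rec.time_ms), dt)
    assert rec.stimulus_onset == timeline.cross_duration
    # leading and trailing cross fixations present in the ground truth
    assert gt.fixations[0].label is None and gt.fixations[-1].label is None
    assert gt.fixations[0].start == 0.0
    assert rec.duration >= timeline.cross_duration + timeline.post_cross_duration


def test_unknown_intended_label_raises(timeline, abc_stimulus, geometry):
    model = AttentionModel(intended_sequence="AXB", adherence=1.0)
    with pytest.raises(ValueError, match="'X'"):
        simulate_trial(timeline, model, abc_stimulus, geometry, seed=0)


def test_cross_inside_aoi_raises(abc_stimulus, geometry, noiseless_model):
    bad = TrialTimeline(cross_position=(560.0, 540.0))  # centre of AOI A
    with pytest.raises(ValueError, match="cross_position"):
        simulate_trial(bad, noiseless_model, abc_stimulus, geometry, seed=0)


def test_adherence_extremes_similarity(timeline, abc_stimulus, geometry):
    """Ground-truth visit sequences align better with the intended order at adherence 1."""
    means = {}
    for adh in (0.0, 1.0):
        model = AttentionModel(adherence=adh)
        vals = []
        for i in range(200):
            _, gt = simulate_trial(
                timeline, model, abc_stimulus, geometry,
                seed=np.random.SeedSequence((5, int(adh), i)),
            )
            vals.append(similarity_ratio("".join(gt.visits), "ABC").ratio)
        means[adh] = np.mean(vals)
    assert means[1.0] > means[0.0]
    assert means[1.0] == 1.0


def test_default_experiment_yields_272_records():
    design, models, stimuli, geometry, timeline = default_study(seed=3)
    result = simulate_experiment(design, models, stimuli, geometry, timeline)
    assert len(result.recordings) == 272
    assert len(result.ground_truths) == 272
    table = result.ground_truth_table()
    assert len(table) == 272
    assert set(table["condition"]) == set(design.conditions)


def test_single_trial_design(abc_stimulus, timeline, geometry):
    design = ExperimentDesign(
        n_participants=1, n_trials=1, conditions=("only",), seed=0
    )
    result = simulate_experiment(
        design, {"only": AttentionModel()}, {"only": abc_stimulus}, geometry, timeline
    )
    assert len(result.recordings) == 1


def test_condition_order_balance():
    design, models, stimuli, geometry, timeline = default_study(seed=4)
    orders = simulate_experiment(design, models, stimuli, geometry, timeline).orders
    k = len(design.conditions)
    # within each complete 8-participant block every condition occupies every
    # ordinal position exactly once
    for b in range(design.n_participants // k):
        block = orders[b * k : (b + 1) * k]
        for col in range(k):
            assert sorted(block[:, col]) == list(range(k))


def test_missing_condition_model_raises(abc_stimulus, timeline, geometry):
    design = ExperimentDesign(n_participants=2, n_trials=2, conditions=("a", "b"), seed=0)
    models = {"a": AttentionModel()}
    stimuli = {"a": abc_stimulus, "b": abc_stimulus}
    with pytest.raises(ValueError, match="'b'"):
        simulate_experiment(design, models, stimuli, geometry, timeline)


def test_detector_recovers_planned_fixations(timeline, abc_stimulus, geometry):
    """Count and boundary agreement between detector output and ground truth."""
    model = AttentionModel(adherence=0.8)
    dt = 1000.0 / 120.0 + 1e-6
    hits = 0
    n_trials = 100
    for i in range(n_trials):
        rec, gt = simulate_trial(
            timeline, model, abc_stimulus, geometry, seed=np.random.SeedSequence((8, i))
        )
        fx = detect_fixations(rec, geometry=geometry)
        if len(fx) == len(gt.fixations) and all(
            abs(f.start - g.start) <= dt and abs(f.end - g.end) <= dt
            for f, g in zip(fx, gt.fixations)
        ):
            hits += 1
    assert hits >= 0.95 * n_trials


def test_fixed_saccade_duration_respected(timeline, abc_stimulus, geometry):
    model = AttentionModel(adherence=1.0, jitter_sd=0.0, measurement_noise_sd=0.0,
                           saccade_duration=50.0)
    rec, gt = simulate_trial(timeline, model, abc_stimulus, geometry, seed=6)
    # gap between consecutive ground-truth fixations equals the fixed saccade time
    gaps = [
        b.start - a.end for a, b in zip(gt.fixations, gt.fixations[1:])
    ]
    assert all(abs(g - 50.0) <= 1000.0 / 120.0 + 1e-6 for g in gaps)


def test_invalid_model_parameters():
    with pytest.raises(ValueError, match="adherence"):
        AttentionModel(adherence=1.5)
    with pytest.raises(ValueError, match="fixation_duration_mean"):
        AttentionModel(fixation_duration_mean=50.0)


def test_salience_must_be_nonnegative(abc_aois):
    with pytest.raises(ValueError, match="salience"):
        StimulusMeta(stimulus_id="s", aois=abc_aois, salience={"A": -1.0})
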