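"""TTFF, dwell time, and per-trial metric assembly."""

import numpy as np
import pytest

from gazeseq import (
    AnalysisWindow,
    AttentionModel,
    Fixation,
    detect_fixations,
    dwell_time,
    is_first_of_block,
    metrics_table,
    simulate_trial,
    trial_metrics,
    ttff,
)


def _fix(x, y, start, dur):
    return Fixation(
        start=start, end=start + dur, duration=dur,
        centroid_x=x, centroid_y=y, dispersion=0.1, n_samples=12,
    )


A = (560.0, 540.0)
B = (960.0, 540.0)


class TestTTFF:
    def test_fixation_at_onset(self, abc_aois):
        fx = [_fix(*A, start=0.0, dur=150.0)]
        assert ttff(fx, "A", abc_aois, onset=0.0) == 0.0

    def test_second_fixation_queried(self, abc_aois):
        # fixations: [0-120 ms in B], [130-260 ms in A] -> TTFF(A) = 130
        fx = [_fix(*B, start=0.0, dur=120.0), _fix(*A, start=130.0, dur=130.0)]
        assert ttff(fx, "A", abc_aois, onset=0.0) == 130.0
        assert ttff(fx, "B", abc_aois, onset=0.0) == 0.0

    def test_missing_when_never_entered(self, abc_aois):
        fx = [_fix(*B, start=0.0, dur=150.0)]
        assert ttff(fx, "A", abc_aois) is None

    def test_relative_to_onset(self, abc_aois):
        fx = [_fix(*A, start=500.0, dur=150.0)]
        assert ttff(fx, "A", abc_aois, onset=400.0) == 100.0

    def test_short_fixation_does_not_qualify(self, abc_aois):
        fx = [_fix(*A, start=0.0, dur=90.0), _fix(*A, start=200.0, dur=120.0)]
        assert ttff(fx, "A", abc_aois) == 200.0

    def test_unknown_aoi_raises(self, abc_aois):
        with pytest.raises(KeyError, match="'Z'"):
            ttff([], "Z", abc_aois)


class TestDwell:
    def test_sums_qualifying_durations(self, abc_aois):
        fx = [_fix(*A, start=0.0, dur=120.0), _fix(*A, start=300.0, dur=200.0)]
        assert dwell_time(fx, "A", abc_aois) == 320.0

    def test_empty_aoi_zero(self, abc_aois):
        assert dwell_time([], "A", abc_aois) == 0.0

    def test_below_gate_excluded(self, abc_aois):
        fx = [_fix(*A, start=0.0, dur=90.0)]
        assert dwell_time(fx, "A", abc_aois) == 0.0

    def test_window_bounds_by_start(self, abc_aois):
        fx = [_fix(*A, start=100.0, dur=200.0), _fix(*A, start=500.0, dur=150.0)]
        w = AnalysisWindow(start=0.0, end=450.0)
        # the 100 ms fixation starts inside the window and counts in full
        assert dwell_time(fx, "A", abc_aois, onset=0.0, window=w) == 200.0

    def test_unknown_aoi_raises(self, abc_aois):
        with pytest.raises(KeyError, match="'Q'"):
            dwell_time([], "Q", abc_aois)


def test_window_validation():
    with pytest.raises(ValueError, match="window"):
        AnalysisWindow(start=100.0, end=100.0)


def test_trial_metrics_full_adherence(timeline, abc_stimulus, geometry, noiseless_model):
    rec, _ = simulate_trial(timeline, noiseless_model, abc_stimulus, geometry, seed=11)
    fx = detect_fixations(rec, geometry=geometry)
    tm = trial_metrics(fx, abc_stimulus.aois, onset=rec.stimulus_onset)
    assert tm.similarity.ratio == 1.0
    assert tm.observed_sequence == "ABC"
    for label in "ABC":
        assert tm.aoi_metrics[label].ttff is not None
        assert tm.aoi_metrics[label].dwell > 0


def test_dwell_sum_bounded_by_total_fixation_time(timeline, abc_stimulus, geometry):
    model = AttentionModel(adherence=0.5)
    rec, _ = simulate_trial(timeline, model, abc_stimulus, geometry, seed=12)
    fx = detect_fixations(rec, geometry=geometry)
    onset = rec.stimulus_onset
    tm = trial_metrics(fx, abc_stimulus.aois, onset=onset)
    total = sum(f.duration for f in fx if f.start >= onset and f.duration >= 100.0)
    assert sum(m.dwell for m in tm.aoi_metrics.values()) <= total + 1e-9


def test_metrics_invariant_to_aoi_order(abc_aois):
    from gazeseq import AOISet

    reordered = AOISet(
        stimulus=abc_aois.stimulus,
        aois=tuple(reversed(abc_aois.aois)),
        intended_sequence=abc_aois.intended_sequence,
    )
    fx = [_fix(*B, start=0.0, dur=120.0), _fix(*A, start=200.0, dur=150.0)]
    for label in "AB":
        assert ttff(fx, label, abc_aois) == ttff(fx, label, reordered)
        assert dwell_time(fx, label, abc_aois) == dwell_time(fx, label, reordered)


def test_first_of_block_exclusion_rule():
    flags = [is_first_of_block(i, block_size=4) for i in range(8)]
    assert flags == [True, False, False, False, True, False, False, False]


def test_trial_metrics_excluded_flag_propagates(abc_aois):
    tm = trial_metrics([], abc_aois, trial=4, excluded=is_first_of_block(4))
    assert tm.excluded is True
    table = metrics_table([tm])
    assert table["excluded"].all()


def test_metrics_table_shape(abc_aois):
    fx = [_fix(*A, start=0.0, dur=120.0)]
    tm = trial_metrics(fx, abc_aois, participant=3, trial=1, condition="c")
    table = metrics_table([tm])
    # 3 AOIs x 3 metrics + 3 sequence metrics
    assert len(table) == 12
    assert set(table["metric"]) == {
        "ttff", "dwell", "n_fix", "distance", "similarity", "similarity_pct"
    }
    ttff_b = table[(table.metric == "ttff") & (table.aoi == "B")]["value"].iloc[0]
    assert np.isnan(ttff_b)  # missing TTFF stored as NaN, never imputed
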