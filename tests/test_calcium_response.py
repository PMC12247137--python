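"""ΔF/F0, activation calls, overlap and amplitude statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from somatomode import (
    DeltaFOverF,
    Epoch,
    FluorescenceRecording,
    StimulusResponseCaller,
    activated_fraction,
    call_responses,
    compare_amplitudes,
    compute_dff,
    population_mean_dff,
    round_half_away,
    summarize_overlap,
)
from somatomode.calcium_response import ResponseCallTable


def _recording_from_traces(traces, frame_rate=1.0, epochs=()):
    return FluorescenceRecording(
        traces=np.asarray(traces, float), frame_rate=frame_rate, epochs=epochs
    )


def _call_table(rows):
    df = pd.DataFrame(rows, columns=["neuron_id", "stimulus", "activated"])
    df["peak_dff"] = np.where(df["activated"], 50.0, 0.0)
    df["window_start"], df["window_end"] = 0.0, 1.0
    return ResponseCallTable(calls=df, threshold_pct=20.0)


def _overlap_fixture(n_both, n_only_a, n_only_b, a="A", b="B"):
    rows = []
    i = 0
    for _ in range(n_both):
        rows += [(f"n{i}", a, True), (f"n{i}", b, True)]
        i += 1
    for _ in range(n_only_a):
        rows += [(f"n{i}", a, True), (f"n{i}", b, False)]
        i += 1
    for _ in range(n_only_b):
        rows += [(f"n{i}", a, False), (f"n{i}", b, True)]
        i += 1
    rows += [(f"n{i}", a, False), (f"n{i}", b, False)]
    return _call_table(rows)


class TestDff:
    def test_constant_trace_gives_zero_dff_everywhere(self):
        rec = _recording_from_traces(np.full((1, 100), 100.0))
        dff = compute_dff(rec, baseline_s=60)
        assert np.allclose(dff.dff, 0.0)

    def test_step_from_100_to_120_gives_20_percent(self):
        trace = np.concatenate([np.full(60, 100.0), np.full(40, 120.0)])
        dff = compute_dff(_recording_from_traces(trace[None, :]), baseline_s=60)
        assert np.allclose(dff.dff[0, 60:], 20.0)
        assert np.allclose(dff.dff[0, :60], 0.0)

    def test_matches_frame_by_frame_oracle_on_small_traces(self):
        rng = np.random.default_rng(0)
        traces = rng.uniform(50, 150, size=(5, 10))
        dff = compute_dff(_recording_from_traces(traces, frame_rate=1.0), baseline_s=3)
        for i in range(5):
            f0 = sum(traces[i, k] for k in range(3)) / 3.0  # independent re-evaluation
            for t in range(10):
                expected = (traces[i, t] - f0) / f0 * 100.0
                assert dff.dff[i, t] == pytest.approx(expected, abs=1e-12)

    def test_baseline_mean_is_zero_for_every_neuron(self, small_recording):
        rec, _ = small_recording
        dff = compute_dff(rec)
        k = int(60 * rec.frame_rate)
        assert np.abs(dff.dff[:, :k].mean(axis=1)).max() < 1e-9

    def test_baseline_overlapping_epoch_is_rejected(self):
        rec = _recording_from_traces(
            np.full((1, 200), 100.0), epochs=(Epoch("pinch", 30.0, 40.0),)
        )
        with pytest.raises(ValueError, match="overlaps epoch"):
            compute_dff(rec, baseline_s=60)

    @given(st.floats(min_value=1.0, max_value=1e4), st.floats(min_value=-0.5, max_value=5.0))
    def test_dff_is_invariant_to_baseline_scale(self, f0, rel):
        trace = np.concatenate([np.full(5, f0), [f0 * (1 + rel)]])
        dff = compute_dff(_recording_from_traces(trace[None, :]), baseline_s=5)
        assert dff.dff[0, -1] == pytest.approx(100 * rel, rel=1e-9, abs=1e-7)


class TestCalls:
    def _dff_with_peak(self, peak, frame=80):
        trace = np.full((1, 200), 100.0)
        trace[0, frame] = 100.0 * (1 + peak / 100.0)
        rec = _recording_from_traces(trace, epochs=(Epoch("pinch", 70.0, 90.0),))
        return compute_dff(rec, baseline_s=60), rec.epochs

    def test_threshold_is_inclusive_at_exactly_20_percent(self):
        dff, epochs = self._dff_with_peak(20.0)
        calls = call_responses(dff, epochs)
        assert calls.calls["activated"].iloc[0]

    def test_just_below_threshold_is_not_activated(self):
        dff, epochs = self._dff_with_peak(19.9)
        calls = call_responses(dff, epochs)
        assert not calls.calls["activated"].iloc[0]

    def test_chemical_excursion_within_first_minute_is_ignored(self):
        trace = np.full((1, 900), 100.0)
        trace[0, 130] = 150.0  # 10 s after injection: inside the excluded minute
        rec = _recording_from_traces(trace, epochs=(Epoch("cq", 120.0, 125.0, "chemical"),))
        calls = call_responses(compute_dff(rec), rec.epochs)
        row = calls.calls.iloc[0]
        assert not row["activated"]
        assert row["window_start"] == pytest.approx(180.0)

    def test_same_excursion_after_the_exclusion_is_called(self):
        trace = np.full((1, 900), 100.0)
        trace[0, 300] = 150.0  # 180 s post injection
        rec = _recording_from_traces(trace, epochs=(Epoch("cq", 120.0, 125.0, "chemical"),))
        calls = call_responses(compute_dff(rec), rec.epochs)
        assert calls.calls["activated"].iloc[0]

    def test_raising_threshold_never_increases_counts(self, small_recording):
        rec, _ = small_recording
        dff = compute_dff(rec)
        prev_counts = None
        for thr in [10.0, 20.0, 30.0, 50.0, 80.0]:
            calls = call_responses(dff, rec.epochs, threshold_pct=thr)
            counts = [calls.n_activated(s) for s in calls.stimuli]
            union = len(calls.activated_ids("pinch") | calls.activated_ids("brush"))
            if prev_counts is not None:
                assert all(c <= p for c, p in zip(counts, prev_counts[0]))
                assert union <= prev_counts[1]
            prev_counts = (counts, union)

    def test_empty_window_after_exclusion_is_an_error(self):
        trace = np.full((1, 700), 100.0)
        rec = _recording_from_traces(trace, epochs=(Epoch("cq", 660.0, 665.0, "chemical"),))
        dff = compute_dff(rec)
        with pytest.raises(ValueError, match="empty"):
            call_responses(dff, rec.epochs)

    def test_estimators_compose_like_a_pipeline(self, small_recording):
        rec, _ = small_recording
        dff_est = DeltaFOverF(frame_rate=rec.frame_rate, baseline_s=60).fit(rec.traces)
        caller = StimulusResponseCaller(epochs=rec.epochs, frame_rate=rec.frame_rate)
        X = dff_est.transform(rec.traces)
        caller.fit(X)
        preds = caller.predict(X)
        calls = call_responses(compute_dff(rec), rec.epochs)
        table = calls.calls.pivot(index="neuron_id", columns="stimulus", values="activated")
        labels = [e.label for e in rec.epochs]
        assert np.array_equal(preds, table[labels].to_numpy())


class TestOverlap:
    def test_mechanical_overlap_counts_give_printed_percentages(self):
        calls = _overlap_fixture(198, 293, 39, a="pinch", b="brush")
        ov = summarize_overlap(calls, "pinch", "brush")
        assert (ov.n_both, ov.n_only_a, ov.n_only_b, ov.n_union) == (198, 293, 39, 530)
        assert (ov.pct_both, ov.pct_only_a, ov.pct_only_b) == (37.4, 55.3, 7.4)

    def test_chemical_overlap_counts_give_printed_percentages(self):
        calls = _overlap_fixture(88, 50, 94, a="chloroquine", b="formalin")
        ov = summarize_overlap(calls, "chloroquine", "formalin")
        assert ov.n_union == 232
        assert (ov.pct_both, ov.pct_only_a, ov.pct_only_b) == (37.9, 21.6, 40.5)

    def test_degenerate_single_stimulus_overlap(self):
        ov = summarize_overlap(_overlap_fixture(0, 5, 0), "A", "B")
        assert (ov.pct_both, ov.pct_only_a, ov.pct_only_b) == (0.0, 100.0, 0.0)

    def test_empty_union_is_flagged_not_divided(self):
        ov = summarize_overlap(_overlap_fixture(0, 0, 0), "A", "B")
        assert not ov.defined
        assert ov.pct_both is None and ov.n_union == 0

    @given(st.integers(0, 400), st.integers(0, 400), st.integers(0, 400))
    def test_unrounded_percentages_sum_to_100_and_rounded_nearly(self, b, oa, ob):
        if b + oa + ob == 0:
            return
        calls = _overlap_fixture(b, oa, ob)
        ov = summarize_overlap(calls, "A", "B")
        exact = 100.0 * (ov.n_both + ov.n_only_a + ov.n_only_b) / ov.n_union
        assert exact == pytest.approx(100.0, abs=1e-9)
        assert 99.8 <= ov.pct_both + ov.pct_only_a + ov.pct_only_b <= 100.2

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(37.358490566, 1) == 37.4
        assert round_half_away(0.05, 1) == 0.1
        assert round_half_away(-0.05, 1) == -0.1
        assert round_half_away(41.7097, 1) == 41.7


class TestFractionsAndAmplitudes:
    def test_activated_fraction_simple_ratios(self):
        calls = _overlap_fixture(0, 50, 0, a="pinch", b="brush")
        assert activated_fraction(calls, "pinch", 200) == 25.0
        assert activated_fraction(calls, "brush", 100) == 0.0
        with pytest.raises(ValueError):
            activated_fraction(calls, "pinch", 0)
        with pytest.raises(ValueError):
            activated_fraction(calls, "pinch", 10)

    def test_population_mean_matches_brute_force_oracle(self, small_recording):
        rec, _ = small_recording
        dff = compute_dff(rec)
        subset = list(dff.neuron_ids[:5])
        out = population_mean_dff(dff, subset)
        sub = dff.dff[:5]
        for t in [0, 100, 500]:
            vals = [sub[i, t] for i in range(5)]
            mean = sum(vals) / 5
            sem = math.sqrt(sum((v - mean) ** 2 for v in vals) / 4) / math.sqrt(5)
            assert out["mean_dff"].iloc[t] == pytest.approx(mean, abs=1e-9)
            assert out["sem_dff"].iloc[t] == pytest.approx(sem, abs=1e-9)

    def test_single_neuron_mean_is_its_trace_and_sem_zero(self, small_recording):
        rec, _ = small_recording
        dff = compute_dff(rec)
        out = population_mean_dff(dff, [dff.neuron_ids[0]])
        assert np.allclose(out["mean_dff"], dff.dff[0])
        assert np.all(out["sem_dff"] == 0)

    def test_two_identical_neurons_have_zero_sem(self):
        trace = np.vstack([np.full(100, 100.0), np.full(100, 100.0)])
        dff = compute_dff(_recording_from_traces(trace), baseline_s=60)
        out = population_mean_dff(dff, list(dff.neuron_ids))
        assert np.all(out["sem_dff"] == 0)

    def test_t_test_matches_closed_form_pooled_variance(self):
        res = compare_amplitudes([1, 2, 3], [4, 5, 6])
        # pooled variance = 1, se = sqrt(1*(1/3+1/3)), t = -3/se, df = 4
        se = math.sqrt(2.0 / 3.0)
        assert res.t == pytest.approx(-3.0 / se, abs=1e-12)
        from scipy.stats import t as tdist

        assert res.p == pytest.approx(2 * tdist.sf(3.0 / se, df=4), abs=1e-12)
        assert res.mean_a == 2.0 and res.n_a == 3
        assert res.sem_a == pytest.approx(1.0 / math.sqrt(3))

    def test_swapping_groups_negates_t_and_preserves_p(self):
        r1 = compare_amplitudes([1, 5, 3, 2], [7, 8, 6])
        r2 = compare_amplitudes([7, 8, 6], [1, 5, 3, 2])
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_identical_groups_give_t_zero_p_one(self):
        res = compare_amplitudes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_groups_smaller_than_two_rejected(self):
        with pytest.raises(ValueError):
            compare_amplitudes([1.0], [2.0, 3.0])
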