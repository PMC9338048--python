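"""Chunk-yield rule, positive packing, negative sampling and balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoseiz import (
    SeizureEvent,
    WindowParams,
    build_balanced_set,
    chunk_yield,
    extract_positive_chunks,
    sample_negative_chunks,
    track_to_events,
)

from conftest import make_recording


def packing_oracle(duration_s: int, window: int, chunks: int) -> int:
    """Count non-overlapping windows packed from the event start that end
    inside the event, capped at the requested number."""
    count, cursor = 0, 1
    while count < chunks and cursor + window - 1 <= duration_s:
        count += 1
        cursor += window
    return count


class TestChunkYield:
    @pytest.mark.parametrize(
        "duration,window,chunks,expected",
        [
            (17, 6, 3, 2),  # third window would leave the seizure
            (18, 6, 3, 3),
            (5, 6, 3, 0),  # window longer than the seizure
            (5, 6, 10_000, 0),
            (40, 5, 10_000, 8),  # sentinel takes the maximum
        ],
    )
    def test_worked_examples(self, duration, window, chunks, expected):
        params = WindowParams(window=window, chunks=chunks)
        assert chunk_yield(duration, params) == expected

    @given(
        duration=st.integers(1, 500),
        window=st.integers(1, 30),
        chunks=st.integers(1, 20),
    )
    @settings(deadline=None)
    def test_matches_packing_oracle(self, duration, window, chunks):
        params = WindowParams(window=window, chunks=chunks)
        assert chunk_yield(duration, params) == packing_oracle(duration, window, chunks)

    def test_monotonicity(self):
        # non-decreasing in chunks, non-increasing in window
        for duration in (17, 18, 40):
            yields_by_chunks = [
                chunk_yield(duration, WindowParams(window=5, chunks=c))
                for c in range(1, 10)
            ]
            assert yields_by_chunks == sorted(yields_by_chunks)
            yields_by_window = [
                chunk_yield(duration, WindowParams(window=w, chunks=5))
                for w in range(1, 10)
            ]
            assert yields_by_window == sorted(yields_by_window, reverse=True)


FIG4_EVENTS = [SeizureEvent(104, 121), SeizureEvent(150, 166)]  # 18 s and 17 s


class TestExtractPositives:
    def _rec(self):
        return make_recording(n_channels=18, fs=64, duration_s=200, seed=3)

    @pytest.mark.parametrize(
        "window,chunks,expected_total",
        [(6, 3, 5), (5, 2, 4), (2, 5, 10)],
    )
    def test_worked_two_seizure_examples(self, window, chunks, expected_total):
        params = WindowParams(window=window, chunks=chunks, fs=64)
        out = extract_positive_chunks(self._rec(), FIG4_EVENTS, params)
        assert len(out) == expected_total
        assert all(c.label == 1 for c in out)

    def test_single_second_window(self):
        params = WindowParams(window=1, chunks=1, fs=64)
        out = extract_positive_chunks(self._rec(), FIG4_EVENTS, params)
        assert [c.start_s for c in out] == [104, 150]

    def test_chunks_contained_in_their_event(self):
        rec = self._rec()
        params = WindowParams(window=6, chunks=3, fs=64)
        for chunk in extract_positive_chunks(rec, FIG4_EVENTS, params):
            end_s = chunk.start_s + params.window - 1
            containing = [
                e for e in FIG4_EVENTS if e.start_s <= chunk.start_s and end_s <= e.end_s
            ]
            assert len(containing) == 1
            np.testing.assert_array_equal(
                chunk.data, rec.second_slice(chunk.start_s, params.window)
            )

    def test_event_beyond_recording_raises(self):
        params = WindowParams(window=2, chunks=1, fs=64)
        with pytest.raises(ValueError, match="exceeds recording"):
            extract_positive_chunks(self._rec(), [SeizureEvent(199, 210)], params)

    def test_short_event_contributes_nothing(self):
        params = WindowParams(window=6, chunks=3, fs=64)
        out = extract_positive_chunks(self._rec(), [SeizureEvent(10, 12)], params)
        assert out == []


class TestSampleNegatives:
    def test_zero_request_is_empty(self):
        params = WindowParams(window=2, fs=64, seed=0)
        assert sample_negative_chunks([make_recording(fs=64)], 0, params) == []

    def test_balances_fig4_positives(self):
        params = WindowParams(window=6, chunks=3, fs=64)
        rec = make_recording(n_channels=18, fs=64, duration_s=200, seed=3)
        positives = extract_positive_chunks(rec, FIG4_EVENTS, params)
        free = make_recording(n_channels=18, fs=64, duration_s=200, seed=4)
        negatives = sample_negative_chunks([free], len(positives), params)
        assert len(negatives) == 5
        assert all(c.label == 0 for c in negatives)

    def test_seeded_determinism(self):
        params = WindowParams(window=3, fs=64, seed=42)
        free = make_recording(n_channels=18, fs=64, duration_s=120, seed=5)
        a = sample_negative_chunks([free], 10, params)
        b = sample_negative_chunks([free], 10, params)
        assert [c.start_s for c in a] == [c.start_s for c in b]

    def test_non_overlapping_within_recording(self):
        params = WindowParams(window=5, fs=64, seed=2)
        free = make_recording(n_channels=18, fs=64, duration_s=100, seed=6)
        chunks = sample_negative_chunks([free], 15, params)
        intervals = sorted((c.start_s, c.start_s + params.window - 1) for c in chunks)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 < s2

    def test_insufficient_material_reports_shortfall(self):
        params = WindowParams(window=10, fs=64, seed=0)
        free = make_recording(n_channels=18, fs=64, duration_s=30, seed=7)
        with pytest.raises(ValueError, match="insufficient"):
            sample_negative_chunks([free], 10, params)

    def test_chunk_data_matches_recording_slice(self):
        params = WindowParams(window=4, fs=64, seed=9)
        free = make_recording(n_channels=18, fs=64, duration_s=60, seed=8)
        for c in sample_negative_chunks([free], 5, params):
            np.testing.assert_array_equal(
                c.data, free.second_slice(c.start_s, params.window)
            )


class TestBuildBalancedSet:
    def test_balance_by_construction(self, balanced_chunkset):
        cs = balanced_chunkset
        assert cs.is_balanced()
        assert len(cs) % 2 == 0

    def test_totals_match_summation_oracle(self, recordings, tracks, manifest):
        """Total chunk count must equal 2 * sum of per-event yields computed
        from the expert's own event lengths on EXP3 subjects."""
        from neoseiz import summarize_cohort

        summary = summarize_cohort(tracks)
        for window, chunks in [(1, 2), (2, 3), (5, 10_000)]:
            params = WindowParams(window=window, chunks=chunks, fs=64, seed=0)
            cs = build_balanced_set(recordings, tracks, "B", params)
            track_of = {t.subject_id: t for t in tracks["B"]}
            expected_pos = sum(
                chunk_yield(ev.duration_s, params)
                for sid in summary.exp3
                for ev in track_to_events(track_of[sid])
            )
            assert len(cs.positives) == expected_pos
            assert len(cs) == 2 * expected_pos

    def test_positive_chunks_only_from_exp3_negatives_from_exp0(
        self, balanced_chunkset, tracks
    ):
        from neoseiz import summarize_cohort

        summary = summarize_cohort(tracks)
        assert {c.subject_id for c in balanced_chunkset.positives} <= set(summary.exp3)
        assert {c.subject_id for c in balanced_chunkset.negatives} <= set(summary.exp0)

    def test_negative_intervals_carry_no_annotated_second(
        self, balanced_chunkset, tracks
    ):
        by_subject = {t.subject_id: t for t in tracks["A"]}
        for c in balanced_chunkset.negatives:
            track = by_subject[c.subject_id]
            window = balanced_chunkset.params.window
            assert track.per_second[c.start_s - 1 : c.start_s - 1 + window].sum() == 0

    def test_shuffled_preserves_content(self, balanced_chunkset):
        shuffled = balanced_chunkset.shuffled(3)
        assert len(shuffled) == len(balanced_chunkset)
        assert shuffled.labels.sum() == balanced_chunkset.labels.sum()
        assert shuffled.chunks != balanced_chunkset.chunks

    def test_sentinel_takes_every_window(self, recordings, tracks):
        from neoseiz import summarize_cohort

        summary = summarize_cohort(tracks)
        params = WindowParams(window=3, chunks=10_000, fs=64, seed=0)
        cs = build_balanced_set(recordings, tracks, "A", params)
        track_of = {t.subject_id: t for t in tracks["A"]}
        expected = sum(
            ev.duration_s // 3
            for sid in summary.exp3
            for ev in track_to_events(track_of[sid])
        )
        assert len(cs.positives) == expected
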