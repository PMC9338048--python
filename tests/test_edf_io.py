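"""EDF round-trips, annotation parsing, event extraction, cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoseiz import (
    AnnotationTrack,
    Recording,
    SeizureEvent,
    events_to_track,
    read_annotations,
    read_edf,
    summarize_cohort,
    track_to_events,
    write_annotations,
    write_edf,
)
from neoseiz.edf_io import EDF_PHYSICAL_RANGE_UV, EdfFormatError

from conftest import make_recording


class TestEdfRoundTrip:
    def test_signal_recovered_within_quantization(self, tmp_path):
        rec = make_recording(n_channels=3, fs=32, duration_s=5, seed=4, amplitude=300)
        path = write_edf(rec, tmp_path / "t.edf")
        back = read_edf(path)
        bound = 2 * EDF_PHYSICAL_RANGE_UV / 2**16
        assert back.fs == rec.fs
        assert back.duration_s == rec.duration_s
        assert back.channel_labels == rec.channel_labels
        assert np.abs(back.signal - rec.signal).max() <= bound

    def test_zero_signal_round_trips_to_zero(self, tmp_path):
        rec = Recording("z", 16, ["a", "b"], np.zeros((2, 32)), 2)
        back = read_edf(write_edf(rec, tmp_path / "z.edf"))
        bound = 2 * EDF_PHYSICAL_RANGE_UV / 2**16
        assert np.abs(back.signal).max() <= bound

    def test_sample_count_is_fs_times_duration(self, tmp_path):
        # 3 channels at 2 Hz for 4 s -> exactly 8 samples per channel
        ramp = np.tile(np.arange(8.0), (3, 1))
        rec = Recording("r", 2, ["x", "y", "z"], ramp, 4)
        back = read_edf(write_edf(rec, tmp_path / "r.edf"))
        assert back.signal.shape == (3, 8)

    def test_rejects_nan_samples(self, tmp_path):
        sig = np.zeros((2, 16))
        sig[0, 3] = np.nan
        rec = Recording("n", 8, ["a", "b"], sig, 2)
        with pytest.raises(ValueError, match="NaN"):
            write_edf(rec, tmp_path / "n.edf")

    def test_rejects_signal_exceeding_physical_range(self, tmp_path):
        sig = np.full((1, 8), 2500.0)
        rec = Recording("big", 8, ["a"], sig, 1)
        with pytest.raises(ValueError, match="physical range"):
            write_edf(rec, tmp_path / "big.edf")

    def test_channel_labels_reflect_on_disk_order(self, cohort_dir, manifest):
        # the generator permutes channel order per file; the reader must not
        # silently canonicalize it
        for sub in manifest.subjects[:3]:
            rec = read_edf(cohort_dir / f"{sub.subject_id}.edf")
            assert rec.channel_labels == sub.channel_order

    def test_mixed_sampling_rates_error_names_channel(self, tmp_path):
        rec = make_recording(n_channels=3, fs=16, duration_s=2, labels=["a", "b", "c"])
        path = write_edf(rec, tmp_path / "m.edf")
        data = bytearray(path.read_bytes())
        # per-signal samples-per-record fields start at 256 + ns*216
        off = 256 + 3 * 216 + 8  # second channel's field
        data[off : off + 8] = b"8       "
        bad = tmp_path / "mixed.edf"
        bad.write_bytes(bytes(data))
        with pytest.raises(EdfFormatError, match="'b'"):
            read_edf(bad)


class TestAnnotations:
    def test_all_zero_column(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("s1\n" + "0\n" * 5)
        (track,) = read_annotations(p, "A")
        assert track.per_second.tolist() == [0] * 5

    def test_one_based_second_mapping(self, tmp_path):
        rows = ["0"] * 10
        for sec in (4, 5, 6):
            rows[sec - 1] = "1"
        p = tmp_path / "a.csv"
        p.write_text("s1\n" + "\n".join(rows) + "\n")
        (track,) = read_annotations(p, "A")
        assert [track.second(i) for i in range(1, 11)] == [0, 0, 0, 1, 1, 1, 0, 0, 0, 0]

    def test_non_binary_cell_error_has_coordinates(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("s1,s2\n0,1\n0,2\n")
        with pytest.raises(ValueError, match=r"row 3.*column 2"):
            read_annotations(p, "A")

    def test_trailing_empty_cells_read_as_zero(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("s1,s2\n1,1\n1,\n0,\n")
        t1, t2 = read_annotations(p, "A")
        assert t2.per_second.tolist() == [1, 0, 0]

    def test_generated_csv_matches_manifest_events(self, cohort_dir, manifest):
        tracks = read_annotations(cohort_dir / "annotations_B.csv", "B")
        by_subject = {t.subject_id: t for t in tracks}
        for sub in manifest.subjects:
            events = track_to_events(by_subject[sub.subject_id])
            assert events == sorted(sub.expert_events["B"])


class TestTrackToEvents:
    def test_worked_two_event_track(self):
        # events at seconds 104-121 and 6847-6863: durations 18 and 17
        events_in = [SeizureEvent(104, 121), SeizureEvent(6847, 6863)]
        track = events_to_track(events_in, 7000, "eeg1", "A")
        events = track_to_events(track)
        assert [e.duration_s for e in events] == [18, 17]
        assert events == events_in

    def test_all_zero_track_has_no_events(self):
        track = AnnotationTrack("s", "A", np.zeros(50, dtype=int))
        assert track_to_events(track) == []

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=300))
    @settings(deadline=None)
    def test_matches_brute_force_scan(self, bits):
        track = AnnotationTrack("s", "A", np.array(bits))
        events = track_to_events(track)
        # oracle: compare each second with its predecessor
        expected = []
        start = None
        for i, b in enumerate(bits + [0], start=1):
            if b and start is None:
                start = i
            elif not b and start is not None:
                expected.append(SeizureEvent(start, i - 1))
                start = None
        assert events == expected
        assert sum(e.duration_s for e in events) == sum(bits)

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(1, 20)), min_size=0, max_size=8
        )
    )
    @settings(deadline=None)
    def test_events_track_events_identity(self, raw):
        # build an event list with gaps >= 1 s
        events, cursor = [], 1
        for offset, length in raw:
            start = cursor + offset
            events.append(SeizureEvent(start, start + length - 1))
            cursor = start + length + 1
        track = events_to_track(events, cursor + 5, "s", "A")
        assert track_to_events(track) == events


class TestCohortSummary:
    def _toy_tracks(self):
        def tr(sid, expert, seconds):
            v = np.zeros(20, dtype=int)
            for s in seconds:
                v[s - 1] = 1
            return AnnotationTrack(sid, expert, v)

        return {
            "1": [tr("a", "1", [3, 4]), tr("b", "1", [7]), tr("c", "1", [])],
            "2": [tr("a", "2", [5]), tr("b", "2", []), tr("c", "2", [])],
            "3": [tr("a", "3", [10]), tr("b", "3", []), tr("c", "3", [])],
        }

    def test_partition_by_definition(self):
        summary = summarize_cohort(self._toy_tracks())
        assert summary.exp3 == ["a"]
        assert summary.exp12 == ["b"]
        assert summary.exp0 == ["c"]

    def test_partition_is_exhaustive_and_disjoint(self, tracks):
        summary = summarize_cohort(tracks)
        all_subjects = set(summary.exp3) | set(summary.exp12) | set(summary.exp0)
        assert all_subjects == set(summary.subjects)
        assert len(summary.exp3) + len(summary.exp12) + len(summary.exp0) == len(
            summary.subjects
        )

    def test_subject_set_mismatch_raises(self):
        toy = self._toy_tracks()
        toy["2"] = toy["2"][:2]
        with pytest.raises(ValueError, match="different subject set"):
            summarize_cohort(toy)

    def test_no_misses_and_no_jitter_leaves_exp12_empty(self, tmp_path):
        from neoseiz import CohortSpec, generate_cohort

        spec = CohortSpec(
            n_subjects=5, duration_s=300, seed=9, expert_jitter_s=0, p_expert_miss=0.0
        )
        generate_cohort(spec, tmp_path)
        tracks = {
            e: read_annotations(tmp_path / f"annotations_{e}.csv", e) for e in "ABC"
        }
        assert summarize_cohort(tracks).exp12 == []

    def test_event_statistics(self):
        summary = summarize_cohort(self._toy_tracks())
        st1 = summary.per_expert["1"]
        assert st1.n_subjects_with_events == 2
        assert st1.total_events == 2
        assert st1.min_duration_s == 1 and st1.max_duration_s == 2
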