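"""Reading and writing EDF recordings and per-second seizure annotations.

The on-disk inputs of the pipeline are (a) standard EDF files holding 19
referential scalp channels sampled at 256 Hz in microvolts, and (b) one CSV
file per annotating expert in which each column is a subject and each row is
the annotation of one second of the recording (1 = seizure, 0 = non-seizure).

Seconds are 1-based and seizure intervals are inclusive at both ends: an
event covering seconds 104..121 lasts 18 seconds, and second ``i`` of a
recording maps to sample indices ``[(i-1)*fs, i*fs)``.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Physical range (symmetric, microvolts) declared when writing EDF files.
EDF_PHYSICAL_RANGE_UV = 2000.0

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfFormatError(ValueError):
    """Raised for malformed or unsupported EDF files."""


@dataclass
class Recording:
    """A labelled multichannel signal in microvolts.

    ``signal`` has shape (n_channels, n_samples) with
    ``n_samples == fs * duration_s`` after truncation to whole seconds.
    """

    subject_id: str
    fs: int
    channel_labels: list[str]
    signal: np.ndarray
    duration_s: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.signal.shape[1] != self.fs * self.duration_s:
            raise ValueError(
                f"expected {self.fs * self.duration_s} samples "
                f"({self.duration_s} s at {self.fs} Hz), got {self.signal.shape[1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def second_slice(self, start_s: int, n_seconds: int) -> np.ndarray:
        """Samples covering the ``n_seconds`` seconds starting at 1-based ``start_s``."""
        i0 = (start_s - 1) * self.fs
        return self.signal[:, i0 : i0 + n_seconds * self.fs]


@dataclass
class AnnotationTrack:
    """One expert's per-second binary seizure annotation of one subject."""

    subject_id: str
    expert_id: str
    per_second: np.ndarray

    def __post_init__(self) -> None:
        self.per_second = np.asarray(self.per_second, dtype=np.int8)
        bad = ~np.isin(self.per_second, (0, 1))
        if bad.any():
            sec = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"annotation of subject {self.subject_id!r} has non-binary value "
                f"at second {sec}"
            )

    @property
    def duration_s(self) -> int:
        return len(self.per_second)

    def second(self, i: int) -> int:
        """Annotation of 1-based second ``i``."""
        return int(self.per_second[i - 1])


@dataclass(frozen=True, order=True)
class SeizureEvent:
    """One annotated seizure interval, in whole seconds, 1-based and inclusive."""

    start_s: int
    end_s: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_s <= self.end_s:
            raise ValueError(f"invalid event interval [{self.start_s}, {self.end_s}]")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s + 1


# ---------------------------------------------------------------------------
# EDF


def _scan_edf_samples_per_record(path: Path) -> tuple[list[str], list[int]]:
    """Read per-signal labels and samples-per-record from the raw EDF header.

    Used to reject files with mixed per-channel sampling rates before the
    data are loaded: generic readers silently resample such files.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise EdfFormatError(f"{path}: truncated EDF header")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EdfFormatError(f"{path}: unreadable signal count field") from exc
        if ns < 1:
            raise EdfFormatError(f"{path}: EDF file declares {ns} signals")
        sig_header = fh.read(ns * 256)
        if len(sig_header) < ns * 256:
            raise EdfFormatError(f"{path}: truncated EDF signal headers")
    labels = [
        sig_header[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * 216
    nsamp = []
    for i in range(ns):
        raw = sig_header[off + i * 8 : off + (i + 1) * 8].decode("ascii", "replace")
        try:
            nsamp.append(int(raw.strip()))
        except ValueError as exc:
            raise EdfFormatError(
                f"{path}: unreadable samples-per-record for channel {labels[i]!r}"
            ) from exc
    return labels, nsamp


def read_edf(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read a standard EDF file into a :class:`Recording` in microvolts.

    Channel labels keep the on-disk order (whitespace trimmed); the signal is
    truncated to whole seconds. Files whose channels carry different sampling
    rates are rejected, naming the offending channel.
    """
    import mne

    path = Path(path)
    labels, nsamp = _scan_edf_samples_per_record(path)
    if len(set(nsamp)) > 1:
        common = statistics.mode(nsamp)
        bad = next(l for l, n in zip(labels, nsamp) if n != common)
        raise EdfFormatError(
            f"{path}: mixed per-channel sampling rates; channel {bad!r} has "
            f"{nsamp[labels.index(bad)]} samples per record, others {common}"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs_f = float(raw.info["sfreq"])
    fs = int(round(fs_f))
    if abs(fs_f - fs) > 1e-9:
        raise EdfFormatError(f"{path}: non-integer sampling rate {fs_f} Hz")
    signal_uv = raw.get_data() * 1e6  # mne returns volts
    duration_s = signal_uv.shape[1] // fs
    signal_uv = signal_uv[:, : duration_s * fs]
    return Recording(
        subject_id=subject_id if subject_id is not None else path.stem,
        fs=fs,
        channel_labels=[c.strip() for c in raw.ch_names],
        signal=signal_uv,
        duration_s=duration_s,
    )


def _ascii_field(value: str, width: int) -> bytes:
    data = value.encode("ascii")
    if len(data) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
    return data.ljust(width)


def write_edf(
    rec: Recording,
    path: str | Path,
    physical_range_uv: float = EDF_PHYSICAL_RANGE_UV,
) -> Path:
    """Write a :class:`Recording` as a standard 16-bit EDF file.

    One data record per second, symmetric physical range (default ±2000 µV),
    digital range −32768..32767. Samples must be finite and inside the
    physical range; quantization error is bounded by range/2^16.
    """
    path = Path(path)
    if not np.isfinite(rec.signal).all():
        raise ValueError("signal contains NaN or infinite samples")
    amax = float(np.abs(rec.signal).max(initial=0.0))
    if amax > physical_range_uv:
        raise ValueError(
            f"signal amplitude {amax:.1f} µV exceeds declared physical range "
            f"±{physical_range_uv:.0f} µV"
        )
    ns = rec.n_channels
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(rec.subject_id[:80], 80),
            _ascii_field("neoseiz synthetic", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(str(256 * (1 + ns)), 8),
            _ascii_field("", 44),
            _ascii_field(str(rec.duration_s), 8),
            _ascii_field("1", 8),
            _ascii_field(str(ns), 4),
        ]
    )
    phys_min, phys_max = -physical_range_uv, physical_range_uv

    def per_signal(fmt: str, width: int) -> bytes:
        return b"".join(_ascii_field(fmt.format(c=c), width) for c in rec.channel_labels)

    sig_header = b"".join(
        [
            per_signal("{c}", 16),
            per_signal("", 80),
            per_signal("uV", 8),
            b"".join(_ascii_field(f"{phys_min:.0f}", 8) for _ in range(ns)),
            b"".join(_ascii_field(f"{phys_max:.0f}", 8) for _ in range(ns)),
            b"".join(_ascii_field(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_ascii_field(str(_DIG_MAX), 8) for _ in range(ns)),
            per_signal("", 80),
            b"".join(_ascii_field(str(rec.fs), 8) for _ in range(ns)),
            per_signal("", 32),
        ]
    )
    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((rec.signal - phys_min) * gain + _DIG_MIN).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # EDF interleaves channels per 1-second record
        records = digital.reshape(ns, rec.duration_s, rec.fs)
        fh.write(np.ascontiguousarray(records.transpose(1, 0, 2)).tobytes())
    return path


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path: str | Path, expert_id: str | None = None) -> list[AnnotationTrack]:
    """Parse an expert's annotation CSV into one track per subject column.

    The CSV has a mandatory header row of subject identifiers, then one row
    per second with cells in {0, 1}. Trailing empty cells (recordings of
    unequal length) are treated as "no annotation" (0) and logged; any other
    non-binary cell raises an error carrying its row/column coordinates.
    """
    path = Path(path)
    if expert_id is None:
        m = re.search(r"([A-Za-z0-9]+)$", path.stem.replace(".csv", ""))
        expert_id = m.group(1) if m else path.stem
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    tracks = []
    for col_idx, subject in enumerate(df.columns):
        cells = df[subject].str.strip()
        values = np.zeros(len(cells), dtype=np.int8)
        n_empty = 0
        for row_idx, cell in enumerate(cells):
            if cell == "" or cell.lower() == "nan":
                n_empty += 1
                continue
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary annotation {cell!r} at row {row_idx + 2}, "
                    f"column {col_idx + 1} (subject {subject!r})"
                )
            values[row_idx] = int(cell)
        if n_empty:
            logger.info(
                "%s: subject %s has %d empty annotation cells, treated as 0",
                path, subject, n_empty,
            )
        tracks.append(AnnotationTrack(str(subject), expert_id, values))
    return tracks


def write_annotations(tracks: Sequence[AnnotationTrack], path: str | Path) -> Path:
    """Write tracks (same duration) as one CSV column per subject."""
    durations = {t.duration_s for t in tracks}
    if len(durations) != 1:
        raise ValueError("tracks must share one duration to share a CSV")
    df = pd.DataFrame({t.subject_id: t.per_second for t in tracks})
    df.to_csv(path, index=False)
    return Path(path)


def track_to_events(track: AnnotationTrack) -> list[SeizureEvent]:
    """Maximal contiguous runs of 1s in a track, ordered by start second."""
    padded = np.concatenate(([0], track.per_second, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1) + 1  # 1-based seconds
    ends = np.flatnonzero(diff == -1)
    return [SeizureEvent(int(s), int(e)) for s, e in zip(starts, ends)]


def events_to_track(
    events: Iterable[SeizureEvent],
    duration_s: int,
    subject_id: str = "",
    expert_id: str = "",
) -> AnnotationTrack:
    """Inverse of :func:`track_to_events` for events inside the recording."""
    per_second = np.zeros(duration_s, dtype=np.int8)
    for ev in events:
        if ev.end_s > duration_s:
            raise ValueError(f"event {ev} exceeds recording duration {duration_s} s")
        per_second[ev.start_s - 1 : ev.end_s] = 1
    return AnnotationTrack(subject_id, expert_id, per_second)


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass
class ExpertStats:
    expert_id: str
    n_subjects_with_events: int
    total_events: int
    min_duration_s: int | None
    max_duration_s: int | None
    mean_duration_s: float | None
    median_duration_s: float | None


@dataclass
class CohortSummary:
    """Per-expert seizure statistics and the consensus subject partition.

    ``exp3`` holds subjects annotated (≥1 event) by all experts, ``exp0``
    subjects annotated by none, ``exp12`` the rest. Only ``exp3`` subjects
    supply positive training material and only ``exp0`` subjects negative.
    """

    subjects: list[str]
    per_expert: dict[str, ExpertStats]
    exp3: list[str]
    exp12: list[str]
    exp0: list[str]

    def __post_init__(self) -> None:
        if len(self.exp3) + len(self.exp12) + len(self.exp0) != len(self.subjects):
            raise ValueError("EXP3/EXP12/EXP0 must partition the subject set")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.per_expert.values():
            rows.append(
                {
                    "expert": st.expert_id,
                    "subjects_with_events": st.n_subjects_with_events,
                    "total_events": st.total_events,
                    "min_s": st.min_duration_s,
                    "max_s": st.max_duration_s,
                    "mean_s": st.mean_duration_s,
                    "median_s": st.median_duration_s,
                }
            )
        return pd.DataFrame(rows)


def summarize_cohort(
    tracks_by_expert: Mapping[str, Sequence[AnnotationTrack]],
) -> CohortSummary:
    """Compute per-expert statistics and the EXP3/EXP12/EXP0 partition."""
    subject_sets = {
        expert: {t.subject_id for t in tracks}
        for expert, tracks in tracks_by_expert.items()
    }
    reference = next(iter(subject_sets.values()))
    for expert, subjects in subject_sets.items():
        if subjects != reference:
            missing = sorted(reference ^ subjects)
            raise ValueError(
                f"expert {expert!r} covers a different subject set (difference: {missing})"
            )
    per_expert: dict[str, ExpertStats] = {}
    annotated: dict[str, set[str]] = {}
    for expert, tracks in tracks_by_expert.items():
        durations: list[int] = []
        with_events = set()
        for track in tracks:
            events = track_to_events(track)
            if events:
                with_events.add(track.subject_id)
            durations.extend(ev.duration_s for ev in events)
        annotated[expert] = with_events
        per_expert[expert] = ExpertStats(
            expert_id=expert,
            n_subjects_with_events=len(with_events),
            total_events=len(durations),
            min_duration_s=min(durations) if durations else None,
            max_duration_s=max(durations) if durations else None,
            mean_duration_s=float(np.mean(durations)) if durations else None,
            median_duration_s=float(np.median(durations)) if durations else None,
        )
    subjects = sorted(reference)
    n_experts = len(tracks_by_expert)
    exp3, exp12, exp0 = [], [], []
    for subject in subjects:
        n = sum(subject in annotated[e] for e in tracks_by_expert)
        if n == n_experts:
            exp3.append(subject)
        elif n == 0:
            exp0.append(subject)
        else:
            exp12.append(subject)
    return CohortSummary(subjects, per_expert, exp3, exp12, exp0)
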