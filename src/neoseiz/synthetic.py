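"""Synthetic neonatal-EEG cohort generator.

Produces a cohort of EDF recordings plus three "expert" annotation CSVs with
the statistical structure the downstream pipeline assumes, so the whole
data-engineering and training path can be exercised without any download.

Signal model
------------
Background activity on every channel is band-limited noise with a 1/f-like
power spectrum (amplitude ∝ f^-1/2 between 0.5 and 30 Hz), scaled to a fixed
RMS. During a seizure a fixed-frequency sinusoidal burst (default 3 Hz) with
per-channel random phase is added on all channels, its amplitude a chosen
multiple of the background RMS. This is a deliberately simple stand-in for
rhythmic ictal activity — linearly separable from background, so classifier
sanity checks are meaningful — not a claim of physiological realism.

Annotation model
----------------
Each subject carries a list of true events (placed uniformly at random,
non-overlapping, with at least 5 s between events). Each of the three
experts independently reproduces every true event with an integer jitter on
onset and offset and omits it entirely with a small probability, emulating
the inter-rater disagreement that drives the consensus subject partition
(EXP3 / EXP12 / EXP0). A fixed fraction of subjects is seizure-free by
construction so negative material always exists.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .edf_io import (
    AnnotationTrack,
    Recording,
    SeizureEvent,
    events_to_track,
    write_annotations,
    write_edf,
)
from .preprocess import CANONICAL_ORDER

EXPERT_IDS = ("A", "B", "C")

#: Nominal background RMS amplitude, microvolts.
BACKGROUND_RMS_UV = 20.0

#: Minimum gap between consecutive true events, seconds.
MIN_EVENT_GAP_S = 5

_BAND_HZ = (0.5, 30.0)


class CohortGenerationError(RuntimeError):
    """Raised when a cohort cannot be generated from the given specification."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``seizure_rate`` is the expected number of events per seizing recording
    (zero-truncated Poisson); ``seizure_free_frac`` of the subjects carry no
    events at all, mirroring the roughly one-quarter seizure-free share of
    real neonatal cohorts and guaranteeing the pipeline its negative
    (EXP0) material.
    """

    n_subjects: int = 10
    duration_s: int = 600
    fs: int = 256
    seizure_rate: float = 3.0
    seizure_len_range: tuple[int, int] = (10, 60)
    seizure_amp_gain: float = 4.0
    seizure_freq_hz: float = 3.0
    expert_jitter_s: int = 2
    p_expert_miss: float = 0.1
    seed: int = 0
    shuffle_channel_order: bool = True
    seizure_free_frac: float = 0.28

    def __post_init__(self) -> None:
        lo, hi = self.seizure_len_range
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid seizure_len_range {self.seizure_len_range}")
        if self.duration_s < hi:
            raise ValueError(
                f"duration_s={self.duration_s} is shorter than the longest "
                f"possible seizure ({hi} s); no event could be placed"
            )
        if not 0.0 <= self.p_expert_miss <= 1.0:
            raise ValueError("p_expert_miss must lie in [0, 1]")
        if not 0.0 <= self.seizure_free_frac <= 1.0:
            raise ValueError("seizure_free_frac must lie in [0, 1]")
        if self.seizure_rate < 0:
            raise ValueError("seizure_rate must be non-negative")
        if self.expert_jitter_s < 0:
            raise ValueError("expert_jitter_s must be non-negative")
        if self.fs <= 2 * self.seizure_freq_hz:
            raise ValueError("sampling rate must exceed twice the burst frequency")


@dataclass
class SubjectRecord:
    """Ground truth for one synthetic subject."""

    subject_id: str
    channel_order: list[str]
    true_events: list[SeizureEvent]
    expert_events: dict[str, list[SeizureEvent]]


@dataclass
class CohortManifest:
    """Ground truth for a generated cohort; written as ``manifest.json``."""

    spec: CohortSpec
    subjects: list[SubjectRecord]
    edf_paths: dict[str, str] = field(default_factory=dict)
    annotation_paths: dict[str, str] = field(default_factory=dict)

    def subject(self, subject_id: str) -> SubjectRecord:
        for rec in self.subjects:
            if rec.subject_id == subject_id:
                return rec
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def to_json(self) -> str:
        def encode(rec: SubjectRecord) -> dict:
            return {
                "subject_id": rec.subject_id,
                "channel_order": rec.channel_order,
                "true_events": [[e.start_s, e.end_s] for e in rec.true_events],
                "expert_events": {
                    ex: [[e.start_s, e.end_s] for e in evs]
                    for ex, evs in rec.expert_events.items()
                },
            }

        return json.dumps(
            {
                "spec": asdict(self.spec),
                "subjects": [encode(s) for s in self.subjects],
                "edf_paths": self.edf_paths,
                "annotation_paths": self.annotation_paths,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortManifest":
        raw = json.loads(text)
        raw["spec"]["seizure_len_range"] = tuple(raw["spec"]["seizure_len_range"])
        subjects = [
            SubjectRecord(
                subject_id=s["subject_id"],
                channel_order=s["channel_order"],
                true_events=[SeizureEvent(a, b) for a, b in s["true_events"]],
                expert_events={
                    ex: [SeizureEvent(a, b) for a, b in evs]
                    for ex, evs in s["expert_events"].items()
                },
            )
            for s in raw["subjects"]
        ]
        return cls(
            spec=CohortSpec(**raw["spec"]),
            subjects=subjects,
            edf_paths=raw.get("edf_paths", {}),
            annotation_paths=raw.get("annotation_paths", {}),
        )


# ---------------------------------------------------------------------------
# signal synthesis


def _background(rng: np.random.Generator, n_channels: int, n: int, fs: int) -> np.ndarray:
    """Band-limited 1/f-like noise, per channel, scaled to BACKGROUND_RMS_UV."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= _BAND_HZ[0]) & (freqs <= min(_BAND_HZ[1], fs / 2))
    shape[band] = freqs[band] ** -0.5
    white = rng.standard_normal((n_channels, n))
    spectrum = np.fft.rfft(white, axis=1) * shape
    sig = np.fft.irfft(spectrum, n=n, axis=1)
    rms = sig.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return sig * (BACKGROUND_RMS_UV / rms)


def _place_events(rng: np.random.Generator, spec: CohortSpec) -> list[SeizureEvent]:
    """Non-overlapping events with ≥ MIN_EVENT_GAP_S seconds between them."""
    n_events = 0
    if spec.seizure_rate > 0:
        # zero-truncated Poisson: a seizing subject has at least one event
        while n_events == 0:
            n_events = int(rng.poisson(spec.seizure_rate))
    events: list[SeizureEvent] = []
    lo, hi = spec.seizure_len_range
    for _ in range(n_events):
        length = int(rng.integers(lo, hi + 1))
        placed = False
        for _attempt in range(1000):
            start = int(rng.integers(1, spec.duration_s - length + 2))
            end = start + length - 1
            ok = all(
                end < ev.start_s - MIN_EVENT_GAP_S or start > ev.end_s + MIN_EVENT_GAP_S
                for ev in events
            )
            if ok:
                events.append(SeizureEvent(start, end))
                placed = True
                break
        if not placed:
            break  # recording saturated; keep what fits
    if not events:
        raise CohortGenerationError(
            f"could not place any event of length in {spec.seizure_len_range} "
            f"within a {spec.duration_s} s recording"
        )
    return sorted(events)


def _jitter_events(
    rng: np.random.Generator, events: list[SeizureEvent], spec: CohortSpec
) -> list[SeizureEvent]:
    """One expert's view: per-event onset/offset jitter and occasional omission.

    Jittered intervals are clamped to the midpoints of the gaps to the
    neighbouring true events so distinct events never merge.
    """
    out: list[SeizureEvent] = []
    for i, ev in enumerate(events):
        if rng.random() < spec.p_expert_miss:
            continue
        lo_bound = 1 if i == 0 else (events[i - 1].end_s + ev.start_s) // 2 + 1
        hi_bound = (
            spec.duration_s
            if i == len(events) - 1
            else (ev.end_s + events[i + 1].start_s) // 2
        )
        j = spec.expert_jitter_s
        start = ev.start_s + int(rng.integers(-j, j + 1)) if j else ev.start_s
        end = ev.end_s + int(rng.integers(-j, j + 1)) if j else ev.end_s
        start = int(np.clip(start, lo_bound, hi_bound))
        end = int(np.clip(end, lo_bound, hi_bound))
        if start > end:
            start, end = end, start
        out.append(SeizureEvent(start, end))
    return out


def synthesize_recording(
    spec: CohortSpec,
    events: list[SeizureEvent],
    rng: np.random.Generator,
    subject_id: str,
    channel_order: list[str],
) -> Recording:
    """Render one subject's multichannel signal: background plus bursts."""
    n = spec.fs * spec.duration_s
    signal = _background(rng, len(channel_order), n, spec.fs)
    amp = spec.seizure_amp_gain * BACKGROUND_RMS_UV
    t = np.arange(n) / spec.fs
    for ev in events:
        sl = slice((ev.start_s - 1) * spec.fs, ev.end_s * spec.fs)
        phases = rng.uniform(0, 2 * np.pi, size=len(channel_order))
        burst = amp * np.sin(
            2 * np.pi * spec.seizure_freq_hz * t[sl][None, :] + phases[:, None]
        )
        signal[:, sl] += burst
    # keep within the declared EDF physical range
    np.clip(signal, -1999.0, 1999.0, out=signal)
    return Recording(subject_id, spec.fs, channel_order, signal, spec.duration_s)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortManifest:
    """Write a synthetic cohort (EDF files, three expert CSVs, manifest).

    Files: ``eeg1.edf`` … ``eegN.edf``, ``annotations_A.csv`` /
    ``_B.csv`` / ``_C.csv`` (one column per subject, one row per second) and
    ``manifest.json`` with the ground-truth events. Deterministic given
    ``spec.seed``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise CohortGenerationError(f"output directory {out_dir} not writable: {exc}")

    root = np.random.SeedSequence(spec.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.spawn(spec.n_subjects)

    n_free = int(round(spec.seizure_free_frac * spec.n_subjects))
    if spec.seizure_rate == 0:
        n_free = spec.n_subjects
    elif spec.n_subjects >= 2:
        n_free = min(max(n_free, 1), spec.n_subjects - 1)
    free_idx = set(
        cohort_rng.choice(spec.n_subjects, size=n_free, replace=False).tolist()
    )

    subjects: list[SubjectRecord] = []
    manifest = CohortManifest(spec=spec, subjects=subjects)
    tracks_by_expert: dict[str, list[AnnotationTrack]] = {e: [] for e in EXPERT_IDS}
    for i in range(spec.n_subjects):
        sid = f"eeg{i + 1}"
        rng = np.random.default_rng(subject_seeds[i])
        order = list(CANONICAL_ORDER)
        if spec.shuffle_channel_order:
            order = [order[k] for k in rng.permutation(len(order))]
        if i in free_idx:
            true_events: list[SeizureEvent] = []
        else:
            true_events = _place_events(rng, spec)
        expert_events = {
            expert: _jitter_events(rng, true_events, spec) for expert in EXPERT_IDS
        }
        rec = synthesize_recording(spec, true_events, rng, sid, order)
        path = out_dir / f"{sid}.edf"
        write_edf(rec, path)
        manifest.edf_paths[sid] = path.name
        for expert in EXPERT_IDS:
            tracks_by_expert[expert].append(
                events_to_track(expert_events[expert], spec.duration_s, sid, expert)
            )
        subjects.append(SubjectRecord(sid, order, true_events, expert_events))

    for expert in EXPERT_IDS:
        path = out_dir / f"annotations_{expert}.csv"
        write_annotations(tracks_by_expert[expert], path)
        manifest.annotation_paths[expert] = path.name
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
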