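"""Balanced sliding-window chunk extraction.

A *chunk* is one training sample: a ``window``-second fragment of the
18-channel bipolar, down-sampled signal. Positive chunks are packed from the
onset of each annotated seizure as consecutive non-overlapping windows that
must end inside the event, so a seizure of L seconds yields
``min(chunks, ⌊L/window⌋)`` of them — requesting 3 six-second chunks from a
17-second seizure yields only 2, because a third would run into non-seizure
signal. Negative chunks are then drawn at random (seeded, non-overlapping
within each recording) from recordings of seizure-free (EXP0) subjects, one
per positive, so the resulting collection is fully balanced by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .edf_io import AnnotationTrack, Recording, SeizureEvent, summarize_cohort, track_to_events

logger = logging.getLogger(__name__)

#: Requesting this many chunks per seizure means "take the maximum possible".
MAX_CHUNKS = 10_000


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window parameters.

    ``window`` is the chunk length in whole seconds; ``chunks`` the number
    of chunks requested per seizure (the sentinel 10000 effectively takes
    every available window); ``fs`` the sampling rate of the already
    down-sampled signal; ``seed`` drives negative sampling only.
    """

    window: int
    chunks: int = MAX_CHUNKS
    fs: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be at least 1 second")
        if self.chunks < 1:
            raise ValueError("chunks must be at least 1")
        if self.fs < 1:
            raise ValueError("fs must be positive")

    @property
    def samples_per_chunk(self) -> int:
        return self.window * self.fs


@dataclass
class Chunk:
    """One labelled window: ``data`` is channels × (window·fs) in µV."""

    subject_id: str
    data: np.ndarray
    label: int
    origin: str  # "event<i>" for positives, "negative" for negatives
    start_s: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class ChunkSet:
    """A collection of equal-length chunks plus the parameters that made it."""

    chunks: list[Chunk]
    params: WindowParams

    @property
    def positives(self) -> list[Chunk]:
        return [c for c in self.chunks if c.label == 1]

    @property
    def negatives(self) -> list[Chunk]:
        return [c for c in self.chunks if c.label == 0]

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.chunks], dtype=np.int8)

    def __len__(self) -> int:
        return len(self.chunks)

    def is_balanced(self) -> bool:
        return len(self.positives) == len(self.negatives)

    def shuffled(self, seed: int) -> "ChunkSet":
        """A seeded random reordering (applied once before splitting)."""
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.chunks))
        return ChunkSet([self.chunks[i] for i in order], self.params)


def chunk_yield(duration_s: int, params: WindowParams) -> int:
    """Number of chunks obtainable from a seizure of ``duration_s`` seconds.

    Non-overlapping windows are packed from the event onset and must end
    inside the event: ``min(chunks, duration_s // window)``.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be at least 1")
    return min(params.chunks, duration_s // params.window)


def extract_positive_chunks(
    rec: Recording, events: Sequence[SeizureEvent], params: WindowParams
) -> list[Chunk]:
    """Seizure chunks packed from the onset of each event (label 1).

    Events shorter than the window contribute nothing (logged); an event
    extending beyond the recording raises.
    """
    out: list[Chunk] = []
    for idx, ev in enumerate(events):
        if ev.end_s > rec.duration_s:
            raise ValueError(
                f"event [{ev.start_s}, {ev.end_s}] exceeds recording "
                f"{rec.subject_id!r} duration {rec.duration_s} s"
            )
        n = chunk_yield(ev.duration_s, params)
        if n == 0:
            logger.info(
                "event %d of %s (%d s) shorter than window %d s; skipped",
                idx, rec.subject_id, ev.duration_s, params.window,
            )
        for k in range(n):
            start = ev.start_s + k * params.window
            out.append(
                Chunk(
                    subject_id=rec.subject_id,
                    data=rec.second_slice(start, params.window).copy(),
                    label=1,
                    origin=f"event{idx}",
                    start_s=start,
                )
            )
    return out


def sample_negative_chunks(
    seizure_free_recs: Sequence[Recording], n: int, params: WindowParams
) -> list[Chunk]:
    """Draw ``n`` non-seizure chunks from seizure-free recordings (label 0).

    Each draw picks a recording uniformly, then a start second uniformly,
    rejecting windows that would overlap an already drawn chunk of the same
    recording. Deterministic given ``params.seed``.
    """
    if n == 0:
        return []
    if not seizure_free_recs:
        raise ValueError("no seizure-free recordings to sample negatives from")
    capacity = sum(r.duration_s // params.window for r in seizure_free_recs)
    if capacity < n:
        raise ValueError(
            f"insufficient seizure-free material: need {n} windows of "
            f"{params.window} s but at most {capacity} fit ({n - capacity} short)"
        )
    rng = np.random.default_rng(params.seed)
    occupied: list[list[tuple[int, int]]] = [[] for _ in seizure_free_recs]
    out: list[Chunk] = []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"negative sampling stalled after {attempts} draws: "
                f"{n - len(out)} of {n} chunks still missing"
            )
        ri = int(rng.integers(len(seizure_free_recs)))
        rec = seizure_free_recs[ri]
        hi = rec.duration_s - params.window + 1
        if hi < 1:
            continue
        start = int(rng.integers(1, hi + 1))
        end = start + params.window - 1
        if any(s <= end and start <= e for s, e in occupied[ri]):
            continue
        occupied[ri].append((start, end))
        out.append(
            Chunk(
                subject_id=rec.subject_id,
                data=rec.second_slice(start, params.window).copy(),
                label=0,
                origin="negative",
                start_s=start,
            )
        )
    return out


def build_balanced_set(
    recordings: Mapping[str, Recording],
    tracks_by_expert: Mapping[str, Sequence[AnnotationTrack]],
    expert: str,
    params: WindowParams,
) -> ChunkSet:
    """Build the fully balanced chunk collection for one expert's annotations.

    Positives come from every event the chosen expert annotated on subjects
    of the consensus subset EXP3 (all experts saw at least one seizure);
    negatives, one per positive, from subjects of EXP0 (no expert saw any).
    ``recordings`` must already be preprocessed (18-channel bipolar,
    down-sampled to ``params.fs``).
    """
    if expert not in tracks_by_expert:
        raise KeyError(f"no annotation tracks for expert {expert!r}")
    summary = summarize_cohort(tracks_by_expert)
    track_of = {t.subject_id: t for t in tracks_by_expert[expert]}
    positives: list[Chunk] = []
    for sid in summary.exp3:
        if sid not in recordings:
            raise KeyError(f"recording for subject {sid!r} missing")
        events = track_to_events(track_of[sid])
        positives.extend(extract_positive_chunks(recordings[sid], events, params))
    free_recs = [recordings[sid] for sid in summary.exp0 if sid in recordings]
    missing = [sid for sid in summary.exp0 if sid not in recordings]
    if missing:
        raise KeyError(f"recordings for seizure-free subjects missing: {missing}")
    negatives = sample_negative_chunks(free_recs, len(positives), params)
    cs = ChunkSet(positives + negatives, params)
    assert cs.is_balanced()
    return cs
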