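"""Shared fixtures: a small seeded synthetic cohort run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from neoseiz import (
    CohortSpec,
    WindowParams,
    build_balanced_set,
    chunkset_to_dataset,
    generate_cohort,
    preprocess_recording,
    read_annotations,
    read_edf,
)

EXPERTS = ("A", "B", "C")

COHORT_SPEC = CohortSpec(n_subjects=10, duration_s=600, seed=1)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("cohort")
    generate_cohort(COHORT_SPEC, path)
    return path


@pytest.fixture(scope="session")
def manifest(cohort_dir):
    from neoseiz.synthetic import CohortManifest

    return CohortManifest.from_json((cohort_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def raw_recordings(cohort_dir, manifest):
    return {
        sid: read_edf(cohort_dir / f"{sid}.edf") for sid in manifest.subject_ids
    }


@pytest.fixture(scope="session")
def recordings(raw_recordings):
    """Preprocessed: canonical order, bipolar montage, down-sampled to 64 Hz."""
    return {sid: preprocess_recording(rec) for sid, rec in raw_recordings.items()}


@pytest.fixture(scope="session")
def tracks(cohort_dir):
    return {
        e: read_annotations(cohort_dir / f"annotations_{e}.csv", e) for e in EXPERTS
    }


@pytest.fixture(scope="session")
def balanced_chunkset(recordings, tracks):
    params = WindowParams(window=2, chunks=10, fs=64, seed=1)
    return build_balanced_set(recordings, tracks, "A", params)


@pytest.fixture(scope="session")
def tensor_dataset(balanced_chunkset):
    return chunkset_to_dataset(balanced_chunkset.shuffled(1), "A")


def make_recording(
    n_channels=18, fs=64, duration_s=30, seed=0, labels=None, amplitude=50.0
):
    """A small random Recording for unit tests."""
    from neoseiz import Recording

    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"ch{i}" for i in range(n_channels)]
    sig = rng.normal(0, amplitude / 3, size=(len(labels), fs * duration_s))
    return Recording("test", fs, list(labels), sig, duration_s)
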