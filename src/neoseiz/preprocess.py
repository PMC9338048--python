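"""Channel reordering, the longitudinal bipolar montage, and down-sampling.

EDF files from different subjects list the same 19 referential 10–20
electrodes in different orders, so the first step fixes a canonical order.
The classifier never sees referential signals: it works on the 18-pair
longitudinal bipolar montage ("double banana"), each channel being the
difference anode − cathode in microvolts. Finally the 256 Hz signals are
down-sampled by an integer factor (default 4, giving 64 Hz) using a
non-overlapping block mean, which decimates and smooths at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edf_io import Recording

#: Canonical referential order of the 19 scalp electrodes (10–20 system).
CANONICAL_ORDER: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3", "C4", "Cz",
    "P3", "P4", "Pz", "T3", "T4", "T5", "T6", "O1", "O2",
)

#: The 18 anode/cathode pairs of the 'double banana' bipolar montage.
DOUBLE_BANANA: tuple[tuple[str, str], ...] = (
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)

#: Default down-sampling factor: 256 Hz → 64 Hz.
DEFAULT_DOWNSAMPLE_FACTOR = 4


def _norm(label: str) -> str:
    # EDF headers vary in padding and case
    return label.strip().casefold()


@dataclass(frozen=True)
class MontageSpec:
    """A bipolar montage: ordered electrode pairs over a canonical label set."""

    pairs: tuple[tuple[str, str], ...] = DOUBLE_BANANA
    canonical_order: tuple[str, ...] = CANONICAL_ORDER

    def __post_init__(self) -> None:
        canonical = {_norm(c) for c in self.canonical_order}
        for anode, cathode in self.pairs:
            for lab in (anode, cathode):
                if _norm(lab) not in canonical:
                    raise ValueError(f"montage label {lab!r} not in the canonical set")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]


def reorder_channels(
    rec: Recording, canonical: tuple[str, ...] | list[str] = CANONICAL_ORDER
) -> Recording:
    """Permute channels into the canonical order (values untouched).

    Label matching is case-insensitive with whitespace stripped. Raises if a
    canonical label is missing from the recording or appears twice.
    """
    index: dict[str, int] = {}
    for i, lab in enumerate(rec.channel_labels):
        key = _norm(lab)
        if key in index:
            raise ValueError(f"duplicate channel label {lab!r} in recording")
        index[key] = i
    rows = []
    for lab in canonical:
        key = _norm(lab)
        if key not in index:
            raise ValueError(f"channel {lab!r} missing from recording {rec.subject_id!r}")
        rows.append(index[key])
    return Recording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channel_labels=list(canonical),
        signal=rec.signal[rows],
        duration_s=rec.duration_s,
    )


def apply_montage(rec: Recording, spec: MontageSpec | None = None) -> Recording:
    """Derive the bipolar montage: each output channel is anode − cathode (µV)."""
    spec = spec or MontageSpec()
    index = {_norm(lab): i for i, lab in enumerate(rec.channel_labels)}
    rows = np.empty((len(spec.pairs), rec.signal.shape[1]))
    for k, (anode, cathode) in enumerate(spec.pairs):
        try:
            ia, ic = index[_norm(anode)], index[_norm(cathode)]
        except KeyError as exc:
            raise ValueError(
                f"montage electrode {exc.args[0]!r} absent from recording "
                f"{rec.subject_id!r}"
            ) from None
        rows[k] = rec.signal[ia] - rec.signal[ic]
    return Recording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channel_labels=spec.labels,
        signal=rows,
        duration_s=rec.duration_s,
    )


def downsample(
    rec: Recording,
    factor: int = DEFAULT_DOWNSAMPLE_FACTOR,
    method: str = "mean",
) -> Recording:
    """Down-sample by an integer factor that divides the sampling rate.

    ``method="mean"`` (default) replaces each block of ``factor`` consecutive
    samples by its arithmetic mean, smoothing while decimating;
    ``method="decimate"`` keeps every ``factor``-th sample, for comparison.
    Output sampling rate is ``fs / factor``; trailing samples that do not
    fill a block are dropped.
    """
    if factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    if rec.fs % factor != 0:
        raise ValueError(f"factor {factor} does not divide sampling rate {rec.fs} Hz")
    n_out = rec.signal.shape[1] // factor
    trimmed = rec.signal[:, : n_out * factor]
    if method == "mean":
        out = trimmed.reshape(rec.n_channels, n_out, factor).mean(axis=2)
    elif method == "decimate":
        out = trimmed[:, ::factor]
    else:
        raise ValueError(f"unknown down-sampling method {method!r}")
    return Recording(
        subject_id=rec.subject_id,
        fs=rec.fs // factor,
        channel_labels=list(rec.channel_labels),
        signal=out,
        duration_s=rec.duration_s,
    )


def preprocess_recording(
    rec: Recording,
    factor: int = DEFAULT_DOWNSAMPLE_FACTOR,
    spec: MontageSpec | None = None,
) -> Recording:
    """Full preprocessing path: canonical order → bipolar montage → block-mean
    down-sampling. Returns the 18-channel recording the windowing stage expects."""
    spec = spec or MontageSpec()
    return downsample(apply_montage(reorder_channels(rec, spec.canonical_order), spec), factor)
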