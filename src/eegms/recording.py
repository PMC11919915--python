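"""In-memory containers for continuous and epoched EEG.

``Recording`` is the carrier of the signal through every stage: a channels x
samples voltage matrix in microvolts with its sampling rate, montage and
reference state.  ``EpochedRecording`` is the fixed-length segmentation used
by the epoch-wise cleaning rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import Montage

#: tolerance on the per-sample channel mean for an average-referenced signal
AVG_REF_ATOL = 1e-9


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    montage: Montage
    reference: str = "average"  # one of {"mastoid", "average", "other"}
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"{self.data.shape[0]} data rows but montage has "
                f"{len(self.montage)} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        unknown = set(self.bad_channels) - set(self.montage.names)
        if unknown:
            raise ValueError(f"bad channels not in montage: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def is_average_referenced(self, atol: float = AVG_REF_ATOL) -> bool:
        return bool(np.all(np.abs(self.data.mean(axis=0)) < atol))

    def copy_with(self, **changes) -> "Recording":
        if "data" not in changes:
            changes["data"] = self.data.copy()
        if "bad_channels" not in changes:
            changes["bad_channels"] = set(self.bad_channels)
        return replace(self, **changes)


@dataclass
class EpochedRecording:
    """Fixed-length epochs: ``data`` is epochs x channels x samples."""

    data: np.ndarray
    fs: float
    montage: Montage
    epoch_len_s: float
    rejected: np.ndarray | None = None  # bool per epoch
    interpolated: list[set[str]] | None = None  # channel names per epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be epochs x channels x samples")
        n_expected = self.epoch_len_s * self.fs
        if abs(n_expected - round(n_expected)) > 1e-9:
            raise ValueError("epoch length times fs must be an integer sample count")
        if self.data.shape[2] != round(n_expected):
            raise ValueError("epoch sample count does not match epoch_len_s * fs")
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        if self.interpolated is None:
            self.interpolated = [set() for _ in range(self.data.shape[0])]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def epoch(recording: Recording, epoch_len_s: float = 2.0) -> EpochedRecording:
    """Cut a recording into consecutive non-overlapping epochs.

    A trailing remainder shorter than one epoch is dropped.
    """
    n_per = epoch_len_s * recording.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch length times fs must be an integer sample count")
    n_per = round(n_per)
    n_epochs = recording.n_samples // n_per
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    cut = recording.data[:, : n_epochs * n_per]
    data = cut.reshape(recording.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochedRecording(
        data=data.copy(), fs=recording.fs, montage=recording.montage,
        epoch_len_s=epoch_len_s,
    )


def merge_epochs(epoched: EpochedRecording, drop_rejected: bool = True) -> Recording:
    """Concatenate (optionally surviving) epochs back into a Recording."""
    keep = ~epoched.rejected if drop_rejected else np.ones(epoched.n_epochs, bool)
    if not keep.any():
        raise ValueError("all epochs rejected; nothing to merge")
    data = epoched.data[keep].transpose(1, 0, 2).reshape(len(epoched.montage), -1)
    return Recording(data=data, fs=epoched.fs, montage=epoched.montage,
                     reference="other")


def average_reference(recording: Recording) -> Recording:
    """Re-reference to the common average; idempotent."""
    data = recording.data - recording.data.mean(axis=0, keepdims=True)
    return recording.copy_with(data=data, reference="average")


def resample(recording: Recording, target_hz: float = 250.0) -> Recording:
    """Polyphase anti-aliased downsampling to ``target_hz``.

    Upsampling is refused: the pipeline only ever reduces the rate (the
    acquisition rate is far above the 40 Hz analysis band).
    """
    if target_hz > recording.fs:
        raise ValueError(
            f"target rate {target_hz} Hz exceeds sampling rate {recording.fs} Hz"
        )
    if target_hz == recording.fs:
        return recording.copy_with()
    from fractions import Fraction

    frac = Fraction(target_hz / recording.fs).limit_denominator(10_000)
    data = sps.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    return recording.copy_with(data=data, fs=target_hz)
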