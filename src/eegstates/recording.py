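"""Core in-memory containers shared across the pipeline.

The central object is :class:`EEGRecording`, a channels x samples array of
voltages (µV) together with its sampling rate, channel labels, bad-channel
bookkeeping and a per-sample retention mask.  Every preprocessing operation
consumes and returns an ``EEGRecording``; none of them changes the channel
count, the labels or the bad-channel list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["EEGRecording", "FilterSpec", "SubjectSpec", "default_channel_labels"]


def default_channel_labels(n_channels: int) -> list[str]:
    """Geodesic-net style labels ``E001 ... E128``."""
    width = max(3, len(str(n_channels)))
    return [f"E{i + 1:0{width}d}" for i in range(n_channels)]


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject generation / metadata record.

    ``CA`` is chronological age and ``BA`` bone age, both in years; their
    difference defines the maturity group.  ``n_bad_channels`` emulates
    electrodes with interrupted signals (observed range 0-12 per subject).
    """

    subject_id: str
    CA: float
    BA: float
    n_bad_channels: int = 0
    seed: int = 0
    duration: float = 300.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_bad_channels <= 12:
            raise ValueError("n_bad_channels must be in [0, 12]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    bad_channels : set of int
        Channel indices with interrupted/unusable signal.
    epoch_mask : ndarray of bool, shape (n_samples,)
        True for retained samples; excised epochs create continuity breaks
        that downstream phase analysis and transition counting must not
        bridge.
    meta : dict
        Free-form metadata; the synthetic generator stores the hidden
        ground-truth state labels here under ``"true_labels"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    bad_channels: set[int] = field(default_factory=set)
    epoch_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_ch, n_samp = self.data.shape
        if not self.channel_labels:
            self.channel_labels = default_channel_labels(n_ch)
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length mismatch")
        if any(not 0 <= c < n_ch for c in self.bad_channels):
            raise ValueError("bad channel index out of range")
        if self.epoch_mask is None:
            self.epoch_mask = np.ones(n_samp, dtype=bool)
        else:
            self.epoch_mask = np.asarray(self.epoch_mask, dtype=bool)
            if self.epoch_mask.shape != (n_samp,):
                raise ValueError("epoch_mask length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def good_channels(self) -> np.ndarray:
        return np.array(
            [c for c in range(self.n_channels) if c not in self.bad_channels],
            dtype=int,
        )

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with new signal (same bookkeeping)."""
        return EEGRecording(
            data=np.asarray(data, dtype=float),
            fs=self.fs if fs is None else fs,
            channel_labels=list(self.channel_labels),
            bad_channels=set(self.bad_channels),
            epoch_mask=None if fs is not None else self.epoch_mask.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class FilterSpec:
    """FIR filter description (Hamming-window design).

    ``edges`` are the passband edges in Hz; ``transition`` the transition
    bandwidth.  The -6 dB cutoff sits at the middle of the transition band,
    matching the convention of the standard windowed-sinc designs used by
    common EEG toolboxes.
    """

    kind: str  # highpass | lowpass
    edge: float
    transition: float
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError("kind must be 'highpass' or 'lowpass'")
        if self.edge <= 0 or self.transition <= 0:
            raise ValueError("edge and transition must be positive")

    @property
    def cutoff_6db(self) -> float:
        if self.kind == "highpass":
            return self.edge - self.transition / 2.0
        return self.edge + self.transition / 2.0
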