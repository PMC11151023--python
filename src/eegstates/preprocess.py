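"""Recording-level conditioning.

The chain mirrors a conventional resting-state EEG workflow: zero-phase FIR
high-pass at 1 Hz (transition 1 Hz) and low-pass at 40 Hz (transition
10 Hz), average re-referencing over good channels, 6th-order Butterworth
band-pass for the analysis band (default alpha, 8-12 Hz) applied
forward-backward, integer-factor downsampling to 100 Hz, and per-channel
linear detrend + demean.  Noisy-epoch rejection is represented by an
externally supplied boolean ``epoch_mask``; excised stretches become
continuity breaks that phase analysis and transition counting never bridge.

No operation changes the channel count, the labels, or the bad-channel
list.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import EEGRecording, FilterSpec

__all__ = [
    "design_fir",
    "fir_filter",
    "average_reference",
    "alpha_bandpass",
    "downsample",
    "detrend_demean",
    "preprocess_recording",
    "contiguous_segments",
]


def design_fir(spec: FilterSpec, fs: float) -> np.ndarray:
    """Hamming-window linear-phase FIR taps for a high- or low-pass spec.

    The -6 dB point sits mid-transition (``spec.cutoff_6db``); the number of
    taps follows the Hamming design rule (transition width 3.3/N cycles).
    """
    nyq = fs / 2.0
    if not 0 < spec.edge < nyq:
        raise ValueError("filter edge must lie strictly inside (0, Nyquist)")
    numtaps = int(np.ceil(3.3 * fs / spec.transition))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay, type I
    return sps.firwin(
        numtaps,
        spec.cutoff_6db,
        window="hamming",
        pass_zero=(spec.kind == "lowpass"),
        fs=fs,
    )


def fir_filter(rec: EEGRecording, spec: FilterSpec) -> EEGRecording:
    """Apply a linear-phase FIR forward with group-delay compensation.

    Symmetric taps convolved in 'same' mode are exactly the forward pass
    shifted back by the group delay, so the output is zero-phase.
    """
    taps = design_fir(spec, rec.fs)
    out = np.empty_like(rec.data)
    for c in range(rec.n_channels):
        out[c] = sps.fftconvolve(rec.data[c], taps, mode="same")
    return rec.with_data(out)


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous mean over good channels.

    Bad channels are excluded from the mean but re-expressed against it,
    so at every sample the mean of the good channels is exactly zero.
    """
    good = rec.good_channels
    if good.size < 2:
        raise ValueError("average reference needs at least 2 good channels")
    ref = rec.data[good].mean(axis=0)
    return rec.with_data(rec.data - ref[None, :])


def alpha_bandpass(
    rec: EEGRecording, band: tuple[float, float] = (8.0, 12.0), order: int = 6
) -> EEGRecording:
    """Butterworth band-pass applied forward-backward (zero net phase).

    ``order`` is the design order per pass (default 6); the two passes give
    a squared magnitude response and cancel the phase.
    """
    lo, hi = band
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(out)


def downsample(rec: EEGRecording, fs_target: float = 100.0) -> EEGRecording:
    """Decimate by an integer factor (band-limiting must already be done).

    The epoch mask and any hidden ground-truth labels are decimated in
    lockstep so alignment with the signal is preserved.
    """
    factor = rec.fs / fs_target
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("fs must be an integer multiple of fs_target")
    factor = int(round(factor))
    out = EEGRecording(
        data=rec.data[:, ::factor],
        fs=fs_target,
        channel_labels=list(rec.channel_labels),
        bad_channels=set(rec.bad_channels),
        epoch_mask=rec.epoch_mask[::factor],
        meta=dict(rec.meta),
    )
    if "true_labels" in out.meta:
        out.meta["true_labels"] = np.asarray(out.meta["true_labels"])[::factor]
    return out


def detrend_demean(rec: EEGRecording) -> EEGRecording:
    """Remove the per-channel best-fit line (residual mean is zero)."""
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples")
    out = sps.detrend(rec.data, axis=1, type="linear")
    return rec.with_data(out)


def contiguous_segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) runs of True in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.r_[False, mask, False].astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def preprocess_recording(
    rec: EEGRecording,
    band: tuple[float, float] = (8.0, 12.0),
    fs_target: float = 100.0,
    highpass: FilterSpec | None = None,
    lowpass: FilterSpec | None = None,
) -> EEGRecording:
    """Full conditioning chain, broadband filtering through detrend."""
    hp = highpass or FilterSpec("highpass", edge=1.0, transition=1.0)
    lp = lowpass or FilterSpec("lowpass", edge=40.0, transition=10.0)
    rec = fir_filter(rec, hp)
    rec = fir_filter(rec, lp)
    rec = average_reference(rec)
    rec = alpha_bandpass(rec, band=band)
    rec = downsample(rec, fs_target=fs_target)
    rec = detrend_demean(rec)
    return rec
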