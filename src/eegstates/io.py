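"""Reading and writing the on-disk formats.

Recordings travel as EDF (16-bit, one file per subject, physical unit µV),
ground truth as a sidecar JSON next to each EDF, and cohort metadata as CSV.
The EDF writer/reader here implements the plain EDF layout (256-byte fixed
header, 256 bytes per signal, little-endian int16 data records); it exists
because none of the installed libraries can *write* EDF, and its output is
cross-checked against an independent EDF reader in the test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording, SubjectSpec

__all__ = [
    "write_edf",
    "read_edf",
    "write_sidecar",
    "read_sidecar",
    "write_cohort_csv",
    "read_cohort_csv",
    "run_length_encode",
    "run_length_decode",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    The recording length must be a whole number of seconds and the sampling
    rate an integer (both hold for the generator's output).  Per-channel
    physical min/max are set symmetrically around zero so quantization is
    sign-preserving.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    if n_samp % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_records = n_samp // fs

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    # round through the 8-char ASCII header field (with a small headroom so
    # rounding never lands below the data range), so writer and reader use
    # identical gains
    phys_max = np.array([float(f"{m * 1.001:.6g}"[:8]) for m in phys_max])
    # standard EDF affine map (phys_min = -phys_max, digital -32768..32767)
    gain = 2.0 * phys_max / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.data + phys_max[:, None]) / gain[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = bytearray()
    header += _pad("0", 8)
    header += _pad("X X X X", 80)  # local patient id (anonymous)
    header += _pad("Startdate X X X X", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(n_ch), 4)

    fields = [
        [_pad(lbl, 16) for lbl in rec.channel_labels],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{-m:.6g}"[:8], 8) for m in phys_max],
        [_pad(f"{m:.6g}"[:8], 8) for m in phys_max],
        [_pad(str(_DIG_MIN), 8)] * n_ch,
        [_pad(str(_DIG_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    for col in fields:
        for item in col:
            header += item

    # data records: for each second, each channel's fs samples contiguously
    blocks = digital.reshape(n_ch, n_records, fs)
    body = np.ascontiguousarray(blocks.transpose(1, 0, 2))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(body.tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file written by :func:`write_edf` (plain EDF, no annotations)."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244].decode().strip())
        n_ch = int(head[252:256].decode().strip())
        sig = fh.read(256 * n_ch)
        labels = [sig[16 * i : 16 * (i + 1)].decode().strip() for i in range(n_ch)]

        def col(offset: int, width: int, i: int) -> str:
            base = offset * n_ch
            return sig[base + width * i : base + width * (i + 1)].decode().strip()

        # field offsets within the per-signal header block, in bytes
        phys_min = np.array([float(col(16 + 80 + 8, 8, i)) for i in range(n_ch)])
        phys_max = np.array([float(col(16 + 80 + 8 + 8, 8, i)) for i in range(n_ch)])
        dig_min = np.array([float(col(16 + 80 + 8 + 16, 8, i)) for i in range(n_ch)])
        dig_max = np.array([float(col(16 + 80 + 8 + 24, 8, i)) for i in range(n_ch)])
        spr = np.array(
            [int(col(16 + 80 + 8 + 32 + 80, 8, i)) for i in range(n_ch)], dtype=int
        )
        if len(set(spr.tolist())) != 1:
            raise ValueError("mixed per-signal rates are not supported")
        fs = int(spr[0])  # 1-second records
        raw = np.frombuffer(fh.read(2 * n_records * int(spr.sum())), dtype="<i2")

    blocks = raw.reshape(n_records, n_ch, fs).transpose(1, 0, 2)
    digital = blocks.reshape(n_ch, n_records * fs).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    data = digital * gain[:, None] + offset[:, None]
    return EEGRecording(data=data, fs=float(fs), channel_labels=labels)


def run_length_encode(labels: np.ndarray) -> list[list[int]]:
    """Encode an integer label sequence as ``[[label, run_length], ...]``."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [[int(labels[s]), int(e - s)] for s, e in zip(starts, ends)]


def run_length_decode(runs: list[list[int]]) -> np.ndarray:
    if not runs:
        return np.array([], dtype=int)
    return np.repeat([r[0] for r in runs], [r[1] for r in runs]).astype(int)


def write_sidecar(
    path: str | Path,
    spec: SubjectSpec,
    topographies: np.ndarray,
    P_cond: np.ndarray,
    pi: np.ndarray,
    H_true: float,
    labels: np.ndarray,
    bad_channels: list[int],
) -> Path:
    """Ground-truth sidecar JSON (kept out of the EDF to leave it conformant)."""
    path = Path(path)
    payload = {
        "subject_id": spec.subject_id,
        "seed": spec.seed,
        "CA": spec.CA,
        "BA": spec.BA,
        "fs": spec.fs,
        "duration": spec.duration,
        "topographies": np.asarray(topographies).tolist(),
        "P_cond": np.asarray(P_cond).tolist(),
        "pi": np.asarray(pi).tolist(),
        "H_true": float(H_true),
        "labels_rle": run_length_encode(np.asarray(labels)),
        "bad_channels": sorted(int(c) for c in bad_channels),
    }
    path.write_text(json.dumps(payload))
    return path


def read_sidecar(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["topographies"] = np.asarray(payload["topographies"], dtype=float)
    payload["P_cond"] = np.asarray(payload["P_cond"], dtype=float)
    payload["pi"] = np.asarray(payload["pi"], dtype=float)
    payload["labels"] = run_length_decode(payload.pop("labels_rle"))
    return payload


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    required = {"subject_id", "CA", "BA", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    table.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})
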