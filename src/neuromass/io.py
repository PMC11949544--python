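"""Format round-tripping: EDF and delimited-text EEG, score reports.

EDF (European Data Format) is the clinical interchange format for EEG; the
writer here emits standard 16-bit EDF with physical dimension uV and whole-
second data records, which any EDF reader can open.  The reader supports
the same (uncompressed, equal-rate, 16-bit) subset.  A plain delimited-text
representation is provided as the human-readable twin.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward_model import EEGRecording

__all__ = ["write_edf", "read_edf", "write_eeg_csv", "read_eeg_csv", "write_score_json"]

_EDF_EPOCH = _dt.datetime(2000, 1, 1, 0, 0, 0)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(eeg: EEGRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF (physical dimension uV).

    Records are 1 s long; the last record is zero-padded when the duration
    is not a whole number of seconds.  The sampling rate must be integer.
    """
    fs = eeg.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    ns = len(eeg.channel_names)
    n_samples = eeg.data.shape[1]
    n_records = int(np.ceil(n_samples / fs))
    padded = np.zeros((ns, n_records * fs))
    padded[:, :n_samples] = eeg.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    dig_max = 32767
    scale = phys_max / dig_max
    digital = np.round(padded / scale[:, None]).astype("<i2")

    hdr = b""
    hdr += _pad("0", 8)
    hdr += _pad("X X X X", 80)
    hdr += _pad(f"Startdate 01-JAN-2000 X X {eeg.kind}", 80)
    hdr += _pad(_EDF_EPOCH.strftime("%d.%m.%y"), 8)
    hdr += _pad(_EDF_EPOCH.strftime("%H.%M.%S"), 8)
    hdr += _pad(str(256 + 256 * ns), 8)
    hdr += _pad("", 44)
    hdr += _pad(str(n_records), 8)
    hdr += _pad("1", 8)
    hdr += _pad(str(ns), 4)

    def field(values, width):
        return b"".join(_pad(v, width) for v in values)

    labels = [name.replace("\n", " ") for name in eeg.channel_names]
    hdr += field(labels, 16)
    hdr += field([""] * ns, 80)
    hdr += field(["uV"] * ns, 8)
    hdr += field([f"{-m:.6g}"[:8] for m in phys_max], 8)
    hdr += field([f"{m:.6g}"[:8] for m in phys_max], 8)
    hdr += field([str(-dig_max - 1)] * ns, 8)
    hdr += field([str(dig_max)] * ns, 8)
    hdr += field([""] * ns, 80)
    hdr += field([str(fs)] * ns, 8)
    hdr += field([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for rec in range(n_records):
            chunk = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(chunk.tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read 16-bit EDF with a uniform per-signal rate (the subset written
    by :func:`write_edf`, and ordinary clinical EDFs of that shape)."""
    raw = Path(path).read_bytes()

    def s(lo, n):
        return raw[lo : lo + n].decode("ascii").strip()

    ns = int(s(252, 4))
    n_records = int(s(236, 8))
    record_dur = float(s(244, 8))
    off = 256

    def sig_field(width):
        nonlocal off
        vals = [s(off + i * width, width) for i in range(ns)]
        off += ns * width
        return vals

    labels = sig_field(16)
    sig_field(80)  # transducer
    dims = sig_field(8)
    phys_min = [float(v) for v in sig_field(8)]
    phys_max = [float(v) for v in sig_field(8)]
    dig_min = [int(v) for v in sig_field(8)]
    dig_max = [int(v) for v in sig_field(8)]
    sig_field(80)  # prefiltering
    spr = [int(v) for v in sig_field(8)]
    sig_field(32)
    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal rates are not supported")
    fs = spr[0] / record_dur

    header_bytes = 256 + 256 * ns
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    data = data.reshape(n_records, ns, spr[0])
    out = np.empty((ns, n_records * spr[0]))
    for i in range(ns):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        offset = phys_max[i] - gain * dig_max[i]
        out[i] = (data[:, i, :].reshape(-1) * gain + offset)
    kind = "bipolar" if all("-" in lab for lab in labels) else "referential"
    return EEGRecording(list(labels), out, fs, kind=kind)


def write_eeg_csv(eeg: EEGRecording, path: str | Path) -> None:
    """Delimited-text EEG: '# fs=... kind=...' comment then channel columns."""
    df = pd.DataFrame(eeg.data.T, columns=eeg.channel_names)
    with open(path, "w") as fh:
        fh.write(f"# fs={eeg.fs} kind={eeg.kind}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_eeg_csv(path: str | Path) -> EEGRecording:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing metadata line '# fs=... kind=...'")
        meta = dict(item.split("=") for item in first[1:].split())
        df = pd.read_csv(fh)
    return EEGRecording(
        list(df.columns), df.to_numpy(dtype=float).T, float(meta["fs"]), kind=meta["kind"]
    )


def write_score_json(score, path: str | Path) -> None:
    Path(path).write_text(json.dumps(score.to_dict(), indent=2) + "\n")
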