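"""EDF import/export for recordings.

Reading goes through MNE's native EDF reader. Writing uses a small
standard-EDF (16-bit) writer implemented here: each channel is scaled to a
symmetric physical range and stored in 1-second data records. The writer is
intentionally minimal — one recording per file, physical unit fixed to uV —
and is round-trip tested against the MNE reader.
"""

from __future__ import annotations

import math

import numpy as np

from .recording import EEG, EOG, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as a standard EDF file with 1-second data records.

    Requires an integer sampling rate and an integer number of seconds of
    data (both hold for the cohort synthesizer's output).
    """
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {rate}")
    rate = int(round(rate))
    n_records, rem = divmod(rec.n_samples, rate)
    if rem:
        raise ValueError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {rate} Hz)"
        )
    ns = len(rec.channels)

    # Symmetric physical range per channel, integer uV bounds keep the
    # header fields short and the quantization step ~amp/32767.
    amps = [max(1.0, math.ceil(float(np.max(np.abs(row))))) for row in rec.data]

    header = b"".join(
        [
            _ascii_field(0, 8),  # version
            _ascii_field("X X X X", 80),  # local patient id (anonymous)
            _ascii_field("Startdate X X X X", 80),  # local recording id
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + ns), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),  # record duration, seconds
            _ascii_field(ns, 4),
        ]
    )
    fields = []
    for label, role, amp in zip(rec.channels, rec.roles, amps):
        fields.append((label, role, amp))
    for getter, width in [
        (lambda f: f[0], 16),  # label
        (lambda f: f[1], 80),  # transducer: abused to carry the role
        (lambda f: "uV", 8),
        (lambda f: -f[2], 8),
        (lambda f: f[2], 8),
        (lambda f: _DIG_MIN, 8),
        (lambda f: _DIG_MAX, 8),
        (lambda f: "", 80),
        (lambda f: rate, 8),
        (lambda f: "", 32),
    ]:
        header += b"".join(_ascii_field(getter(f), width) for f in fields)

    digital = np.empty((ns, rec.n_samples), dtype="<i2")
    for i, (row, amp) in enumerate(zip(rec.data, amps)):
        scaled = np.clip(np.round(row / amp * _DIG_MAX), _DIG_MIN, _DIG_MAX)
        digital[i] = scaled.astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * rate, (r + 1) * rate)
            fh.write(digital[:, sl].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (values in microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG/EOG in volts
    channels = list(raw.ch_names)
    roles = [EOG if c.upper().startswith("EOG") else EEG for c in channels]
    return Recording(data, float(raw.info["sfreq"]), channels, roles)
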