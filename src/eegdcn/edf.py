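"""Minimal EDF (European Data Format) reader/writer.

Supports continuous multi-channel EDF files with identical sampling rates
across signals: a 256-byte fixed header, 256 bytes per signal of field
headers, then data records of little-endian int16 samples scaled between the
declared digital and physical ranges. Annotation signals (EDF+) are skipped
on read. The reader returns a single-trial :class:`RawRecording`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .features import RawRecording

__all__ = ["read_edf", "write_edf"]

_HEADER = 256


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def read_edf(path) -> RawRecording:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER:
        raise ValueError(f"truncated EDF: file is {len(raw)} bytes, header needs {_HEADER}")
    try:
        n_records = int(_field(raw, 236, 8))
        record_seconds = float(_field(raw, 244, 8))
        n_signals = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise ValueError(f"malformed EDF header near byte 236: {exc}") from exc
    sig_header_len = n_signals * 256
    if len(raw) < _HEADER + sig_header_len:
        raise ValueError(f"truncated EDF: signal headers need {sig_header_len} bytes at offset {_HEADER}")
    sh = raw[_HEADER : _HEADER + sig_header_len]

    # per-signal fields are stored field-major: all labels, then all
    # transducers, etc. Field widths: label 16, transducer 80, dimension 8,
    # phys_min 8, phys_max 8, dig_min 8, dig_max 8, prefilter 80,
    # samples/record 8, reserved 32 -> byte offsets 0, 16, 96, 104, 112,
    # 120, 128, 136, 216, 224
    def block(start_byte: int, width: int, idx: int) -> str:
        start = start_byte * n_signals + idx * width
        return sh[start : start + width].decode("ascii", errors="replace").strip()

    try:
        labels = [block(0, 16, i) for i in range(n_signals)]
        phys_min = [float(block(104, 8, i)) for i in range(n_signals)]
        phys_max = [float(block(112, 8, i)) for i in range(n_signals)]
        dig_min = [int(float(block(120, 8, i))) for i in range(n_signals)]
        dig_max = [int(float(block(128, 8, i))) for i in range(n_signals)]
        samples_per_record = [int(block(216, 8, i)) for i in range(n_signals)]
    except ValueError as exc:
        raise ValueError(f"malformed EDF signal headers at offset {_HEADER}: {exc}") from exc

    keep = [i for i, lab in enumerate(labels) if "EDF Annotations" not in lab]
    rates = {samples_per_record[i] / record_seconds for i in keep}
    if len(rates) != 1:
        raise ValueError(f"mixed sampling rates across signals: {sorted(rates)}")
    rate = rates.pop()

    data_start = _HEADER + sig_header_len
    record_len = sum(samples_per_record) * 2
    expected = data_start + n_records * record_len
    if len(raw) < expected:
        raise ValueError(
            f"truncated EDF: expected {expected} bytes ({n_records} records of "
            f"{record_len} bytes from offset {data_start}), got {len(raw)}"
        )
    payload = np.frombuffer(raw, dtype="<i2", offset=data_start, count=n_records * record_len // 2)
    payload = payload.reshape(n_records, -1)
    offsets = np.cumsum([0] + samples_per_record)
    channels = []
    for i in keep:
        digital = payload[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        scale = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        channels.append((digital - dig_min[i]) * scale + phys_min[i])
    data = np.stack(channels)[None, :, :]  # one continuous trial
    return RawRecording(
        data=data,
        sampling_rate=rate,
        channel_names=tuple(labels[i] for i in keep),
        baseline_seconds=0.0,
    )


def write_edf(path, rec: RawRecording, record_seconds: float = 1.0) -> None:
    """Write the trials of a recording concatenated as one continuous EDF."""
    data = np.concatenate([rec.data[t] for t in range(rec.n_trials)], axis=-1).astype(np.float64)
    n_ch, n_samp = data.shape
    spr = round(rec.sampling_rate * record_seconds)
    if n_samp % spr != 0:
        raise ValueError("total samples must divide evenly into data records")
    n_records = n_samp // spr

    # round the physical bounds outward to the 2 decimals the ASCII header
    # carries, and quantize against those same rounded bounds
    phys_min = np.floor(data.min(axis=1) * 100) / 100
    phys_max = np.ceil(data.max(axis=1) * 100) / 100
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("synthetic subject", 80),
            pad("eegdcn recording", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(_HEADER + 256 * n_ch), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(f"{record_seconds:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        b"".join(pad(name, 16) for name in rec.channel_names),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{phys_min[i]:.2f}"[:8], 8) for i in range(n_ch)),
        b"".join(pad(f"{phys_max[i]:.2f}"[:8], 8) for i in range(n_ch)),
        b"".join(pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ]
    # re-quantize physical values into the digital range
    scale = (np.array(phys_max) - np.array(phys_min)) / (dig_max - dig_min)
    digital = np.rint((data - phys_min[:, None]) / scale[:, None] + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, r * spr : (r + 1) * spr].tobytes())
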