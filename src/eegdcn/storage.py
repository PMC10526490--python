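"""On-disk formats.

The array container is a single file: an 8-byte magic, an 8-byte little-endian
header length, a UTF-8 JSON header (metadata plus per-array dtype/shape/byte
offsets), then the raw little-endian array bytes. Inspectable with a hex
editor or ``read_container_header``; round-trips are bit-exact.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .features import RawRecording

__all__ = [
    "write_arrays",
    "read_arrays",
    "read_container_header",
    "write_recording",
    "read_recording_container",
    "write_feature_store",
    "read_feature_store",
    "write_checkpoint",
    "read_checkpoint",
]

MAGIC = b"EEGARC01"


def write_arrays(path, arrays: dict[str, np.ndarray], meta: dict | None = None) -> None:
    path = Path(path)
    entries = {}
    offset = 0
    blobs = []
    for name, arr in arrays.items():
        arr = np.ascontiguousarray(arr)
        if arr.dtype.byteorder == ">":
            arr = arr.astype(arr.dtype.newbyteorder("<"))
        blob = arr.tobytes()
        entries[name] = {"dtype": arr.dtype.str, "shape": list(arr.shape), "offset": offset, "nbytes": len(blob)}
        blobs.append(blob)
        offset += len(blob)
    header = json.dumps({"meta": meta or {}, "arrays": entries}, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        for blob in blobs:
            fh.write(blob)


def _read_header(fh) -> dict:
    magic = fh.read(8)
    if magic != MAGIC:
        raise ValueError(f"not an array container (bad magic {magic!r} at byte 0)")
    (hlen,) = struct.unpack("<Q", fh.read(8))
    raw = fh.read(hlen)
    if len(raw) != hlen:
        raise ValueError(f"truncated header: expected {hlen} bytes at offset 16, got {len(raw)}")
    return json.loads(raw.decode())


def read_container_header(path) -> dict:
    with open(path, "rb") as fh:
        return _read_header(fh)


def read_arrays(path) -> tuple[dict[str, np.ndarray], dict]:
    with open(path, "rb") as fh:
        header = _read_header(fh)
        base = fh.tell()
        arrays = {}
        for name, entry in header["arrays"].items():
            fh.seek(base + entry["offset"])
            raw = fh.read(entry["nbytes"])
            if len(raw) != entry["nbytes"]:
                raise ValueError(
                    f"truncated array {name!r}: expected {entry['nbytes']} bytes "
                    f"at offset {base + entry['offset']}"
                )
            arrays[name] = np.frombuffer(raw, dtype=np.dtype(entry["dtype"])).reshape(entry["shape"]).copy()
    return arrays, header["meta"]


# ------------------------------------------------------------- recordings

def write_recording(path, rec: RawRecording) -> None:
    arrays = {"data": np.asarray(rec.data, dtype=np.float32)}
    if rec.ratings is not None:
        arrays["ratings"] = np.asarray(rec.ratings, dtype=np.float64)
    if rec.labels is not None:
        arrays["labels"] = np.asarray(rec.labels, dtype=np.int64)
    meta = {
        "kind": "recording",
        "sampling_rate": rec.sampling_rate,
        "channel_names": list(rec.channel_names),
        "baseline_seconds": rec.baseline_seconds,
        "subject_id": rec.subject_id,
    }
    write_arrays(path, arrays, meta)


def read_recording_container(path) -> RawRecording:
    arrays, meta = read_arrays(path)
    if meta.get("kind") != "recording":
        raise ValueError(f"container at {path} is not a recording (kind={meta.get('kind')!r})")
    return RawRecording(
        data=arrays["data"],
        sampling_rate=meta["sampling_rate"],
        channel_names=tuple(meta["channel_names"]),
        baseline_seconds=meta["baseline_seconds"],
        ratings=arrays.get("ratings"),
        labels=arrays.get("labels"),
        subject_id=meta["subject_id"],
    )


# ------------------------------------------------------------- feature store

def write_feature_store(
    path,
    tensors: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    trial_ids: np.ndarray,
    band_names,
    layout_name: str,
    layout_version: int,
) -> None:
    write_arrays(
        path,
        {
            "tensors": np.asarray(tensors, dtype=np.float64),
            "mask": np.asarray(mask, dtype=bool),
            "labels": np.asarray(labels, dtype=np.int64),
            "subject_ids": np.asarray(subject_ids, dtype=np.int64),
            "trial_ids": np.asarray(trial_ids, dtype=np.int64),
        },
        {
            "kind": "features",
            "band_names": list(band_names),
            "layout": layout_name,
            "layout_version": layout_version,
        },
    )


def read_feature_store(path):
    arrays, meta = read_arrays(path)
    if meta.get("kind") != "features":
        raise ValueError(f"container at {path} is not a feature store (kind={meta.get('kind')!r})")
    return arrays, meta


# ------------------------------------------------------------- checkpoints

def write_checkpoint(path, state: dict[str, np.ndarray], config: dict) -> None:
    write_arrays(path, dict(state), {"kind": "checkpoint", "config": config})


def read_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    arrays, meta = read_arrays(path)
    if meta.get("kind") != "checkpoint":
        raise ValueError(f"container at {path} is not a checkpoint (kind={meta.get('kind')!r})")
    return arrays, meta["config"]
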