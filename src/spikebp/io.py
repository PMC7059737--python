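"""Readers/writers for the MNIST IDX container and N-MNIST AER event files.

Both are tiny binary formats: IDX stores an n-dimensional uint8 array with
a big-endian header, and the N-MNIST address-event (AER) format packs one
event into 5 bytes — x, y, then a 24-bit field whose top bit is the
polarity and whose low 23 bits are the microsecond timestamp.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .encoding import EventStream

__all__ = ["read_idx", "write_idx", "read_aer_events", "write_aer_events"]

_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: ">i2",
    0x0C: ">i4",
    0x0D: ">f4",
    0x0E: ">f8",
}


def read_idx(path: str | Path) -> np.ndarray:
    """Read an IDX-format array (e.g. MNIST images or labels)."""
    raw = Path(path).read_bytes()
    zero, dtype_code, ndim = struct.unpack(">HBB", raw[:4])
    if zero != 0 or dtype_code not in _IDX_DTYPES:
        raise ValueError(f"not an IDX file: {path}")
    dims = struct.unpack(f">{ndim}I", raw[4 : 4 + 4 * ndim])
    data = np.frombuffer(raw[4 + 4 * ndim :], dtype=_IDX_DTYPES[dtype_code])
    if data.size != int(np.prod(dims)):
        raise ValueError("IDX payload size does not match header dimensions")
    return data.reshape(dims).astype(np.dtype(_IDX_DTYPES[dtype_code]).newbyteorder("="))


def write_idx(path: str | Path, array: np.ndarray) -> None:
    """Write a uint8 array in IDX format."""
    arr = np.ascontiguousarray(array, dtype=np.uint8)
    header = struct.pack(">HBB", 0, 0x08, arr.ndim)
    header += struct.pack(f">{arr.ndim}I", *arr.shape)
    Path(path).write_bytes(header + arr.tobytes())


def read_aer_events(path: str | Path, width: int = 34, height: int = 34) -> EventStream:
    """Read an N-MNIST-style 5-byte AER event file."""
    raw = np.frombuffer(Path(path).read_bytes(), dtype=np.uint8)
    if raw.size % 5:
        raise ValueError("AER file length is not a multiple of 5 bytes")
    rec = raw.reshape(-1, 5).astype(np.int64)
    x, y = rec[:, 0], rec[:, 1]
    polarity = rec[:, 2] >> 7
    timestamp = ((rec[:, 2] & 0x7F) << 16) | (rec[:, 3] << 8) | rec[:, 4]
    return EventStream(x=x, y=y, polarity=polarity, timestamp=timestamp,
                       width=width, height=height)


def write_aer_events(path: str | Path, stream: EventStream) -> None:
    """Write an event stream in the 5-byte AER format."""
    if stream.timestamp.size and stream.timestamp.max() >= (1 << 23):
        raise ValueError("timestamps exceed the 23-bit AER field")
    rec = np.empty((len(stream), 5), dtype=np.uint8)
    rec[:, 0] = stream.x
    rec[:, 1] = stream.y
    rec[:, 2] = (stream.polarity << 7) | ((stream.timestamp >> 16) & 0x7F)
    rec[:, 3] = (stream.timestamp >> 8) & 0xFF
    rec[:, 4] = stream.timestamp & 0xFF
    Path(path).write_bytes(rec.tobytes())
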