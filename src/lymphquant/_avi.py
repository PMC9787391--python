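"""Minimal uncompressed RGB24 AVI (RIFF) reader and writer.

Implements the plain 'DIB ' (BI_RGB) codec only: 24-bit BGR pixel data,
bottom-up rows, each row padded to a 4-byte boundary.  This is the
lossless default container for both input fixtures and overlay output;
anything a real player writes with "uncompressed RGB" settings decodes
here, and the files written here open in standard players.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_avi", "write_avi", "AviFormatError"]

_FPS_SCALE = 1000  # frame rate stored as rate/scale to allow fractional FPS


class AviFormatError(ValueError):
    """Raised when a file is not a decodable uncompressed AVI."""


def _pad4(n: int) -> int:
    return (n + 3) & ~3


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write frames (T, H, W, 3) uint8 RGB as an uncompressed AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be (T, H, W, 3) uint8")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    n, h, w, _ = frames.shape
    row_bytes = _pad4(w * 3)
    frame_bytes = row_bytes * h

    # BGR, bottom-up, padded rows
    padded = np.zeros((n, h, row_bytes), dtype=np.uint8)
    padded[:, :, : w * 3] = frames[:, ::-1, :, ::-1].reshape(n, h, w * 3)

    rate = round(fps * _FPS_SCALE)
    avih = struct.pack(
        "<14I",
        round(1e6 * _FPS_SCALE / rate),  # dwMicroSecPerFrame
        frame_bytes * round(fps + 1),  # dwMaxBytesPerSec (advisory)
        0,  # dwPaddingGranularity
        0x10,  # dwFlags: AVIF_HASINDEX
        n, 0, 1,  # totalframes, initialframes, streams
        frame_bytes,  # dwSuggestedBufferSize
        w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sI2H8I4h",
        b"vids", b"DIB ", 0, 0, 0, 0,
        _FPS_SCALE, rate,  # dwScale, dwRate -> fps = rate / scale
        0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    )
    strf = struct.pack(
        "<I2i2H2I2i2I",
        40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0,
    )

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"".join(chunk(b"00db", padded[i].tobytes()) for i in range(n))
    movi = lst(b"movi", movi_payload)

    # idx1: offsets are relative to the start of the 'movi' fourcc
    idx, offset = [], 4
    for _ in range(n):
        idx.append(struct.pack("<4s3I", b"00db", 0x10, offset, frame_bytes))
        offset += 8 + _pad4(frame_bytes) if frame_bytes % 2 else 8 + frame_bytes
    idx1 = chunk(b"idx1", b"".join(idx))

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed (BI_RGB) AVI; returns ((T, H, W, 3) uint8, fps)."""
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise AviFormatError(f"not a RIFF/AVI file: {path}")

    width = height = None
    bitcount = compression = None
    rate = scale = None
    frames_raw: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, compression, rate, scale
        for fourcc, payload, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(payload + 4, payload + size)
            elif fourcc == b"strh" and size >= 40:
                fcc_type = buf[payload : payload + 4]
                if fcc_type == b"vids":
                    scale, rate = struct.unpack_from("<2I", buf, payload + 20)
            elif fourcc == b"strf" and size >= 40 and width is None:
                (_, w, h, _, bc, comp) = struct.unpack_from("<I2i2HI", buf, payload)
                width, height, bitcount, compression = w, h, bc, comp
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames_raw.append(buf[payload : payload + size])

    walk(12, len(buf))

    if width is None or height is None:
        raise AviFormatError(f"no video stream header found in {path}")
    if compression != 0 or bitcount != 24:
        raise AviFormatError(
            f"unsupported codec in {path}: only uncompressed 24-bit RGB "
            f"(BI_RGB) is supported (got biCompression={compression}, "
            f"biBitCount={bitcount})"
        )
    if not frames_raw:
        raise AviFormatError(f"no frames found in {path}")

    flip = height > 0  # positive height means bottom-up rows
    h = abs(height)
    row_bytes = _pad4(width * 3)
    out = np.empty((len(frames_raw), h, width, 3), dtype=np.uint8)
    for i, raw in enumerate(frames_raw):
        if len(raw) < row_bytes * h:
            raise AviFormatError(f"truncated frame {i} in {path}")
        rows = np.frombuffer(raw, np.uint8, row_bytes * h).reshape(h, row_bytes)
        img = rows[:, : width * 3].reshape(h, width, 3)[:, :, ::-1]  # BGR -> RGB
        out[i] = img[::-1] if flip else img

    fps = (rate / scale) if rate and scale else 25.0
    return out, fps
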