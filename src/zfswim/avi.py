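"""Minimal uncompressed AVI reader/writer.

High-speed cameras of the kind used for fish tanks store raw
(uncompressed) AVI, which none of the scientific imaging libraries in a
typical analysis environment decode without an external ffmpeg binary.
The subset of the RIFF/AVI format implemented here is exactly what those
recordings use: a single ``vids`` stream of device-independent bitmaps
(``BI_RGB``), either 8-bit palettized grayscale or 24-bit BGR, bottom-up
with rows padded to 4 bytes.  Writing always produces 8-bit grayscale
with a linear gray palette, so a write/read round trip is lossless.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import DecodeError

_AVIF_HASINDEX = 0x10


def _pad4(n: int) -> int:
    return (n + 3) & ~3


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (T, H, W) uint8 as an uncompressed grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be a (T, H, W) uint8 array")
    n, h, w = frames.shape
    stride = _pad4(w)
    frame_bytes = stride * h

    if abs(fps - round(fps)) < 1e-9:
        rate, scale = int(round(fps)), 1
    else:
        rate, scale = int(round(fps * 1000)), 1000

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),          # microseconds per frame
        int(frame_bytes * fps),         # max bytes per second
        0,                              # padding granularity
        _AVIF_HASINDEX,
        n, 0, 1,                        # total frames, initial frames, streams
        frame_bytes,                    # suggested buffer size
        w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sI2H8I4h",
        b"vids", b"DIB ", 0, 0, 0, 0,
        scale, rate, 0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    )
    # BITMAPINFOHEADER + 256-entry gray palette
    bmih = struct.pack("<I2i2H2I2i2I", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 256)
    palette = bytes(b for v in range(256) for b in (v, v, v, 0))
    strf = bmih + palette

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    hdrl = lst(b"hdrl", chunk(b"avih", avih) + lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)))

    movi_body = b""
    offsets = []
    for frame in frames:
        # bottom-up row order, each row padded to 4 bytes
        rows = frame[::-1]
        if stride != w:
            rows = np.pad(rows, ((0, 0), (0, stride - w)))
        offsets.append(4 + len(movi_body))
        movi_body += chunk(b"00db", rows.tobytes())
    movi = lst(b"movi", movi_body)

    idx1 = b"".join(
        struct.pack("<4s3I", b"00db", 0x10, off, frame_bytes) for off in offsets
    )
    riff_body = b"AVI " + hdrl + movi + chunk(b"idx1", idx1)
    data = b"RIFF" + struct.pack("<I", len(riff_body)) + riff_body
    Path(path).write_bytes(data)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI; returns (frames (T, H, W) uint8 grayscale, fps)."""
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise DecodeError(f"{path}: not an AVI (RIFF) file")

    fps = None
    width = height = bits = None
    palette = None
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal fps, width, height, bits, palette
        pos = start
        while pos + 8 <= end:
            fourcc = data[pos : pos + 4]
            (size,) = struct.unpack_from("<I", data, pos + 4)
            body = pos + 8
            if fourcc == b"LIST":
                walk(body + 4, body + size)
            elif fourcc == b"strh" and data[body : body + 4] == b"vids":
                scale, rate = struct.unpack_from("<2I", data, body + 20)
                if scale:
                    fps = rate / scale
            elif fourcc == b"strf" and bits is None:
                _, w_, h_, _, bits_ = struct.unpack_from("<I2i2H", data, body)
                (compression,) = struct.unpack_from("<I", data, body + 16)
                if compression != 0:
                    raise DecodeError(f"{path}: compressed AVI not supported")
                width, height, bits = w_, abs(h_), bits_
                if bits == 8:
                    pal = np.frombuffer(data[body + 40 : body + 40 + 1024], np.uint8)
                    palette = pal.reshape(-1, 4)[:, :3][:, ::-1]  # BGR0 -> RGB
            elif fourcc[2:] in (b"db", b"dc") and size:
                frames.append(_decode_dib(data[body : body + size], width, height, bits, palette, path))
            pos = body + size + (size & 1)

    walk(12, len(data))
    if not frames:
        raise DecodeError(f"{path}: no video frames found")
    if fps is None or fps <= 0:
        raise DecodeError(f"{path}: missing or invalid stream rate")
    return np.stack(frames), fps


def _decode_dib(raw: bytes, w: int, h: int, bits: int, palette, path) -> np.ndarray:
    if w is None or bits not in (8, 24):
        raise DecodeError(f"{path}: unsupported pixel format ({bits}-bit)")
    px_bytes = bits // 8
    stride = _pad4(w * px_bytes)
    if len(raw) < stride * h:
        raise DecodeError(f"{path}: truncated frame chunk")
    arr = np.frombuffer(raw[: stride * h], np.uint8).reshape(h, stride)[::-1]
    if bits == 8:
        idx = arr[:, :w]
        if palette is None:
            return idx.copy()
        rgb = palette[idx].astype(np.float64)
        return _luminance(rgb[..., 0], rgb[..., 1], rgb[..., 2])
    bgr = arr[:, : w * 3].reshape(h, w, 3).astype(np.float64)
    return _luminance(bgr[..., 2], bgr[..., 1], bgr[..., 0])


def _luminance(r, g, b) -> np.ndarray:
    """ITU-R 601 luma, rounded to uint8."""
    return np.clip(np.rint(0.299 * r + 0.587 * g + 0.114 * b), 0, 255).astype(np.uint8)
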