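"""Uncompressed RIFF/AVI container support.

Reads and writes AVI files holding raw device-independent bitmap ("DIB ")
frames, the uncompressed interchange format that video tools such as
VirtualDub and ImageJ produce and consume.  Only this codec is handled:
8-bit palettized (written with a grey ramp palette) and 24-bit BGR frames,
constant frame rate.  Writing always uses 8-bit grayscale, which makes the
round trip bit-exact for the grayscale frame stacks this package works on.

The format itself is simple: a RIFF container with an ``hdrl`` list (main
header + one video stream header), a ``movi`` list of per-frame ``00db``
chunks, and an optional ``idx1`` index.  DIB rows are stored bottom-up and
padded to 4-byte boundaries; the frame rate is the rational
``dwRate / dwScale`` from the stream header.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import EmptyVideoError, VideoDecodeError

_AVIF_HASINDEX = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def _fps_to_rational(fps: float) -> tuple[int, int]:
    """Represent fps as dwRate/dwScale with millihertz resolution."""
    if abs(fps - round(fps)) < 1e-9:
        return int(round(fps)), 1
    return int(round(fps * 1000)), 1000


def write_gray_avi(path: str | Path, frames: np.ndarray, fps: float) -> Path:
    """Write a (n, h, w) uint8 stack as an uncompressed 8-bit grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.size == 0:
        raise ValueError("frames must be a non-empty (n, h, w) stack")
    if frames.dtype != np.uint8:
        raise ValueError("frames must be uint8 (grey levels 0-255)")
    n, h, w = frames.shape
    rate, scale = _fps_to_rational(fps)
    stride = (w + 3) & ~3
    frame_bytes = stride * h

    avih = struct.pack(
        "<14I",
        int(round(1_000_000 / fps)),      # dwMicroSecPerFrame
        frame_bytes * int(round(fps)),    # dwMaxBytesPerSec (advisory)
        0,                                # dwPaddingGranularity
        _AVIF_HASINDEX,                   # dwFlags
        n,                                # dwTotalFrames
        0, 1,                             # dwInitialFrames, dwStreams
        frame_bytes,                      # dwSuggestedBufferSize
        w, h,
        0, 0, 0, 0,                       # dwReserved
    )
    # AVISTREAMHEADER: flags, priority, language, initial frames, then
    # scale/rate (fps = rate/scale), start, length, buffer, quality,
    # sample size, rcFrame
    strh = struct.pack(
        "<4s4sIHHIIIIIIII4H",
        b"vids", b"DIB ",
        0, 0, 0, 0,
        scale, rate,
        0, n,
        frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    )
    # BITMAPINFOHEADER + 256-entry grey BGRA palette
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 256)
    palette = bytes(
        b for v in range(256) for b in (v, v, v, 0)
    )
    strf = bmih + palette

    hdrl = _list(
        b"hdrl",
        _chunk(b"avih", avih) + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)),
    )

    # bottom-up, stride-padded rows
    padded = np.zeros((n, h, stride), dtype=np.uint8)
    padded[:, :, :w] = frames[:, ::-1, :]
    movi_payload = b"movi"
    chunks = []
    offsets = []
    offset = 4  # relative to start of 'movi' fourcc
    for i in range(n):
        data = padded[i].tobytes()
        chunks.append(_chunk(b"00db", data))
        offsets.append(offset)
        offset += 8 + len(data) + (len(data) % 2)
    movi = _chunk(b"LIST", movi_payload + b"".join(chunks))

    idx_entries = b"".join(
        struct.pack("<4sIII", b"00db", 0x10, off, frame_bytes) for off in offsets
    )
    idx1 = _chunk(b"idx1", idx_entries)

    riff_payload = b"AVI " + hdrl + movi + idx1
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)
    return path


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI, returning ((n, h, w) uint8 grayscale, fps).

    24-bit BGR frames are converted to grayscale with BT.601 luminance
    weights; 8-bit frames are taken as direct grey levels (the palette is
    assumed to be a grey ramp, as written by :func:`write_gray_avi`).
    """
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise VideoDecodeError(f"not a RIFF/AVI file: {path}")

    width = height = bitcount = None
    rate = scale = None
    frame_chunks: list[tuple[int, int]] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, rate, scale
        for fourcc, data_pos, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(data_pos + 4, data_pos + size)
            elif fourcc == b"strh" and rate is None:
                fcc_type = buf[data_pos : data_pos + 4]
                if fcc_type == b"vids":
                    sc, rt = struct.unpack_from("<II", buf, data_pos + 20)
                    scale, rate = sc, rt
            elif fourcc == b"strf" and width is None:
                _, w, h, _, bc = struct.unpack_from("<IiiHH", buf, data_pos)
                width, height, bitcount = w, abs(h), bc
            elif fourcc in (b"00db", b"00dc"):
                frame_chunks.append((data_pos, size))

    walk(12, len(buf))

    if width is None or bitcount is None:
        raise VideoDecodeError(f"missing video format header in {path}")
    if bitcount not in (8, 24):
        raise VideoDecodeError(
            f"unsupported AVI bit depth {bitcount} in {path}: only uncompressed "
            "8-bit grayscale or 24-bit BGR frames are handled"
        )
    if not frame_chunks:
        raise EmptyVideoError(f"no video frames found in {path}")
    if not rate or not scale:
        raise VideoDecodeError(f"missing frame-rate metadata in {path}")
    fps = rate / scale

    bytes_px = bitcount // 8
    stride = (width * bytes_px + 3) & ~3
    frames = np.empty((len(frame_chunks), height, width), dtype=np.uint8)
    for i, (pos, size) in enumerate(frame_chunks):
        if size < stride * height:
            raise VideoDecodeError(f"truncated frame {i} in {path}")
        raw = np.frombuffer(buf, dtype=np.uint8, count=stride * height, offset=pos)
        rows = raw.reshape(height, stride)[::-1]  # bottom-up -> top-down
        if bitcount == 8:
            frames[i] = rows[:, :width]
        else:
            bgr = rows[:, : width * 3].reshape(height, width, 3)
            lum = 0.114 * bgr[..., 0] + 0.587 * bgr[..., 1] + 0.299 * bgr[..., 2]
            frames[i] = np.round(lum).astype(np.uint8)
    return frames, fps
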