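"""Minimal AVI (RIFF) video reader/writer.

Two codecs are supported, which covers the mandatory input formats:

* ``"raw"`` — uncompressed DIB frames (8-bit greyscale with a grey palette,
  or 24-bit BGR for colour), lossless; used wherever pixel-exact round trips
  matter.
* ``"MJPG"`` — Motion-JPEG, each frame an independent JPEG (encoded and
  decoded through Pillow), the codec used for saved overlay videos.

The container layer is self-contained because no pre-installed package
handles AVI without an external ffmpeg binary.  The writer emits a standard
single-stream AVI with an ``idx1`` index; the reader walks the RIFF chunk
tree and accepts files from this writer as well as other single-video-stream
AVIs using the same codecs.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path

import numpy as np
from PIL import Image

_AVIIF_KEYFRAME = 0x10
_GREY_WEIGHTS = np.array([0.299, 0.587, 0.114])  # Rec.601 luma


class VideoFormatError(ValueError):
    """Raised for files this reader cannot interpret."""


def _fourcc(tag: bytes) -> int:
    return struct.unpack("<I", tag)[0]


class AviWriter:
    """Streaming AVI writer; frames are uint8 ``(H, W)`` grey or ``(H, W, 3)`` RGB."""

    def __init__(self, path, fps: float, frame_shape, codec: str = "MJPG",
                 jpeg_quality: int = 95):
        if codec not in ("MJPG", "raw"):
            raise ValueError(f"unsupported codec {codec!r} (use 'MJPG' or 'raw')")
        self.path = Path(path)
        self.fps = float(fps)
        if len(frame_shape) == 2:
            self.height, self.width = frame_shape
            self.color = False
        elif len(frame_shape) == 3 and frame_shape[2] == 3:
            self.height, self.width = frame_shape[:2]
            self.color = True
        else:
            raise ValueError(f"unsupported frame shape {frame_shape}")
        self.codec = codec
        self.jpeg_quality = jpeg_quality
        self._chunks: list[bytes] = []
        self._closed = False

    def add(self, frame: np.ndarray) -> None:
        frame = np.asarray(frame)
        if frame.dtype != np.uint8:
            raise ValueError("frames must be uint8")
        expected = (self.height, self.width, 3) if self.color else (self.height, self.width)
        if frame.shape != expected:
            raise ValueError(f"frame shape {frame.shape} != {expected}")
        if self.codec == "MJPG":
            img = Image.fromarray(frame, mode="RGB" if self.color else "L")
            buf = io.BytesIO()
            img.save(buf, format="JPEG", quality=self.jpeg_quality)
            self._chunks.append(buf.getvalue())
        else:
            # bottom-up rows, 4-byte aligned
            if self.color:
                data = frame[::-1, :, ::-1]  # RGB -> BGR
                row_bytes = self.width * 3
            else:
                data = frame[::-1]
                row_bytes = self.width
            pad = (-row_bytes) % 4
            if pad:
                data = np.pad(data.reshape(self.height, -1), ((0, 0), (0, pad)))
            self._chunks.append(data.tobytes())

    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        n = len(self._chunks)
        bits = 24 if (self.color or self.codec == "MJPG") else 8
        compression = _fourcc(b"MJPG") if self.codec == "MJPG" else 0
        palette = b""
        clr_used = 0
        if self.codec == "raw" and not self.color:
            palette = b"".join(struct.pack("<BBBB", g, g, g, 0) for g in range(256))
            clr_used = 256
        strf = struct.pack(
            "<IiihhIIiiII", 40 + len(palette), self.width, self.height, 1, bits,
            compression, self.width * self.height * bits // 8, 0, 0, clr_used, 0,
        ) + palette
        scale, rate = 1000, int(round(self.fps * 1000))
        max_chunk = max((len(c) for c in self._chunks), default=0)
        strh = struct.pack(
            "<4s4sIHHIIIIIIIi4H",
            b"vids", b"MJPG" if self.codec == "MJPG" else b"DIB ",
            0, 0, 0, 0, scale, rate, 0, n, max_chunk, -1 & 0xFFFFFFFF, 0,
            0, 0, self.width, self.height,
        )
        strl = _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf))
        avih = struct.pack(
            "<14I", int(round(1e6 / self.fps)), 0, 0, 0x10, n, 0, 1, max_chunk,
            self.width, self.height, 0, 0, 0, 0,
        )
        hdrl = _list(b"hdrl", _chunk(b"avih", avih) + strl)
        ckid = b"00dc" if self.codec == "MJPG" else b"00db"
        movi_body = b"movi"
        index = b""
        for data in self._chunks:
            offset = len(movi_body)
            movi_body += _chunk(ckid, data)
            index += struct.pack("<4sIII", ckid, _AVIIF_KEYFRAME, offset, len(data))
        movi = _chunk(b"LIST", movi_body)
        idx1 = _chunk(b"idx1", index)
        riff_body = b"AVI " + hdrl + movi + idx1
        self.path.write_bytes(_chunk(b"RIFF", riff_body))

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _chunk(ckid: bytes, data: bytes) -> bytes:
    out = ckid + struct.pack("<I", len(data)) + data
    if len(data) % 2:
        out += b"\x00"
    return out


def _list(list_type: bytes, body: bytes) -> bytes:
    return _chunk(b"LIST", list_type + body)


def write_video(path, frames, fps: float, codec: str = "MJPG") -> Path:
    """Write an iterable of uint8 frames as an AVI file."""
    frames = iter(frames)
    try:
        first = next(frames)
    except StopIteration:
        raise ValueError("cannot write a video with zero frames") from None
    first = np.asarray(first)
    with AviWriter(path, fps, first.shape, codec=codec) as writer:
        writer.add(first)
        for frame in frames:
            writer.add(np.asarray(frame))
    return Path(path)


def _walk_chunks(data: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        ckid = data[pos:pos + 4]
        (size,) = struct.unpack("<I", data[pos + 4:pos + 8])
        body = (pos + 8, pos + 8 + size)
        yield ckid, body
        pos = pos + 8 + size + (size % 2)


class VideoReader:
    """Decode a single-stream AVI into uint8 frames.

    Attributes ``fps``, ``width``, ``height``, ``n_frames`` are read from the
    headers; iterate the object (or call :meth:`read_all`) for frames.
    Greyscale content yields ``(H, W)`` arrays, colour yields ``(H, W, 3)``
    RGB.
    """

    def __init__(self, path):
        self.path = Path(path)
        data = self.path.read_bytes()
        if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
            raise VideoFormatError(f"not an AVI file: {self.path}")
        self._frame_chunks: list[tuple[int, int]] = []
        self._strh = None
        self._strf = None
        self._data = data
        self._parse_list(12, len(data))
        if self._strh is None or self._strf is None:
            raise VideoFormatError(f"no video stream headers in {self.path}")
        scale, rate = struct.unpack("<II", self._strh[20:28])
        self.fps = rate / scale if scale else 0.0
        (self._bits,) = struct.unpack("<h", self._strf[14:16])
        (self._compression,) = struct.unpack("<I", self._strf[16:20])
        self.width, self.height = struct.unpack("<ii", self._strf[4:12])
        self.height = abs(self.height)
        if self._compression not in (0, _fourcc(b"MJPG")):
            raise VideoFormatError(
                f"unsupported codec in {self.path} "
                f"(only raw DIB and MJPG are readable)"
            )
        self.n_frames = len(self._frame_chunks)

    def _parse_list(self, start: int, end: int) -> None:
        for ckid, (b0, b1) in _walk_chunks(self._data, start, end):
            if ckid == b"LIST":
                list_type = self._data[b0:b0 + 4]
                if list_type in (b"hdrl", b"strl", b"movi", b"rec "):
                    self._parse_list(b0 + 4, b1)
            elif ckid == b"strh" and self._strh is None:
                if self._data[b0:b0 + 4] == b"vids":
                    self._strh = self._data[b0:b1]
                    self._expect_strf = True
            elif ckid == b"strf" and self._strf is None and getattr(self, "_expect_strf", False):
                self._strf = self._data[b0:b1]
                self._expect_strf = False
            elif ckid[2:4] in (b"db", b"dc") and ckid[:2] == b"00":
                self._frame_chunks.append((b0, b1))

    def _decode(self, raw: bytes) -> np.ndarray:
        if self._compression == _fourcc(b"MJPG"):
            img = Image.open(io.BytesIO(raw))
            if img.mode == "L":
                return np.asarray(img)
            arr = np.asarray(img.convert("RGB"))
            if np.ptp(arr, axis=2).max() == 0:  # grey stored as colour JPEG
                return arr[:, :, 0].copy()
            return arr
        if self._bits == 8:
            row = self.width + ((-self.width) % 4)
            arr = np.frombuffer(raw, dtype=np.uint8, count=row * self.height)
            arr = arr.reshape(self.height, row)[::-1, :self.width]
            palette_raw = self._strf[40:]
            if len(palette_raw) >= 1024:
                pal = np.frombuffer(palette_raw[:1024], dtype=np.uint8).reshape(256, 4)
                if not (pal[:, 0] == np.arange(256)).all():
                    arr = pal[arr, 0]
            return np.ascontiguousarray(arr)
        if self._bits == 24:
            row = self.width * 3 + ((-self.width * 3) % 4)
            arr = np.frombuffer(raw, dtype=np.uint8, count=row * self.height)
            arr = arr.reshape(self.height, row)[::-1, :self.width * 3]
            bgr = arr.reshape(self.height, self.width, 3)
            rgb = bgr[:, :, ::-1]
            if np.ptp(rgb, axis=2).max() == 0:
                return np.ascontiguousarray(rgb[:, :, 0])
            return np.ascontiguousarray(rgb)
        raise VideoFormatError(f"unsupported bit depth {self._bits}")

    def __iter__(self):
        for b0, b1 in self._frame_chunks:
            yield self._decode(self._data[b0:b1])

    def __len__(self) -> int:
        return self.n_frames

    def read_all(self) -> list[np.ndarray]:
        return list(self)


def read_video(path) -> tuple[list[np.ndarray], float]:
    """Read all frames of an AVI file; returns ``(frames, fps)``."""
    reader = VideoReader(path)
    return reader.read_all(), reader.fps


def to_grey(frame: np.ndarray) -> np.ndarray:
    """Collapse a colour frame to 8-bit luminance; greyscale passes through."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        return np.rint(frame @ _GREY_WEIGHTS).clip(0, 255).astype(np.uint8)
    raise VideoFormatError(f"unsupported frame shape {frame.shape}")
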