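"""Sample-synchronous multichannel audio container and WAV/FLAC file I/O.

Audio is carried as integer ADC counts (never floats) so that file
round-trips can be checked bit-exactly, mirroring how the logger itself
stores converter output.  All channels share one sample clock by
construction — the container cannot represent channel skew, matching the
hardware's sub-sample synchronization guarantee.
"""

from __future__ import annotations

import struct
import wave
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["MultichannelAudio", "AudioFormatError", "read_audio", "write_audio"]


class AudioFormatError(ValueError):
    """Unsupported or malformed audio file."""


@dataclass
class MultichannelAudio:
    """Integer-count audio, shape (n_channels, n_frames), with chain metadata."""

    samples: np.ndarray
    sample_rate_sps: float
    bit_depth: int = 16
    sensitivity_db_re_fs_per_upa: float = -205.0
    start_epoch_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        if not np.issubdtype(self.samples.dtype, np.integer):
            raise AudioFormatError("samples must be integer counts")
        self.samples = self.samples.astype(np.int32, copy=False)
        if self.bit_depth not in (16, 24):
            raise AudioFormatError(f"bit depth must be 16 or 24, got {self.bit_depth}")
        lim = 2 ** (self.bit_depth - 1)
        if self.samples.size and (self.samples.max() >= lim or self.samples.min() < -lim):
            raise AudioFormatError(f"counts exceed the {self.bit_depth}-bit range")
        if self.sample_rate_sps <= 0:
            raise AudioFormatError("sample rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_frames(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_sps

    def slice_frames(self, start: int, stop: int) -> "MultichannelAudio":
        out = replace(self, samples=self.samples[:, start:stop].copy())
        out.start_epoch_s = self.start_epoch_s + start / self.sample_rate_sps
        return out


def _pack_counts(samples: np.ndarray, bit_depth: int) -> bytes:
    """Interleave (channels, frames) int32 counts into little-endian PCM bytes."""
    interleaved = np.ascontiguousarray(samples.T.reshape(-1)).astype("<i4")
    if bit_depth == 16:
        return interleaved.astype("<i2").tobytes()
    raw = interleaved.view(np.uint8).reshape(-1, 4)
    return np.ascontiguousarray(raw[:, :3]).tobytes()


def _unpack_counts(data: bytes, bit_depth: int, n_channels: int) -> np.ndarray:
    if bit_depth == 16:
        flat = np.frombuffer(data, dtype="<i2").astype(np.int32)
    else:
        b = np.frombuffer(data, dtype=np.uint8).reshape(-1, 3)
        flat = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int8).astype(np.int32) << 16)
        )
    if flat.size % n_channels:
        raise AudioFormatError("PCM payload is not a whole number of frames")
    return flat.reshape(-1, n_channels).T.copy()


def write_audio(audio: MultichannelAudio, path: str | Path, fmt: str | None = None) -> Path:
    """Write audio as WAV or FLAC (inferred from the extension when ``fmt``
    is None).  Both are lossless: a read-back reproduces counts bit-exactly."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "wav":
        with wave.open(str(path), "wb") as w:
            w.setnchannels(audio.n_channels)
            w.setsampwidth(audio.bit_depth // 8)
            w.setframerate(int(round(audio.sample_rate_sps)))
            w.writeframes(_pack_counts(audio.samples, audio.bit_depth))
        return path
    if fmt == "flac":
        from . import flacio

        flacio.write_flac(path, audio.samples, int(round(audio.sample_rate_sps)), audio.bit_depth)
        return path
    raise AudioFormatError(f"unsupported audio format {fmt!r} (WAV and FLAC are supported)")


def read_audio(
    path: str | Path,
    sensitivity_db_re_fs_per_upa: float = -205.0,
    start_epoch_s: float = 0.0,
) -> MultichannelAudio:
    """Read a WAV or FLAC file into a `MultichannelAudio` of integer counts."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"fLaC":
        from . import flacio

        samples, rate, bits = flacio.read_flac(path)
        return MultichannelAudio(samples, rate, bits, sensitivity_db_re_fs_per_upa, start_epoch_s)
    if magic == b"RIFF":
        try:
            with wave.open(str(path), "rb") as w:
                n_channels = w.getnchannels()
                width = w.getsampwidth()
                rate = w.getframerate()
                n_frames = w.getnframes()
                data = w.readframes(n_frames)
        except (wave.Error, EOFError, struct.error) as exc:
            raise AudioFormatError(f"cannot parse WAV {path} (size {path.stat().st_size} bytes): {exc}") from exc
        if width not in (2, 3):
            raise AudioFormatError(f"unsupported WAV sample width {width * 8} bits")
        expected = n_frames * n_channels * width
        if len(data) < expected:
            raise AudioFormatError(
                f"truncated WAV {path}: payload ends at byte {len(data)} of {expected}"
            )
        samples = _unpack_counts(data, width * 8, n_channels)
        return MultichannelAudio(samples, rate, width * 8, sensitivity_db_re_fs_per_upa, start_epoch_s)
    raise AudioFormatError(f"{path} is neither WAV nor FLAC (magic {magic!r})")
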