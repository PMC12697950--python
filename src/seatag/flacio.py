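"""Compact FLAC codec for lossless on-disk audio (16/24-bit PCM).

Implements the subset of the FLAC stream format (RFC 9639) that the logger
toolkit needs: independent channels, fixed-order linear predictors (orders
0–4) with Rice-coded residuals, plus constant and verbatim subframes as
fallbacks.  The encoder chooses per-subframe whichever of these is smallest,
which compresses smooth synthetic waveforms well while remaining strictly
lossless for arbitrary integer input.  Streams carry the standard integrity
metadata — CRC-8 frame headers, CRC-16 frame footers, and an MD5 signature
of the raw interleaved samples in STREAMINFO — all of which the decoder
verifies, so a successful read certifies bit-exactness end to end.

Not implemented (and rejected on read where distinguishable): stereo
decorrelation modes, arbitrary-order LPC subframes, and metadata blocks
other than STREAMINFO (others are skipped).
"""

from __future__ import annotations

import hashlib
import struct
from pathlib import Path

import numpy as np
from numba import njit

__all__ = ["FlacError", "write_flac", "read_flac"]

_BLOCKSIZE = 4096
_BPS_CODE = {16: 0b100, 24: 0b110}
_CODE_BPS = {v: k for k, v in _BPS_CODE.items()}


class FlacError(ValueError):
    """Malformed, unsupported, or corrupt FLAC stream."""


# ---------------------------------------------------------------------------
# CRC tables (CRC-8 poly 0x07, CRC-16 poly 0x8005, both init 0)

def _make_crc_table(poly: int, width: int) -> np.ndarray:
    top = 1 << (width - 1)
    mask = (1 << width) - 1
    table = np.empty(256, dtype=np.uint32)
    for byte in range(256):
        crc = byte << (width - 8)
        for _ in range(8):
            crc = ((crc << 1) ^ poly) & mask if crc & top else (crc << 1) & mask
        table[byte] = crc
    return table


_CRC8_TABLE = _make_crc_table(0x07, 8)
_CRC16_TABLE = _make_crc_table(0x8005, 16)


@njit(cache=False)
def _crc_kernel(data, table, width):
    crc = 0
    mask = (1 << width) - 1
    for i in range(data.size):
        idx = ((crc >> (width - 8)) ^ data[i]) & 0xFF
        crc = ((crc << 8) & mask) ^ table[idx]
    return crc


def _crc8(data: bytes) -> int:
    return int(_crc_kernel(np.frombuffer(data, dtype=np.uint8), _CRC8_TABLE, 8))


def _crc16(data: bytes) -> int:
    return int(_crc_kernel(np.frombuffer(data, dtype=np.uint8), _CRC16_TABLE, 16))


# ---------------------------------------------------------------------------
# Bit-level helpers

class _BitWriter:
    def __init__(self) -> None:
        self._parts: list[np.ndarray] = []
        self.n_bits = 0

    def write_uint(self, value: int, nbits: int) -> None:
        bits = (value >> np.arange(nbits - 1, -1, -1)) & 1
        self._parts.append(bits.astype(np.uint8))
        self.n_bits += nbits

    def write_signed(self, value: int, nbits: int) -> None:
        self.write_uint(int(value) & ((1 << nbits) - 1), nbits)

    def write_signed_array(self, values: np.ndarray, nbits: int) -> None:
        masked = values.astype(np.int64) & ((1 << nbits) - 1)
        shifts = np.arange(nbits - 1, -1, -1)
        bits = ((masked[:, None] >> shifts) & 1).astype(np.uint8).ravel()
        self._parts.append(bits)
        self.n_bits += bits.size

    def write_bits(self, bits: np.ndarray) -> None:
        self._parts.append(bits)
        self.n_bits += bits.size

    def align(self) -> None:
        pad = (-self.n_bits) % 8
        if pad:
            self.write_uint(0, pad)

    def to_bytes(self) -> bytes:
        if self.n_bits % 8:
            raise FlacError("bit stream not byte-aligned")
        if not self._parts:
            return b""
        return np.packbits(np.concatenate(self._parts)).tobytes()


@njit(cache=False)
def _rice_encode_bits(u, k):
    total = 0
    for i in range(u.size):
        total += (u[i] >> k) + 1 + k
    out = np.zeros(total, dtype=np.uint8)
    pos = 0
    for i in range(u.size):
        q = u[i] >> k
        pos += q
        out[pos] = 1
        pos += 1
        for b in range(k - 1, -1, -1):
            out[pos] = (u[i] >> b) & 1
            pos += 1
    return out


@njit(cache=False)
def _rice_decode_bits(bits, start, n, k):
    out = np.empty(n, dtype=np.int64)
    pos = start
    for i in range(n):
        q = 0
        while bits[pos] == 0:
            q += 1
            pos += 1
        pos += 1
        low = 0
        for _ in range(k):
            low = (low << 1) | bits[pos]
            pos += 1
        u = (q << k) | low
        out[i] = (u >> 1) ^ -(u & 1)
    return out, pos


@njit(cache=False)
def _fixed_restore(warmup, residual, order):
    n = warmup.size + residual.size
    x = np.empty(n, dtype=np.int64)
    for i in range(warmup.size):
        x[i] = warmup[i]
    if order == 0:
        for i in range(residual.size):
            x[i] = residual[i]
    elif order == 1:
        for i in range(1, n):
            x[i] = residual[i - 1] + x[i - 1]
    elif order == 2:
        for i in range(2, n):
            x[i] = residual[i - 2] + 2 * x[i - 1] - x[i - 2]
    elif order == 3:
        for i in range(3, n):
            x[i] = residual[i - 3] + 3 * x[i - 1] - 3 * x[i - 2] + x[i - 3]
    else:
        for i in range(4, n):
            x[i] = residual[i - 4] + 4 * x[i - 1] - 6 * x[i - 2] + 4 * x[i - 3] - x[i - 4]
    return x


def _zigzag(r: np.ndarray) -> np.ndarray:
    r = r.astype(np.int64)
    return ((r << 1) ^ (r >> 63)).view(np.uint64)


def _utf8_code(value: int) -> bytes:
    """UTF-8-style coded frame number used in frame headers."""
    if value < 0x80:
        return bytes([value])
    for n_cont, prefix in ((1, 0xC0), (2, 0xE0), (3, 0xF0), (4, 0xF8), (5, 0xFC)):
        if value < 1 << (6 * n_cont + (6 - n_cont)):
            out = [prefix | (value >> (6 * n_cont))]
            for i in range(n_cont - 1, -1, -1):
                out.append(0x80 | ((value >> (6 * i)) & 0x3F))
            return bytes(out)
    raise FlacError("frame number too large to code")


# ---------------------------------------------------------------------------
# Encoder

def _best_rice_k(u: np.ndarray) -> tuple[int, int]:
    """(k, total_bits) minimizing the Rice cost for folded residuals."""
    best_k, best_cost = 0, None
    for k in range(31):
        cost = int(np.sum(u >> np.uint64(k))) + u.size * (k + 1)
        if best_cost is None or cost < best_cost:
            best_k, best_cost = k, cost
    return best_k, best_cost


def _encode_subframe(bw: _BitWriter, x: np.ndarray, bps: int) -> None:
    bs = x.size
    if np.all(x == x[0]):
        bw.write_uint(0, 1)
        bw.write_uint(0b000000, 6)
        bw.write_uint(0, 1)
        bw.write_signed(int(x[0]), bps)
        return

    best = None  # (total_bits, order, k, u)
    for order in range(0, min(4, bs - 1) + 1):
        res = np.diff(x, n=order) if order else x
        u = _zigzag(res)
        k, rice_bits = _best_rice_k(u)
        total = order * bps + 2 + 4 + (5 if k > 14 else 4) + rice_bits
        if best is None or total < best[0]:
            best = (total, order, k, u)

    if best[0] >= bs * bps:  # verbatim is cheaper (incompressible block)
        bw.write_uint(0, 1)
        bw.write_uint(0b000001, 6)
        bw.write_uint(0, 1)
        bw.write_signed_array(x, bps)
        return

    _, order, k, u = best
    bw.write_uint(0, 1)
    bw.write_uint(0b001000 | order, 6)
    bw.write_uint(0, 1)
    if order:
        bw.write_signed_array(x[:order], bps)
    method = 0b01 if k > 14 else 0b00
    bw.write_uint(method, 2)
    bw.write_uint(0, 4)  # partition order 0
    bw.write_uint(k, 5 if method else 4)
    bw.write_bits(_rice_encode_bits(u, k))


def _encode_frame(frame_idx: int, block: np.ndarray, bps: int) -> bytes:
    n_channels, bs = block.shape
    bw = _BitWriter()
    bw.write_uint(0b11111111111110, 14)
    bw.write_uint(0, 1)  # reserved
    bw.write_uint(0, 1)  # fixed blocking strategy
    bw.write_uint(0b0111, 4)  # 16-bit blocksize field follows
    bw.write_uint(0b0000, 4)  # sample rate from STREAMINFO
    bw.write_uint(n_channels - 1, 4)
    bw.write_uint(_BPS_CODE[bps], 3)
    bw.write_uint(0, 1)  # reserved
    for byte in _utf8_code(frame_idx):
        bw.write_uint(byte, 8)
    bw.write_uint(bs - 1, 16)
    bw.write_uint(_crc8(bw.to_bytes()), 8)
    for ch in range(n_channels):
        _encode_subframe(bw, block[ch].astype(np.int64), bps)
    bw.align()
    body = bw.to_bytes()
    return body + struct.pack(">H", _crc16(body))


def write_flac(path: str | Path, samples: np.ndarray, sample_rate: int, bit_depth: int) -> Path:
    """Encode (channels, frames) integer counts to a FLAC file."""
    samples = np.atleast_2d(np.asarray(samples))
    n_channels, n_frames = samples.shape
    if bit_depth not in _BPS_CODE:
        raise FlacError(f"bit depth must be 16 or 24, got {bit_depth}")
    if not 1 <= n_channels <= 8:
        raise FlacError("FLAC supports 1-8 channels")
    if n_frames == 0:
        raise FlacError("cannot encode empty audio")
    lim = 1 << (bit_depth - 1)
    if samples.max() >= lim or samples.min() < -lim:
        raise FlacError(f"samples exceed the {bit_depth}-bit range")

    md5 = hashlib.md5(_interleave_bytes(samples, bit_depth)).digest()
    blocksize = min(_BLOCKSIZE, n_frames)

    info = _BitWriter()
    info.write_uint(blocksize, 16)
    info.write_uint(blocksize, 16)
    info.write_uint(0, 24)  # min frame size unknown
    info.write_uint(0, 24)
    info.write_uint(sample_rate, 20)
    info.write_uint(n_channels - 1, 3)
    info.write_uint(bit_depth - 1, 5)
    info.write_uint(n_frames, 36)
    streaminfo = info.to_bytes() + md5

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(b"fLaC")
        fh.write(bytes([0x80]))  # last metadata block, type 0 (STREAMINFO)
        fh.write(len(streaminfo).to_bytes(3, "big"))
        fh.write(streaminfo)
        for idx, start in enumerate(range(0, n_frames, blocksize)):
            fh.write(_encode_frame(idx, samples[:, start : start + blocksize], bit_depth))
    return path


def _interleave_bytes(samples: np.ndarray, bit_depth: int) -> bytes:
    flat = np.ascontiguousarray(samples.T.reshape(-1)).astype("<i4")
    if bit_depth == 16:
        return flat.astype("<i2").tobytes()
    raw = flat.view(np.uint8).reshape(-1, 4)
    return np.ascontiguousarray(raw[:, :3]).tobytes()


# ---------------------------------------------------------------------------
# Decoder

class _BitReader:
    def __init__(self, bits: np.ndarray, pos: int = 0) -> None:
        self.bits = bits
        self.pos = pos

    def read_uint(self, nbits: int) -> int:
        if self.pos + nbits > self.bits.size:
            raise FlacError("unexpected end of stream")
        chunk = self.bits[self.pos : self.pos + nbits]
        self.pos += nbits
        value = 0
        for b in chunk:
            value = (value << 1) | int(b)
        return value

    def read_signed(self, nbits: int) -> int:
        v = self.read_uint(nbits)
        return v - (1 << nbits) if v >= 1 << (nbits - 1) else v

    def read_signed_array(self, n: int, nbits: int) -> np.ndarray:
        if self.pos + n * nbits > self.bits.size:
            raise FlacError("unexpected end of stream")
        chunk = self.bits[self.pos : self.pos + n * nbits].reshape(n, nbits)
        self.pos += n * nbits
        powers = (1 << np.arange(nbits - 1, -1, -1)).astype(np.int64)
        vals = chunk.astype(np.int64) @ powers
        vals[vals >= 1 << (nbits - 1)] -= 1 << nbits
        return vals

    def read_unary(self) -> int:
        q = 0
        while self.bits[self.pos] == 0:
            q += 1
            self.pos += 1
        self.pos += 1
        return q


def _decode_residual(br: _BitReader, bs: int, order: int) -> np.ndarray:
    method = br.read_uint(2)
    if method not in (0, 1):
        raise FlacError(f"reserved residual coding method {method}")
    porder = br.read_uint(4)
    n_partitions = 1 << porder
    if bs % n_partitions:
        raise FlacError("block size not divisible by partition count")
    param_bits = 5 if method else 4
    escape = (1 << param_bits) - 1
    parts = []
    for p in range(n_partitions):
        n = bs // n_partitions - (order if p == 0 else 0)
        k = br.read_uint(param_bits)
        if k == escape:
            width = br.read_uint(5)
            parts.append(
                br.read_signed_array(n, width) if width else np.zeros(n, dtype=np.int64)
            )
        else:
            out, newpos = _rice_decode_bits(br.bits, br.pos, n, k)
            br.pos = newpos
            parts.append(out)
    return np.concatenate(parts) if len(parts) > 1 else parts[0]


def _decode_subframe(br: _BitReader, bs: int, bps: int) -> np.ndarray:
    if br.read_uint(1) != 0:
        raise FlacError("invalid subframe header padding bit")
    ftype = br.read_uint(6)
    wasted = 0
    if br.read_uint(1):
        wasted = br.read_unary() + 1
        bps -= wasted
    if ftype == 0b000000:
        x = np.full(bs, br.read_signed(bps), dtype=np.int64)
    elif ftype == 0b000001:
        x = br.read_signed_array(bs, bps)
    elif 0b001000 <= ftype <= 0b001100:
        order = ftype & 0b000111
        warmup = br.read_signed_array(order, bps) if order else np.empty(0, dtype=np.int64)
        residual = _decode_residual(br, bs, order)
        x = _fixed_restore(warmup, residual, order)
    elif ftype & 0b100000:
        raise FlacError("LPC subframes are not supported by this decoder")
    else:
        raise FlacError(f"reserved subframe type {ftype:06b}")
    return x << wasted if wasted else x


def read_flac(path: str | Path) -> tuple[np.ndarray, int, int]:
    """Decode a FLAC file to ((channels, frames) int32 counts, rate, bits).

    Verifies the per-frame CRC-16 and the stream MD5 signature; a mismatch
    raises `FlacError` rather than returning corrupt audio.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"fLaC":
        raise FlacError("missing fLaC stream marker")
    pos = 4
    streaminfo = None
    while True:
        if pos + 4 > len(data):
            raise FlacError(f"truncated metadata at byte {pos}")
        header = data[pos]
        length = int.from_bytes(data[pos + 1 : pos + 4], "big")
        block = data[pos + 4 : pos + 4 + length]
        if len(block) < length:
            raise FlacError(f"truncated metadata block at byte {pos}")
        if header & 0x7F == 0:
            streaminfo = block
        pos += 4 + length
        if header & 0x80:
            break
    if streaminfo is None or len(streaminfo) != 34:
        raise FlacError("missing or malformed STREAMINFO")

    fields = int.from_bytes(streaminfo[:18], "big")
    sample_rate = (fields >> (144 - 80 - 20)) & 0xFFFFF
    n_channels = ((fields >> (144 - 100 - 3)) & 0x7) + 1
    bps = ((fields >> (144 - 103 - 5)) & 0x1F) + 1
    total_samples = fields & ((1 << 36) - 1)
    md5_expected = streaminfo[18:34]
    if bps not in _BPS_CODE:
        raise FlacError(f"unsupported bit depth {bps}")

    bits = np.unpackbits(np.frombuffer(data[pos:], dtype=np.uint8))
    br = _BitReader(bits)
    channels: list[list[np.ndarray]] = [[] for _ in range(n_channels)]
    collected = 0
    while collected < total_samples:
        frame_start_byte = br.pos // 8
        if br.read_uint(14) != 0b11111111111110:
            raise FlacError(f"lost frame sync at byte {pos + frame_start_byte}")
        br.read_uint(1)  # reserved
        br.read_uint(1)  # blocking strategy
        bs_code = br.read_uint(4)
        sr_code = br.read_uint(4)
        ch_code = br.read_uint(4)
        size_code = br.read_uint(3)
        br.read_uint(1)  # reserved
        if ch_code > 7:
            raise FlacError("stereo-decorrelated channel modes are not supported")
        # coded frame/sample number: skip by UTF-8-style length
        lead = br.read_uint(8)
        n_cont = 0
        while lead & (0x80 >> n_cont) and n_cont < 7:
            n_cont += 1
        for _ in range(max(0, n_cont - 1)):
            br.read_uint(8)
        if bs_code == 0b0110:
            bs = br.read_uint(8) + 1
        elif bs_code == 0b0111:
            bs = br.read_uint(16) + 1
        elif bs_code == 0b0001:
            bs = 192
        elif 0b0010 <= bs_code <= 0b0101:
            bs = 576 << (bs_code - 2)
        elif bs_code >= 0b1000:
            bs = 256 << (bs_code - 8)
        else:
            raise FlacError(f"reserved block size code {bs_code:04b}")
        if sr_code == 0b1100:
            br.read_uint(8)
        elif sr_code in (0b1101, 0b1110):
            br.read_uint(16)
        header_crc = br.read_uint(8)
        header_bytes = data[pos + frame_start_byte : pos + br.pos // 8 - 1]
        if _crc8(header_bytes) != header_crc:
            raise FlacError(f"frame header CRC-8 mismatch at byte {pos + frame_start_byte}")
        frame_bps = _CODE_BPS.get(size_code, bps)
        for ch in range(ch_code + 1):
            channels[ch].append(_decode_subframe(br, bs, frame_bps))
        br.pos += (-br.pos) % 8
        frame_bytes = data[pos + frame_start_byte : pos + br.pos // 8]
        if _crc16(frame_bytes) != br.read_uint(16):
            raise FlacError(f"frame CRC-16 mismatch at byte {pos + frame_start_byte}")
        collected += bs

    samples = np.vstack([np.concatenate(c)[:total_samples] for c in channels]).astype(np.int32)
    if hashlib.md5(_interleave_bytes(samples, bps)).digest() != md5_expected:
        raise FlacError("stream MD5 mismatch: decoded audio differs from encoded audio")
    return samples, sample_rate, bps
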