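"""Deployment bundle layout, sensor CSV round-tripping, and validation.

A bundle is a directory standing in for one deployment:

    manifest.json        device id, start epoch, chain spec, geometry,
                         file inventory
    audio/seg_NNN.wav    contiguous audio segments (five-minute convention)
    sensors/<name>.csv   timestamped sensor streams (RFC-4180, header row)
    events.csv           mission event log
    truth.json           synthetic bundles only: generator ground truth

Timestamps are epoch seconds written as decimal text with six fractional
digits (microsecond precision, lossless for ~1 s cross-platform alignment);
other values carry nine fractional digits.  All writes are deterministic so
a bundle regenerates byte-identically from the same seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .aoa import ArrayGeometry
from .audio import MultichannelAudio, read_audio, write_audio
from .chain import AudioChainSpec

__all__ = [
    "SensorCsvError",
    "BundleError",
    "read_sensor_csv",
    "write_sensor_csv",
    "write_bundle",
    "load_manifest",
    "validate_bundle",
    "CheckResult",
]


class SensorCsvError(ValueError):
    """Malformed sensor stream file."""


class BundleError(ValueError):
    """Inconsistent bundle directory."""


def write_sensor_csv(stream: pd.DataFrame, path: str | Path) -> Path:
    """Write a timestamped stream with a fixed decimal-text format:
    epoch_s at 6 fractional digits, values at 9."""
    if "epoch_s" not in stream.columns:
        raise SensorCsvError("stream must have an epoch_s column")
    path = Path(path)
    out = pd.DataFrame()
    out["epoch_s"] = stream["epoch_s"].map(lambda v: f"{v:.6f}")
    for col in stream.columns:
        if col != "epoch_s":
            out[col] = stream[col].map(lambda v: f"{v:.9f}")
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def read_sensor_csv(path: str | Path) -> pd.DataFrame:
    """Read a sensor stream; rejects missing headers and non-monotone
    timestamps (reporting the first offending row)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SensorCsvError(f"cannot parse {path}: {exc}") from exc
    if "epoch_s" not in df.columns:
        raise SensorCsvError(f"{path} has no epoch_s column (header required)")
    epochs = df["epoch_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(epochs) < 0)
    if bad.size:
        raise SensorCsvError(
            f"{path}: non-monotone timestamp at row {int(bad[0]) + 1} "
            f"(epoch {epochs[bad[0] + 1]} after {epochs[bad[0]]})"
        )
    return df


def write_bundle(
    outdir: str | Path,
    device_id: str,
    audio: MultichannelAudio,
    streams: dict[str, pd.DataFrame],
    event_log: pd.DataFrame,
    truth: dict | None,
    chain: AudioChainSpec,
    geometry: ArrayGeometry,
    segment_s: float = 300.0,
    audio_format: str = "wav",
) -> dict:
    """Write a deployment bundle directory; returns the manifest dict."""
    outdir = Path(outdir)
    (outdir / "audio").mkdir(parents=True, exist_ok=True)
    (outdir / "sensors").mkdir(exist_ok=True)

    seg_frames = int(round(segment_s * audio.sample_rate_sps))
    segments = []
    for idx, start in enumerate(range(0, audio.n_frames, seg_frames)):
        seg = audio.slice_frames(start, min(start + seg_frames, audio.n_frames))
        name = f"audio/seg_{idx:03d}.{audio_format}"
        write_audio(seg, outdir / name, audio_format)
        segments.append(
            {"file": name, "start_epoch_s": seg.start_epoch_s, "n_frames": seg.n_frames}
        )

    sensor_files = {}
    for name, stream in streams.items():
        rel = f"sensors/{name}.csv"
        write_sensor_csv(stream, outdir / rel)
        sensor_files[name] = rel

    event_log.to_csv(outdir / "events.csv", index=False, lineterminator="\n", float_format="%.6f")

    manifest = {
        "device_id": device_id,
        "start_epoch_s": audio.start_epoch_s,
        "chain": {
            "sensitivity_db_re_fs_per_upa": chain.sensitivity_db_re_fs_per_upa,
            "bit_depth": chain.bit_depth,
            "sample_rate_sps": audio.sample_rate_sps,
            "n_channels": chain.n_channels,
        },
        "geometry": {
            "positions_m": geometry.positions.tolist(),
            "sound_speed_m_s": geometry.sound_speed_m_s,
            "sample_rate_sps": geometry.sample_rate_sps,
        },
        "segments": segments,
        "sensors": sensor_files,
        "events_file": "events.csv",
    }
    if truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        manifest["truth_file"] = "truth.json"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_manifest(bundle_dir: str | Path) -> dict:
    path = Path(bundle_dir) / "manifest.json"
    if not path.exists():
        raise BundleError(f"no manifest.json in {bundle_dir}")
    with open(path) as fh:
        return json.load(fh)


def bundle_geometry(manifest: dict) -> ArrayGeometry:
    g = manifest["geometry"]
    return ArrayGeometry(
        np.asarray(g["positions_m"]), g["sound_speed_m_s"], g["sample_rate_sps"]
    )


class CheckResult(NamedTuple):
    check: str
    ok: bool
    message: str


def validate_bundle(bundle_dir: str | Path) -> list[CheckResult]:
    """Self-check a bundle: manifest/directory consistency, readable audio,
    contiguous non-overlapping segments, monotone sensor streams."""
    bundle_dir = Path(bundle_dir)
    results: list[CheckResult] = []
    try:
        manifest = load_manifest(bundle_dir)
        results.append(CheckResult("manifest", True, "manifest.json parsed"))
    except (BundleError, json.JSONDecodeError) as exc:
        return [CheckResult("manifest", False, str(exc))]

    listed = [s["file"] for s in manifest.get("segments", [])]
    listed += list(manifest.get("sensors", {}).values())
    listed += [manifest.get("events_file", "")]
    if "truth_file" in manifest:
        listed.append(manifest["truth_file"])
    missing = [f for f in listed if f and not (bundle_dir / f).exists()]
    results.append(
        CheckResult(
            "files_present",
            not missing,
            "all manifest files present" if not missing else f"missing: {missing}",
        )
    )

    prev_end = None
    contiguous = True
    msg = "segments contiguous"
    for seg in manifest.get("segments", []):
        path = bundle_dir / seg["file"]
        if not path.exists():
            contiguous = False
            msg = f"segment {seg['file']} missing"
            break
        try:
            audio = read_audio(path)
        except Exception as exc:
            results.append(CheckResult("audio_readable", False, f"{seg['file']}: {exc}"))
            contiguous = False
            msg = f"unreadable segment {seg['file']}"
            break
        if audio.n_frames != seg["n_frames"]:
            contiguous = False
            msg = f"{seg['file']}: {audio.n_frames} frames, manifest says {seg['n_frames']}"
            break
        start = seg["start_epoch_s"]
        if prev_end is not None and abs(start - prev_end) > 1e-6:
            contiguous = False
            msg = f"{seg['file']} starts at {start}, previous segment ended at {prev_end}"
            break
        prev_end = start + audio.n_frames / audio.sample_rate_sps
    results.append(CheckResult("segments_contiguous", contiguous, msg))

    sensors_ok = True
    msg = "sensor streams monotone"
    for name, rel in manifest.get("sensors", {}).items():
        if not (bundle_dir / rel).exists():
            sensors_ok = False
            msg = f"{rel} missing"
            break
        try:
            read_sensor_csv(bundle_dir / rel)
        except SensorCsvError as exc:
            sensors_ok = False
            msg = str(exc)
            break
    results.append(CheckResult("sensor_streams", sensors_ok, msg))
    return results
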