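"""File formats, run manifests and serialization helpers.

Traces are flat binary (float32 or int16 with a µV scale factor) plus a
JSON sidecar; events, masks and result tables are CSV.  Field names are
fixed in ``docs/formats.md``.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .artifact import BlackoutMask
from .events import LightLog, PulseEvent, RecordingBlock
from .spikes import PSTH, SpikeEvent, UnitTemplate

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

__all__ = [
    "write_block", "read_block", "write_light", "read_light",
    "write_pulses", "read_pulses", "write_mask", "read_mask",
    "write_spikes", "read_spikes", "write_psth", "read_psth",
    "write_units", "read_units", "write_snippet_stack", "read_snippet_stack",
    "sha256_file", "write_manifest", "read_manifest",
]


def _write_trace(path: Path, data: np.ndarray, sidecar: dict,
                 dtype: str = "float32", uv_per_unit: float = 1.0):
    path = Path(path)
    data = np.asarray(data)
    if dtype == "float32":
        raw = data.astype("<f4")
    elif dtype == "int16":
        raw = np.round(data / uv_per_unit).astype("<i2")
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    raw.T.tofile(path.with_suffix(".bin"))  # sample-major on disk
    sidecar = dict(sidecar)
    sidecar.update({
        "format": "optoclean-trace",
        "version": FORMAT_VERSION,
        "dtype": dtype,
        "layout": "sample_major",
        "uv_per_unit": uv_per_unit,
        "n_channels": int(data.shape[0]),
        "n_samples": int(data.shape[1]),
    })
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _read_trace(path: Path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("format") != "optoclean-trace":
        raise ValueError(f"{path}: not an optoclean trace sidecar")
    dt = {"float32": "<f4", "int16": "<i2"}[meta["dtype"]]
    raw = np.fromfile(path.with_suffix(".bin"), dtype=dt)
    data = raw.reshape(meta["n_samples"], meta["n_channels"]).T.astype(float)
    if meta["dtype"] == "int16":
        data = data * meta["uv_per_unit"]
    return data, meta


def write_block(path, block: RecordingBlock, dtype: str = "float32",
                uv_per_unit: float = 1.0) -> None:
    _write_trace(Path(path), block.samples, {
        "kind": "recording",
        "rate_hz": block.rate,
        "channel_positions_um": block.channel_positions.tolist(),
        "shank_ids": block.shank_ids.tolist(),
    }, dtype, uv_per_unit)


def read_block(path) -> RecordingBlock:
    data, meta = _read_trace(Path(path))
    return RecordingBlock(
        samples=data,
        rate=meta["rate_hz"],
        channel_positions=np.array(meta["channel_positions_um"]),
        shank_ids=np.array(meta["shank_ids"]),
    )


def write_light(path, light: LightLog) -> None:
    _write_trace(Path(path), light.intensity, {
        "kind": "light",
        "rate_hz": light.rate,
        "fiber_ids": light.fiber_ids.tolist(),
    })


def read_light(path) -> LightLog:
    data, meta = _read_trace(Path(path))
    return LightLog(intensity=data, fiber_ids=np.array(meta["fiber_ids"]),
                    rate=meta["rate_hz"])


def write_pulses(path, pulses) -> None:
    pd.DataFrame([
        {
            "fiber_id": p.fiber_id,
            "shank_id": -1 if p.shank_id is None else p.shank_id,
            "onset_sample": p.onset_sample,
            "offset_sample": p.offset_sample,
            "intensity_summary": p.intensity_summary,
        }
        for p in pulses
    ]).to_csv(path, index=False)


def read_pulses(path) -> list:
    df = pd.read_csv(path)
    return [
        PulseEvent(
            int(r.onset_sample), int(r.offset_sample), int(r.fiber_id),
            float(r.intensity_summary),
            None if int(r.shank_id) < 0 else int(r.shank_id),
        )
        for r in df.itertuples()
    ]


def write_mask(path, mask: BlackoutMask) -> None:
    rows = [
        {"snippet_id": s, "channel": c, "start_sample": a, "end_sample": b}
        for s in range(mask.n_snippets)
        for c in range(mask.n_channels)
        for a, b in mask.intervals(s, c)
    ]
    pd.DataFrame(rows, columns=["snippet_id", "channel", "start_sample",
                                "end_sample"]).to_csv(path, index=False)


def read_mask(path, n_snippets: int, n_channels: int, snippet_lengths) -> BlackoutMask:
    mask = BlackoutMask(n_snippets, n_channels, snippet_lengths)
    df = pd.read_csv(path)
    for r in df.itertuples():
        mask.add(int(r.snippet_id), int(r.channel), int(r.start_sample),
                 int(r.end_sample))
    return mask


def write_spikes(path, events) -> None:
    pd.DataFrame([
        {
            "snippet_id": e.snippet_index,
            "time_sample": e.time_sample,
            "block_sample": e.block_sample,
            "unit_id": e.unit_id,
            "channel": e.channel,
            "error": e.error,
            "valid": int(e.valid),
        }
        for e in events
    ], columns=["snippet_id", "time_sample", "block_sample", "unit_id",
                "channel", "error", "valid"]).to_csv(path, index=False)


def read_spikes(path) -> list:
    df = pd.read_csv(path)
    return [
        SpikeEvent(int(r.snippet_id), int(r.time_sample), int(r.block_sample),
                   int(r.unit_id), float(r.error), bool(r.valid), int(r.channel))
        for r in df.itertuples()
    ]


def write_psth(path, psth: PSTH) -> None:
    pd.DataFrame({
        "bin_start_ms": psth.bin_edges_ms[:-1],
        "bin_end_ms": psth.bin_edges_ms[1:],
        "rate_hz": psth.rate_hz,
        "pct_masked_trials": psth.pct_masked_trials,
    }).to_csv(path, index=False)


def read_psth(path) -> PSTH:
    df = pd.read_csv(path)
    edges = np.concatenate([df.bin_start_ms.values, [df.bin_end_ms.values[-1]]])
    return PSTH(edges, df.rate_hz.values, df.pct_masked_trials.values, n_trials=-1)


def write_units(path, units) -> None:
    path = Path(path)
    if units:
        stack = np.stack([u.waveform for u in units]).astype("<f4")
    else:
        stack = np.zeros((0, 0, 60), dtype="<f4")
    stack.tofile(path.with_suffix(".bin"))
    path.with_suffix(".json").write_text(json.dumps({
        "format": "optoclean-units",
        "version": FORMAT_VERSION,
        "n_units": len(units),
        "n_channels": int(stack.shape[1]) if len(units) else 0,
        "n_samples": 60,
        "unit_ids": [u.unit_id for u in units],
        "primary_channels": [u.primary_channel for u in units],
        "channel_scale": [u.channel_scale.tolist() for u in units],
        "n_spikes": [u.n_spikes for u in units],
    }, indent=1))


def read_units(path) -> list:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = np.fromfile(path.with_suffix(".bin"), dtype="<f4")
    if meta["n_units"] == 0:
        return []
    stack = raw.reshape(meta["n_units"], meta["n_channels"], meta["n_samples"])
    return [
        UnitTemplate(
            waveform=stack[i].astype(float),
            unit_id=meta["unit_ids"][i],
            primary_channel=meta["primary_channels"][i],
            channel_scale=np.array(meta["channel_scale"][i]),
            n_spikes=meta["n_spikes"][i],
        )
        for i in range(meta["n_units"])
    ]


def write_snippet_stack(path, arrays, sidecar: dict | None = None) -> None:
    """Equal-shape snippet arrays as one binary stack plus sidecar."""
    path = Path(path)
    stack = np.stack(arrays).astype("<f4")
    stack.tofile(path.with_suffix(".bin"))
    meta = dict(sidecar or {})
    meta.update({
        "format": "optoclean-snippets",
        "version": FORMAT_VERSION,
        "shape": list(stack.shape),
    })
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_snippet_stack(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = np.fromfile(path.with_suffix(".bin"), dtype="<f4")
    stack = raw.reshape(meta["shape"]).astype(float)
    return [stack[i] for i in range(stack.shape[0])], meta


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed, stages: dict) -> dict:
    """Run manifest: config snapshot, seed and per-stage output digests."""
    manifest = {
        "format": "optoclean-manifest",
        "version": FORMAT_VERSION,
        "seed": seed,
        "config": config,
        "stages": stages,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
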