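"""End-to-end pipeline: simulate/load -> detect -> clean -> sort -> match -> PSTH.

Stages run in order, write their outputs with content digests into a run
manifest, and are skipped on reruns when their configuration and inputs are
unchanged (partial resume).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import io as oio
from .artifact import PVRConfig, clean_group, expand_blackout
from .events import Snippet, SnippetGroup, detect_pulses, extract_snippets
from .spikes import MatchConfig, SorterConfig, match_spikes, sort_interpulse, weighted_psth
from .synth import SynthConfig, generate_session, scenario

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Configuration schema violation, reported with the offending field path."""


_SECTIONS = {
    "synth": SynthConfig,
    "pvr": PVRConfig,
    "sorter": SorterConfig,
    "match": MatchConfig,
}
_SCALARS = {
    "seed": int,
    "scenario": str,
    "min_separation_s": float,
    "pre_ms": float,
    "post_ms": float,
    "bin_ms": float,
    "input_session": str,
}


def validate_config(config: dict) -> dict:
    """Validate a nested config mapping and instantiate stage configs.

    Raises :class:`ConfigError` naming the offending field path, e.g.
    ``pvr.k_neighbors``.
    """
    if not isinstance(config, dict):
        raise ConfigError("config root must be a mapping")
    out = {}
    for key, val in config.items():
        if key in _SCALARS:
            try:
                out[key] = _SCALARS[key](val)
            except (TypeError, ValueError):
                raise ConfigError(f"{key}: expected {_SCALARS[key].__name__}, got {val!r}")
            continue
        if key not in _SECTIONS:
            raise ConfigError(f"{key}: unknown section")
        cls = _SECTIONS[key]
        if not isinstance(val, dict):
            raise ConfigError(f"{key}: expected a mapping of fields")
        names = {f.name for f in dataclasses.fields(cls)}
        for fname in val:
            if fname not in names:
                raise ConfigError(f"{key}.{fname}: unknown field")
        try:
            obj = cls(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in val.items()})
        except ValueError as err:
            msg = str(err)
            field = next((f for f in val if f in msg), next(iter(val), ""))
            raise ConfigError(f"{key}.{field}: {msg}") from err
        if isinstance(obj, SynthConfig):
            errs = obj.validate()
            if errs:
                field = errs[0].split()[0]
                raise ConfigError(f"{key}.{field}: " + "; ".join(errs))
        out[key] = obj
    return out


def _digest_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Stages:
    """Stage bookkeeping with digest-based resume."""

    def __init__(self, outdir: Path, prev: dict | None):
        self.outdir = outdir
        self.prev = (prev or {}).get("stages", {})
        self.stages: dict = {}

    def cached(self, name: str, key: str) -> bool:
        st = self.prev.get(name)
        if not st or st.get("key") != key:
            return False
        for f, dig in st.get("outputs", {}).items():
            p = self.outdir / f
            if not p.exists() or oio.sha256_file(p) != dig:
                return False
        self.stages[name] = st
        logger.info("stage %s: cached, skipping", name)
        return True

    def record(self, name: str, key: str, outputs: list) -> None:
        self.stages[name] = {
            "key": key,
            "outputs": {f: oio.sha256_file(self.outdir / f) for f in outputs},
        }


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full PVR-management pipeline; returns the manifest dict.

    ``config`` is the nested mapping accepted by :func:`validate_config`
    (typically parsed from YAML).  Artifacts are written under ``outdir``.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed", 0)
    prev = None
    man_path = outdir / "manifest.json"
    if man_path.exists():
        prev = oio.read_manifest(man_path)
    st = _Stages(outdir, prev)

    pvr_cfg: PVRConfig = cfg.get("pvr", PVRConfig())
    sorter_cfg: SorterConfig = cfg.get("sorter", SorterConfig())
    match_cfg: MatchConfig = cfg.get("match", MatchConfig())
    pre_ms = cfg.get("pre_ms", 30.0)
    post_ms = cfg.get("post_ms", 30.0)
    bin_ms = cfg.get("bin_ms", 1.0)

    # ---- stage: simulate / load -------------------------------------
    if "input_session" in cfg:
        key = _digest_obj({"input": cfg["input_session"]})
        block = oio.read_block(Path(cfg["input_session"]) / "recording")
        light = oio.read_light(Path(cfg["input_session"]) / "light")
        if not st.cached("simulate", key):
            oio.write_block(outdir / "recording", block)
            oio.write_light(outdir / "light", light)
            st.record("simulate", key, ["recording.bin", "recording.json",
                                        "light.bin", "light.json"])
    else:
        syn = cfg.get("synth", scenario("default", seed=seed))
        syn = replace(syn, seed=seed)
        key = _digest_obj({"synth": dataclasses.asdict(syn)})
        if st.cached("simulate", key):
            block = oio.read_block(outdir / "recording")
            light = oio.read_light(outdir / "light")
        else:
            block, light, truth = generate_session(syn)
            oio.write_block(outdir / "recording", block)
            oio.write_light(outdir / "light", light)
            rows = [
                {"unit_id": u, "time_sample": int(t)}
                for u, times in enumerate(truth.spike_times) for t in times
            ]
            import pandas as pd

            pd.DataFrame(rows, columns=["unit_id", "time_sample"]).to_csv(
                outdir / "truth_spikes.csv", index=False)
            st.record("simulate", key, ["recording.bin", "recording.json",
                                        "light.bin", "light.json",
                                        "truth_spikes.csv"])

    # ---- stage: detect ----------------------------------------------
    key = _digest_obj({
        "min_sep": cfg.get("min_separation_s", 0.0),
        "in": st.stages["simulate"]["outputs"],
    })
    if st.cached("detect", key):
        pulses = oio.read_pulses(outdir / "pulses.csv")
    else:
        pulses = detect_pulses(light, cfg.get("min_separation_s", 0.0), rate=block.rate)
        oio.write_pulses(outdir / "pulses.csv", pulses)
        st.record("detect", key, ["pulses.csv"])
    logger.info("detected %d pulses", len(pulses))

    # ---- stage: clean -----------------------------------------------
    groups = extract_snippets(block, pulses, pre_ms, post_ms)
    key = _digest_obj({
        "pvr": dataclasses.asdict(pvr_cfg),
        "pre_ms": pre_ms, "post_ms": post_ms,
        "in": st.stages["detect"]["outputs"],
    })
    gnames = [f"g{g.fiber_id}_{g.shank_id}" for g in groups]
    clean_files = []
    for gn in gnames:
        clean_files += [f"cleaned_{gn}.bin", f"cleaned_{gn}.json", f"mask_{gn}.csv"]
    results = {}
    if st.cached("clean", key):
        for g, gn in zip(groups, gnames):
            arrays, meta = oio.read_snippet_stack(outdir / f"cleaned_{gn}")
            lengths = [a.shape[1] for a in arrays]
            mask = oio.read_mask(outdir / f"mask_{gn}.csv", len(arrays),
                                 arrays[0].shape[0], lengths)
            results[gn] = (g, arrays, mask, expand_blackout(mask, pvr_cfg))
    else:
        for g, gn in zip(groups, gnames):
            res = clean_group(g, pvr_cfg)
            oio.write_snippet_stack(
                outdir / f"cleaned_{gn}", res.cleaned,
                {"fiber_id": g.fiber_id, "shank_id": g.shank_id},
            )
            oio.write_mask(outdir / f"mask_{gn}.csv", res.mask)
            results[gn] = (g, res.cleaned, res.mask, res.expanded_mask)
        st.record("clean", key, clean_files)
    n_masked = sum(r[2].total_masked() for r in results.values())
    logger.info("clean: %d base-rate samples masked across %d groups",
                n_masked, len(groups))

    # ---- stage: sort ------------------------------------------------
    key = _digest_obj({
        "sorter": dataclasses.asdict(sorter_cfg),
        "in": st.stages["simulate"]["outputs"],
    })
    if st.cached("sort", key):
        units = oio.read_units(outdir / "units")
    else:
        units = sort_interpulse(block, pulses, sorter_cfg, pre_ms, post_ms)
        oio.write_units(outdir / "units", units)
        st.record("sort", key, ["units.bin", "units.json"])
    logger.info("sorted %d units", len(units))

    # ---- stage: match + psth ----------------------------------------
    key = _digest_obj({
        "match": dataclasses.asdict(match_cfg), "bin_ms": bin_ms,
        "in": {**st.stages["clean"]["outputs"], **st.stages["sort"]["outputs"]},
    })
    out_files = []
    for gn in gnames:
        out_files += [f"spikes_{gn}.csv", f"psth_{gn}.csv"]
    if not st.cached("match", key):
        n_acc = n_inv = 0
        for gn in gnames:
            g, cleaned, mask, expanded = results[gn]
            snips = [
                replace(s, data=arr) for s, arr in zip(g.snippets, cleaned)
            ]
            gunits = [  # restrict unit waveforms to this shank's channels
                replace(
                    u,
                    waveform=u.waveform[g.snippets[0].channel_indices],
                    channel_scale=u.channel_scale[g.snippets[0].channel_indices],
                )
                for u in units
            ] if units else []
            # only units actually visible on this shank can be matched
            gunits = [u for u in gunits
                      if u.waveform.min() <= sorter_cfg.detect_threshold_uv]
            if gunits:
                events = match_spikes(snips, mask, expanded, gunits, match_cfg)
            else:
                events = []
            oio.write_spikes(outdir / f"spikes_{gn}.csv", events)
            psth = weighted_psth(events, expanded, snips, bin_ms)
            oio.write_psth(outdir / f"psth_{gn}.csv", psth)
            n_acc += sum(e.valid for e in events)
            n_inv += sum(not e.valid for e in events)
        logger.info("match: %d valid spikes, %d invalid", n_acc, n_inv)
        st.record("match", key, out_files)

    manifest = oio.write_manifest(
        man_path, config={k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                              else v) for k, v in cfg.items()},
        seed=seed, stages=st.stages,
    )
    return manifest
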