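"""Shared fixtures: a desk-scale synthetic session and its cleaned output.

The session keeps the statistical structure of the full-scale default
(10 ms pulses, five interleaved light-power levels with >= 20 trials per
level per group, ~0.75 units per electrode, PVR linear to ~1000 µV and
saturating at 6000 µV) at a size that cleans in seconds: 8 channels on two
shanks, two fibers, 200 pulses.
"""
from dataclasses import replace

import numpy as np
import pytest

import optoclean as oc

DESK = dict(
    n_pulses=200,
    channels=8,
    fibers=2,
    period_ms=100.0,
    n_units=6,
)


def desk_config(seed=1, scenario_name="default", **overrides):
    params = {**DESK, **overrides}
    return oc.scenario(scenario_name, seed=seed, **params)


@pytest.fixture(scope="session")
def desk_session():
    cfg = desk_config(seed=1)
    block, light, truth = oc.generate_session(cfg)
    return cfg, block, light, truth


@pytest.fixture(scope="session")
def desk_pulses(desk_session):
    _, block, light, _ = desk_session
    return oc.detect_pulses(light, rate=block.rate)


@pytest.fixture(scope="session")
def desk_groups(desk_session, desk_pulses):
    _, block, _, _ = desk_session
    return oc.extract_snippets(block, desk_pulses)


@pytest.fixture(scope="session")
def desk_cleaned(desk_groups):
    """CleanResult for every (fiber, shank) group of the desk session."""
    cfg = oc.PVRConfig()
    return [oc.clean_group(g, cfg) for g in desk_groups]


@pytest.fixture(scope="session")
def desk_units(desk_session, desk_pulses):
    _, block, _, _ = desk_session
    return oc.sort_interpulse(block, desk_pulses)


def shank_restricted_units(units, group):
    """Units restricted to the group's channels, dropping units invisible there."""
    chidx = group.snippets[0].channel_indices
    out = [
        replace(u, waveform=u.waveform[chidx], channel_scale=u.channel_scale[chidx])
        for u in units
    ]
    return [u for u in out if u.waveform.min() <= -30.0]


@pytest.fixture(scope="session")
def desk_matches(desk_groups, desk_cleaned, desk_units):
    """Per group: (snippets with cleaned data, spike events)."""
    out = []
    for g, res in zip(desk_groups, desk_cleaned):
        snips = [replace(s, data=arr) for s, arr in zip(g.snippets, res.cleaned)]
        gunits = shank_restricted_units(desk_units, g)
        events = oc.match_spikes(snips, res.mask, res.expanded_mask, gunits)
        out.append((snips, events))
    return out


def truth_primary_channels(truth):
    return [int(np.unravel_index(np.argmin(w), w.shape)[0])
            for w in truth.unit_waveforms]


def score_recovery(block, truth, groups, cleaned, matches, tol=30):
    """Time-based precision/recall/F1 of valid recovered spikes against
    ground-truth spikes whose windows avoid the expanded blackout mask."""
    prim = truth_primary_channels(truth)
    tp = fp = fn = 0
    for g, res, (snips, events) in zip(groups, cleaned, matches):
        shank_units = [u for u in range(len(truth.unit_waveforms))
                       if block.shank_ids[prim[u]] == g.shank_id]
        for si, s in enumerate(snips):
            a = s.start_sample
            masked = res.expanded_mask.masked_array(si)
            all_tt, clean_tt = [], []
            for u in shank_units:
                for t in truth.spike_times[u]:
                    tt = t - a
                    if 0 <= tt < s.n_samples:
                        all_tt.append(tt)
                        if (20 <= tt < s.n_samples - 40
                                and not masked[:, tt - 20:tt + 40].any()):
                            clean_tt.append(tt)
            clean_tt = np.array(sorted(clean_tt))
            used = np.zeros(len(clean_tt), dtype=bool)
            for t in sorted(e.time_sample for e in events
                            if e.valid and e.snippet_index == si):
                d = np.abs(clean_tt - t) if len(clean_tt) else np.array([np.inf])
                i = int(np.argmin(d))
                if len(clean_tt) and d[i] <= tol and not used[i]:
                    used[i] = True
                    tp += 1
                elif min((abs(t - x) for x in all_tt), default=np.inf) <= tol:
                    pass  # recovered a spike excluded from the scored set
                else:
                    fp += 1
            fn += int((~used).sum())
    precision = tp / max(tp + fp, 1)
    recall = tp / max(tp + fn, 1)
    f1 = 2 * precision * recall / max(precision + recall, 1e-12)
    return precision, recall, f1
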