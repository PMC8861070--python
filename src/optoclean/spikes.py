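"""Spike sorting on artifact-free data, spike recovery in cleaned windows,
and blackout-aware weighted peri-stimulus averaging.

Sorting is a pluggable stage: any sorter that yields per-unit mean waveforms
can feed the matcher.  The built-in sorter (threshold detection plus waveform
clustering) exists so the pipeline is testable end to end without external
software.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .artifact import BlackoutMask
from .events import RecordingBlock, Snippet, SnippetGroup

logger = logging.getLogger(__name__)

__all__ = [
    "SorterConfig",
    "MatchConfig",
    "UnitTemplate",
    "SpikeEvent",
    "PSTH",
    "inter_pulse_segments",
    "detect_threshold_events",
    "sort_interpulse",
    "match_spikes",
    "weighted_psth",
]

WIN_PRE = 20  # samples before the trough
WIN_POST = 40  # samples after the trough
WIN = WIN_PRE + WIN_POST  # half-open spike window [t-20, t+40)


@dataclass
class SorterConfig:
    """Built-in sorter: -30 µV threshold detection, then waveform clustering
    into ``2 x n_channels`` clusters, followed by merge and amplitude curation.

    Curation drops units whose trough exceeds 400 µV and units showing the
    artifact-like signature of three or more channels simultaneously above
    +20 µV at the trough sample; both filters can be disabled.
    """

    detect_threshold_uv: float = -30.0
    min_peak_distance: int = 20  # samples between detections on one channel
    clusters_per_channel: int = 2
    max_trough_uv: float = 400.0
    trough_filter: bool = True
    artifact_min_channels: int = 3
    artifact_amp_uv: float = 20.0
    artifact_filter: bool = True
    merge_similarity: float = 0.95
    min_spikes: int = 5  # clusters with fewer events are discarded
    min_total_seconds: float = 0.5
    pca_components: int = 10
    random_state: int = 0


@dataclass
class MatchConfig:
    """Greedy template matching in normalized units.

    Events are accepted while the most negative remaining sample exceeds
    ``stop_threshold_sd`` standard deviations; a unit match is accepted when
    the mean squared error over three probe-adjacent channels and the spike
    window is below ``error_threshold`` (one, i.e. the variance of the data).
    """

    error_threshold: float = 1.0
    stop_threshold_sd: float = 4.0
    exclusion_radius: int = WIN // 2  # consumed samples around a picked trough
    align_radius: int = 2  # window shifts tried around the picked trough,
    # absorbing the +-1 sample jitter of noisy trough detection
    unit_scale: str = "trial"  # "trial": unit waveforms divided by the same
    # per-trial SDs as the data (everything in units of the data SD);
    # "source": divided by the SD of the data the unit was sorted from


@dataclass
class UnitTemplate:
    """Mean waveform of a sorted unit across all probe channels.

    ``waveform`` is (channels, 60) in µV with the trough at sample 20;
    ``channel_scale`` holds the per-channel standard deviation of the data
    the unit was sorted from, so the waveform can be compared against
    SD-normalized snippets.
    """

    waveform: np.ndarray
    unit_id: int
    primary_channel: int
    channel_scale: np.ndarray = None
    n_spikes: int = 0

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("unit waveform contains non-finite values")
        if self.waveform.shape[1] != WIN:
            raise ValueError(f"unit waveform must have {WIN} samples")
        if self.channel_scale is None:
            self.channel_scale = np.ones(self.waveform.shape[0])
        self.channel_scale = np.asarray(self.channel_scale, dtype=float)

    @property
    def trough_uv(self) -> float:
        return float(self.waveform.min())


@dataclass
class SpikeEvent:
    """A recovered spike occurrence.

    ``valid`` is False iff the spike window intersects the expanded
    blackout mask.
    """

    snippet_index: int
    time_sample: int  # snippet-relative, base rate
    block_sample: int
    unit_id: int
    error: float  # mean squared error in normalized units
    valid: bool
    channel: int = -1  # channel carrying the picked trough


@dataclass
class PSTH:
    """Peri-stimulus time histogram with per-bin blackout bookkeeping."""

    bin_edges_ms: np.ndarray  # relative to light onset
    rate_hz: np.ndarray  # NaN where all trials are masked
    pct_masked_trials: np.ndarray  # 0..100, the "remaining PVR" percentage
    n_trials: int

    @property
    def undefined_bins(self) -> np.ndarray:
        return self.pct_masked_trials >= 100.0


def inter_pulse_segments(n_samples: int, pulses, pre: int, post: int):
    """Complement of the peri-pulse windows ``[onset-pre, offset+post)``."""
    spans = sorted((p.onset_sample - pre, p.offset_sample + post) for p in pulses)
    segs, cur = [], 0
    for a, b in spans:
        if a > cur:
            segs.append((cur, min(a, n_samples)))
        cur = max(cur, b)
    if cur < n_samples:
        segs.append((cur, n_samples))
    return [(max(0, a), b) for a, b in segs if b > max(0, a)]


def detect_threshold_events(
    data: np.ndarray,
    threshold_uv: float = -30.0,
    min_distance: int = 20,
):
    """Negative threshold crossings, deduplicated across channels.

    Returns (times, channels, amplitudes) sorted by time; coincident
    detections on neighbouring channels within ``min_distance`` samples are
    collapsed onto the most negative one.
    """
    cand = []
    for c, x in enumerate(np.atleast_2d(data)):
        pk, props = find_peaks(-x, height=-threshold_uv, distance=min_distance)
        for t, h in zip(pk, props["peak_heights"]):
            cand.append((-h, int(t), c))
    cand.sort()  # most negative first
    accepted = []
    for amp, t, c in cand:
        # a spike spans a few neighbouring channels; coincident detections on
        # distant channels are distinct events
        if any(abs(t - t0) < min_distance and abs(c - c0) <= 2
               for t0, c0, _ in accepted):
            continue
        accepted.append((t, c, amp))
    accepted.sort()
    if not accepted:
        return np.array([], int), np.array([], int), np.array([])
    times, chans, amps = map(np.array, zip(*accepted))
    return times, chans, amps


def _curate(waveform: np.ndarray, cfg: SorterConfig) -> bool:
    """True if the unit survives the amplitude rules.

    The artifact signature is evaluated at the trough sample: a genuine
    spike is negative-going on every channel it reaches at that moment,
    whereas a residual light artifact shows large positive deflections on
    several channels simultaneously.
    """
    if cfg.trough_filter and waveform.min() < -cfg.max_trough_uv:
        return False
    if cfg.artifact_filter:
        t = int(np.unravel_index(np.argmin(waveform), waveform.shape)[1])
        if (waveform[:, t] > cfg.artifact_amp_uv).sum() >= cfg.artifact_min_channels:
            return False
    return True


def sort_interpulse(
    block: RecordingBlock,
    pulses,
    cfg: SorterConfig | None = None,
    pre_ms: float = 30.0,
    post_ms: float = 30.0,
    return_events: bool = False,
):
    """Sort units from the PVR-free periods between light pulses.

    The inter-pulse periods are concatenated and passed to the built-in
    sorter; the cluster budget is twice the number of channels.  Returns a
    list of :class:`UnitTemplate` (and, optionally, the detected events with
    their unit assignments).
    """
    cfg = cfg or SorterConfig()
    pre = int(round(pre_ms * block.rate / 1000.0))
    post = int(round(post_ms * block.rate / 1000.0))
    segs = inter_pulse_segments(block.n_samples, pulses, pre, post)
    total = sum(b - a for a, b in segs)
    if total < cfg.min_total_seconds * block.rate:
        raise ValueError(
            f"only {total / block.rate:.3f} s of inter-pulse data available "
            f"(minimum {cfg.min_total_seconds} s)"
        )
    C = block.n_channels
    scale = np.sqrt(
        sum(block.samples[:, a:b].var(axis=1) * (b - a) for a, b in segs) / total
    )
    scale[scale == 0] = 1.0

    times, waveforms = [], []
    for a, b in segs:
        seg = block.samples[:, a:b]
        t, ch, amp = detect_threshold_events(
            seg, cfg.detect_threshold_uv, cfg.min_peak_distance
        )
        for ti in t:
            if ti - WIN_PRE < 0 or ti + WIN_POST > seg.shape[1]:
                continue
            times.append(a + ti)
            waveforms.append(seg[:, ti - WIN_PRE:ti + WIN_POST])
    if not waveforms:
        return ([], []) if return_events else []
    Wv = np.stack(waveforms)  # (n, C, WIN)
    n = Wv.shape[0]

    n_clusters = min(cfg.clusters_per_channel * C, n)
    feats = Wv.reshape(n, -1)
    n_comp = min(cfg.pca_components, n, feats.shape[1])
    Z = PCA(n_components=n_comp, random_state=cfg.random_state).fit_transform(feats)
    labels = (
        KMeans(n_clusters=n_clusters, n_init=4, random_state=cfg.random_state)
        .fit_predict(Z)
    )

    # cluster templates, trough-aligned at WIN_PRE by construction
    clusters = {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        clusters[lab] = [Wv[idx].mean(axis=0), idx]

    # merge near-identical clusters (over-splitting from the fixed budget)
    def _cos(a, b):
        a, b = a.ravel(), b.ravel()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))

    merged = True
    while merged and len(clusters) > 1:
        merged = False
        keys = sorted(clusters)
        best = (cfg.merge_similarity, None)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                s = _cos(clusters[ka][0], clusters[kb][0])
                if s > best[0]:
                    best = (s, (ka, kb))
        if best[1] is not None:
            ka, kb = best[1]
            wa, ia = clusters[ka]
            wb, ib = clusters[kb]
            idx = np.concatenate([ia, ib])
            clusters[ka] = [Wv[idx].mean(axis=0), idx]
            del clusters[kb]
            merged = True

    units, assignments = [], {}
    uid = 0
    for lab in sorted(clusters):
        w, idx = clusters[lab]
        if len(idx) < cfg.min_spikes:
            continue
        if not _curate(w, cfg):
            logger.info("sorter: cluster %d dropped by amplitude curation", lab)
            continue
        units.append(
            UnitTemplate(
                waveform=w,
                unit_id=uid,
                primary_channel=int(np.unravel_index(np.argmin(w), w.shape)[0]),
                channel_scale=scale,
                n_spikes=len(idx),
            )
        )
        for i in idx:
            assignments[int(i)] = uid
        uid += 1
    logger.info("sorter: %d events, %d units after curation", n, len(units))
    if return_events:
        events = [
            (int(times[i]), assignments[i]) for i in sorted(assignments)
        ]
        return units, events
    return units


def match_spikes(
    snippets: list,
    mask: BlackoutMask,
    expanded_mask: BlackoutMask,
    units: list,
    cfg: MatchConfig | None = None,
) -> list:
    """Recover spikes inside cleaned peri-pulse snippets by template matching.

    Per snippet: channels are normalized to unit standard deviation (over
    unmasked samples); the most negative unmasked sample is picked greedily
    and its three probe-adjacent channels (clamped at the probe edges) over
    the -20/+40 window are compared against every unit's correspondingly
    normalized waveform.  The best unit is accepted when its mean squared
    error is below one; the loop stops when no remaining event exceeds four
    standard deviations.  Events whose window intersects the *expanded*
    blackout mask are emitted with ``valid=False``.
    """
    cfg = cfg or MatchConfig()
    if not units:
        raise ValueError("no unit templates supplied")
    events = []
    for si, snip in enumerate(snippets):
        if isinstance(snip, Snippet):
            data, start = snip.data, snip.start_sample
        else:
            data, start = np.atleast_2d(np.asarray(snip, dtype=float)), 0
        C, T = data.shape
        m_raw = mask.masked_array(si)
        m_exp = expanded_mask.masked_array(si)
        unmasked = ~m_raw
        if not unmasked.any():
            logger.warning("snippet %d entirely masked; no spikes recovered", si)
            continue
        sd = np.array(
            [data[c, unmasked[c]].std() if unmasked[c].any() else 0.0 for c in range(C)]
        )
        sd[sd == 0] = 1.0
        Z = data / sd[:, None]
        if cfg.unit_scale == "trial":
            Uz = [u.waveform / sd[:, None] for u in units]
        elif cfg.unit_scale == "source":
            Uz = [u.waveform / u.channel_scale[:, None] for u in units]
        else:
            raise ValueError(f"unknown unit_scale {cfg.unit_scale!r}")

        avail = unmasked.copy()
        avail[:, :WIN_PRE] = False
        avail[:, max(0, T - WIN_POST):] = False
        while True:
            zm = np.where(avail, Z, np.inf)
            flat = np.argmin(zm)
            c, t = np.unravel_index(flat, zm.shape)
            v = zm[c, t]
            if not np.isfinite(v) or v > -cfg.stop_threshold_sd:
                break
            lo_c, hi_c = max(0, c - 1), min(C, c + 2)
            r = cfg.exclusion_radius
            # consume the trough on its own channel; on the neighbours only a
            # narrow span for now, so nearby spikes of other units stay
            # pickable if this pick is rejected
            avail[c, max(0, t - r):t + r] = False
            avail[lo_c:hi_c, max(0, t - 5):t + 5] = False
            best_err, best_u, best_t = np.inf, None, t
            for dt in range(-cfg.align_radius, cfg.align_radius + 1):
                tc = t + dt
                if tc - WIN_PRE < 0 or tc + WIN_POST > T:
                    continue
                win = Z[lo_c:hi_c, tc - WIN_PRE:tc + WIN_POST]
                keep = ~m_raw[lo_c:hi_c, tc - WIN_PRE:tc + WIN_POST]
                if not keep.any():
                    continue
                for u, uz in zip(units, Uz):
                    err = ((win - uz[lo_c:hi_c]) ** 2)[keep].mean()
                    if err < best_err:
                        best_err, best_u, best_t = err, u, tc
            if best_err < cfg.error_threshold:
                t = best_t
                # an accepted spike consumes its whole neighbourhood so its
                # deflections on adjacent channels cannot be re-accepted
                ex_lo, ex_hi = max(0, c - 2), min(C, c + 3)
                avail[ex_lo:ex_hi, max(0, t - r):t + r] = False
                valid = not m_exp[lo_c:hi_c, t - WIN_PRE:t + WIN_POST].any()
                events.append(
                    SpikeEvent(si, int(t), int(start + t), best_u.unit_id,
                               float(best_err), bool(valid), int(c))
                )
    events.sort(key=lambda e: (e.snippet_index, e.time_sample))
    return events


def weighted_psth(
    events: list,
    expanded_mask: BlackoutMask,
    snippets: list,
    bin_ms: float = 1.0,
    unit_id: int | None = None,
    valid_only: bool = True,
) -> PSTH:
    """Peri-stimulus histogram weighted by the per-bin unmasked trials.

    The rate in a bin is averaged over only the trials whose bin is fully
    outside the expanded blackout mask (on every channel); the percentage
    of masked trials is reported alongside.  A bin masked in all trials is
    undefined (NaN rate) and flagged via ``pct_masked_trials == 100``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if not snippets:
        raise ValueError("no trials")
    rate = snippets[0].rate
    pre = snippets[0].pre
    post = snippets[0].post
    max_dur = max(s.pulse.duration for s in snippets)
    t0_ms = -pre / rate * 1000.0
    t1_ms = (max_dur + post) / rate * 1000.0
    edges = np.arange(t0_ms, t1_ms + bin_ms / 2, bin_ms)
    B = len(edges) - 1
    bin_s = bin_ms / 1000.0

    n_trials = len(snippets)
    counts = np.zeros((n_trials, B))
    for e in events:
        if valid_only and not e.valid:
            continue
        if unit_id is not None and e.unit_id != unit_id:
            continue
        t_ms = (e.time_sample - pre) / rate * 1000.0
        b = int(np.floor((t_ms - t0_ms) / bin_ms))
        if 0 <= b < B:
            counts[e.snippet_index, b] += 1

    masked = np.zeros((n_trials, B), dtype=bool)
    for i, s in enumerate(snippets):
        iv = expanded_mask.intervals_any_channel(i)
        for a, b in iv:
            a_ms = (a - pre) / rate * 1000.0
            b_ms = (b - pre) / rate * 1000.0
            lo = int(np.floor((a_ms - t0_ms) / bin_ms))
            hi = int(np.ceil((b_ms - t0_ms) / bin_ms))
            masked[i, max(0, lo):min(B, hi)] = True
        # bins beyond this trial's snippet end are unavailable
        hi = int(np.ceil(((s.n_samples - pre) / rate * 1000.0 - t0_ms) / bin_ms))
        masked[i, hi:] = True

    ok = ~masked
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        rate_hz = np.where(
            n_ok > 0,
            (counts * ok).sum(axis=0) / np.maximum(n_ok, 1) / bin_s,
            np.nan,
        )
    pct = 100.0 * masked.sum(axis=0) / n_trials
    return PSTH(edges, rate_hz, pct, n_trials)
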