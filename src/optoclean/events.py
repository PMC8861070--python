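"""Recordings, light logs, pulse detection and peri-pulse snippet handling.

Conventions used throughout the package: sample indices are 0-based and
intervals are half-open ``[onset, offset)``; voltages are in microvolts;
the nominal acquisition rate is 30 kHz.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "RecordingBlock",
    "LightLog",
    "PulseEvent",
    "Snippet",
    "SnippetGroup",
    "detect_pulses",
    "extract_snippets",
    "preprocess",
    "decimate",
]


@dataclass
class RecordingBlock:
    """Multichannel extracellular voltage trace with channel geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    rate : float
        Sampling rate in samples per second.
    channel_positions : ndarray, shape (n_channels,)
        Depth of each channel along its shank, in micrometres.  Positions
        must be strictly monotone within a shank (linear probe layout).
    shank_ids : ndarray, shape (n_channels,)
        Shank membership of each channel.
    """

    samples: np.ndarray
    rate: float = 30000.0
    channel_positions: np.ndarray = None
    shank_ids: np.ndarray = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        n = self.samples.shape[0]
        if self.channel_positions is None:
            self.channel_positions = np.arange(n, dtype=float)
        if self.shank_ids is None:
            self.shank_ids = np.zeros(n, dtype=int)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        self.shank_ids = np.asarray(self.shank_ids, dtype=int)
        if self.channel_positions.shape != (n,) or self.shank_ids.shape != (n,):
            raise ValueError("channel_positions and shank_ids must have one entry per channel")
        for s in np.unique(self.shank_ids):
            d = np.diff(self.channel_positions[self.shank_ids == s])
            if d.size and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(
                    f"channel_positions must be strictly monotone within shank {s}"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def shanks(self) -> np.ndarray:
        return np.unique(self.shank_ids)

    def channels_on_shank(self, shank: int) -> np.ndarray:
        return np.flatnonzero(self.shank_ids == shank)


@dataclass
class LightLog:
    """Per-fiber light-intensity traces from the patch-cord photodiode.

    ``rate=None`` means the log shares the recording timebase.
    """

    intensity: np.ndarray  # (n_fibers, n_samples), photodiode units
    fiber_ids: np.ndarray = None
    rate: float | None = None

    def __post_init__(self):
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if self.fiber_ids is None:
            self.fiber_ids = np.arange(self.intensity.shape[0])
        self.fiber_ids = np.asarray(self.fiber_ids, dtype=int)
        if self.fiber_ids.shape != (self.intensity.shape[0],):
            raise ValueError("fiber_ids must have one entry per fiber trace")

    @property
    def n_fibers(self) -> int:
        return self.intensity.shape[0]


@dataclass(frozen=True)
class PulseEvent:
    """One light pulse; onset/offset at the half-maximum crossings."""

    onset_sample: int
    offset_sample: int
    fiber_id: int
    intensity_summary: float
    shank_id: int | None = None

    def __post_init__(self):
        if not self.offset_sample > self.onset_sample:
            raise ValueError("offset_sample must exceed onset_sample")
        if self.intensity_summary < 0:
            raise ValueError("intensity_summary must be non-negative")

    @property
    def duration(self) -> int:
        return self.offset_sample - self.onset_sample


@dataclass
class Snippet:
    """Peri-pulse data segment from one shank.

    ``data`` spans block samples ``[start_sample, start_sample + data.shape[1])``,
    i.e. ``[onset - pre, offset + post)``.
    """

    pulse: PulseEvent
    data: np.ndarray  # (shank channels, time), µV
    pre: int  # margin before onset, samples
    post: int  # margin after offset, samples
    rate: float
    start_sample: int
    channel_indices: np.ndarray  # indices into the parent block

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class SnippetGroup:
    """All snippets sharing one (fiber, shank) combination."""

    fiber_id: int
    shank_id: int
    snippets: list

    def __len__(self):
        return len(self.snippets)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s.pulse.intensity_summary for s in self.snippets])


def detect_pulses(
    light: LightLog,
    min_separation: float = 0.0,
    rate: float = 30000.0,
    floor_fraction: float = 0.02,
) -> list:
    """Detect light pulses from photodiode traces.

    A pulse is one contiguous supra-half-maximum excursion; the half-maximum
    is taken relative to that pulse's own plateau peak, so trials of different
    commanded intensity are timed consistently.  Onset is the first sample at
    or above half-maximum, offset the first sample after the last one
    (half-open interval).

    Parameters
    ----------
    light : LightLog
    min_separation : float
        Excursions separated by less than this many seconds are merged into
        a single pulse.
    rate : float
        Recording sampling rate; a log on its own timebase is linearly
        interpolated onto this rate first.
    floor_fraction : float
        Candidate excursions are segmented where the trace exceeds this
        fraction of the fiber's global maximum (guards against baseline
        photodiode noise); the half-maximum timing itself is per pulse.

    Returns
    -------
    list of PulseEvent, sorted by onset within each fiber and globally.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    if light.n_fibers < 1:
        raise ValueError("light log must contain at least one fiber trace")
    if not np.all(np.isfinite(light.intensity)):
        raise ValueError("light intensity contains non-finite samples")

    events = []
    min_sep = int(round(min_separation * rate))
    for fiber, trace in zip(light.fiber_ids, light.intensity):
        x = np.asarray(trace, dtype=float)
        if light.rate is not None and light.rate != rate:
            t_src = np.arange(x.size) / light.rate
            n_dst = int(round(x.size * rate / light.rate))
            x = np.interp(np.arange(n_dst) / rate, t_src, x)
        peak_all = x.max(initial=0.0)
        if peak_all <= 0:
            continue
        above = x > floor_fraction * peak_all
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        run_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
        # merge runs separated by less than min_sep samples
        merged = [[run_starts[0], run_ends[0]]]
        for a, b in zip(run_starts[1:], run_ends[1:]):
            if a - merged[-1][1] < min_sep:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            peak = x[a:b].max()
            half = peak / 2.0
            sup = np.flatnonzero(x[a:b] >= half)
            onset = int(a + sup[0])
            offset = int(a + sup[-1] + 1)
            events.append(
                PulseEvent(onset, offset, int(fiber), float(peak))
            )
    events.sort(key=lambda e: (e.onset_sample, e.fiber_id))
    return events


def extract_snippets(
    block: RecordingBlock,
    pulses,
    pre_ms: float = 30.0,
    post_ms: float = 30.0,
    pulse_rate: float | None = None,
) -> list:
    """Cut peri-pulse snippets and group them by (fiber, shank).

    Each snippet spans ``[onset - pre, offset + post)``.  A pulse whose
    window exceeds the recording bounds is dropped with a logged warning.
    Overlapping windows of the same fiber are an error; overlaps across
    fibers are logged.
    """
    if pulse_rate is not None and pulse_rate != block.rate:
        raise ValueError(
            f"pulse indices at {pulse_rate} Hz do not match block rate {block.rate} Hz"
        )
    pre = int(round(pre_ms * block.rate / 1000.0))
    post = int(round(post_ms * block.rate / 1000.0))

    windows = []
    for p in pulses:
        windows.append((p.onset_sample - pre, p.offset_sample + post, p))
    windows.sort(key=lambda w: w[0])
    for (a1, b1, p1), (a2, b2, p2) in zip(windows, windows[1:]):
        if a2 < b1:
            if p1.fiber_id == p2.fiber_id:
                raise ValueError(
                    f"overlapping snippet windows for fiber {p1.fiber_id} "
                    f"at samples {a2} < {b1}"
                )
            logger.warning(
                "snippet windows of fibers %d and %d overlap (samples %d-%d)",
                p1.fiber_id, p2.fiber_id, a2, b1,
            )

    groups: dict = {}
    for a, b, p in windows:
        if a < 0 or b > block.n_samples:
            logger.warning(
                "dropping pulse at sample %d: window [%d, %d) outside recording",
                p.onset_sample, a, b,
            )
            continue
        for shank in block.shanks():
            ch = block.channels_on_shank(shank)
            snip = Snippet(
                pulse=replace(p, shank_id=int(shank)),
                data=block.samples[ch, a:b].copy(),
                pre=pre,
                post=post,
                rate=block.rate,
                start_sample=int(a),
                channel_indices=ch,
            )
            groups.setdefault((p.fiber_id, int(shank)), []).append(snip)

    return [
        SnippetGroup(f, s, sn) for (f, s), sn in sorted(groups.items())
    ]


def preprocess(
    data: np.ndarray,
    rate: float,
    hp_cutoff_hz: float = 1.0,
    supersample_factor: int = 4,
    method: str = "fourier",
) -> np.ndarray:
    """High-pass filter and supersample a snippet.

    The high-pass is a first-order Butterworth applied forward-backward
    (zero phase); supersampling is band-limited Fourier resampling by
    default, with a cubic-spline alternative.  The snippet is reflect-padded
    internally so that the periodic wrap of the Fourier interpolation does
    not contaminate the snippet edges.

    When the cutoff period is much longer than the snippet itself (the
    default 1 Hz acquisition cutoff against a 70 ms snippet), a recursive
    filter is ill-conditioned — its initial-condition transient spans the
    whole snippet and injects a trial-specific baseline.  In that regime the
    only attainable effect of the filter is DC removal, which is applied
    exactly instead.
    """
    f = supersample_factor
    if not float(f).is_integer() or int(f) < 1:
        raise ValueError("supersample_factor must be an integer >= 1")
    f = int(f)
    x = np.asarray(data, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    T = x.shape[-1]
    if hp_cutoff_hz and hp_cutoff_hz > 0:
        if hp_cutoff_hz * T / rate < 1.0:  # less than one cutoff period of data
            x = x - x.mean(axis=-1, keepdims=True)
        else:
            sos = _signal.butter(1, hp_cutoff_hz, btype="highpass", fs=rate,
                                 output="sos")
            x = _signal.sosfiltfilt(sos, x, axis=-1)
    pad = min(T - 1, 256)
    xp = np.pad(x, [(0, 0), (pad, pad)], mode="reflect") if pad else x
    if f == 1:
        out = xp[:, pad:pad + T]
    elif method == "fourier":
        up = _signal.resample(xp, xp.shape[-1] * f, axis=-1)
        out = up[:, pad * f:(pad + T) * f]
    elif method == "spline":
        t = np.arange(xp.shape[-1], dtype=float)
        tf = pad + np.arange(T * f, dtype=float) / f
        out = CubicSpline(t, xp, axis=-1, bc_type="natural")(tf)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return out[0] if squeeze else out


def decimate(data: np.ndarray, factor: int) -> np.ndarray:
    """Return every ``factor``-th sample (inverse of the supersampling grid)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.asarray(data)[..., ::factor].copy()
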