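"""Photovoltaic-response (PVR) artifact removal by per-pulse template subtraction.

Light striking a silicon probe induces a voltage artifact (the photovoltaic
response) that is time-locked to light onset and offset.  Because it is
highly reproducible across pulses of similar intensity, the artifact on each
pulse can be estimated as the mean of the pulses most similar to it and
subtracted.  Whatever survives subtraction is found by a rectified-derivative
statistic averaged across intensity-sorted neighbouring trials and recorded
as *blackout* intervals during which no spike can be trusted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .events import SnippetGroup, decimate, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "PVRConfig",
    "PulseTemplate",
    "BlackoutMask",
    "build_pulse_template",
    "merge_onset_offset",
    "subtract_template",
    "detect_residual_pvr",
    "expand_blackout",
    "overlap_ms",
    "clean_group",
    "CleanResult",
]


@dataclass
class PVRConfig:
    """Constants of the PVR management procedure.

    Defaults: templates average the ``k_neighbors=20`` most similar pulses;
    onset and offset templates are joined over ``overlap_samples=100`` base-rate
    samples (3.3 ms at 30 kHz); the residual detector averages
    ``residual_window_trials=7`` intensity-adjacent trials and thresholds at
    ``residual_threshold_sd=4`` standard deviations of the pre-stimulation
    period; blackout intervals grow 40 samples back and 20 forward.
    """

    k_neighbors: int = 20
    overlap_samples: int = 100  # base-rate samples
    residual_window_trials: int = 7
    residual_threshold_sd: float = 4.0
    blackout_expand_back: int = 40  # base-rate samples
    blackout_expand_fwd: int = 20
    supersample_factor: int = 4
    hp_cutoff_hz: float = 1.0
    resample_method: str = "fourier"

    def __post_init__(self):
        if self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        if self.residual_window_trials < 3 or self.residual_window_trials % 2 == 0:
            raise ValueError("residual_window_trials must be odd and >= 3")
        if self.residual_threshold_sd <= 0:
            raise ValueError("residual_threshold_sd must be positive")
        if self.overlap_samples <= 0:
            raise ValueError("overlap_samples must be positive")
        if self.blackout_expand_back < 0 or self.blackout_expand_fwd < 0:
            raise ValueError("blackout expansions must be >= 0")
        if self.supersample_factor < 1:
            raise ValueError("supersample_factor must be >= 1")


def overlap_ms(cfg: PVRConfig, rate: float = 30000.0) -> float:
    """Duration of the onset/offset template overlap in milliseconds."""
    return cfg.overlap_samples / rate * 1000.0


@dataclass
class PulseTemplate:
    """Onset- and offset-aligned artifact templates tailored to one pulse."""

    onset: np.ndarray  # (channels, samples), aligned to snippet start
    offset: np.ndarray  # (channels, samples), aligned to snippet end
    pulse_index: int

    def __post_init__(self):
        if not (np.all(np.isfinite(self.onset)) and np.all(np.isfinite(self.offset))):
            raise ValueError("template contains non-finite values")
        if self.onset.shape[0] != self.offset.shape[0]:
            raise ValueError("onset/offset templates disagree on channel count")


class BlackoutMask:
    """Per-snippet, per-channel run-length intervals of invalidated samples.

    Intervals are half-open ``[start, end)`` in base-rate snippet samples,
    kept sorted, merged and clipped to the snippet span.
    """

    def __init__(self, n_snippets: int, n_channels: int, snippet_lengths):
        if np.isscalar(snippet_lengths):
            snippet_lengths = [int(snippet_lengths)] * n_snippets
        if len(snippet_lengths) != n_snippets:
            raise ValueError("need one snippet length per snippet")
        self.n_snippets = int(n_snippets)
        self.n_channels = int(n_channels)
        self.snippet_lengths = [int(t) for t in snippet_lengths]
        self._iv: dict = {}

    # -- construction -------------------------------------------------
    def add(self, snippet: int, channel: int, start: int, end: int) -> None:
        T = self.snippet_lengths[snippet]
        start, end = max(0, int(start)), min(T, int(end))
        if end <= start:
            return
        self._iv.setdefault((snippet, channel), []).append((start, end))

    @staticmethod
    def _merge(intervals):
        intervals = sorted(intervals)
        out = [list(intervals[0])]
        for a, b in intervals[1:]:
            if a <= out[-1][1]:
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        return [tuple(iv) for iv in out]

    # -- queries ------------------------------------------------------
    def intervals(self, snippet: int, channel: int):
        iv = self._iv.get((snippet, channel))
        return self._merge(iv) if iv else []

    def intervals_any_channel(self, snippet: int):
        iv = []
        for c in range(self.n_channels):
            iv.extend(self.intervals(snippet, c))
        return self._merge(iv) if iv else []

    def overlaps(self, snippet: int, channels, start: int, end: int) -> bool:
        if np.isscalar(channels):
            channels = [channels]
        for c in channels:
            for a, b in self.intervals(snippet, c):
                if a < end and start < b:
                    return True
        return False

    def masked_array(self, snippet: int) -> np.ndarray:
        out = np.zeros((self.n_channels, self.snippet_lengths[snippet]), dtype=bool)
        for c in range(self.n_channels):
            for a, b in self.intervals(snippet, c):
                out[c, a:b] = True
        return out

    def total_masked(self) -> int:
        return sum(
            b - a
            for s in range(self.n_snippets)
            for c in range(self.n_channels)
            for a, b in self.intervals(s, c)
        )

    def is_empty(self) -> bool:
        return self.total_masked() == 0

    def issubset(self, other: "BlackoutMask") -> bool:
        for s in range(self.n_snippets):
            for c in range(self.n_channels):
                for a, b in self.intervals(s, c):
                    cov = np.zeros(b - a, dtype=bool)
                    for oa, ob in other.intervals(s, c):
                        lo, hi = max(a, oa), min(b, ob)
                        if hi > lo:
                            cov[lo - a:hi - a] = True
                    if not cov.all():
                        return False
        return True

    def expanded(self, back: int, fwd: int) -> "BlackoutMask":
        out = BlackoutMask(self.n_snippets, self.n_channels, self.snippet_lengths)
        for (s, c), iv in self._iv.items():
            for a, b in iv:
                out.add(s, c, a - back, b + fwd)
        return out


def build_pulse_template(
    group: SnippetGroup | list,
    pulse_index: int,
    cfg: PVRConfig,
    supersampled: list | None = None,
) -> PulseTemplate:
    """Template for one pulse: mean of the k nearest pulses by MSE.

    The candidate set includes the pulse of interest itself, so a spike
    present only in the cleaned pulse enters the template with weight 1/k
    and is attenuated by exactly that factor after subtraction (about 5%
    at the default k=20).

    Parameters
    ----------
    group : SnippetGroup or list of ndarray
        The snippets of one (fiber, shank) group; arrays are interpreted
        directly, a :class:`SnippetGroup` is preprocessed first unless
        ``supersampled`` is given.
    """
    if supersampled is not None:
        arrs = supersampled
    elif isinstance(group, SnippetGroup):
        arrs = [
            preprocess(s.data, s.rate, cfg.hp_cutoff_hz, cfg.supersample_factor,
                       cfg.resample_method)
            for s in group.snippets
        ]
    else:
        arrs = [np.atleast_2d(np.asarray(a, dtype=float)) for a in group]
    n = len(arrs)
    if n < cfg.k_neighbors:
        raise ValueError(
            f"group has {n} snippets, fewer than k_neighbors={cfg.k_neighbors}; "
            "use a smaller k_neighbors"
        )
    lon = min(a.shape[1] for a in arrs)
    loff = lon
    x_on = np.stack([a[:, :lon] for a in arrs])
    ref = x_on[pulse_index]
    mse = ((x_on - ref) ** 2).mean(axis=(1, 2))
    sel = np.argsort(mse, kind="stable")[: cfg.k_neighbors]
    x_off = np.stack([a[:, -loff:] for a in arrs])
    return PulseTemplate(x_on[sel].mean(axis=0), x_off[sel].mean(axis=0), pulse_index)


def merge_onset_offset(
    tpl: PulseTemplate,
    snippet_len: int,
    pulse_duration: int,
    pre: int,
    cfg: PVRConfig,
    at_supersampled_rate: bool = True,
) -> np.ndarray:
    """Join the onset and offset templates with a linear cross-fade.

    The overlap region (100 base-rate samples = 3.3 ms at 30 kHz) is centred
    on the pulse midpoint; onset weights ramp 1→0 while offset weights ramp
    0→1, summing to one at every sample so no discontinuity is introduced.
    All sample arguments are at the template's own rate (supersampled by
    default).
    """
    ov = cfg.overlap_samples * (cfg.supersample_factor if at_supersampled_rate else 1)
    if pulse_duration < ov:
        raise ValueError(
            f"pulse duration {pulse_duration} shorter than template overlap {ov}"
        )
    mid = pre + pulse_duration // 2
    a = mid - ov // 2
    b = a + ov
    if tpl.onset.shape[1] < b:
        raise ValueError("onset template does not reach the overlap region")
    off_origin = snippet_len - tpl.offset.shape[1]  # snippet index of offset[:,0]
    if off_origin > a:
        raise ValueError("offset template does not reach the overlap region")
    C = tpl.onset.shape[0]
    merged = np.empty((C, snippet_len), dtype=float)
    merged[:, :a] = tpl.onset[:, :a]
    merged[:, b:] = tpl.offset[:, b - off_origin:]
    w = np.linspace(1.0, 0.0, ov)
    merged[:, a:b] = w * tpl.onset[:, a:b] + (1.0 - w) * tpl.offset[:, a - off_origin:b - off_origin]
    return merged


def subtract_template(snippet: np.ndarray, merged_template: np.ndarray) -> np.ndarray:
    """Residual after per-channel template subtraction."""
    snippet = np.asarray(snippet, dtype=float)
    if snippet.shape != merged_template.shape:
        raise ValueError(
            f"shape mismatch: snippet {snippet.shape} vs template {merged_template.shape}"
        )
    return snippet - merged_template


def _window_bounds(j: int, n: int, half: int):
    """Symmetric window around intensity rank j, shrunk at the ends, >= 3 trials."""
    m = min(j, n - 1 - j, half)
    lo, hi = j - m, j + m + 1
    if hi - lo < 3:
        lo, hi = (0, 3) if j < n // 2 else (n - 3, n)
    return lo, hi


def detect_residual_pvr(
    residuals: list,
    intensities,
    cfg: PVRConfig,
    pre_samples: int,
    base_factor: int | None = None,
) -> BlackoutMask:
    """Flag samples where artifact survived subtraction.

    The residuals are differentiated in time and rectified; trials are
    ordered by light intensity and, for each trial/channel/time point, the
    rectified derivative is averaged over a window of
    ``residual_window_trials`` intensity-adjacent trials after dropping the
    single largest value (which protects genuine spikes from triggering the
    detector).  Samples where this statistic exceeds
    ``residual_threshold_sd`` times the standard deviation of the rectified
    derivative over the pre-stimulation span (pooled per channel across
    trials) are added to the mask of that trial.

    ``residuals`` are at the supersampled rate; flagged samples are stored
    at base rate (``base_factor`` defaults to ``cfg.supersample_factor``).
    """
    n = len(residuals)
    if n < cfg.residual_window_trials:
        raise ValueError(
            f"{n} trials is fewer than residual_window_trials="
            f"{cfg.residual_window_trials}"
        )
    factor = cfg.supersample_factor if base_factor is None else base_factor
    intensities = np.asarray(intensities, dtype=float)
    T = min(r.shape[1] for r in residuals)
    C = residuals[0].shape[0]
    R = np.stack([np.asarray(r)[:, :T] for r in residuals])
    D = np.abs(np.diff(R, axis=2))  # (n, C, T-1)
    order = np.argsort(intensities, kind="stable")
    d_ord = D[order]

    pre_d = max(1, pre_samples - 1)  # derivative indices fully inside the pre-onset span
    sd = D[:, :, :pre_d].std(axis=(0, 2))  # per channel, pooled across trials
    thr = cfg.residual_threshold_sd * sd  # (C,)

    half = cfg.residual_window_trials // 2
    mask = BlackoutMask(n, C, [r.shape[1] // factor for r in residuals])
    for j in range(n):
        lo, hi = _window_bounds(j, n, half)
        W = d_ord[lo:hi]
        stat = (W.sum(axis=0) - W.max(axis=0)) / (W.shape[0] - 1)
        flags = stat > thr[:, None]
        trial = int(order[j])
        for c, t in zip(*np.nonzero(flags)):
            b = int(t) // factor
            mask.add(trial, int(c), b, b + 1)
    return mask


def expand_blackout(mask: BlackoutMask, cfg: PVRConfig) -> BlackoutMask:
    """Grow every interval ``[a, b)`` to ``[a - 40, b + 20)`` (defaults), merged."""
    return mask.expanded(cfg.blackout_expand_back, cfg.blackout_expand_fwd)


@dataclass
class CleanResult:
    """Output of :func:`clean_group` for one (fiber, shank) group."""

    group: SnippetGroup
    cleaned: list  # base-rate residual snippets, (C, T) each
    residuals_ss: list  # supersampled residuals
    templates: list  # merged templates, supersampled
    mask: BlackoutMask  # base-rate, pre-expansion
    expanded_mask: BlackoutMask


def clean_group(group: SnippetGroup, cfg: PVRConfig | None = None) -> CleanResult:
    """Run the full artifact-removal chain on one snippet group.

    Preprocess (high-pass + supersample) every snippet, build a tailored
    template per pulse from its k nearest neighbours, join onset/offset
    templates over the overlap, subtract, detect residual artifacts, and
    expand the blackout mask.  Cleaned snippets are returned at base rate.
    """
    cfg = cfg or PVRConfig()
    if len(group) == 0:
        raise ValueError("empty snippet group")
    f = cfg.supersample_factor
    ss = [
        preprocess(s.data, s.rate, cfg.hp_cutoff_hz, f, cfg.resample_method)
        for s in group.snippets
    ]
    lon = min(a.shape[1] for a in ss)
    flat = np.stack([a[:, :lon] for a in ss]).reshape(len(ss), -1)
    mse = squareform(pdist(flat, metric="sqeuclidean")) / flat.shape[1]

    if len(ss) < cfg.k_neighbors:
        raise ValueError(
            f"group ({group.fiber_id},{group.shank_id}) has {len(ss)} snippets, "
            f"fewer than k_neighbors={cfg.k_neighbors}; use a smaller k_neighbors"
        )
    x_on = np.stack([a[:, :lon] for a in ss])
    x_off = np.stack([a[:, -lon:] for a in ss])
    residuals, templates = [], []
    for i, s in enumerate(group.snippets):
        sel = np.argsort(mse[i], kind="stable")[: cfg.k_neighbors]
        tpl = PulseTemplate(x_on[sel].mean(axis=0), x_off[sel].mean(axis=0), i)
        merged = merge_onset_offset(
            tpl, ss[i].shape[1], s.pulse.duration * f, s.pre * f, cfg
        )
        residuals.append(ss[i] - merged)
        templates.append(merged)

    pre_ss = group.snippets[0].pre * f
    mask = detect_residual_pvr(residuals, group.intensities, cfg, pre_ss, f)
    expanded = expand_blackout(mask, cfg)
    cleaned = [decimate(r, f) for r in residuals]
    logger.info(
        "group (fiber=%d, shank=%d): %d snippets cleaned, %d samples masked",
        group.fiber_id, group.shank_id, len(group), mask.total_masked(),
    )
    return CleanResult(group, cleaned, residuals, templates, mask, expanded)
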