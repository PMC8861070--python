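"""Inhibition-latency bootstrap and pre-inhibition split analysis.

The latency estimator asks how quickly firing falls to a stated percentage
of the pre-light baseline, bootstrapped across sorted units (1000 replicates
by default).  The split analysis asks whether trials with high pre-inhibition
activity keep higher activity after inhibition onset, separately for units
with low, moderate and high mean firing rates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "LatencyResult",
    "SplitResult",
    "bootstrap_latency",
    "pre_split_analysis",
]


@dataclass
class LatencyResult:
    """Bootstrap quartiles of the inhibition latency per suppression level."""

    levels: np.ndarray  # percent of pre-inhibition rate
    median_ms: np.ndarray
    q25_ms: np.ndarray
    q75_ms: np.ndarray
    replicates_ms: np.ndarray  # (n_boot, n_levels)

    def __post_init__(self):
        ok = np.isfinite(self.median_ms)
        if np.any(self.median_ms[ok] < 0):
            raise ValueError("latencies must be non-negative")


@dataclass
class SplitResult:
    """Per firing-rate group: high-minus-low pre-inhibition effect on post rate."""

    groups: list  # "low", "moderate", "high"
    effect_hz: np.ndarray  # mean over units
    sem_hz: np.ndarray
    p_value: np.ndarray  # two-sided one-sample t-test vs 0
    n: np.ndarray
    boundaries_hz: np.ndarray
    excluded_units: list


def bootstrap_latency(
    spike_times,
    pulses,
    levels,
    n_boot: int = 1000,
    bin_ms: float = 0.5,
    pre_ms: float = 30.0,
    post_ms: float | None = None,
    rate: float = 30000.0,
    smooth_bins: int = 1,
    seed: int | None = None,
    resample: str = "units",
) -> LatencyResult:
    """Bootstrap the latency to reach given percentages of the baseline rate.

    Parameters
    ----------
    spike_times : list of ndarray
        Spike times per sorted unit, in samples on the recording timebase.
    pulses : sequence of PulseEvent
    levels : sequence of float
        Percentages of the pre-onset baseline rate, each in (0, 100).
    n_boot : int
        Bootstrap replicates; units are resampled with replacement
        (``resample="trials"`` resamples pulses instead).
    bin_ms, smooth_bins
        Histogram bin width and the boxcar smoothing width (in bins) applied
        to each replicate's pooled histogram before the threshold crossing.
    seed : int
        Seed for the bootstrap resampling.

    Returns
    -------
    LatencyResult
        Median and quartiles (over replicates) of the first post-onset time
        at which the pooled rate falls to each level, in ms.
    """
    U = len(spike_times)
    if U < 2:
        raise ValueError("need at least two units to bootstrap across units")
    levels = np.asarray(levels, dtype=float)
    if np.any((levels <= 0) | (levels >= 100)):
        raise ValueError("levels must lie strictly between 0 and 100 percent")
    pulses = list(pulses)
    if not pulses:
        raise ValueError("no pulses")
    if post_ms is None:
        post_ms = max(p.duration for p in pulses) / rate * 1000.0
    edges = np.arange(-pre_ms, post_ms + bin_ms / 2, bin_ms)
    B = len(edges) - 1
    bin_s = bin_ms / 1000.0
    onsets = np.array([p.onset_sample for p in pulses])
    n_pulses = len(pulses)

    # per-unit, per-trial counts so either axis can be resampled
    counts = np.zeros((U, n_pulses, B))
    for u, st in enumerate(spike_times):
        st = np.asarray(st, dtype=float)
        for j, o in enumerate(onsets):
            rel_ms = (st - o) / rate * 1000.0
            sel = rel_ms[(rel_ms >= -pre_ms) & (rel_ms < post_ms)]
            if sel.size:
                counts[u, j], _ = np.histogram(sel, bins=edges)

    pre_bins = edges[:-1] < 0
    post_bins = ~pre_bins
    pooled_all = counts.sum(axis=(0, 1)) / (U * n_pulses * bin_s)
    if pooled_all[pre_bins].mean() == 0:
        raise ValueError("baseline rate is zero; latency undefined")

    rng = np.random.default_rng(seed)
    box = np.ones(max(1, int(smooth_bins))) / max(1, int(smooth_bins))
    post_edges = edges[:-1][post_bins]
    lat = np.full((n_boot, levels.size), np.nan)
    unit_rates = counts.sum(axis=1) / (n_pulses * bin_s)  # (U, B)
    trial_rates = counts.sum(axis=0) / (U * bin_s)  # (n_pulses, B)
    for b in range(n_boot):
        if resample == "units":
            idx = rng.integers(0, U, U)
            pooled = unit_rates[idx].mean(axis=0)
        elif resample == "trials":
            idx = rng.integers(0, n_pulses, n_pulses)
            pooled = trial_rates[idx].mean(axis=0)
        else:
            raise ValueError(f"unknown resample mode {resample!r}")
        if box.size > 1:
            pooled = np.convolve(pooled, box, mode="same")
        base = pooled[pre_bins].mean()
        if base <= 0:
            continue
        post_rate = pooled[post_bins]
        for li, lvl in enumerate(levels):
            hit = np.flatnonzero(post_rate <= base * lvl / 100.0)
            if hit.size:
                lat[b, li] = post_edges[hit[0]]
    med = np.nanpercentile(lat, 50, axis=0)
    q25 = np.nanpercentile(lat, 25, axis=0)
    q75 = np.nanpercentile(lat, 75, axis=0)
    return LatencyResult(levels, med, q25, q75, lat)


def pre_split_analysis(
    pre_counts,
    post_rates,
    unit_rates=None,
    boundaries=None,
) -> SplitResult:
    """Median-split each unit's trials by pre-inhibition count and test the
    post-onset rate difference per firing-rate tercile.

    Parameters
    ----------
    pre_counts : list of ndarray
        Per-unit spike counts in the pre-inhibition window, one entry per trial.
    post_rates : list of ndarray
        Per-unit post-onset rates (Hz), aligned with ``pre_counts``.
    unit_rates : ndarray, optional
        Mean firing rate per unit used for the tercile grouping; defaults to
        the mean pre-inhibition count per unit.
    boundaries : (float, float), optional
        Explicit group boundaries; defaults to data-driven terciles.

    Notes
    -----
    Trials are rank-split at the median pre-inhibition count (lower half vs
    upper half; the middle trial of an odd count belongs to neither).  Units
    whose pre counts are all identical are excluded and logged.  Per tercile,
    a two-sided one-sample t-test of the high-minus-low effects against zero
    is reported without multiple-comparison adjustment.
    """
    if len(pre_counts) != len(post_rates):
        raise ValueError("pre_counts and post_rates must align per unit")
    effects, kept_rates, excluded = [], [], []
    default_rates = []
    for u, (x, y) in enumerate(zip(pre_counts, post_rates)):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError(f"unit {u}: trial counts disagree")
        if x.size < 4:
            raise ValueError(f"unit {u}: needs at least 4 trials, has {x.size}")
        if x.max() == x.min():
            logger.info("pre_split_analysis: unit %d excluded (degenerate split)", u)
            excluded.append(u)
            continue
        order = np.argsort(x, kind="stable")
        half = x.size // 2
        low = order[:half]
        high = order[-half:]
        effects.append(y[high].mean() - y[low].mean())
        default_rates.append(x.mean())
        kept_rates.append(u)
    effects = np.asarray(effects)
    if effects.size < 2:
        raise ValueError("fewer than two units with a usable split")
    if unit_rates is None:
        rates = np.asarray(default_rates)
    else:
        rates = np.asarray(unit_rates, dtype=float)[kept_rates]
    if boundaries is None:
        boundaries = np.quantile(rates, [1 / 3, 2 / 3])
    boundaries = np.asarray(boundaries, dtype=float)
    labels = np.searchsorted(boundaries, rates, side="right")

    names = ["low", "moderate", "high"]
    eff = np.full(3, np.nan)
    sem = np.full(3, np.nan)
    pval = np.full(3, np.nan)
    ns = np.zeros(3, dtype=int)
    for g in range(3):
        e = effects[labels == g]
        ns[g] = e.size
        if e.size > 1:
            eff[g] = e.mean()
            sem[g] = _stats.sem(e)
            pval[g] = _stats.ttest_1samp(e, 0.0, alternative="two-sided").pvalue
        else:
            logger.warning("pre_split_analysis: group %s has n=%d", names[g], e.size)
    return SplitResult(names, eff, sem, pval, ns, boundaries, excluded)
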