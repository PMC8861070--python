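"""Ground-truthed synthetic sessions for hermetic testing of the pipeline.

A session is built additively: Gaussian background noise, biphasic spike
waveforms (troughs of 100-200 µV spread over neighbouring channels) whose
rates are optogenetically suppressed with millisecond latency during light
pulses, and photovoltaic artifacts whose amplitude is linear in light
intensity up to about 1000 µV and saturates at +6000 µV, with sharp onset
and offset transients (strongest temporal derivative ~260 µs after light
onset, lasting ~300 µs).  The three components and all spike times are
returned as ground truth, so ``block == noise + spikes + artifact`` holds
to machine precision.

The suppression model is phenomenological (thinned Poisson), not a
biophysical opsin model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .events import LightLog, RecordingBlock

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "pvr_amplitude",
    "pvr_waveform",
    "spike_shape",
    "generate_session",
    "scenario",
]


@dataclass
class SynthConfig:
    """Parameters of the synthetic session.

    Defaults mirror the recording conditions the pipeline targets: 30 kHz
    sampling, on the order of 500 pulses of 10 ms with a 0.1 ms commanded
    slope, four fibers and two electrode shanks, spike troughs between 100
    and 200 µV, and a PVR that is linear up to ~1000 µV and saturates at
    +6000 µV with an onset transient peaking in derivative 260 µs after
    onset for ~300 µs.
    """

    channels: int = 16
    rate: float = 30000.0
    n_pulses: int = 500
    pulse_ms: float = 10.0
    slope_ms: float = 0.1
    fibers: int = 4
    shanks: int = 2
    period_ms: float = 120.0
    channel_spacing_um: float = 50.0

    noise_sd_uv: float = 4.5

    n_units: int = 12  # ~0.75 sortable units per electrode
    trough_range_uv: tuple = (100.0, 200.0)
    unit_rate_hz: float = 10.0
    channel_spread: tuple = (1.0, 0.6, 0.3)  # primary, +-1, +-2 neighbours

    inhibition_latency_ms: float = 1.0
    inhibition_tau_ms: float = 1.0
    suppression: float = 0.05  # firing-rate factor under full inhibition
    recovery_ms: float = 5.0
    refractory_ms: float = 2.0

    pvr_slope_uv: float = 10.0  # µV per photodiode unit in the linear regime
    linear_limit_uv: float = 1000.0
    saturation_uv: float = 6000.0
    transient_peak_us: float = 260.0
    transient_fwhm_us: float = 300.0
    pvr_polarity: int = 1
    intensity_levels: tuple = (50.0, 100.0, 200.0, 400.0, 800.0)

    seed: int = 0

    def validate(self) -> list:
        errs = []
        pos = [
            ("channels", self.channels), ("rate", self.rate),
            ("n_pulses", self.n_pulses), ("pulse_ms", self.pulse_ms),
            ("slope_ms", self.slope_ms), ("fibers", self.fibers),
            ("shanks", self.shanks), ("period_ms", self.period_ms),
        ]
        for name, v in pos:
            if not v > 0:
                errs.append(f"{name} must be positive (got {v})")
        if self.noise_sd_uv < 0:
            errs.append("noise_sd_uv must be non-negative")
        if self.n_units < 0:
            errs.append("n_units must be non-negative")
        if not 0 <= self.suppression <= 1:
            errs.append("suppression must lie in [0, 1]")
        if self.channels % self.shanks != 0:
            errs.append("channels must divide evenly over shanks")
        if not self.linear_limit_uv < self.saturation_uv:
            errs.append("linear_limit_uv must be below saturation_uv")
        if self.pvr_slope_uv < 0:
            errs.append("pvr_slope_uv must be non-negative")
        if self.pvr_polarity not in (-1, 1):
            errs.append("pvr_polarity must be +1 or -1")
        if self.period_ms <= self.pulse_ms:
            errs.append("period_ms must exceed pulse_ms")
        return errs


@dataclass
class GroundTruth:
    """Exact additive decomposition of the synthetic block plus spike times."""

    spike_times: list  # per unit, block samples (trough time)
    unit_waveforms: list  # per unit, (channels, 60) µV
    noise: np.ndarray
    spikes_trace: np.ndarray
    artifact: np.ndarray
    artifact_intervals: list  # (start, end) base-rate intervals of transients
    pulse_onsets: np.ndarray  # scheduled, before half-max redefinition
    pulse_offsets: np.ndarray
    pulse_fibers: np.ndarray
    pulse_intensities: np.ndarray


def pvr_amplitude(intensity, cfg: SynthConfig):
    """Peak PVR amplitude (µV) for a photodiode intensity.

    An exponential-approach saturation law: linear with slope
    ``pvr_slope_uv`` at low intensity, asymptoting at ``saturation_uv``.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    s = cfg.saturation_uv
    out = s * (1.0 - np.exp(-cfg.pvr_slope_uv * intensity / s))
    return float(out) if out.ndim == 0 else out


def pvr_waveform(duration_s: float, rate: float, cfg: SynthConfig) -> np.ndarray:
    """Unit-amplitude PVR time course for one pulse.

    Sharp onset transient whose absolute temporal derivative peaks
    ``transient_peak_us`` after light onset and stays above half that peak
    for about ``transient_fwhm_us``; a near-flat plateau with a slow decay;
    and a mirrored offset transient returning to zero.  The waveform starts
    at light onset (zero before, by construction) and extends one transient
    extent past the light offset.
    """
    dt = 1.0 / rate
    t_peak = cfg.transient_peak_us * 1e-6
    sigma = cfg.transient_fwhm_us * 1e-6 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    extent = t_peak + 4.0 * sigma
    if duration_s <= extent:
        raise ValueError(
            f"pulse of {duration_s * 1e3:.3f} ms shorter than the transient "
            f"extent {extent * 1e3:.3f} ms"
        )
    n = int(round((duration_s + extent) * rate))
    t = np.arange(n) * dt
    g_on = np.exp(-((t - t_peak) ** 2) / (2 * sigma ** 2))
    rise = np.cumsum(g_on)
    rise /= rise[-1] if rise[-1] > 0 else 1.0
    # slow plateau decay, mild relative to the pulse duration
    decay = np.exp(-t / (50.0 * duration_s))
    wave = rise * decay
    g_off = np.exp(-((t - duration_s - t_peak) ** 2) / (2 * sigma ** 2))
    fall = np.cumsum(g_off)
    fall /= fall[-1] if fall[-1] > 0 else 1.0
    off_start = int(round(duration_s * rate))
    level = wave[off_start]
    wave = wave - level * fall
    wave = np.clip(wave, 0.0, None)
    peak = wave.max()
    if peak > 0:
        wave = wave / peak
    return cfg.pvr_polarity * wave


def spike_shape(rate: float, trough_uv: float, rng=None) -> np.ndarray:
    """Biphasic extracellular spike: difference of Gaussians, 60 samples,
    trough at sample 20, normalized to the requested trough amplitude."""
    t = (np.arange(60) - 20) / rate * 1000.0  # ms relative to trough
    w = -np.exp(-(t ** 2) / (2 * 0.15 ** 2)) + 0.35 * np.exp(
        -((t - 0.45) ** 2) / (2 * 0.35 ** 2)
    )
    w = w / abs(w.min()) * trough_uv
    return w


def _suppression_profile(times, onsets, offsets, cfg: SynthConfig, rate: float):
    """Spike-survival probability at absolute sample times (thinning weights)."""
    keep = np.ones(times.size)
    lat = cfg.inhibition_latency_ms * 1e-3 * rate
    tau = max(cfg.inhibition_tau_ms, 1e-6) * 1e-3 * rate
    rec = max(cfg.recovery_ms, 1e-6) * 1e-3 * rate
    s = cfg.suppression
    for o, f in zip(onsets, offsets):
        start = o + lat
        during = (times >= start) & (times < f)
        dt = times[during] - start
        keep[during] = s + (1 - s) * np.exp(-dt / tau)
        after = (times >= f) & (times < f + 10 * rec)
        if after.any():
            dt_f = f - start
            level_at_off = s + (1 - s) * np.exp(-dt_f / tau) if dt_f > 0 else 1.0
            keep[after] = 1.0 - (1.0 - level_at_off) * np.exp(-(times[after] - f) / rec)
    return keep


def generate_session(cfg: SynthConfig):
    """Generate a full synthetic session.

    Returns
    -------
    (RecordingBlock, LightLog, GroundTruth)
        The block is exactly ``noise + spikes + artifact``; identical
        configurations (including the seed) produce identical output.
    """
    errs = cfg.validate()
    if errs:
        raise ValueError("invalid config: " + "; ".join(errs))
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate
    C = cfg.channels
    per_shank = C // cfg.shanks
    shank_ids = np.repeat(np.arange(cfg.shanks), per_shank)
    positions = np.tile(np.arange(per_shank) * cfg.channel_spacing_um, cfg.shanks)

    period = int(round(cfg.period_ms * rate / 1000.0))
    dur = int(round(cfg.pulse_ms * rate / 1000.0))
    slope = max(1, int(round(cfg.slope_ms * rate / 1000.0)))
    lead = int(round(0.05 * rate))
    onsets = lead + np.arange(cfg.n_pulses) * period
    offsets = onsets + dur
    n_samples = int(offsets[-1] + lead)

    pulse_fibers = np.arange(cfg.n_pulses) % cfg.fibers
    levels = np.asarray(cfg.intensity_levels, dtype=float)
    # balance levels within each fiber so every (fiber, shank) group sees
    # (nearly) equal trial counts per light-power condition
    pulse_levels = np.empty(cfg.n_pulses)
    for f in range(cfg.fibers):
        idx = np.flatnonzero(pulse_fibers == f)
        reps = int(np.ceil(idx.size / levels.size))
        pulse_levels[idx] = rng.permutation(np.tile(levels, reps)[: idx.size])

    # light log: trapezoid pulses per fiber
    light = np.zeros((cfg.fibers, n_samples))
    ramp = np.arange(1, slope + 1) / slope
    for o, f_id, lev in zip(onsets, pulse_fibers, pulse_levels):
        light[f_id, o:o + slope] = ramp * lev
        light[f_id, o + slope:o + dur] = lev
        light[f_id, o + dur:o + dur + slope] = lev * ramp[::-1]

    noise = rng.normal(0.0, cfg.noise_sd_uv, (C, n_samples))

    # units and spikes
    spikes_trace = np.zeros((C, n_samples))
    spike_times, unit_waveforms = [], []
    spread = np.asarray(cfg.channel_spread, dtype=float)
    primaries = np.linspace(1, C - 2, max(cfg.n_units, 1)).round().astype(int)
    for u in range(cfg.n_units):
        trough = rng.uniform(*cfg.trough_range_uv)
        shape1d = spike_shape(rate, trough)
        wf = np.zeros((C, 60))
        pc = int(primaries[u])
        for off in range(-(spread.size - 1), spread.size):
            c = pc + off
            if 0 <= c < C and shank_ids[c] == shank_ids[pc]:
                wf[c] = shape1d * spread[abs(off)]
        unit_waveforms.append(wf)
        # homogeneous Poisson, thinned by the optogenetic suppression profile
        expected = cfg.unit_rate_hz * n_samples / rate
        n_cand = rng.poisson(expected)
        cand = np.sort(rng.uniform(0, n_samples, n_cand))
        keep_p = _suppression_profile(cand, onsets, offsets, cfg, rate)
        kept = cand[rng.uniform(size=n_cand) < keep_p].astype(int)
        # refractory period
        if kept.size:
            refr = int(round(cfg.refractory_ms * 1e-3 * rate))
            good = [kept[0]]
            for t in kept[1:]:
                if t - good[-1] >= refr:
                    good.append(t)
            kept = np.array(good)
        kept = kept[(kept >= 20) & (kept < n_samples - 40)]
        spike_times.append(kept)
        for t in kept:
            spikes_trace[:, t - 20:t + 40] += wf

    # PVR artifact
    artifact = np.zeros((C, n_samples))
    artifact_intervals = []
    if cfg.pvr_slope_uv > 0:
        wave = pvr_waveform(dur / rate, rate, cfg)
        L = wave.size
        # depth profile: artifact strongest near the fiber entry (top of shank)
        depth_frac = positions / max(positions.max(), 1.0)
        profile = 1.0 - 0.5 * depth_frac
        amps = pvr_amplitude(pulse_levels, cfg)
        t_ext = int(np.ceil(
            (cfg.transient_peak_us + 2 * cfg.transient_fwhm_us) * 1e-6 * rate
        ))
        for o, f_id, amp in zip(onsets, pulse_fibers, amps):
            stop = min(n_samples, o + L)
            seg = wave[: stop - o]
            # fiber-to-shank coupling: each fiber lights both shanks, the
            # paired shank slightly stronger
            for s in range(cfg.shanks):
                coup = 1.0 if (f_id % cfg.shanks) == s else 0.7
                ch = shank_ids == s
                artifact[ch, o:stop] += amp * coup * profile[ch][:, None] * seg
            artifact_intervals.append((int(o), int(o + t_ext)))
            artifact_intervals.append((int(o + dur), int(min(n_samples, o + dur + t_ext))))

    block = RecordingBlock(
        samples=noise + spikes_trace + artifact,
        rate=rate,
        channel_positions=positions,
        shank_ids=shank_ids,
    )
    log = LightLog(intensity=light, fiber_ids=np.arange(cfg.fibers), rate=None)
    truth = GroundTruth(
        spike_times=spike_times,
        unit_waveforms=unit_waveforms,
        noise=noise,
        spikes_trace=spikes_trace,
        artifact=artifact,
        artifact_intervals=artifact_intervals,
        pulse_onsets=onsets,
        pulse_offsets=offsets,
        pulse_fibers=pulse_fibers,
        pulse_intensities=pulse_levels,
    )
    logger.info(
        "synth: %d pulses, %d channels, %.1f s, %d units",
        cfg.n_pulses, C, n_samples / rate, cfg.n_units,
    )
    return block, log, truth


_SCENARIOS = {
    "default": {},
    "artifact-free": {"pvr_slope_uv": 0.0},
    "heavy-artifact": {"pvr_slope_uv": 50.0},
}


def scenario(name: str = "default", seed: int = 0, **overrides) -> SynthConfig:
    """One-command scenario presets; overrides apply on top of the preset."""
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    params = dict(_SCENARIOS[name])
    params.update(overrides)
    return replace(SynthConfig(seed=seed), **params)
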