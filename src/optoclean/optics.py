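"""Fiber-optics quantifications for side-emitting fibers.

Covers the angular emission profile of a polished side-emitting fiber and
its fit to a Lambertian cosine law, cylindrical power-density estimates at
a given radius around the fiber, grid addressability of a fiber-matrix
connector, and the PVR-matched light-intensity ratio between two fiber
configurations (e.g. a back-emission probe versus a fiber matrix).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmissionProfile",
    "FiberGeometry",
    "PVRTransferCurve",
    "LambertianFit",
    "IntensityRatioResult",
    "emission_at_angle",
    "roi_from_polygon",
    "fit_lambertian",
    "cylinder_area",
    "power_density",
    "addressable_fibers",
    "intensity_ratio",
]


@dataclass
class EmissionProfile:
    """Angle -> summed ROI intensity samples for one fiber.

    Angle zero points radially out of the fiber, 90 degrees along the fiber
    axis; emission values are summed gamma-uncorrected pixel intensities
    (arbitrary units).  Angles are conventionally measured in 25-degree
    increments.
    """

    angles_deg: np.ndarray
    emission: np.ndarray

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if self.angles_deg.shape != self.emission.shape:
            raise ValueError("angles and emission must have matching shapes")
        if np.any((self.angles_deg < 0) | (self.angles_deg > 90)):
            raise ValueError("angles must lie in [0, 90] degrees")
        if np.any(self.emission < 0):
            raise ValueError("emission values must be non-negative")


@dataclass
class FiberGeometry:
    """Side-emitting segment geometry; all lengths in millimetres, power in mW."""

    radius_mm: float
    emitting_length_mm: float
    total_power_mw: float

    def __post_init__(self):
        if self.radius_mm <= 0 or self.emitting_length_mm <= 0:
            raise ValueError("radius and emitting length must be positive")
        if self.total_power_mw < 0:
            raise ValueError("total power must be non-negative")


@dataclass
class PVRTransferCurve:
    """PVR amplitude time courses measured at increasing light intensities.

    ``amplitudes`` is (levels, channels, time) in µV; ``intensities`` are
    photodiode units, strictly increasing.  The PVR grows linearly with
    intensity up to about ``linear_limit`` (1000 µV) and saturates near
    ``saturation`` (+6000 µV).
    """

    intensities: np.ndarray
    amplitudes: np.ndarray
    onset_sample: int = 0
    linear_limit: float = 1000.0
    saturation: float = 6000.0

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 3 or self.amplitudes.shape[0] != self.intensities.size:
            raise ValueError("amplitudes must be (levels, channels, time)")
        if np.any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[1]


def emission_at_angle(image: np.ndarray, roi) -> float:
    """Summed pixel intensity over a region of interest.

    ``roi`` is either a boolean mask of the image shape or an
    ``(rows, cols)`` index pair.  Pixel values are used as stored
    (gamma-uncorrected).
    """
    image = np.asarray(image, dtype=float)
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != image.shape:
            raise ValueError("boolean ROI must match the image shape")
        if not roi.any():
            raise ValueError("empty ROI")
        return float(image[roi].sum())
    rows, cols = roi
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if rows.size == 0:
        raise ValueError("empty ROI")
    if (rows.min() < 0 or cols.min() < 0 or rows.max() >= image.shape[0]
            or cols.max() >= image.shape[1]):
        raise ValueError("ROI indices fall outside the image")
    return float(image[rows, cols].sum())


def roi_from_polygon(shape, vertices):
    """(rows, cols) indices of the pixels inside a polygon given as (row, col) vertices."""
    from skimage.draw import polygon

    vertices = np.asarray(vertices, dtype=float)
    rr, cc = polygon(vertices[:, 0], vertices[:, 1], shape=tuple(shape))
    return rr, cc


@dataclass
class LambertianFit:
    """Least-squares fit of ``I = I0 cos(angle)`` to an emission profile."""

    i0: float
    residual_norm: float

    def predict(self, angles_deg) -> np.ndarray:
        return self.i0 * np.cos(np.radians(np.asarray(angles_deg, dtype=float)))


def fit_lambertian(profile: EmissionProfile) -> LambertianFit:
    """Fit the Lambertian cosine law to an angular emission profile.

    A single amplitude I0 is estimated by least squares against the model
    I0*cos(angle); the residual 2-norm is returned as goodness of fit.
    """
    if np.unique(profile.angles_deg).size < 2:
        raise ValueError("need at least two distinct angles")
    c = np.cos(np.radians(profile.angles_deg))
    if np.allclose(c, 0):
        raise ValueError("degenerate design: all angles at 90 degrees")
    i0 = float(c @ profile.emission / (c @ c))
    res = float(np.linalg.norm(profile.emission - i0 * c))
    return LambertianFit(i0, res)


def cylinder_area(radius_mm: float, length_mm: float) -> float:
    """Lateral area of the cylinder surrounding the emitting segment, mm^2."""
    if radius_mm <= 0 or length_mm <= 0:
        raise ValueError("radius and length must be positive")
    return 2.0 * np.pi * radius_mm * length_mm


def power_density(geom: FiberGeometry, eval_radius_mm: float | None = None) -> float:
    """Power density (mW/mm^2) through a cylinder around the fiber.

    The emitted power is assumed to pass through the lateral surface of a
    cylinder of radius ``eval_radius_mm`` (default: the fiber surface) and
    the length of the emitting segment.
    """
    r = geom.radius_mm if eval_radius_mm is None else eval_radius_mm
    if r < geom.radius_mm:
        raise ValueError("evaluation radius cannot be smaller than the fiber radius")
    return geom.total_power_mw / cylinder_area(r, geom.emitting_length_mm)


def addressable_fibers(pitch_mm: float, area_mm2: float = 1.0) -> int:
    """Number of individually addressable fibers on a square grid.

    Positions at the given pitch are packed into a square of the given
    area; the count per side is floored.  At the 100 µm pitch resolvable
    by the scanner this gives 100 fibers per square millimetre.
    """
    if pitch_mm <= 0:
        raise ValueError("pitch must be positive")
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    side = np.sqrt(area_mm2)
    per_side = int(np.floor(side / pitch_mm + 1e-9))
    return per_side * per_side


@dataclass
class IntensityRatioResult:
    """Per-channel and mean intensity ratio between two fiber configurations."""

    per_channel: np.ndarray  # NaN where no match bracketed the target
    mean: float
    time_points: np.ndarray  # post-onset sample used per channel
    flagged_channels: list


def intensity_ratio(
    curve_a: PVRTransferCurve,
    curve_b: PVRTransferCurve,
    mode: str = "interp",
) -> IntensityRatioResult:
    """Light-intensity ratio that equalizes the PVR of two configurations.

    For each electrode, the post-onset time point where configuration A's
    maximal-intensity PVR is closest to the linear limit (1000 µV) is found;
    if A never reaches the limit, the time of its maximal amplitude is used.
    The intensity of configuration B producing the most similar PVR at that
    time point is then located (linear interpolation between measured levels
    by default, ``mode="nearest"`` snaps to a measured level) and the ratio
    is A's maximal intensity divided by that B intensity.  Channels whose
    target amplitude is not bracketed by B's measurements are flagged and
    excluded from the mean.
    """
    if curve_a.n_channels != curve_b.n_channels:
        raise ValueError("transfer curves must share channels")
    C = curve_a.n_channels
    ratios = np.full(C, np.nan)
    tpoints = np.zeros(C, dtype=int)
    flagged = []
    ia_max = curve_a.intensities[-1]
    for c in range(C):
        prof = curve_a.amplitudes[-1, c, curve_a.onset_sample:]
        if prof.max() < curve_a.linear_limit:
            t = int(np.argmax(prof))
        else:
            t = int(np.argmin(np.abs(prof - curve_a.linear_limit)))
        tpoints[c] = t
        target = prof[t]
        bvals = curve_b.amplitudes[:, c, curve_b.onset_sample + t]
        if not (bvals.min() <= target <= bvals.max()):
            flagged.append(c)
            logger.info("intensity_ratio: channel %d target %.1f µV not bracketed", c, target)
            continue
        if mode == "interp":
            order = np.argsort(bvals, kind="stable")
            ib = float(np.interp(target, bvals[order], curve_b.intensities[order]))
        elif mode == "nearest":
            ib = float(curve_b.intensities[np.argmin(np.abs(bvals - target))])
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if ib <= 0:
            flagged.append(c)
            continue
        ratios[c] = ia_max / ib
    valid = np.isfinite(ratios)
    mean = float(ratios[valid].mean()) if valid.any() else float("nan")
    return IntensityRatioResult(ratios, mean, tpoints, flagged)
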