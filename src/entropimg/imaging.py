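"""Sliding-window entropy parametric imaging.

A square analysis window (side expressed in pulse lengths, converted to
axial samples via c/(2 fs) and to scan lines via the lateral line pitch)
slides across the RF frame at steps of a fixed fraction of the window side.
The RF samples inside each fully contained window are concatenated line by
line into a 1-D series whose sample or Shannon entropy becomes one pixel of
a coarse parametric map; bilinear interpolation of the window-center values
restores the full frame size for display and ROI statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import RegularGridInterpolator

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import entropy
from .errors import (
    DegenerateImageError,
    GeometryError,
    MaskError,
    ParameterError,
)
from .rf import BModeImage, RFFrame

__all__ = [
    "EntropyConfig",
    "WindowGeometry",
    "ParametricMap",
    "window_geometry",
    "window_to_series",
    "entropy_map",
    "upsample_map",
    "overlay",
    "roi_mean",
    "SAMPLE_DISPLAY_RANGE",
    "SHANNON_DISPLAY_RANGE",
]

logger = logging.getLogger(__name__)

# Default overlay display ranges for the two estimators.
SAMPLE_DISPLAY_RANGE = (1.7, 3.0)
SHANNON_DISPLAY_RANGE = (3.8, 4.2)


@dataclass
class EntropyConfig:
    """Computational setting of the entropy imaging pipeline.

    Defaults are the recommended setting for hepatic RF data: a one
    pulse-length window, embedding dimension m = 4 (≈ samples per carrier
    cycle at fs/fc = 12/3), tolerance r = 0.1 of the window standard
    deviation, 50% window overlap, and a 200-bin histogram for the Shannon
    baseline.
    """

    wsl_pulse_lengths: float = 1.0
    m: int = 4
    r: float = 0.1
    overlap_fraction: float = 0.5
    shannon_bins: int = 200
    estimator: Literal["sample", "shannon"] = "sample"

    def __post_init__(self) -> None:
        if self.wsl_pulse_lengths <= 0:
            raise ParameterError("wsl_pulse_lengths must be positive")
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.r <= 0:
            raise ParameterError("r must be positive")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ParameterError("overlap_fraction must lie in (0, 1)")
        if self.shannon_bins < 2:
            raise ParameterError("shannon_bins must be >= 2")
        if self.estimator not in ("sample", "shannon"):
            raise ParameterError(f"unknown estimator {self.estimator!r}")


@dataclass
class WindowGeometry:
    """Sliding-window size and step, in samples/lines."""

    side_axial_samples: int
    side_lateral_lines: int
    step_axial: int
    step_lateral: int


@dataclass
class ParametricMap:
    """Coarse grid of per-window entropy values (NaN = undefined window)."""

    values: np.ndarray  # (n_axial_positions, n_lateral_positions)
    axial_origins: np.ndarray
    lateral_origins: np.ndarray
    source_shape: tuple[int, int]
    geometry: WindowGeometry

    @property
    def axial_centers(self) -> np.ndarray:
        return self.axial_origins + (self.geometry.side_axial_samples - 1) / 2.0

    @property
    def lateral_centers(self) -> np.ndarray:
        return self.lateral_origins + (self.geometry.side_lateral_lines - 1) / 2.0

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


def window_geometry(frame: RFFrame, config: EntropyConfig) -> WindowGeometry:
    """Physically square window geometry for a frame and config.

    The window side in mm is ``wsl_pulse_lengths * pulse_length_mm``;
    converted to axial samples through c/(2 fs) and to scan lines through
    the frame's lateral line pitch. Steps are ``overlap_fraction`` of each
    side, at least 1.
    """
    side_mm = config.wsl_pulse_lengths * frame.pulse_length_mm
    side_ax = int(round(side_mm / frame.axial_spacing_mm))
    side_lat = int(round(side_mm / frame.line_pitch_mm))
    side_ax = max(side_ax, 2)
    side_lat = max(side_lat, 1)
    if side_ax > frame.axial_samples or side_lat > frame.num_lines:
        raise GeometryError(
            f"window {side_ax}x{side_lat} exceeds frame "
            f"{frame.axial_samples}x{frame.num_lines}"
        )
    step_ax = max(1, int(round(config.overlap_fraction * side_ax)))
    step_lat = max(1, int(round(config.overlap_fraction * side_lat)))
    return WindowGeometry(side_ax, side_lat, step_ax, step_lat)


def window_to_series(window: np.ndarray) -> np.ndarray:
    """Concatenate a 2-D window into a 1-D series, line by line.

    Scan lines (columns) are taken in lateral order, each contributing its
    axial samples in depth order.
    """
    window = np.asarray(window)
    if window.size == 0:
        raise ParameterError("empty window")
    return window.ravel(order="F")


def _origins(length: int, side: int, step: int) -> np.ndarray:
    n = (length - side) // step + 1
    return np.arange(n) * step


def entropy_map(frame: RFFrame, config: EntropyConfig | None = None) -> ParametricMap:
    """Per-window entropy of an RF frame on the sliding-window grid.

    Only fully contained windows are evaluated (no boundary padding).
    Zero-variance windows and windows with no template matches are marked
    NaN and logged with their origin coordinates.
    """
    config = config or EntropyConfig()
    geo = window_geometry(frame, config)
    ax_orig = _origins(frame.axial_samples, geo.side_axial_samples, geo.step_axial)
    lat_orig = _origins(frame.num_lines, geo.side_lateral_lines, geo.step_lateral)
    values = np.full((ax_orig.size, lat_orig.size), np.nan)
    samples = np.asarray(frame.samples, dtype=float)
    for ia, a0 in enumerate(ax_orig):
        for il, l0 in enumerate(lat_orig):
            win = samples[a0:a0 + geo.side_axial_samples, l0:l0 + geo.side_lateral_lines]
            series = window_to_series(win)
            if series.std() == 0:
                logger.info("degenerate (zero-variance) window at origin (%d, %d)", a0, l0)
                continue
            if config.estimator == "sample":
                val = entropy.sample_entropy(series, config.m, config.r)
                if np.isnan(val):
                    logger.info("undefined sample entropy at window origin (%d, %d)", a0, l0)
            else:
                val = entropy.shannon_entropy(series, config.shannon_bins)
            values[ia, il] = val
    return ParametricMap(values, ax_orig, lat_orig,
                         (frame.axial_samples, frame.num_lines), geo)


def _fill_missing_nearest(values: np.ndarray) -> np.ndarray:
    """Replace NaN cells by the nearest valid cell (grid metric)."""
    from scipy.ndimage import distance_transform_edt

    mask = np.isnan(values)
    if not mask.any():
        return values
    idx = distance_transform_edt(mask, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def upsample_map(pmap: ParametricMap) -> np.ndarray:
    """Bilinearly interpolate window-center values to the full RF grid.

    Pixels beyond the outermost window centers take the nearest-center
    value. NaN cells are first replaced by their nearest valid neighbour
    (logged); an all-NaN map raises, and > 20% missing triggers a quality
    warning.
    """
    values = pmap.values
    n_missing = int(np.isnan(values).sum())
    if n_missing == values.size:
        raise DegenerateImageError("all windows undefined; nothing to interpolate")
    if n_missing:
        frac = n_missing / values.size
        msg = f"{n_missing}/{values.size} undefined windows filled by nearest-valid value"
        if frac > 0.2:
            import warnings

            warnings.warn(f"low-quality parametric map: {msg}", stacklevel=2)
        logger.info(msg)
        values = _fill_missing_nearest(values)

    n_ax, n_lat = pmap.source_shape
    ax_c = pmap.axial_centers
    lat_c = pmap.lateral_centers
    rows = np.clip(np.arange(n_ax), ax_c[0], ax_c[-1])
    cols = np.clip(np.arange(n_lat), lat_c[0], lat_c[-1])
    if values.shape[0] == 1 and values.shape[1] == 1:
        return np.full(pmap.source_shape, values[0, 0])
    if values.shape[0] == 1:
        interp = np.interp(cols, lat_c, values[0])
        return np.tile(interp, (n_ax, 1))
    if values.shape[1] == 1:
        interp = np.interp(rows, ax_c, values[:, 0])
        return np.tile(interp[:, None], (1, n_lat))
    rgi = RegularGridInterpolator((ax_c, lat_c), values, method="linear")
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    return rgi(np.stack([grid_r.ravel(), grid_c.ravel()], axis=1)).reshape(n_ax, n_lat)


def overlay(
    bmode: BModeImage,
    entropy_image: np.ndarray,
    display_range: tuple[float, float] = SAMPLE_DISPLAY_RANGE,
    roi: np.ndarray | None = None,
    cmap: str = "inferno",
    alpha: float = 1.0,
) -> np.ndarray:
    """Pseudo-color entropy over a grayscale B-mode; returns an RGB array.

    Entropy values are clipped to ``display_range`` and mapped through a
    perceptually ordered colormap; the color replaces (``alpha = 1``) or is
    blended into the B-mode inside ``roi`` (whole frame when ``roi`` is
    None).
    """
    lo, hi = display_range
    if lo >= hi:
        raise ParameterError(f"display range must have lo < hi, got ({lo}, {hi})")
    entropy_image = np.asarray(entropy_image, dtype=float)
    if entropy_image.shape != bmode.values.shape:
        raise ParameterError("entropy image and B-mode shapes differ")
    t = (np.clip(entropy_image, lo, hi) - lo) / (hi - lo)
    t = np.where(np.isnan(t), 0.0, t)
    colored = plt.get_cmap(cmap)(t)[..., :3]
    gray = np.repeat(bmode.values[..., None], 3, axis=-1)
    blended = (1.0 - alpha) * gray + alpha * colored
    if roi is None:
        return blended
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != bmode.values.shape:
        raise MaskError("ROI mask shape differs from the image")
    return np.where(roi[..., None], blended, gray)


def roi_mean(entropy_image: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Mean of the non-missing entropy pixels under an ROI mask.

    ``roi=None`` averages the whole image. Raises on an empty mask or when
    every masked pixel is missing.
    """
    entropy_image = np.asarray(entropy_image, dtype=float)
    if roi is None:
        vals = entropy_image.ravel()
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != entropy_image.shape:
            raise MaskError("ROI mask shape differs from the image")
        if not roi.any():
            raise MaskError("empty ROI mask")
        vals = entropy_image[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DegenerateImageError("no defined entropy values under the ROI")
    return float(vals.mean())
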