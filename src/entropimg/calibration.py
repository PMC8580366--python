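"""Calibration of the entropy computational setting (WSL, m, r).

Sweeps the window side length, embedding dimension and tolerance over a
labelled cohort, correlating the per-frame ROI-mean sample entropy with a
continuous reference (e.g. a fat-fraction surrogate, optionally
log-transformed), and selects the setting maximizing the Pearson
correlation. The pairwise-distance recursion is shared across all (m, r)
cells of a window, so the full grid costs little more than its largest m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .entropy import sample_entropy_grid
from .errors import DegenerateImageError, InsufficientDataError, ParameterError
from .imaging import EntropyConfig, _origins, window_geometry, window_to_series
from .rf import RFFrame

__all__ = ["SweepGrid", "CorrelationMatrix", "sweep", "best_setting", "frame_roi_entropy_grid"]

logger = logging.getLogger(__name__)


def _default_wsl() -> list[float]:
    return [1.0, 2.0, 3.0]


def _default_m() -> list[int]:
    return list(range(1, 11))


def _default_r() -> list[float]:
    return [round(0.05 * k, 2) for k in range(1, 11)]


@dataclass
class SweepGrid:
    """Grid of computational settings: WSL in pulse lengths, m, r."""

    wsl_values: Sequence[float] = field(default_factory=_default_wsl)
    m_values: Sequence[int] = field(default_factory=_default_m)
    r_values: Sequence[float] = field(default_factory=_default_r)

    def __post_init__(self) -> None:
        for name in ("wsl_values", "m_values", "r_values"):
            vals = list(getattr(self, name))
            if not vals:
                raise ParameterError(f"{name} must be nonempty")
            if sorted(vals) != vals:
                raise ParameterError(f"{name} must be sorted ascending")
            setattr(self, name, vals)


@dataclass
class CorrelationMatrix:
    """Pearson correlations indexed (wsl, m, r); NaN marks undefined cells."""

    r_p: np.ndarray
    wsl_values: list[float]
    m_values: list[int]
    r_values: list[float]
    n_frames: int


def frame_roi_entropy_grid(
    frame: RFFrame,
    grid: SweepGrid,
    wsl: float,
    roi: np.ndarray | None = None,
    overlap_fraction: float = 0.5,
) -> np.ndarray:
    """ROI-mean sample entropy of one frame for every (m, r) cell at one WSL.

    The ROI restriction keeps the windows whose center pixel falls inside
    the mask (equivalent to averaging the interpolated parametric image over
    the ROI, without paying for per-cell interpolation). Returns an
    ``(n_m, n_r)`` array, NaN where no window produced a defined value.
    """
    cfg = EntropyConfig(wsl_pulse_lengths=wsl, overlap_fraction=overlap_fraction)
    geo = window_geometry(frame, cfg)
    ax = _origins(frame.axial_samples, geo.side_axial_samples, geo.step_axial)
    lat = _origins(frame.num_lines, geo.side_lateral_lines, geo.step_lateral)
    acc = np.zeros((len(grid.m_values), len(grid.r_values)))
    cnt = np.zeros_like(acc)
    samples = np.asarray(frame.samples, dtype=float)
    for a0 in ax:
        for l0 in lat:
            if roi is not None:
                ca = a0 + (geo.side_axial_samples - 1) // 2
                cl = l0 + (geo.side_lateral_lines - 1) // 2
                if not roi[ca, cl]:
                    continue
            series = window_to_series(
                samples[a0:a0 + geo.side_axial_samples, l0:l0 + geo.side_lateral_lines]
            )
            if series.std() == 0:
                logger.info("degenerate window at (%d, %d) skipped in sweep", a0, l0)
                continue
            vals = sample_entropy_grid(series, grid.m_values, grid.r_values)
            defined = np.isfinite(vals)
            acc[defined] += vals[defined]
            cnt[defined] += 1
    out = np.full(acc.shape, np.nan)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out


def sweep(
    frames: Sequence[RFFrame],
    continuous_ref: Sequence[float],
    grid: SweepGrid | None = None,
    rois: Sequence[np.ndarray | None] | None = None,
    transform: Literal["log", "identity"] = "log",
) -> CorrelationMatrix:
    """Correlate ROI-mean sample entropy with a continuous reference.

    For every (WSL, m, r) cell the per-frame ROI-mean sample entropy is
    computed and its Pearson correlation with the (optionally
    log-transformed) reference recorded. Frames whose entropy is undefined
    at a cell are dropped pairwise; cells where more than half the frames
    are undefined are marked NaN.
    """
    grid = grid or SweepGrid()
    refs = np.asarray(continuous_ref, dtype=float)
    if len(frames) != refs.size:
        raise ParameterError("frames and continuous_ref lengths differ")
    if refs.size < 3:
        raise InsufficientDataError("sweep needs at least 3 labelled frames")
    if transform == "log":
        if np.any(refs <= 0):
            raise ParameterError("log transform requires strictly positive references")
        refs = np.log(refs)
    elif transform != "identity":
        raise ParameterError(f"unknown transform {transform!r}")
    if rois is None:
        rois = [None] * len(frames)

    n_w, n_m, n_r = len(grid.wsl_values), len(grid.m_values), len(grid.r_values)
    ent = np.full((len(frames), n_w, n_m, n_r), np.nan)
    for fi, (frame, roi) in enumerate(zip(frames, rois)):
        for wi, wsl in enumerate(grid.wsl_values):
            ent[fi, wi] = frame_roi_entropy_grid(frame, grid, wsl, roi)

    r_p = np.full((n_w, n_m, n_r), np.nan)
    for wi in range(n_w):
        for mi in range(n_m):
            for ri in range(n_r):
                y = ent[:, wi, mi, ri]
                ok = np.isfinite(y)
                if ok.sum() < max(3, len(frames) // 2 + 1):
                    continue
                if y[ok].std() == 0 or refs[ok].std() == 0:
                    continue
                r_p[wi, mi, ri] = np.corrcoef(refs[ok], y[ok])[0, 1]
    return CorrelationMatrix(r_p, list(grid.wsl_values), list(grid.m_values),
                             list(grid.r_values), len(frames))


def best_setting(matrix: CorrelationMatrix) -> tuple[float, int, float]:
    """Setting (wsl, m, r) with the maximum correlation.

    Exact ties are broken toward the smallest WSL (better spatial
    resolution), then smallest m, then smallest r.
    """
    r_p = matrix.r_p
    if np.all(np.isnan(r_p)):
        raise DegenerateImageError("correlation matrix has no defined cells")
    best = np.nanmax(r_p)
    # argwhere scans in (wsl, m, r) lexical order => first hit is the tie-break winner
    wi, mi, ri = np.argwhere(r_p == best)[0]
    return matrix.wsl_values[wi], matrix.m_values[mi], matrix.r_values[ri]
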