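"""Convolutional speckle phantoms with steatosis- and fibrosis-like scattering.

Each scan line is a 1-D point-scatterer reflectivity train convolved with a
Gaussian-modulated transmit pulse, emulating the acquisition used for liver
imaging: 3 MHz center frequency sampled at 12 MHz, 128 scan lines, ~2.3 mm
pulse length. No lateral point-spread coupling is simulated; per-line
convolution is sufficient to produce the speckle statistics that drive
entropy imaging.

Tissue effects
--------------
* Baseline parenchyma: scatterers arrive as a Poisson process along depth at
  ``scatterer_density`` per resolution cell (one pulse length), with
  standard-normal amplitudes. The default density of 3 per cell puts normal
  tissue in the pre-Rayleigh regime, leaving headroom for the steatosis
  effect below.
* Steatosis (``fat_level``): fat droplets act as newly added scatterers with
  increased density and scattering cross-section. Extra scatterers are added
  at a rate of ``fat_density_factor * fat_level`` times the baseline density,
  with amplitudes scaled by ``fat_gain``. Envelope amplitude rises and the
  speckle moves toward the fully developed (Rayleigh) regime, raising sample
  entropy.
* Fibrosis (``fibrosis_level``): heterogeneous scattering cross-sections are
  modelled as a lognormal amplitude multiplier of that sigma applied to every
  scatterer. Heavy-tailed amplitude dominance makes the normalized RF more
  bursty and *lowers* sample entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .rf import RFFrame, write_rf_frame

__all__ = [
    "PhantomSpec",
    "make_pulse",
    "simulate_frame",
    "simulate_cohort",
    "fat_level_to_hff_percent",
    "steatosis_grade",
    "fibrosis_score",
]


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic RF frame."""

    axial_samples: int = 2048
    num_lines: int = 128
    sampling_rate: float = 12e6  # Hz
    center_frequency: float = 3e6  # Hz
    pulse_length_mm: float = 2.3
    sound_speed: float = 1540.0  # m/s
    line_pitch_mm: float = 0.3
    scatterer_density: float = 3.0  # mean scatterers per resolution cell
    fat_level: float = 0.0  # steatosis severity in [0, 1]
    fat_gain: float = 1.5  # amplitude gain of fat-droplet scatterers
    fat_density_factor: float = 3.0  # added fat density per unit fat_level
    fibrosis_level: float = 0.0  # lognormal sigma of amplitude heterogeneity
    noise_floor: float = 0.0  # std of additive Gaussian RF noise
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.axial_samples, self.num_lines) < 1:
            raise ParameterError("frame dimensions must be positive")
        for name in ("sampling_rate", "center_frequency", "pulse_length_mm",
                     "sound_speed", "line_pitch_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 <= self.fat_level <= 1.0:
            raise ParameterError("fat_level must lie in [0, 1]")
        if self.scatterer_density < 0 or self.fibrosis_level < 0 or self.noise_floor < 0:
            raise ParameterError("density, fibrosis_level and noise_floor must be >= 0")

    @property
    def axial_spacing_mm(self) -> float:
        return self.sound_speed / (2.0 * self.sampling_rate) * 1e3

    @property
    def cell_samples(self) -> float:
        """Axial extent of one resolution cell (pulse length) in samples."""
        return self.pulse_length_mm / self.axial_spacing_mm


def _pulse_sigma_samples(spec: PhantomSpec) -> float:
    """Gaussian envelope sigma (in samples) from the -6 dB pulse length."""
    fwhm_samples = spec.pulse_length_mm / spec.axial_spacing_mm
    return fwhm_samples / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def make_pulse(spec: PhantomSpec) -> np.ndarray:
    """Gaussian-modulated sinusoid transmit pulse, unit peak envelope.

    The Gaussian envelope width is set so its -6 dB (half-amplitude) axial
    extent, converted through c/2, equals ``pulse_length_mm``; the kernel is
    truncated at +-3 sigma.
    """
    sigma = _pulse_sigma_samples(spec)
    half = int(np.ceil(3.0 * sigma))
    k = np.arange(-half, half + 1)
    envelope = np.exp(-(k ** 2) / (2.0 * sigma ** 2))
    carrier = np.cos(2.0 * np.pi * spec.center_frequency / spec.sampling_rate * k)
    return envelope * carrier


def simulate_frame(spec: PhantomSpec, seed: int | None = None) -> tuple[RFFrame, dict]:
    """Simulate one RF frame; returns the frame and a ground-truth record.

    Deterministic for a fixed seed (``seed`` overrides ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, lines = spec.axial_samples, spec.num_lines
    base_rate = spec.scatterer_density / spec.cell_samples  # per sample
    fat_rate = base_rate * spec.fat_density_factor * spec.fat_level
    sigma = _pulse_sigma_samples(spec)
    half = int(np.ceil(3.0 * sigma))
    omega = 2.0 * np.pi * spec.center_frequency / spec.sampling_rate
    offsets = np.arange(-half, half + 1)
    rf = np.zeros((n, lines))
    n_scatterers = 0
    for j in range(lines):
        k_base = rng.poisson(base_rate * n)
        k_fat = rng.poisson(fat_rate * n)
        k_tot = k_base + k_fat
        # continuous depths: echo phase is not quantized to the sample grid
        pos = rng.uniform(0.0, n, k_tot)
        amp = rng.standard_normal(k_tot)
        amp[k_base:] *= spec.fat_gain
        if spec.fibrosis_level > 0:
            amp *= rng.lognormal(0.0, spec.fibrosis_level, amp.size)
        if k_tot:
            centers = np.floor(pos).astype(np.int64)
            idx = centers[:, None] + offsets[None, :]
            t = idx - pos[:, None]
            echo = amp[:, None] * np.exp(-(t ** 2) / (2.0 * sigma ** 2)) * np.cos(omega * t)
            valid = (idx >= 0) & (idx < n)
            line = np.zeros(n)
            np.add.at(line, idx[valid], echo[valid])
            rf[:, j] = line
        n_scatterers += k_tot
    if spec.noise_floor > 0:
        rf += rng.normal(0.0, spec.noise_floor, rf.shape)
    frame = RFFrame(
        samples=rf,
        sampling_rate=spec.sampling_rate,
        center_frequency=spec.center_frequency,
        pulse_length_mm=spec.pulse_length_mm,
        sound_speed=spec.sound_speed,
        line_pitch_mm=spec.line_pitch_mm,
        frame_id=f"phantom_f{spec.fat_level:g}_b{spec.fibrosis_level:g}_s{spec.seed if seed is None else seed}",
    )
    truth = {
        "fat_level": spec.fat_level,
        "fibrosis_level": spec.fibrosis_level,
        "scatterer_density": spec.scatterer_density,
        "n_scatterers": int(n_scatterers),
        "seed": int(spec.seed if seed is None else seed),
    }
    return frame, truth


def fat_level_to_hff_percent(fat_level: float) -> float:
    """Surrogate hepatic fat fraction (percent) for a phantom fat level.

    An arbitrary monotone map chosen to span realistic values: normal
    parenchyma ~2%, severe steatosis >30%. Only its monotonicity matters.
    """
    return 2.0 + 60.0 * float(fat_level)


def steatosis_grade(fat_level: float) -> int:
    """Ordinal steatosis grade 0-3 from the phantom fat level (construction bins)."""
    if fat_level < 0.05:
        return 0
    if fat_level < 0.2:
        return 1
    if fat_level < 0.4:
        return 2
    return 3


def fibrosis_score(fibrosis_level: float) -> int:
    """Ordinal fibrosis score F0-F4 from the lognormal sigma (construction bins)."""
    return int(min(4, round(fibrosis_level / 0.25)))


def simulate_cohort(
    outdir: str | Path,
    n_per_level: int,
    fat_levels,
    fibrosis_levels=(0.0,),
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a labelled cohort of phantom frames and write it to disk.

    One frame per (fat_level, fibrosis_level, replicate) combination, written
    through the RF container I/O, plus a ``manifest.csv`` with columns
    ``rf_path, roi_path, continuous_ref, ordinal_grade, fibrosis_score``
    (and the generative levels for reference). Fully reproducible from
    ``seed``.
    """
    fat_levels = list(fat_levels)
    fibrosis_levels = list(fibrosis_levels)
    if not fat_levels or not fibrosis_levels or n_per_level < 1:
        raise ParameterError("need at least one level and one frame per level")
    base = base_spec if base_spec is not None else PhantomSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    idx = 0
    for fat in fat_levels:
        for fib in fibrosis_levels:
            for rep in range(n_per_level):
                frame_seed = int(seed + idx)
                spec = replace(base, fat_level=fat, fibrosis_level=fib, seed=frame_seed)
                frame, _ = simulate_frame(spec)
                stem = outdir / f"frame_{idx:04d}"
                write_rf_frame(frame, stem)
                rows.append(
                    {
                        "rf_path": str(stem.with_suffix(".rfbin")),
                        "roi_path": "",
                        "continuous_ref": fat_level_to_hff_percent(fat),
                        "ordinal_grade": steatosis_grade(fat),
                        "fibrosis_score": fibrosis_score(fib),
                        "fat_level": fat,
                        "fibrosis_level": fib,
                    }
                )
                idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
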