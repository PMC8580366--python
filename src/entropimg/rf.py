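"""Beamformed-RF frame container, file I/O, TGC, envelope and B-mode.

A frame is a 2-D array of beamformed RF samples, ``axial_samples x
num_lines``, plus the acquisition metadata needed to interpret it: sampling
rate, transducer center frequency, measured pulse length, assumed sound
speed and lateral line pitch. Sample ``k`` of a line sits at depth
``k * c / (2 * fs)`` (0-based, pulse-echo two-way convention).

On disk a frame is a raw little-endian binary (``.rfbin``, int16 or float32,
column-major: one scan line after another, each line's axial samples in
depth order) next to a JSON sidecar carrying shape, dtype and metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .errors import DegenerateImageError, FormatError, ParameterError

__all__ = [
    "RFFrame",
    "EnvelopeImage",
    "BModeImage",
    "read_rf_frame",
    "write_rf_frame",
    "apply_tgc",
    "hilbert_envelope",
    "log_compress",
    "save_bmode_png",
]

_SIDECAR_REQUIRED = (
    "shape",
    "dtype",
    "sampling_rate_hz",
    "center_frequency_hz",
    "pulse_length_mm",
    "sound_speed_m_s",
    "frame_id",
)
_DTYPES = {"int16": np.int16, "float32": np.float32}


@dataclass
class RFFrame:
    """One beamformed RF frame with acquisition metadata."""

    samples: np.ndarray  # (axial_samples, num_lines)
    sampling_rate: float  # Hz
    center_frequency: float  # Hz
    pulse_length_mm: float  # axial extent of the transmit pulse
    sound_speed: float = 1540.0  # m/s
    line_pitch_mm: float = 0.3  # lateral spacing between scan lines
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ParameterError("RF samples must be a 2-D array (axial x lines)")
        if self.sampling_rate <= 2 * self.center_frequency:
            raise ParameterError(
                "sampling_rate must exceed twice the center frequency "
                f"({self.sampling_rate:g} Hz vs fc {self.center_frequency:g} Hz)"
            )
        if self.pulse_length_mm <= 0:
            raise ParameterError("pulse_length_mm must be positive")
        if self.line_pitch_mm <= 0:
            raise ParameterError("line_pitch_mm must be positive")

    @property
    def axial_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def num_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_spacing_mm(self) -> float:
        """Depth increment per axial sample (two-way), in mm."""
        return self.sound_speed / (2.0 * self.sampling_rate) * 1e3

    def depths_cm(self) -> np.ndarray:
        """Depth of each axial sample, in cm."""
        return np.arange(self.axial_samples) * self.axial_spacing_mm / 10.0


@dataclass
class EnvelopeImage:
    """Magnitude of the analytic RF signal, same shape as the source frame."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ParameterError("envelope values must be nonnegative")


@dataclass
class BModeImage:
    """Log-compressed envelope, values in [0, 1]."""

    values: np.ndarray
    dynamic_range_db: float = 40.0


def write_rf_frame(frame: RFFrame, path: str | Path, dtype: str = "float32") -> Path:
    """Write ``frame`` as ``<path>.rfbin`` + ``<path>.json`` sidecar.

    ``path`` may be given with or without the ``.rfbin`` suffix. int16 data
    are stored losslessly as int16; anything else as float32 unless
    ``dtype`` says otherwise.
    """
    if dtype not in _DTYPES:
        raise FormatError(f"unsupported dtype {dtype!r} (use int16 or float32)")
    path = Path(path)
    if path.suffix == ".rfbin":
        path = path.with_suffix("")
    if frame.samples.dtype == np.int16:
        dtype = "int16"
    raw = np.ascontiguousarray(frame.samples.astype(_DTYPES[dtype]).T)
    bin_path = path.with_suffix(".rfbin")
    bin_path.write_bytes(raw.tobytes())
    sidecar = {
        "shape": [frame.axial_samples, frame.num_lines],
        "dtype": dtype,
        "sampling_rate_hz": frame.sampling_rate,
        "center_frequency_hz": frame.center_frequency,
        "pulse_length_mm": frame.pulse_length_mm,
        "sound_speed_m_s": frame.sound_speed,
        "line_pitch_mm": frame.line_pitch_mm,
        "frame_id": frame.frame_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return bin_path


def read_rf_frame(path: str | Path, sidecar_path: str | Path | None = None) -> RFFrame:
    """Read a frame written by :func:`write_rf_frame`.

    Raises :class:`FormatError` naming the first missing sidecar field, or
    describing a mismatch between the declared shape and the file size.
    """
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if not sidecar_path.exists():
        raise FileNotFoundError(str(sidecar_path))
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise FormatError(f"sidecar {sidecar_path} missing field {key!r}")
    dtype = meta["dtype"]
    if dtype not in _DTYPES:
        raise FormatError(f"unsupported dtype {dtype!r} in sidecar")
    axial, lines = (int(v) for v in meta["shape"])
    raw = np.frombuffer(path.read_bytes(), dtype=_DTYPES[dtype])
    if raw.size != axial * lines:
        raise FormatError(
            f"size mismatch: sidecar declares {axial}x{lines}={axial * lines} samples "
            f"but {path.name} holds {raw.size}"
        )
    samples = raw.reshape(lines, axial).T
    if dtype == "float32":
        samples = samples.astype(float)
    return RFFrame(
        samples=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        center_frequency=float(meta["center_frequency_hz"]),
        pulse_length_mm=float(meta["pulse_length_mm"]),
        sound_speed=float(meta["sound_speed_m_s"]),
        line_pitch_mm=float(meta.get("line_pitch_mm", 0.3)),
        frame_id=str(meta["frame_id"]),
    )


def apply_tgc(frame: RFFrame, attenuation_db_mhz_cm: float = 0.3) -> RFFrame:
    """Time-gain compensation with an exponentially increasing gain curve.

    Each sample at depth z (cm) is multiplied by
    ``10 ** (attenuation * f_MHz * 2 * z / 20)``, undoing a two-way
    propagation loss of ``attenuation`` dB/MHz-cm.
    """
    if attenuation_db_mhz_cm < 0:
        raise ParameterError("attenuation must be nonnegative")
    f_mhz = frame.center_frequency / 1e6
    gain_db = attenuation_db_mhz_cm * f_mhz * 2.0 * frame.depths_cm()
    gain = 10.0 ** (gain_db / 20.0)
    return replace(frame, samples=frame.samples * gain[:, None])


def hilbert_envelope(frame: RFFrame) -> EnvelopeImage:
    """Envelope image: magnitude of the analytic signal, line by line."""
    return EnvelopeImage(np.abs(hilbert(np.asarray(frame.samples, dtype=float), axis=0)))


def log_compress(env: EnvelopeImage, dynamic_range_db: float = 40.0) -> BModeImage:
    """Log-compress an envelope into a [0, 1] B-mode image.

    value = clip(1 + 20*log10(env / max(env)) / DR, 0, 1); the global
    maximum maps to 1 and anything at or below -DR dB maps to 0.
    """
    if dynamic_range_db <= 0:
        raise ParameterError("dynamic range must be positive")
    vals = env.values
    peak = vals.max()
    if peak <= 0:
        raise DegenerateImageError("all-zero envelope cannot be log-compressed")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(vals / peak)
    return BModeImage(np.clip(1.0 + db / dynamic_range_db, 0.0, 1.0), dynamic_range_db)


def save_bmode_png(bmode: BModeImage, path: str | Path) -> Path:
    """Export a B-mode image as 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.round(np.clip(bmode.values, 0.0, 1.0) * 255.0).astype(np.uint8)
    path = Path(path)
    Image.fromarray(arr, mode="L").save(path)
    return path
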