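"""Core data containers shared across the pipeline.

Conventions used throughout:

* Images are row-major 2-D ``uint8`` arrays, 0-based indices, isotropic pixel
  spacing in mm/pixel (default calibration: 20 mm depth over 400 rows = 0.05).
* Diameter series are sampled at 1 Hz for 50 s; respiration at 100 Hz.
* Breathing conditions: spontaneous (SB), 3-s paced (PB3, 0.333 Hz) and 10-s
  paced (PB10, 0.1 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError

__all__ = [
    "Condition",
    "PACED_CYCLE_S",
    "FLAG_OK",
    "FLAG_FALLBACK",
    "FLAG_MISSING",
    "DiameterSeries",
    "RespirationTrace",
    "ImageSequence",
]


class Condition(str, Enum):
    """Breathing condition labels."""

    SB = "SB"
    PB3 = "PB3"
    PB10 = "PB10"

    @classmethod
    def coerce(cls, value) -> "Condition":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError as exc:
            raise ConfigError(f"unknown condition {value!r}; expected one of "
                              f"{[c.value for c in cls]}") from exc


#: Nominal breath-cycle length (s) for the paced conditions.
PACED_CYCLE_S = {Condition.PB3: 3.0, Condition.PB10: 10.0}

FLAG_OK = "ok"
FLAG_FALLBACK = "fallback_threshold"
FLAG_MISSING = "missing"


@dataclass
class DiameterSeries:
    """A 1-Hz vein-diameter record (mm) with provenance labels.

    ``quality_flags`` carries one flag per sample: ``ok`` (primary threshold
    succeeded), ``fallback_threshold`` (automatic Otsu retry was used) or
    ``missing`` (value interpolated from neighbours).
    """

    values_mm: np.ndarray
    participant_id: str = ""
    condition: Condition | None = None
    repetition: int = 0
    quality_flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values_mm = np.asarray(self.values_mm, dtype=float)
        if self.values_mm.ndim != 1:
            raise ConfigError("values_mm must be one-dimensional")
        if not self.quality_flags:
            self.quality_flags = [FLAG_OK] * len(self.values_mm)
        if len(self.quality_flags) != len(self.values_mm):
            raise ConfigError("quality_flags length must match values_mm")
        valid = self.values_mm[[f != FLAG_MISSING for f in self.quality_flags]]
        if valid.size and np.any(valid <= 0):
            raise ConfigError("non-missing diameters must be positive")

    def __len__(self) -> int:
        return len(self.values_mm)

    @property
    def times_s(self) -> np.ndarray:
        """Sample times (s); 1 Hz from t = 0."""
        return np.arange(len(self.values_mm), dtype=float)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_s": self.times_s,
            "diameter_mm": self.values_mm,
            "quality_flag": self.quality_flags,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, participant_id: str = "",
                 condition=None, repetition: int = 0) -> "DiameterSeries":
        df = pd.read_csv(path)
        flags = (list(df["quality_flag"]) if "quality_flag" in df
                 else [FLAG_OK] * len(df))
        cond = Condition.coerce(condition) if condition is not None else None
        return cls(df["diameter_mm"].to_numpy(float), participant_id=participant_id,
                   condition=cond, repetition=repetition, quality_flags=flags)


@dataclass
class RespirationTrace:
    """Nasal-temperature respiration signal sampled at ``fs_hz`` (default 100)."""

    values: np.ndarray
    fs_hz: float = 100.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ConfigError("respiration values must be one-dimensional")
        if self.fs_hz <= 0:
            raise ConfigError("fs_hz must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs_hz

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times_s,
                      "temperature": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RespirationTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 100.0
        return cls(df["temperature"].to_numpy(float), fs_hz=fs)


@dataclass
class ImageSequence:
    """Calibrated 8-bit grayscale frames at 1 frame/s (short-axis vessel view)."""

    frames: np.ndarray            # (n_frames, rows, cols) uint8
    pixel_spacing_mm: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ConfigError("frames must be a (n, rows, cols) array")
        if self.frames.dtype != np.uint8:
            raise ConfigError("frames must be 8-bit (uint8)")
        if self.pixel_spacing_mm <= 0:
            raise ConfigError("pixel_spacing_mm must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def timestamps_s(self) -> np.ndarray:
        return np.arange(len(self), dtype=float)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save_tiff(self, path) -> None:
        """Write the sequence as one multi-page TIFF stack."""
        tifffile.imwrite(str(path), self.frames)

    def save_frames(self, directory) -> list[Path]:
        """Write one TIFF per second: frame_000.tif, frame_001.tif, ..."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, frame in enumerate(self.frames):
            p = directory / f"frame_{i:03d}.tif"
            tifffile.imwrite(str(p), frame)
            paths.append(p)
        return paths

    @classmethod
    def load(cls, path, pixel_spacing_mm: float) -> "ImageSequence":
        """Read a multi-page TIFF stack or a directory of per-frame TIFFs."""
        path = Path(path)
        if path.is_dir():
            files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
            if not files:
                raise ConfigError(f"no TIFF files in {path}")
            frames = np.stack([tifffile.imread(str(f)) for f in files])
        else:
            frames = tifffile.imread(str(path))
            if frames.ndim == 2:
                frames = frames[None]
        return cls(frames.astype(np.uint8), pixel_spacing_mm)
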