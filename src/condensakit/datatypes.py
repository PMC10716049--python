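"""Shared containers for images, traces, curves and ground truth.

The containers are deliberately thin: pixel data live in numpy arrays,
tabular measurements in pandas DataFrames, and every synthetic dataset
carries the :class:`GroundTruth` that produced it so downstream estimators
can be tested by parameter recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "GroundTruth",
    "ImageStack",
    "TimeTrace",
    "Curve",
    "ContactMatrix",
]


@dataclass
class GroundTruth:
    """True parameters behind a synthetic dataset.

    ``params`` holds scalar truths (e.g. ``true_Tc``, ``true_mobile_fraction``);
    ``extras`` holds array-valued truths such as label masks or per-frame
    object tables. ``seed`` is the RNG seed used, so regeneration is
    bit-identical.
    """

    params: dict[str, float]
    seed: int
    extras: dict[str, Any] = field(default_factory=dict)

    def to_sidecar(self) -> dict[str, Any]:
        """Scalar view suitable for a YAML/JSON sidecar file."""
        out = {k: (float(v) if isinstance(v, (int, float, np.floating, np.integer)) else v)
               for k, v in self.params.items()}
        out["seed"] = int(self.seed)
        return out


@dataclass
class ImageStack:
    """Pixel array with axes (t, z, y, x, channel), physical pixel size in nm."""

    pixels: np.ndarray
    pixel_size: float  # nm per pixel
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (nm)")
        if self.pixels.ndim != 5:
            raise ValueError(
                f"ImageStack expects 5 axes (t,z,y,x,channel), got {self.pixels.ndim}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @classmethod
    def from_2d(cls, frame: np.ndarray, pixel_size: float, bit_depth: int = 16) -> "ImageStack":
        return cls(frame[None, None, :, :, None], pixel_size, bit_depth)

    @property
    def n_timepoints(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[4]

    def frame(self, t: int = 0, z: int = 0, channel: int = 0) -> np.ndarray:
        return self.pixels[t, z, :, :, channel]

    def max_project(self, t: int = 0, channel: int = 0) -> np.ndarray:
        """Maximum-intensity z-projection of one timepoint/channel."""
        return self.pixels[t, :, :, :, channel].max(axis=0)

    def sum_project(self, t: int = 0, channel: int = 0) -> np.ndarray:
        """Sum z-projection (float) of one timepoint/channel."""
        return self.pixels[t, :, :, :, channel].astype(np.float64).sum(axis=0)


@dataclass
class TimeTrace:
    """Time-stamped intensity series for one ROI role."""

    t: np.ndarray  # seconds (negative = pre-bleach for FRAP)
    value: np.ndarray
    roi: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have the same length")


@dataclass
class Curve:
    """Sampled (x, y) function such as a turbidity ramp or dose-response table.

    ``replicate`` optionally labels repeated measurements at the same x.
    """

    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.x.shape:
                raise ValueError("replicate labels must match x length")


@dataclass
class ContactMatrix:
    """Frames x residues boolean ligand-contact record."""

    contacts: np.ndarray  # (n_frames, n_residues) bool
    residue_ids: np.ndarray  # e.g. 391..446
    cutoff: float = 6.0  # Angstrom, inclusive
    frame_stride_ps: float | None = None

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=bool)
        self.residue_ids = np.asarray(self.residue_ids)
        if self.contacts.ndim != 2:
            raise ValueError("contacts must be 2-D (frames x residues)")
        if self.contacts.shape[1] != self.residue_ids.size:
            raise ValueError("residue_ids length must match contact columns")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if len(set(self.residue_ids.tolist())) != self.residue_ids.size:
            raise ValueError("residue ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.contacts.shape[0]
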