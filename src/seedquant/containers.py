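"""In-memory containers shared across the imaging pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MicrographMeta", "Micrograph", "ZStack"]


@dataclass(frozen=True)
class MicrographMeta:
    """Assay metadata attached to a single micrograph."""

    species: str = ""
    aef_fraction: float = float("nan")
    time_h: float = float("nan")
    replicate_id: int = 0


@dataclass(frozen=True)
class Micrograph:
    """A single 2-D grayscale fluorescence image plus assay metadata.

    ``pixels`` is a non-empty 2-D array of finite, non-negative
    intensities within the stated bit range.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    meta: MicrographMeta = field(default_factory=MicrographMeta)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:  # color: average channels to grayscale
            px = px.astype(np.float64).mean(axis=-1)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(px.astype(np.float64))):
            raise ValueError("pixels must be finite")
        if px.min() < 0 or px.max() > 2 ** self.bit_depth - 1:
            raise ValueError("intensities outside bit range")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ZStack:
    """An ordered stack of equally shaped 2-D slices.

    ``z_step`` is the axial distance between consecutive slices in
    micrometers.
    """

    slices: np.ndarray
    z_step: float = 1.0
    bit_depth: int = 16
    meta: MicrographMeta = field(default_factory=MicrographMeta)

    def __post_init__(self) -> None:
        s = np.asarray(self.slices)
        if s.ndim != 3 or s.shape[0] < 2:
            raise ValueError("a z-stack needs >= 2 equally shaped slices")
        if self.z_step <= 0:
            raise ValueError("z_step must be > 0")
        object.__setattr__(self, "slices", s)

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])
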