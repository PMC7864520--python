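"""Synthetic fluorescence micrograph rendering.

Turns a fibril mass fraction into 2-D images (and z-stacks) with the two
aggregate morphologies seen in seeded SAA assays: "dotted" (isolated
puncta; a Poisson point process of Gaussian blobs) and "mesh" (a single
connected filament network; a branched correlated random walk).  Both are
blurred with a Gaussian point-spread function, placed on Gaussian read
noise and quantised to the requested bit depth.

The aggregate signal budget is linear in mass fraction with a fixed
per-element amplitude, so the per-pixel brightness SD of the rendered
image grows monotonically with the amount of aggregate - the property the
quantification stage measures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import Micrograph, MicrographMeta, ZStack

__all__ = ["ImagingParams", "render_micrograph", "render_zstack"]

_MORPHOLOGIES = ("dotted", "mesh")


@dataclass(frozen=True)
class ImagingParams:
    """Rendering parameters for one synthetic micrograph or z-stack.

    ``signal_scale`` is the mean above-background intensity per pixel
    contributed by aggregates at mass fraction 1 (before blurring, which
    conserves it); ``blobs_at_full`` / ``path_len_at_full`` set the spatial
    granularity of the dotted / mesh morphologies at full conversion.
    """

    height: int = 128
    width: int = 128
    z_slices: int = 1
    background_mean: float = 500.0
    background_sd: float = 20.0
    morphology: str = "dotted"
    psf_sigma: float = 1.2
    bit_depth: int = 16
    rng_seed: int = 0
    signal_scale: float = 150.0
    blobs_at_full: int = 40
    blob_sigma: float = 2.5
    path_len_at_full: int = 1200
    z_step: float = 2.0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")
        if self.morphology not in _MORPHOLOGIES:
            raise ValueError(f"morphology must be one of {_MORPHOLOGIES}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.background_sd < 0 or self.psf_sigma < 0:
            raise ValueError("background_sd and psf_sigma must be >= 0")


def _dotted_field(mass_fraction: float, p: ImagingParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Poisson-placed Gaussian puncta with fixed per-blob intensity."""
    field = np.zeros((p.height, p.width))
    n_blobs = int(round(mass_fraction * p.blobs_at_full))
    if mass_fraction > 0:
        n_blobs = max(1, n_blobs)
    if n_blobs == 0:
        return field
    per_blob = p.signal_scale * p.height * p.width / p.blobs_at_full
    ys = rng.uniform(0, p.height, n_blobs)
    xs = rng.uniform(0, p.width, n_blobs)
    for y, x in zip(ys, xs):
        field[int(y) % p.height, int(x) % p.width] += per_blob
    return gaussian_filter(field, p.blob_sigma, mode="wrap")


def _mesh_field(mass_fraction: float, p: ImagingParams,
                rng: np.random.Generator) -> np.ndarray:
    """One connected branched filament drawn as a correlated random walk.

    Branches start from pixels already on the filament, so the network is
    connected by construction.
    """
    field = np.zeros((p.height, p.width))
    total_len = int(round(mass_fraction * p.path_len_at_full))
    if mass_fraction > 0:
        total_len = max(8, total_len)
    if total_len == 0:
        return field
    per_px = p.signal_scale * p.height * p.width / p.path_len_at_full

    visited: list[tuple[int, int]] = []
    y = int(rng.uniform(0, p.height))
    x = int(rng.uniform(0, p.width))
    theta = rng.uniform(0, 2 * np.pi)
    segment = 0
    max_segment = 120  # start a new branch every ~120 steps
    for _ in range(total_len):
        field[y, x] += per_px
        visited.append((y, x))
        theta += rng.normal(0.0, 0.35)
        # unit lattice step: consecutive pixels stay 8-connected
        y += int(round(np.sin(theta)))
        x += int(round(np.cos(theta)))
        if not 0 <= y < p.height:
            y = min(max(y, 0), p.height - 1)
            theta = -theta
        if not 0 <= x < p.width:
            x = min(max(x, 0), p.width - 1)
            theta = np.pi - theta
        segment += 1
        if segment >= max_segment:
            y, x = visited[int(rng.integers(len(visited)))]
            theta = rng.uniform(0, 2 * np.pi)
            segment = 0
    # local saturation: revisited pixels cannot get arbitrarily bright,
    # keeping the filament brightness roughly uniform along its length
    np.clip(field, 0.0, 2.0 * per_px, out=field)
    return gaussian_filter(field, max(p.psf_sigma, 0.8), mode="wrap")


def _finish(field: np.ndarray, p: ImagingParams,
            rng: np.random.Generator) -> np.ndarray:
    img = gaussian_filter(field, p.psf_sigma, mode="wrap")
    img = img + rng.normal(p.background_mean, p.background_sd, field.shape)
    top = 2 ** p.bit_depth - 1
    img = np.clip(np.rint(img), 0, top)
    return img.astype(np.uint8 if p.bit_depth == 8 else np.uint16)


def render_micrograph(mass_fraction: float, params: ImagingParams,
                      meta: MicrographMeta | None = None) -> Micrograph:
    """Render one 2-D micrograph for a given fibril mass fraction.

    Deterministic for a fixed ``params.rng_seed``.  At mass fraction 0 the
    image is pure background, so its brightness SD is about
    ``background_sd``.
    """
    if not 0.0 <= mass_fraction <= 1.0:
        raise ValueError("mass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(params.rng_seed)
    if params.morphology == "dotted":
        field = _dotted_field(mass_fraction, params, rng)
    else:
        field = _mesh_field(mass_fraction, params, rng)
    pixels = _finish(field, params, rng)
    return Micrograph(pixels=pixels, bit_depth=params.bit_depth,
                      meta=meta or MicrographMeta())


def render_zstack(mass_fraction: float, params: ImagingParams,
                  meta: MicrographMeta | None = None) -> ZStack:
    """Render a z-stack whose occupied z-extent grows with mass fraction.

    The aggregate pattern is shared across occupied slices (one coherent
    3-D object centred in z); unoccupied slices are pure background.  The
    number of occupied slices is ``round(mass_fraction * z_slices)``.
    """
    if params.z_slices < 2:
        raise ValueError("render_zstack needs z_slices >= 2")
    if not 0.0 <= mass_fraction <= 1.0:
        raise ValueError("mass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(params.rng_seed)
    if params.morphology == "dotted":
        field = _dotted_field(mass_fraction, params, rng)
    else:
        field = _mesh_field(mass_fraction, params, rng)
    field = gaussian_filter(field, params.psf_sigma, mode="wrap")

    n_occ = int(round(mass_fraction * params.z_slices))
    if mass_fraction > 0:
        n_occ = max(1, n_occ)
    lo = (params.z_slices - n_occ) // 2
    occupied = range(lo, lo + n_occ)

    top = 2 ** params.bit_depth - 1
    slices = np.empty((params.z_slices, params.height, params.width))
    for z in range(params.z_slices):
        img = field.copy() if z in occupied else np.zeros_like(field)
        img += rng.normal(params.background_mean, params.background_sd,
                          field.shape)
        slices[z] = np.clip(np.rint(img), 0, top)
    slices = slices.astype(np.uint8 if params.bit_depth == 8 else np.uint16)
    return ZStack(slices=slices, z_step=params.z_step,
                  bit_depth=params.bit_depth, meta=meta or MicrographMeta())
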