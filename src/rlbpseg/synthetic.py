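"""Synthetic phantoms emulating a warped multi-atlas segmentation problem.

A phantom is an ellipsoidal structure in a noisy two-class intensity image:
the ground-truth mask is the ellipsoid, the noiseless image is background
mean outside and foreground mean inside with a Gaussian-blurred transition,
and i.i.d. Gaussian intensity noise is added on top.

An *atlas set* emulates atlases nonlinearly registered to the target with
residual registration error: each atlas is the same underlying phantom seen
through an independent smooth random displacement field (i.i.d. Gaussian
vector noise smoothed with a Gaussian filter, then rescaled so its RMS
magnitude equals the requested amplitude in voxels) plus fresh intensity
noise.  Image and label are warped by the same field — trilinear
interpolation for intensities, nearest-neighbor for labels — so each
atlas's label remains a valid segmentation of its own image.

All randomness derives from the single spec seed through independent named
substreams, so any subset of the outputs is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fusion import AtlasSet
from .volume_io import LabelMap, Volume

__all__ = ["PhantomSpec", "make_phantom", "make_atlas_set"]

# substream tags for the per-purpose RNGs
_NOISE, _WARP, _ATLAS_NOISE = 11, 22, 33


@dataclass
class PhantomSpec:
    """Conditions of one synthetic segmentation problem.

    ``displacement_amplitude`` is the post-smoothing RMS displacement in
    voxels; ``displacement_scale`` is the smoothing sigma of the random
    field, i.e. the spatial coherence length of the simulated registration
    error.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    semi_axes: tuple[float, float, float] = (12.0, 10.0, 9.0)
    center: tuple[float, float, float] | None = None
    fg_mean: float = 120.0
    bg_mean: float = 60.0
    noise_sd: float = 10.0
    blur_sigma: float = 1.0
    n_atlases: int = 10
    displacement_amplitude: float = 1.5
    displacement_scale: float = 4.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.displacement_amplitude < 0:
            raise ValueError("noise sd and displacement amplitude must be >= 0")
        if self.n_atlases < 1:
            raise ValueError("n_atlases must be >= 1")
        c = self.center if self.center is not None else tuple((s - 1) / 2.0 for s in self.shape)
        self.center = c
        for ax in range(3):
            if c[ax] - self.semi_axes[ax] < 0 or c[ax] + self.semi_axes[ax] > self.shape[ax] - 1:
                raise ValueError(
                    f"ellipsoid (axis {ax}: center {c[ax]}, semi-axis "
                    f"{self.semi_axes[ax]}) does not fit in grid {self.shape}"
                )


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in spec.shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, spec.center, spec.semi_axes))
    return q <= 1.0


def _noiseless_image(spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    field_ = mask.astype(np.float64)
    if spec.blur_sigma > 0:
        field_ = ndimage.gaussian_filter(field_, spec.blur_sigma)
    return spec.bg_mean + (spec.fg_mean - spec.bg_mean) * field_


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """The target image and its ground-truth mask, deterministic in the seed."""
    mask = _ellipsoid_mask(spec)
    image = _noiseless_image(spec, mask)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, _NOISE])
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return (
        Volume(image, spec.spacing),
        LabelMap(mask.astype(np.uint8), spec.spacing),
    )


def _displacement_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random (3, X, Y, Z) field with RMS magnitude = amplitude."""
    raw = rng.normal(size=(3, *spec.shape))
    smooth = np.stack([ndimage.gaussian_filter(raw[c], spec.displacement_scale) for c in range(3)])
    rms = np.sqrt(np.mean(np.sum(smooth ** 2, axis=0)))
    if rms == 0:
        return np.zeros_like(smooth)
    return smooth * (spec.displacement_amplitude / rms)


def make_atlas_set(spec: PhantomSpec) -> AtlasSet:
    """N warped atlases of the phantom with independent registration error.

    With zero displacement amplitude and zero noise every atlas equals the
    noiseless target and its truth mask exactly.
    """
    mask = _ellipsoid_mask(spec)
    clean = _noiseless_image(spec, mask)
    grid = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in spec.shape], indexing="ij")

    images, labels = [], []
    for i in range(spec.n_atlases):
        if spec.displacement_amplitude > 0:
            warp_rng = np.random.default_rng([spec.seed, _WARP, i])
            disp = _displacement_field(spec, warp_rng)
            coords = [g + d for g, d in zip(grid, disp)]
            img = ndimage.map_coordinates(clean, coords, order=1, mode="nearest")
            lab = ndimage.map_coordinates(mask.astype(np.uint8), coords, order=0, mode="nearest")
        else:
            img = clean.copy()
            lab = mask.astype(np.uint8)
        if spec.noise_sd > 0:
            noise_rng = np.random.default_rng([spec.seed, _ATLAS_NOISE, i])
            img = img + noise_rng.normal(0.0, spec.noise_sd, size=spec.shape)
        images.append(Volume(img, spec.spacing))
        labels.append(LabelMap(lab, spec.spacing))
    return AtlasSet(images, labels)
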