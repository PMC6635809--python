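"""Edge front end: opponent channels and oriented, polarity-split S cells.

An input image is first split into an intensity channel and two broadly
tuned color-opponent channels (red-green and blue-yellow) following the
Itti-Koch saliency construction.  Each channel is then filtered with a bank
of odd-symmetric Gabor filters at ``n_orientations`` undirected orientations
spaced pi/n apart.  The signed filter output is split into two
contrast-polarity maps and, per pixel, every orientation except the one with
the maximal response magnitude is zeroed (winner-orientation rule; ties go
to the lowest orientation index).

Polarity convention.  For an undirected orientation u (the edge tangent),
the filter normal is n = u + pi/2.  A response is assigned to the L map when
the bright side of the edge lies toward +n, and to the D map when it lies
toward -n.  For the color channels "bright" reads as the positive opponent
sign (e.g. red-green vs green-red edges).  An image and its contrast
inversion 1 - p therefore produce exactly swapped L and D maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .config import ModelConfig

L, D = 0, 1  # polarity axis indices used throughout the package


@dataclass
class ChannelSet:
    """Intensity and color-opponent rasters of one image."""

    intensity: np.ndarray
    rg: np.ndarray
    by: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"intensity": self.intensity, "rg": self.rg, "by": self.by}


@dataclass
class OrientedEdgeVolume:
    """S-cell responses over a pyramid.

    ``levels[k]`` has shape (n_orientations, 2, H_k, W_k); axis 1 is the
    contrast polarity (L, D).  Non-negative, and per pixel at most one
    orientation bin is nonzero across both polarities.
    """

    levels: list[np.ndarray]
    orientations: np.ndarray  # undirected angles, radians in [0, pi)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def directed(self, k: int) -> np.ndarray:
        """View level k as (2*n_orientations, 2, H, W) directed channels.

        The polarity label of a directed channel is the contrast of the
        figure it would own: channel theta with polarity L is an edge whose
        bright side lies toward theta + pi/2.  For theta in [pi, 2*pi) this
        is the D map of the underlying undirected orientation, so the two
        halves of the directed stack carry swapped polarity axes.  The two
        members of an opposing pair, (theta, L) and (theta + pi, D), share
        the same S input.
        """
        s = self.levels[k]
        return np.concatenate([s, s[:, ::-1]], axis=0)


def to_channels(image: np.ndarray) -> ChannelSet:
    """Split an image in [0, 1] into intensity and opponent channels.

    Grayscale input yields zero color channels.  The opponency follows the
    broadly tuned construction of the Itti-Koch saliency model:
    R = r - (g+b)/2, G = g - (r+b)/2, B = b - (r+g)/2,
    Y = (r+g)/2 - |r-g|/2 - b, with rg = R - G and by = B - Y.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    if image.ndim == 2:
        z = np.zeros_like(image)
        return ChannelSet(intensity=image, rg=z, by=z.copy())
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W) or (H, W, 3) image, got {image.shape}")
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    intensity = (r + g + b) / 3.0
    R = r - (g + b) / 2.0
    G = g - (r + b) / 2.0
    B = b - (r + g) / 2.0
    Y = (r + g) / 2.0 - np.abs(r - g) / 2.0 - b
    return ChannelSet(intensity=intensity, rg=R - G, by=B - Y)


@lru_cache(maxsize=64)
def _gabor_bank(
    n_orientations: int, wavelength: float, aspect: float
) -> tuple[np.ndarray, ...]:
    """Odd-symmetric Gabor kernels in array coordinates, one per orientation.

    Kernel positive lobe lies toward the +normal side (normal = u + pi/2 in
    the y-up convention), so correlation is positive when the bright side of
    an edge lies toward +normal.
    """
    sigma_n = wavelength / 4.0
    sigma_t = sigma_n / aspect
    radius = int(np.ceil(3.0 * max(sigma_n, sigma_t)))
    dr, dc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    x, y = dc.astype(float), -dr.astype(float)
    kernels = []
    for i in range(n_orientations):
        u = i * np.pi / n_orientations
        phi = u + np.pi / 2.0
        xn = x * np.cos(phi) + y * np.sin(phi)
        xt = -x * np.sin(phi) + y * np.cos(phi)
        env = np.exp(-0.5 * (xn**2 / sigma_n**2 + xt**2 / sigma_t**2))
        k = env * np.sin(2.0 * np.pi * xn / wavelength)
        k /= np.linalg.norm(k)
        kernels.append(k)
    return tuple(kernels)


def oriented_edges(
    raster: np.ndarray,
    n_orientations: int = 8,
    wavelength: float = 8.0,
    aspect: float = 0.5,
) -> np.ndarray:
    """Oriented, polarity-split S-cell responses of a single raster.

    Returns an array of shape (n_orientations, 2, H, W): axis 1 is the
    polarity (L, D).  Only the winning orientation per pixel is kept.
    """
    raster = np.asarray(raster, dtype=float)
    if not np.all(np.isfinite(raster)):
        raise ValueError("raster must be finite")
    responses = np.stack(
        [
            ndimage.correlate(raster, k, mode="reflect")
            for k in _gabor_bank(n_orientations, wavelength, aspect)
        ]
    )
    # Winner-orientation rule: keep only the maximal-magnitude orientation.
    # The winner is the lowest orientation index within a small relative
    # tolerance of the maximum, so that exact ties (e.g. at square corners)
    # resolve identically for an image and its contrast inversion.
    mag = np.abs(responses)
    tie_eps = 1e-9 * mag.max()  # absolute, so near-cancellation pixels resolve stably
    near_max = mag >= mag.max(axis=0) - tie_eps
    winner = near_max.argmax(axis=0)  # first True -> lowest tied index
    keep = winner[None] == np.arange(n_orientations)[:, None, None]
    responses = np.where(keep, responses, 0.0)
    return np.stack([np.maximum(responses, 0.0), np.maximum(-responses, 0.0)], axis=1)


def edge_volume(
    channel_pyramid: list[np.ndarray], config: ModelConfig
) -> OrientedEdgeVolume:
    """Apply :func:`oriented_edges` at every pyramid level of one channel."""
    levels = [
        oriented_edges(
            lvl,
            n_orientations=config.n_orientations,
            wavelength=config.filter_wavelength,
            aspect=config.filter_aspect,
        )
        for lvl in channel_pyramid
    ]
    return OrientedEdgeVolume(levels=levels, orientations=config.undirected_angles())
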