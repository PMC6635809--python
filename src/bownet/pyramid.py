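"""Multiscale image pyramid.

Successive anti-aliased downsampling of a raster by a fixed factor.  With
the default factor 2 and five levels the pyramid spans five octaves; the
half-octave variant is ``factor=sqrt(2), n_levels=10``.

Upsampling back to a finer level uses align-corners bilinear interpolation
so that identical shapes give the identity and constants are preserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def _level_shape(shape: tuple[int, int], factor: float, k: int) -> tuple[int, int]:
    return (
        int(np.ceil(shape[0] / factor**k)),
        int(np.ceil(shape[1] / factor**k)),
    )


@dataclass
class Pyramid:
    """Ordered list of rasters; level 0 is the input resolution."""

    levels: list[np.ndarray]
    factor: float

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def shape(self, k: int) -> tuple[int, int]:
        return self.levels[k].shape

    def upsample_to(self, raster: np.ndarray, from_level: int, to_level: int) -> np.ndarray:
        """Resample ``raster`` (defined at ``from_level``) to ``to_level``'s grid."""
        if from_level < to_level:
            raise ValueError(
                f"can only upsample coarse-to-fine: level {from_level} -> {to_level}"
            )
        if raster.shape != self.shape(from_level):
            raise ValueError("raster shape does not match its stated level")
        return resize_bilinear(raster, self.shape(to_level))


def build_pyramid(raster: np.ndarray, n_levels: int = 5, factor: float = 2.0) -> Pyramid:
    """Blur-and-decimate pyramid of ``raster``.

    Each level is a Gaussian blur (sigma = factor/2, reflect padding) of the
    previous level followed by decimation.  For an integer factor the
    decimation is exact subsampling ``[::factor]``; otherwise the blurred
    level is resampled onto the target grid bilinearly.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ValueError("build_pyramid expects a 2-D raster")
    min_size = factor ** (n_levels - 1)
    if min(raster.shape) <= min_size:
        raise ValueError(
            f"raster of shape {raster.shape} too small for {n_levels} levels at "
            f"factor {factor}; both dimensions must exceed {min_size:.0f}"
        )
    levels = [raster]
    sigma = factor / 2.0
    int_factor = int(factor) if float(factor).is_integer() else None
    for k in range(1, n_levels):
        prev = levels[-1]
        blurred = ndimage.gaussian_filter(prev, sigma=sigma, mode="reflect")
        if int_factor is not None:
            nxt = blurred[::int_factor, ::int_factor]
        else:
            nxt = resize_bilinear(blurred, _level_shape(raster.shape, factor, k))
        levels.append(nxt)
    return Pyramid(levels=levels, factor=factor)


def resize_bilinear(raster: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Align-corners bilinear resampling to an exact target shape."""
    raster = np.asarray(raster, dtype=float)
    if raster.shape == tuple(target_shape):
        return raster.copy()
    h, w = raster.shape
    th, tw = target_shape
    rows = np.linspace(0.0, h - 1.0, th) if th > 1 else np.array([(h - 1) / 2.0])
    cols = np.linspace(0.0, w - 1.0, tw) if tw > 1 else np.array([(w - 1) / 2.0])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(raster, [rr, cc], order=1, mode="nearest")
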