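"""Decoding B-cell activity into a border-ownership vector field.

The final B-cell activity at the finest pyramid level is summed over
contrast polarity (which makes the read-out invariant to figure-ground
contrast) and converted to a population vector: each directed channel
contributes its activity along the unit vector of its preferred figure
side (the border orientation rotated +90 degrees).  The magnitude of the
resultant is the border-ownership strength, its direction the continuous
figure-side label.

Signed, per-image-normalized BOS values compare the decoded direction with
a ground-truth figure direction: the sign is positive when the two agree to
within 90 degrees, and magnitudes are divided by the image-wide maximum so
signed values lie in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import TWO_PI

__all__ = [
    "FigureGroundField",
    "combine_polarity",
    "combine_grouping",
    "population_vector",
    "fuse_channels",
    "normalize_bos",
    "scene_point_bos",
    "angular_difference",
]


@dataclass
class FigureGroundField:
    """Per-pixel border-ownership strength and figure-side direction."""

    magnitude: np.ndarray
    angle: np.ndarray  # radians in [0, 2*pi)
    normalized: bool = False

    @property
    def vx(self) -> np.ndarray:
        return self.magnitude * np.cos(self.angle)

    @property
    def vy(self) -> np.ndarray:
        return self.magnitude * np.sin(self.angle)

    @classmethod
    def from_components(cls, vx: np.ndarray, vy: np.ndarray) -> "FigureGroundField":
        return cls(
            magnitude=np.hypot(vx, vy),
            angle=np.mod(np.arctan2(vy, vx), TWO_PI),
        )


def angular_difference(a, b) -> np.ndarray:
    """Smallest absolute circular difference between two angles, in [0, pi]."""
    return np.abs(np.mod(np.asarray(a) - np.asarray(b) + np.pi, TWO_PI) - np.pi)


def combine_polarity(b_level: np.ndarray) -> np.ndarray:
    """Sum the L and D polarities of a (n_directed, 2, H, W) B-cell level."""
    if b_level.ndim != 4 or b_level.shape[1] != 2:
        raise ValueError("expected B-cell level of shape (n_directed, 2, H, W)")
    return b_level.sum(axis=1)


def combine_grouping(g_level: np.ndarray) -> np.ndarray:
    """Sum the L and D polarities of a (2, H, W) grouping level."""
    if g_level.ndim != 3 or g_level.shape[0] != 2:
        raise ValueError("expected grouping level of shape (2, H, W)")
    return g_level.sum(axis=0)


def population_vector(combined: np.ndarray, directed_angles: np.ndarray) -> FigureGroundField:
    """Vector sum of directed B activity along preferred figure sides.

    ``combined`` has shape (n_directed, H, W); channel d points toward
    ``directed_angles[d] + pi/2``.  Opposing channels contribute opposite
    unit vectors, so the resultant encodes the pairwise BOS differences.
    """
    if combined.shape[0] != directed_angles.shape[0]:
        raise ValueError("channel count does not match the number of directed angles")
    side = directed_angles + np.pi / 2.0
    vx = np.tensordot(np.cos(side), combined, axes=(0, 0))
    vy = np.tensordot(np.sin(side), combined, axes=(0, 0))
    return FigureGroundField.from_components(vx, vy)


def fuse_channels(
    fields: list[FigureGroundField], weights=(0.8, 0.1, 0.1)
) -> FigureGroundField:
    """Weighted vector sum of per-channel fields (intensity, rg, by)."""
    weights = np.asarray(weights, dtype=float)
    if len(fields) != weights.size:
        raise ValueError("one weight per field required")
    total = weights.sum()
    if not np.isclose(total, 1.0):
        warnings.warn(
            f"channel weights sum to {total:.3f}; renormalizing to 1", stacklevel=2
        )
        weights = weights / total
    vx = sum(w * f.vx for w, f in zip(weights, fields))
    vy = sum(w * f.vy for w, f in zip(weights, fields))
    return FigureGroundField.from_components(vx, vy)


def normalize_bos(field: FigureGroundField, fg_orientation: np.ndarray) -> np.ndarray:
    """Signed, per-image-normalized BOS raster.

    ``fg_orientation`` holds the ground-truth figure direction on boundary
    pixels and NaN elsewhere.  On boundary pixels the result is
    ``sign * magnitude / max(magnitude)`` with a positive sign when the
    decoded direction lies within 90 degrees of the truth; off-boundary
    pixels are NaN.  An all-zero field maps to all zeros (with a warning)
    rather than dividing by zero.
    """
    if field.magnitude.shape != fg_orientation.shape:
        raise ValueError("field and ground-truth rasters must share a shape")
    peak = float(field.magnitude.max())
    if peak == 0.0:
        warnings.warn("all-zero BOS field; normalized BOS set to 0", stacklevel=2)
        scaled = np.zeros_like(field.magnitude)
    else:
        scaled = field.magnitude / peak
    diff = angular_difference(field.angle, fg_orientation)
    sign = np.where(diff < np.pi / 2.0, 1.0, -1.0)
    signed = sign * scaled
    signed[field.magnitude == 0.0] = 0.0
    return np.where(np.isfinite(fg_orientation), signed, np.nan)


def scene_point_bos(
    signed_bos: np.ndarray, location: tuple[int, int], window_radius: float = 2.0
) -> float:
    """Average signed BOS over a disc around a scene point.

    Pixels without a defined value (NaN, i.e. off the annotated boundary)
    are excluded from the average; ``window_radius=0`` reads one pixel.
    """
    r, c = location
    h, w = signed_bos.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"scene point {location} outside image of shape {signed_bos.shape}")
    rad = int(np.floor(window_radius))
    r0, r1 = max(r - rad, 0), min(r + rad, h - 1)
    c0, c1 = max(c - rad, 0), min(c + rad, w - 1)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    disc = (rr - r) ** 2 + (cc - c) ** 2 <= window_radius**2
    vals = signed_bos[rr, cc][disc]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())
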