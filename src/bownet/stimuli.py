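"""Synthetic stimuli, simulated cell responses, and raster/annotation I/O.

The canonical laboratory stimulus for border-ownership experiments is a
uniform square on a uniform background.  :func:`make_square_stimulus` builds
such images together with exact geometric ground truth: the set of boundary
pixels and, at each boundary pixel, the direction pointing from the border
into the figure (the "figure side").

Ground-truth figure directions follow the package-wide angle convention
(see :mod:`bownet.config`): 0 = rightward, counterclockwise positive,
y up.  Edge pixels take the inward normal of their side; corner pixels take
the diagonal inward direction, which is what the gradient of the
distance-to-figure transform yields there.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import TWO_PI

__all__ = [
    "ScenePointRecord",
    "AnnotatedImage",
    "make_square_stimulus",
    "sample_scene_points",
    "simulate_cell_responses",
    "read_image",
    "write_boundary_annotation",
    "read_boundary_annotation",
    "write_scene_point_table",
    "read_scene_point_table",
]


@dataclass
class ScenePointRecord:
    """A boundary location at which a border-ownership signal is measured.

    ``bos_values`` holds one value per stimulus repeat for a (simulated or
    recorded) cell, or a single entry for the deterministic model.
    """

    scene_point_id: int
    row: int
    col: int
    true_side: float  # ground-truth figure direction, radians in [0, 2*pi)
    bos_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_side = float(np.mod(self.true_side, TWO_PI))
        if not np.all(np.isfinite(self.bos_values)):
            raise ValueError("bos_values must be finite")


@dataclass
class AnnotatedImage:
    """An image plus optional boundary / figure-side ground truth.

    ``fg_orientation`` is an angle raster in radians, defined exactly on the
    pixels of ``boundary_mask`` and NaN elsewhere.
    """

    pixels: np.ndarray
    boundary_mask: np.ndarray | None = None
    fg_orientation: np.ndarray | None = None
    scene_points: list[ScenePointRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = p
        if self.boundary_mask is None:
            self.boundary_mask = np.zeros(p.shape[:2], dtype=bool)
        if self.fg_orientation is None:
            self.fg_orientation = np.full(p.shape[:2], np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def make_square_stimulus(
    image_size: int,
    square_side: int,
    center: tuple[int, int] | None = None,
    polarity: str = "light",
    background: float = 0.25,
    figure: float = 0.75,
) -> AnnotatedImage:
    """Uniform square on a uniform background with geometric ground truth.

    Parameters
    ----------
    image_size : int
        Side of the (square) image in pixels; must be >= 16.
    square_side : int
        Side of the figure square in pixels.
    center : (row, col), optional
        Centre of the square; defaults to the image centre.  The square must
        lie fully inside the image.
    polarity : {"light", "dark"}
        ``"light"`` draws a bright square on a dark background; ``"dark"``
        the exact contrast inversion (pixel map 1 - p, because the default
        gray levels are symmetric around 0.5).
    """
    if image_size < 16:
        raise ValueError(f"image_size must be >= 16, got {image_size}")
    if square_side < 2:
        raise ValueError(f"square_side must be >= 2, got {square_side}")
    if polarity not in ("light", "dark"):
        raise ValueError(f"polarity must be 'light' or 'dark', got {polarity!r}")
    if center is None:
        center = (image_size // 2, image_size // 2)
    r0 = center[0] - square_side // 2
    c0 = center[1] - square_side // 2
    r1, c1 = r0 + square_side - 1, c0 + square_side - 1
    if r0 < 0 or c0 < 0 or r1 >= image_size or c1 >= image_size:
        raise ValueError(
            f"square rows {r0}..{r1}, cols {c0}..{c1} not fully inside a "
            f"{image_size}x{image_size} image"
        )

    lo, hi = (background, figure) if polarity == "light" else (1 - background, 1 - figure)
    pixels = np.full((image_size, image_size), lo, dtype=float)
    pixels[r0 : r1 + 1, c0 : c1 + 1] = hi

    boundary = np.zeros((image_size, image_size), dtype=bool)
    boundary[r0, c0 : c1 + 1] = True
    boundary[r1, c0 : c1 + 1] = True
    boundary[r0 : r1 + 1, c0] = True
    boundary[r0 : r1 + 1, c1] = True

    fg = np.full((image_size, image_size), np.nan)
    rows, cols = np.nonzero(boundary)
    # Inward normal per side; corners get the diagonal inward direction.
    d_row = np.where(rows == r0, 1, 0) + np.where(rows == r1, -1, 0)
    d_col = np.where(cols == c0, 1, 0) + np.where(cols == c1, -1, 0)
    # y is up: a downward row step is a negative y displacement.
    fg[rows, cols] = np.mod(np.arctan2(-d_row, d_col), TWO_PI)

    return AnnotatedImage(pixels=pixels, boundary_mask=boundary, fg_orientation=fg)


def sample_scene_points(image: AnnotatedImage, n_points: int) -> list[ScenePointRecord]:
    """Pick ``n_points`` evenly spaced boundary pixels as scene points."""
    rows, cols = np.nonzero(image.boundary_mask)
    if rows.size == 0:
        raise ValueError("image has no boundary annotation")
    n_points = min(n_points, rows.size)
    idx = np.linspace(0, rows.size - 1, n_points).round().astype(int)
    return [
        ScenePointRecord(
            scene_point_id=i,
            row=int(rows[j]),
            col=int(cols[j]),
            true_side=float(image.fg_orientation[rows[j], cols[j]]),
        )
        for i, j in enumerate(idx)
    ]


def simulate_cell_responses(
    scene_points: list[ScenePointRecord],
    gain: float,
    noise_sd: float,
    n_repeats: int,
    seed: int,
) -> list[ScenePointRecord]:
    """Simulate a noisy border-ownership cell from reference BOS values.

    Each input record must carry a single reference BOS in ``bos_values``
    (typically the model's signed BOS at that scene point, or the ideal
    value +1).  Per repeat, the simulated response is
    ``gain * reference + N(0, noise_sd**2)``, i.i.d. across repeats and
    scene points.  Reproducible for a fixed ``seed``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (noise variance is undefined otherwise)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for rec in scene_points:
        if len(rec.bos_values) < 1:
            raise ValueError(f"scene point {rec.scene_point_id} has no reference BOS")
        ref = float(rec.bos_values[0])
        draws = gain * ref + noise_sd * rng.standard_normal(n_repeats)
        out.append(
            dataclasses.replace(rec, bos_values=[float(v) for v in draws])
        )
    return out


def read_image(path: str | Path) -> AnnotatedImage:
    """Read a raster image (PNG/JPEG/TIFF), scaled to [0, 1], no annotations."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # backends raise format-specific errors
        raise OSError(f"could not read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"image {path} has values outside [0, 1] after scaling")
    return AnnotatedImage(pixels=arr)


# ---------------------------------------------------------------------------
# Plain-text annotation formats


def write_boundary_annotation(image: AnnotatedImage, path: str | Path) -> None:
    """One row per boundary pixel: row, col, angle_radians (CSV)."""
    rows, cols = np.nonzero(image.boundary_mask)
    pd.DataFrame(
        {"row": rows, "col": cols, "angle_radians": image.fg_orientation[rows, cols]}
    ).to_csv(path, index=False)


def read_boundary_annotation(path: str | Path, shape: tuple[int, int]):
    """Inverse of :func:`write_boundary_annotation`; returns (mask, angles)."""
    df = pd.read_csv(path)
    mask = np.zeros(shape, dtype=bool)
    ang = np.full(shape, np.nan)
    mask[df["row"], df["col"]] = True
    ang[df["row"], df["col"]] = df["angle_radians"]
    return mask, ang


def write_scene_point_table(records: list[ScenePointRecord], path: str | Path) -> None:
    """Long-format CSV: scene_point_id, row, col, true_side, repeat_index, bos."""
    rows = [
        {
            "scene_point_id": r.scene_point_id,
            "row": r.row,
            "col": r.col,
            "true_side": r.true_side,
            "repeat_index": i,
            "bos": v,
        }
        for r in records
        for i, v in enumerate(r.bos_values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scene_point_table(path: str | Path) -> list[ScenePointRecord]:
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("scene_point_id", sort=True):
        grp = grp.sort_values("repeat_index")
        out.append(
            ScenePointRecord(
                scene_point_id=int(pid),
                row=int(grp["row"].iloc[0]),
                col=int(grp["col"].iloc[0]),
                true_side=float(grp["true_side"].iloc[0]),
                bos_values=[float(v) for v in grp["bos"]],
            )
        )
    return out
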