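"""End-to-end model runs: image -> channels -> pyramid -> S -> recurrence -> field.

This is the orchestration layer over the individual stages.  A run returns
the fused border-ownership field, the per-channel fields and traces, the
final B/G activity, and the scale-summed grouping map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .decode import (
    FigureGroundField,
    angular_difference,
    combine_grouping,
    fuse_channels,
)
from .frontend import OrientedEdgeVolume, edge_volume, to_channels
from .pyramid import build_pyramid, resize_bilinear
from .recurrence import (
    BorderOwnershipVolume,
    GroupingPyramid,
    IterationTrace,
    run_recurrence,
)
from .stimuli import AnnotatedImage

CHANNEL_NAMES = ("intensity", "rg", "by")


@dataclass
class ModelOutput:
    """Everything a single model run produces."""

    field: FigureGroundField  # fused across channels
    channel_fields: dict[str, FigureGroundField]
    traces: dict[str, IterationTrace]
    b_volumes: dict[str, BorderOwnershipVolume]
    s_volumes: dict[str, OrientedEdgeVolume]
    g_pyramids: dict[str, GroupingPyramid]
    grouping_map: np.ndarray  # combined-polarity G summed over scales, level-0 grid
    config: ModelConfig


def run_model(
    image: np.ndarray | AnnotatedImage, config: ModelConfig | None = None
) -> ModelOutput:
    """Run the full network on an image (grayscale or RGB, values in [0, 1]).

    Channels that are identically constant (e.g. the color channels of a
    grayscale image) carry no edges and are short-circuited to zero fields.
    """
    config = config or ModelConfig()
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
    channels = to_channels(pixels)
    shape = channels.intensity.shape

    fields: dict[str, FigureGroundField] = {}
    traces: dict[str, IterationTrace] = {}
    b_volumes: dict[str, BorderOwnershipVolume] = {}
    s_volumes: dict[str, OrientedEdgeVolume] = {}
    g_pyramids: dict[str, GroupingPyramid] = {}
    grouping_map = np.zeros(shape)
    weights = dict(zip(CHANNEL_NAMES, config.channel_weights))

    for name, raster in channels.as_dict().items():
        if np.ptp(raster) == 0.0:
            zero = np.zeros(shape)
            fields[name] = FigureGroundField(magnitude=zero, angle=zero.copy())
            continue
        pyr = build_pyramid(raster, n_levels=config.n_levels, factor=config.pyramid_factor)
        s = edge_volume(pyr.levels, config)
        b, g, trace = run_recurrence(s, config)
        fields[name] = trace.fields[-1]
        traces[name] = trace
        b_volumes[name] = b
        s_volumes[name] = s
        g_pyramids[name] = g
        for k, glev in enumerate(g.levels):
            grouping_map += weights[name] * resize_bilinear(combine_grouping(glev), shape)

    fused = fuse_channels(
        [fields[n] for n in CHANNEL_NAMES], weights=config.channel_weights
    )
    return ModelOutput(
        field=fused,
        channel_fields=fields,
        traces=traces,
        b_volumes=b_volumes,
        s_volumes=s_volumes,
        g_pyramids=g_pyramids,
        grouping_map=grouping_map,
        config=config,
    )


def sign_map(field: FigureGroundField, fg_orientation: np.ndarray) -> np.ndarray:
    """Per-boundary-pixel agreement sign (+1 correct side, -1 opposite, 0 silent)."""
    agree = angular_difference(field.angle, fg_orientation) < np.pi / 2.0
    sign = np.where(agree, 1.0, -1.0)
    sign = np.where(field.magnitude > 0.0, sign, 0.0)
    return np.where(np.isfinite(fg_orientation), sign, np.nan)


def convergence_iteration(trace: IterationTrace, fg_orientation: np.ndarray) -> int:
    """First iteration (1-based) from which decoded boundary signs are final.

    The decoded sign at every annotated boundary pixel is compared with its
    value after the last iteration; returns the earliest iteration such that
    no boundary sign changes from then on.
    """
    mask = np.isfinite(fg_orientation)
    signs = [sign_map(f, fg_orientation)[mask] for f in trace.fields]
    final = signs[-1]
    stable_from = len(signs)
    for i in range(len(signs) - 1, -1, -1):
        if np.array_equal(signs[i], final):
            stable_from = i + 1
        else:
            break
    return stable_from


def latency_ms(n_iterations: int, ms_per_pass: float = 10.0) -> float:
    """Map iterations-to-convergence to a cortical latency estimate.

    One iteration is one feedforward plus one feedback pass; with fast
    white-matter projections a pass is assumed to take ~10 ms.
    """
    return n_iterations * ms_per_pass


def activity_bound_ratio(b: BorderOwnershipVolume, s: OrientedEdgeVolume) -> float:
    """max B / (2 S) over all cells with nonzero bottom-up input (should be <= 1)."""
    worst = 0.0
    for k in range(b.n_levels):
        s_dir = s.directed(k)
        nz = s_dir > 0
        if nz.any():
            worst = max(worst, float((b.levels[k][nz] / (2.0 * s_dir[nz])).max()))
    return worst
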