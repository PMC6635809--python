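"""The B/G cell recurrence: grouping kernels, feedforward pooling,
light/dark winner-take-all, cross-scale modulatory feedback, iteration loop.

Sketch of one iteration at each pyramid level k and polarity P in {L, D}:

    feedforward   G_P^k = relu( sum_theta [B_theta,P^k - B_theta+pi,P^k] * v_theta )
    competition   only the strictly larger of G_L^k, G_D^k survives per pixel
    feedback      B_theta,P^k = 2 S_theta,P^k * sigmoid( sum_{j>=k} 2^{-(j-k)}
                      [ v_theta+pi * G_P^j  -  v_theta * G_opp(P)^j ] )

where ``*`` is unflipped correlation, coarse-level correlations are
upsampled to level k before the weighted sum, and on the first iteration
the inhibitory (theta+pi) term of the feedforward sum is omitted because
both members of every B pair start with identical bottom-up activity.

The kernel v_theta is an annular "donut" slice: a von Mises profile in
angle with concentration growing with distance from the annulus radius R0,
so each directed orientation contributes one oriented lobe of the donut.
B cells are bounded by 0 <= B <= 2 S through the logistic, and the two
members of a pair — (theta, L) and (theta + pi, D), which share the same S
input — receive exactly opposite feedback arguments, so their summed
activity is conserved at 2 S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import fft as sp_fft
from scipy import special
from scipy.special import expit

from .config import ModelConfig, TWO_PI
from .decode import FigureGroundField, combine_polarity, population_vector
from .frontend import OrientedEdgeVolume
from .pyramid import resize_bilinear

__all__ = [
    "grouping_kernel",
    "KernelBank",
    "BorderOwnershipVolume",
    "GroupingPyramid",
    "feedforward_grouping",
    "winner_take_all",
    "feedback_modulation",
    "run_recurrence",
    "IterationTrace",
]


def grouping_kernel(
    theta: float,
    r0: float = 2.0,
    support_radius: float = 16.0,
    tail_cutoff: float = 1e-4,
) -> np.ndarray:
    """Annulus-slice grouping kernel for one directed orientation.

    On a grid of offsets m = (x, y) with r = |m| and phi = atan2(y, x):

        v(m) = exp[(r - r0) cos(phi - theta + pi/2)] / (2 pi I0(r - r0))

    i.e. a von Mises density in angle with concentration r - r0, which at
    r = r0 is the uniform ring value 1/(2 pi) and away from the annulus
    concentrates into a single lobe pointing toward phi = theta - pi/2.
    The kernel is evaluated on a centered odd-sized grid truncated at
    ``support_radius``, values below ``tail_cutoff`` of the maximum are
    zeroed, and the result is divided by its maximum.

    The kernel is returned in array coordinates (row, col) with y = -row,
    matching the package angle convention.
    """
    if r0 <= 0:
        raise ValueError(f"r0 must be positive, got {r0}")
    if support_radius <= r0:
        raise ValueError("support_radius must exceed r0")
    rad = int(np.ceil(support_radius))
    dr, dc = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    x, y = dc.astype(float), -dr.astype(float)
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    kappa = r - r0
    # exp(kappa*cos - |kappa|) / (2 pi i0e(|kappa|)) == exp(kappa*cos)/(2 pi I0(kappa));
    # the exponent is <= 0, so this never overflows.
    v = np.exp(kappa * np.cos(phi - theta + np.pi / 2.0) - np.abs(kappa))
    v /= TWO_PI * special.i0e(np.abs(kappa))
    # The angle is undefined at the origin; use the angular mean of the von
    # Mises profile there, which is 1/(2 pi) for every concentration.  This
    # keeps the v_theta / v_theta+pi point-reflection identity exact.
    v[r == 0.0] = 1.0 / TWO_PI
    v[r > support_radius] = 0.0
    peak = v.max()
    v[v < tail_cutoff * peak] = 0.0
    return v / peak


@dataclass
class KernelBank:
    """Grouping kernels for all directed orientations at one support radius.

    Caches FFTs of the (flipped) kernels per padded image shape so that the
    correlation of Eq-style ``f * g`` (no kernel flip) reduces to one batched
    multiply per pass.
    """

    kernels: np.ndarray  # (n_directed, K, K), K odd
    r0: float
    support_radius: float
    _fft_cache: dict = field(default_factory=dict, repr=False)

    @property
    def size(self) -> int:
        return self.kernels.shape[1]

    def fft_for(self, image_shape: tuple[int, int]):
        """(kernel FFTs, fft_shape) for correlating with images of a shape."""
        key = tuple(image_shape)
        if key not in self._fft_cache:
            full = (image_shape[0] + self.size - 1, image_shape[1] + self.size - 1)
            fshape = tuple(sp_fft.next_fast_len(n, real=True) for n in full)
            flipped = self.kernels[:, ::-1, ::-1]
            self._fft_cache[key] = (sp_fft.rfft2(flipped, s=fshape), fshape)
        return self._fft_cache[key]

    def correlate(self, maps: np.ndarray, pairwise_sum: bool = False) -> np.ndarray:
        """Correlate maps with the bank (zero padding, 'same' output).

        With ``pairwise_sum`` the maps must match the kernels one-to-one and
        the result is ``sum_d maps[d] * v_d`` of shape (H, W); otherwise the
        result has shape (n_directed, M, H, W) for input shape (M, H, W).
        """
        maps = np.atleast_3d(maps)
        h, w = maps.shape[-2:]
        kffts, fshape = self.fft_for((h, w))
        mffts = sp_fft.rfft2(maps, s=fshape)
        lo = (self.size - 1) // 2
        if pairwise_sum:
            spec = (mffts * kffts).sum(axis=0)
        else:
            spec = kffts[:, None] * mffts[None]
        out = sp_fft.irfft2(spec, s=fshape)
        return out[..., lo : lo + h, lo : lo + w]


@lru_cache(maxsize=32)
def _bank(n_orientations: int, r0: float, support_radius: float, cutoff: float) -> KernelBank:
    angles = np.arange(2 * n_orientations) * np.pi / n_orientations
    kernels = np.stack(
        [grouping_kernel(a, r0, support_radius, cutoff) for a in angles]
    )
    return KernelBank(kernels=kernels, r0=r0, support_radius=support_radius)


def banks_for_levels(shapes: list[tuple[int, int]], config: ModelConfig) -> list[KernelBank]:
    """One kernel bank per pyramid level, truncated at the level diagonal."""
    out = []
    for h, w in shapes:
        support = max(float(np.ceil(np.hypot(h, w))), config.r0 + 1.0)
        out.append(
            _bank(config.n_orientations, config.r0, support, config.kernel_tail_cutoff)
        )
    return out


@dataclass
class BorderOwnershipVolume:
    """B-cell activity; ``levels[k]`` has shape (n_directed, 2, H_k, W_k)."""

    levels: list[np.ndarray]
    directed_angles: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class GroupingPyramid:
    """G-cell activity; ``levels[k]`` has shape (2, H_k, W_k), axis 0 = (L, D)."""

    levels: list[np.ndarray]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _pair_index(n_directed: int) -> np.ndarray:
    return (np.arange(n_directed) + n_directed // 2) % n_directed


def feedforward_grouping(
    b: BorderOwnershipVolume,
    banks: list[KernelBank],
    first_iteration: bool = False,
) -> GroupingPyramid:
    """B -> G pass: annular pooling of opponent B-cell differences.

    On the first iteration the inhibitory term (the opposing pair member)
    is dropped, because the opposing activities are identical then and the
    difference would vanish everywhere.
    """
    if len(banks) != b.n_levels:
        raise ValueError("need one kernel bank per level")
    levels = []
    for blev, bank in zip(b.levels, banks):
        n_dir = blev.shape[0]
        pair = _pair_index(n_dir)
        g = np.empty((2,) + blev.shape[-2:])
        for p in (0, 1):
            drive = blev[:, p] if first_iteration else blev[:, p] - blev[pair, p]
            g[p] = np.maximum(bank.correlate(drive, pairwise_sum=True), 0.0)
        levels.append(g)
    return GroupingPyramid(levels=levels)


def winner_take_all(g: GroupingPyramid) -> GroupingPyramid:
    """Pointwise light/dark competition; ties zero both polarities."""
    levels = []
    for glev in g.levels:
        gl, gd = glev[0], glev[1]
        levels.append(
            np.stack([np.where(gl > gd, gl, 0.0), np.where(gd > gl, gd, 0.0)])
        )
    return GroupingPyramid(levels=levels)


def feedback_modulation(
    s: OrientedEdgeVolume,
    g: GroupingPyramid,
    banks: list[KernelBank],
) -> BorderOwnershipVolume:
    """G -> B pass: cross-scale modulatory feedback through the logistic.

    For level k, directed channel theta and polarity P the feedback argument
    sums, over levels j >= k, the correlation of G at level j with the
    opposite-lobe kernel v_theta+pi (same polarity, preferred side) minus
    the correlation with v_theta (opposite polarity, non-preferred side);
    each level-j result is upsampled to the level-k grid and weighted by
    2^-(j-k).  Then B = 2 S sigmoid(argument).
    """
    n_levels = s.n_levels
    if g.n_levels != n_levels or len(banks) != n_levels:
        raise ValueError("S, G and kernel banks must cover the same levels")
    n_dir = 2 * s.levels[0].shape[0]
    pair = _pair_index(n_dir)
    # Per level j: diff[j][d, p] = v_{d+pi} * G_p - v_d * G_{1-p}, at level-j grid.
    diffs = []
    for glev, bank in zip(g.levels, banks):
        c = bank.correlate(glev)  # (n_dir, 2, Hj, Wj)
        diffs.append(c[pair] - c[:, ::-1])
    b_levels = []
    for k in range(n_levels):
        shape_k = s.levels[k].shape[-2:]
        arg = np.zeros((n_dir, 2) + shape_k)
        for j in range(k, n_levels):
            w = 0.5 ** (j - k)
            d = diffs[j]
            if d.shape[-2:] == shape_k:
                arg += w * d
            else:
                for di in range(n_dir):
                    for p in (0, 1):
                        arg[di, p] += w * resize_bilinear(d[di, p], shape_k)
        s_dir = s.directed(k)
        b_levels.append(2.0 * s_dir * expit(arg))
    return BorderOwnershipVolume(
        levels=b_levels,
        directed_angles=np.arange(n_dir) * np.pi / (n_dir // 2),
    )


@dataclass
class IterationTrace:
    """Decoded finest-level BOS field after each iteration, for timing analysis."""

    fields: list[FigureGroundField]
    deltas: list[float]  # max abs change of the vector field between iterations

    @property
    def n_iterations(self) -> int:
        return len(self.fields)


def run_recurrence(
    s: OrientedEdgeVolume,
    config: ModelConfig | None = None,
    n_iterations: int | None = None,
    convergence_tol: float | None = None,
) -> tuple[BorderOwnershipVolume, GroupingPyramid, IterationTrace]:
    """Run the full feedforward/feedback loop on an edge volume.

    B cells start at their bottom-up input (both members of each pair
    identical).  Each iteration is one feedforward B->G pass (with the
    first-iteration rule), the light/dark winner-take-all, and one G->B
    feedback pass.  The trace records the decoded finest-level field after
    every iteration; with ``convergence_tol`` set the loop stops early once
    the maximum absolute change of the decoded vector field drops below it.
    """
    config = config or ModelConfig()
    n_iter = n_iterations if n_iterations is not None else config.n_iterations
    tol = convergence_tol if convergence_tol is not None else config.convergence_tol
    if n_iter < 1:
        raise ValueError("n_iterations must be >= 1")
    banks = banks_for_levels([lev.shape[-2:] for lev in s.levels], config)
    directed = config.directed_angles()
    b = BorderOwnershipVolume(
        levels=[s.directed(k).copy() for k in range(s.n_levels)],
        directed_angles=directed,
    )
    g = None
    fields: list[FigureGroundField] = []
    deltas: list[float] = []
    prev_vx = prev_vy = None
    for it in range(n_iter):
        g = winner_take_all(feedforward_grouping(b, banks, first_iteration=(it == 0)))
        b = feedback_modulation(s, g, banks)
        fld = population_vector(combine_polarity(b.levels[0]), directed)
        fields.append(fld)
        if prev_vx is None:
            deltas.append(float("inf"))
        else:
            deltas.append(
                float(
                    max(
                        np.abs(fld.vx - prev_vx).max(),
                        np.abs(fld.vy - prev_vy).max(),
                    )
                )
            )
        prev_vx, prev_vy = fld.vx, fld.vy
        if tol is not None and deltas[-1] < tol:
            break
    return b, g, IterationTrace(fields=fields, deltas=deltas)
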