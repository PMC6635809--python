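"""Model-vs-neuron comparison statistics.

A cell (or the model) is characterized by its signed border-ownership
signal across a set of scene points, treated as one vector with one axis
per scene point.  This module implements:

* consistency — the fraction of scene points owned on the correct side;
* cosine similarity between two BOS vectors on their shared scene points
  (Pearson correlation is unsuitable here because mean-centering a signed
  BOS vector destroys the side information);
* Fisher-z averaged means and a seeded bootstrap test for a difference in
  mean similarity between two groups;
* TOST equivalence testing with a preset zone of indifference;
* a noise-corrected explainable-variance R^2 for how much of a cell's
  repeatable response a deterministic model captures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.weightstats import ttost_ind

__all__ = [
    "BOSVector",
    "FitResult",
    "consistency",
    "cosine_similarity",
    "fisher_z_mean",
    "bootstrap_mean_difference",
    "tost_equivalence",
    "explainable_variance_r2",
    "select_consistent",
]

_Z_CLAMP = 1.0 - 1e-6


@dataclass
class BOSVector:
    """Signed BOS values indexed by scene-point ids."""

    scene_point_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.scene_point_ids = np.asarray(self.scene_point_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scene_point_ids.shape != self.values.shape:
            raise ValueError("ids and values must align")
        if np.unique(self.scene_point_ids).size != self.scene_point_ids.size:
            raise ValueError("scene point ids must be unique")

    def align(self, other: "BOSVector") -> tuple[np.ndarray, np.ndarray]:
        """Order-aligned values on the shared scene-point intersection."""
        shared, ia, ib = np.intersect1d(
            self.scene_point_ids, other.scene_point_ids, return_indices=True
        )
        if shared.size == 0:
            raise ValueError("no shared scene points")
        return self.values[ia], other.values[ib]


@dataclass
class FitResult:
    """Explainable-variance fit of a model BOS vector to cell responses."""

    scale: float
    r2: float
    sigma_response2: float
    sigma_noise2: float
    sigma_predicted2: float
    n_scene_points: int
    valid: bool  # False when the explainable variance is not positive


def consistency(bos: BOSVector | np.ndarray) -> float:
    """Fraction of scene points with strictly positive signed BOS.

    Zero values (model silent at a scene point) count as inconsistent.
    """
    values = bos.values if isinstance(bos, BOSVector) else np.asarray(bos, dtype=float)
    if values.size == 0:
        raise ValueError("consistency of an empty BOS vector is undefined")
    return float(np.mean(values > 0.0))


def cosine_similarity(a: BOSVector, b: BOSVector) -> float:
    """cos of the angle between two BOS vectors on their shared scene points."""
    va, vb = a.align(b)
    if va.size < 2:
        raise ValueError("need at least 2 shared scene points")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def _to_z(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "similarities at +-1 clamped before Fisher z-transform", stacklevel=3
        )
    return np.arctanh(np.clip(r, -_Z_CLAMP, _Z_CLAMP))


def fisher_z_mean(similarities: np.ndarray) -> float:
    """Mean of correlation-like values through the Fisher z-transform."""
    return float(np.tanh(np.mean(_to_z(similarities))))


def bootstrap_mean_difference(
    group1: np.ndarray,
    group2: np.ndarray,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided bootstrap p-value for a difference in Fisher-z means.

    Group means are taken in Fisher-z space.  The null distribution pools
    both groups (exchangeability) and redraws groups of the original sizes
    with replacement; the p-value is the fraction of resampled absolute
    mean differences at least as large as the observed one (with the +1
    continuity correction).  Seeded and reproducible.
    """
    z1, z2 = _to_z(group1), _to_z(group2)
    if z1.size == 0 or z2.size == 0:
        raise ValueError("both groups must be nonempty")
    observed = abs(z1.mean() - z2.mean())
    pooled = np.concatenate([z1, z2])
    rng = np.random.default_rng(seed)
    idx1 = rng.integers(0, pooled.size, size=(n_samples, z1.size))
    idx2 = rng.integers(0, pooled.size, size=(n_samples, z2.size))
    diffs = np.abs(pooled[idx1].mean(axis=1) - pooled[idx2].mean(axis=1))
    return float((1 + np.sum(diffs >= observed)) / (n_samples + 1))


def tost_equivalence(
    group1: np.ndarray,
    group2: np.ndarray,
    zone: tuple[float, float] = (-0.25, 0.25),
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two one-sided t tests for equivalence of two group means.

    The null hypothesis is that the mean difference lies outside ``zone``
    (the zone of indifference); the reported p is the larger of the two
    one-sided Welch p-values and equivalence is declared when p < alpha.
    A zone with empty interior can never yield equivalence.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    low, upp = zone
    if not low < upp:
        return 1.0, False
    if g1.std(ddof=1) == 0.0 and g2.std(ddof=1) == 0.0:
        # Degenerate zero-variance groups: decide by the observed difference.
        diff = g1.mean() - g2.mean()
        inside = low < diff < upp
        return (0.0 if inside else 1.0), inside
    p, _, _ = ttost_ind(g1, g2, low, upp, usevar="unequal")
    return float(p), bool(p < alpha)


def explainable_variance_r2(
    cell_repeats: list[np.ndarray] | np.ndarray, model_bos: BOSVector | np.ndarray
) -> FitResult:
    """Noise-corrected fraction of explainable variance captured by the model.

    ``cell_repeats[i]`` holds the repeated responses of the cell at scene
    point i (>= 2 repeats each); ``model_bos`` the model's deterministic BOS
    at the same scene points, in the same order.  A free scale factor is fit
    by least squares of the per-point mean response on the model (the two
    live on different scales), and

        R^2 = [sigma2_predicted - sigma2_noise / Ns] / [sigma2_response - sigma2_noise]

    where sigma2_response is the total single-trial response variance,
    sigma2_noise the mean within-scene-point repeat variance, and
    sigma2_predicted the variance of the scaled model.  The numerator
    correction removes the share of noise variance absorbed by fitting the
    one-parameter scale (1 degree of freedom against Ns scene points).  When
    the explainable variance sigma2_response - sigma2_noise is not positive
    the fit is flagged invalid and R^2 is NaN.
    """
    x = model_bos.values if isinstance(model_bos, BOSVector) else np.asarray(model_bos, float)
    reps = [np.asarray(r, dtype=float) for r in cell_repeats]
    ns = len(reps)
    if ns < 3:
        raise ValueError("need at least 3 scene points")
    if ns != x.size:
        raise ValueError("model BOS and cell repeats must cover the same scene points")
    if any(r.size < 2 for r in reps):
        raise ValueError("every scene point needs >= 2 repeats")

    means = np.array([r.mean() for r in reps])
    sigma_noise2 = float(np.mean([r.var(ddof=1) for r in reps]))
    # Total single-trial response variance via the between/within decomposition
    # (balanced-design form, with the mean repeat count for mildly unbalanced
    # data): var(means) carries sigma_noise2 / n_rep of noise, single trials
    # carry the full sigma_noise2.
    mean_reps = float(np.mean([r.size for r in reps]))
    sigma_response2 = float(means.var(ddof=1)) + (1.0 - 1.0 / mean_reps) * sigma_noise2
    denom_x = float(np.dot(x, x))
    scale = float(np.dot(means, x) / denom_x) if denom_x > 0 else 0.0
    sigma_predicted2 = float(np.var(scale * x, ddof=1))

    explainable = sigma_response2 - sigma_noise2
    if explainable <= 0.0:
        return FitResult(
            scale=scale,
            r2=float("nan"),
            sigma_response2=sigma_response2,
            sigma_noise2=sigma_noise2,
            sigma_predicted2=sigma_predicted2,
            n_scene_points=ns,
            valid=False,
        )
    r2 = (sigma_predicted2 - sigma_noise2 / ns) / explainable
    return FitResult(
        scale=scale,
        r2=float(r2),
        sigma_response2=sigma_response2,
        sigma_noise2=sigma_noise2,
        sigma_predicted2=sigma_predicted2,
        n_scene_points=ns,
        valid=True,
    )


def select_consistent(consistencies: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Indices of cells whose consistency strictly exceeds a threshold."""
    return np.nonzero(np.asarray(consistencies) > threshold)[0]
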