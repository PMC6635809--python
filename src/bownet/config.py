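"""Model configuration.

A single frozen dataclass carries every tunable of the network so that a run
is fully described by (image, config).  All angles in the package follow one
convention, stated here once and used everywhere:

* pixel grids are row-major with the origin at the top-left corner;
* angles are measured in standard mathematical convention — 0 points
  rightward (increasing column), angles increase counterclockwise with the
  y axis pointing *up*, so a displacement of one row downward is y = -1;
* angles are kept in [0, 2*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the recurrent figure-ground network.

    Attributes
    ----------
    n_orientations : int
        Number of undirected edge orientations, evenly spaced on [0, pi).
        Each spawns a pair of directed border-ownership channels, so the
        network carries ``2 * n_orientations`` directed channels.
    n_levels : int
        Pyramid depth.  Five levels at factor 2 span five octaves.
    pyramid_factor : float
        Downsampling step between successive pyramid levels.
    r0 : float
        Radius, in pixels, of the annular grouping-cell receptive field.
        The effective radius grows with pyramid level because the kernel is
        fixed while the image shrinks.
    n_iterations : int
        Number of feedforward/feedback passes of the recurrence.
    convergence_tol : float or None
        Optional early-stopping tolerance on the maximum absolute change of
        the decoded border-ownership vector field between iterations.
    channel_weights : tuple of float
        Weights for fusing the intensity, red-green and blue-yellow fields.
    filter_wavelength : float
        Wavelength, in pixels, of the odd-symmetric Gabor edge filters at
        every pyramid level (scale is handled by the pyramid, not the bank).
    filter_aspect : float
        Gabor aspect ratio sigma_normal / sigma_tangential; values below 1
        elongate the filter along the edge.
    kernel_tail_cutoff : float
        Grouping-kernel values below this fraction of the kernel maximum
        are zeroed (the support is additionally truncated at the image
        diagonal of each level).
    window_radius : float
        Radius, in pixels, of the disc over which a scene-point BOS is
        averaged when read out of the decoded field.
    """

    n_orientations: int = 8
    n_levels: int = 5
    pyramid_factor: float = 2.0
    r0: float = 2.0
    n_iterations: int = 10
    convergence_tol: float | None = None
    channel_weights: tuple[float, float, float] = (0.8, 0.1, 0.1)
    filter_wavelength: float = 8.0
    filter_aspect: float = 0.5
    kernel_tail_cutoff: float = 1e-4
    window_radius: float = 2.0

    @property
    def n_directed(self) -> int:
        return 2 * self.n_orientations

    def undirected_angles(self) -> np.ndarray:
        """Edge-tangent orientations on [0, pi)."""
        return np.arange(self.n_orientations) * np.pi / self.n_orientations

    def directed_angles(self) -> np.ndarray:
        """Directed channel angles on [0, 2*pi); channel d pairs with d + n."""
        return np.arange(self.n_directed) * np.pi / self.n_orientations

    def side_vectors(self) -> np.ndarray:
        """Unit vectors (x, y) of each directed channel's preferred figure side.

        The preferred side of directed channel theta is theta + pi/2 (the
        border normal rotated +90 degrees from the border orientation).
        """
        a = self.directed_angles() + np.pi / 2.0
        return np.stack([np.cos(a), np.sin(a)], axis=-1)


DEFAULT_CONFIG = ModelConfig()
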