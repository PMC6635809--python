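# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish.

## Conventions

Pixel grids are row-major with the origin top-left.  Angles follow the
mathematical convention: 0 points rightward, counterclockwise is positive,
and the y axis points up, so a displacement of one row downward is y = -1.
All angles are reduced to [0, 2*pi).  Undirected edge orientations (the
tangent of a contour) live on [0, pi) in 8 bins of 22.5 degrees; each spawns
two directed border-ownership channels theta and theta + pi whose preferred
figure side is the tangent rotated +90 degrees.

## Front end

Images are split into an intensity channel and two broadly tuned opponent
channels (rg = R - G, by = B - Y with the Itti-Koch definitions of R, G, B,
Y).  Each channel is filtered with odd-symmetric Gabor kernels
(wavelength 8 px, sigma 2 px across the edge, aspect 0.5, i.e. sigma 4 px
along it) at one scale only — spatial scale is handled by the pyramid, not
the filter bank.  The signed response splits into two polarity maps, and
per pixel only the orientation with the largest response magnitude
survives.  The winner is chosen as the lowest orientation index within an
absolute tie tolerance of 1e-9 times the global response maximum; a
relative tolerance is deliberately avoided because near-cancellation
pixels (e.g. on a square's corner diagonals) carry tiny responses whose
floating-point ordering is not stable under contrast inversion, and the
package guarantees that an image and its inversion 1 - p produce exactly
swapped polarity maps.

The polarity label of a *directed* channel is the contrast of the figure it
would own: S_dir(theta, L) is the edge map whose bright side lies toward
theta + pi/2.  For theta in [pi, 2*pi) this is the dark-polarity map of the
underlying undirected orientation.  Under this indexing the two members of
an opposing pair, (theta, L) and (theta + pi, D), share one S input —
which is what makes their onset activities identical and their feedback
arguments exact negatives (see below).  The grouping pools G_L / G_D then
collect the *entire* boundary of a light / dark object respectively; with
the polarity label attached to the undirected edge instead, a symmetric
square would drive G_L and G_D equally at its center and the strict
winner-take-all would silence both, so that reading is rejected.

## Pyramid

Five levels at factor 2 (five octaves); both are configurable, so the
half-octave variant is `factor=sqrt(2), n_levels=10`.  Each level is a
Gaussian blur (sigma = factor/2, reflect padding) followed by decimation.
The edge bank runs at every level on the downsampled image, which keeps
the winner-orientation sparsity exact per level.  Upsampling back to finer
grids is align-corners bilinear: identical shapes give the identity and
constants are preserved exactly.

## Grouping kernel

v_theta is a von Mises profile in polar angle with concentration
kappa = r - R0 and normalizer 2*pi*I0(kappa), R0 = 2 px.  At r = R0 it is
the uniform ring value 1/(2*pi); away from the annulus it concentrates
into a single lobe pointing toward theta - pi/2.  Numerically the kernel is
evaluated with the exponentially scaled Bessel function (the exponent
kappa*cos(.) - |kappa| is never positive, so no overflow).  Choices where
the construction is underdetermined:

* **Origin pixel.**  The polar angle is undefined at r = 0; the center
  takes the angular mean of the profile, which is 1/(2*pi) for every
  concentration.  This keeps the point-reflection identity
  v_theta(-m) = v_theta+pi(m) exact on the grid.
* **Truncation.**  The support is cut at the image diagonal of each level,
  and values below 1e-4 of the kernel maximum are zeroed.  The on-axis
  value grows slowly (~sqrt(r)) while the ring-integrated mass per radius
  is constant, so the diagonal cut is the binding one.
* **Normalization.**  Each kernel is divided by its maximum over the
  truncated support, i.e. the normalization depends on the level size.
* Negative kappa (inside the annulus) is evaluated as written; I0 is even
  and the cosine term flips the lobe.

## Recurrence

One iteration = feedforward + feedback.  Feedforward pools the opponent
difference B_theta,P - B_theta+pi,P through v_theta, summed over all 16
directed channels and half-wave rectified; summing over all directed
channels (rather than 8) is required for the pass to be
rotation-symmetric.  On the first iteration the inhibitory term is
dropped: both pair members start at the same bottom-up activity, so the
difference would vanish identically.  The light/dark winner-take-all is
strict — exact ties silence both polarities.  Feedback correlates each
G level with the kernel bank at that level, upsamples the result to the
target level, weights it by 2^-(j-k), and passes the accumulated argument
through a logistic: B = 2S*sigma(arg).  Consequences used as tests: G == 0
implies B = S (fixed point of a silent surround); 0 <= B <= 2S always;
(theta, L) and (theta + pi, D) have exactly opposite arguments, so each
pair conserves 2S.

All computation is deterministic; there is no random state anywhere in the
network.  Correlations use zero padding (kernels reach outside the image
near borders) and are evaluated with cached FFTs, batched per level.

## Decoding

B activity at the finest level is summed over polarity (making the
read-out invariant to figure-ground contrast) and accumulated as a
population vector along each channel's preferred side.  Signed BOS values
compare the decoded direction to ground truth with the +-90-degree rule
(strict at exactly 90 degrees) and are normalized by the image-wide
magnitude maximum, bounding them in [-1, 1].  The paper-level read-out of
a "scene point BOS" is not fully specified anywhere; here it is the mean
signed BOS over a disc of radius 2 px around the scene point, excluding
pixels without ground truth — a documented default, configurable via
`ModelConfig.window_radius`.

Channels are fused as a weighted vector sum (0.8 intensity, 0.1 each for
rg and by); weights that do not sum to one are renormalized with a
warning.  Constant channels (e.g. color planes of a grayscale image) are
short-circuited to zero fields without running the recurrence.

## Benchmarking

Predicted boundary maps are thinned by non-maximum suppression along the
decoded figure direction (bilinear samples one pixel to either side),
normalized to [0, 1], and thresholded at 99 levels.  Matching to ground
truth is greedy nearest-neighbor one-to-one within a tolerance of
0.0075 x image diagonal — a deliberate, documented approximation of the
benchmark suite's bipartite assignment solver; identical point sets match
perfectly under both.  ODS is the best F over a dataset-wide threshold on
aggregated counts, OIS the mean per-image best F, AP the trapezoidal area
under the precision-recall curve.  Empty predictions give precision 0 by
convention.  Figure-ground accuracy counts a point correct when the
predicted direction is strictly within 90 degrees of the label.

## Comparison statistics

* **Consistency** is the fraction of scene points with strictly positive
  signed BOS; zeros count as inconsistent (conservative choice).
* **Cosine similarity** operates on the order-aligned intersection of two
  scene-point id sets; at least 2 shared points and nonzero norms are
  required.
* **Group means** of similarities go through the Fisher z-transform,
  clamped at |r| = 1 - 1e-6 (with a warning) since z diverges at +-1.
* **Bootstrap**: the null pools both groups and redraws groups of the
  original sizes with replacement (exchangeability); the two-sided p-value
  uses the +1 continuity correction and a required seed.  Whether pairs or
  groups should be resampled is not determined by the source material;
  pooled group resampling is the choice here.
* **TOST** uses Welch (unequal-variance) one-sided t tests against the
  zone bounds (default [-0.25, 0.25]); reported p is the larger of the
  two.  Degenerate zero-variance groups are decided by whether the
  observed difference lies inside the zone; an empty zone never declares
  equivalence.
* **Explainable-variance R^2**: sigma2_noise is the mean within-point
  repeat variance; sigma2_response is the total single-trial response
  variance, computed through the balanced between/within decomposition
  var(point means) + (1 - 1/n_rep)*sigma2_noise so that a noiseless scaled
  copy of the model recovers exactly R^2 = 1; the scale is a through-origin
  least-squares fit of point means on the model; the numerator subtracts
  sigma2_noise/Ns for the one fitted degree of freedom.  When the
  explainable variance is not positive the fit is flagged invalid rather
  than reported.

## Synthetic fixtures: what they show and what they do not

The square generator produces the canonical laboratory stimulus with exact
geometric ground truth: gray levels 0.25/0.75 (symmetric around 0.5, so
contrast inversion is the exact pixel map 1 - p), the perimeter as the
boundary mask, inward normals as figure directions (diagonals at corners —
the gradient of the distance-to-figure transform).  Simulated cells are
gain-scaled references plus i.i.d. Gaussian noise per repeat, seeded.

Passing the square suite establishes the network's sign conventions,
symmetries, bounds and convergence behavior — not natural-scene
performance: uniform squares have no clutter, occlusion, texture or
curvature, and the simulated cells have none of the response
nonstationarity of real recordings.  Natural-scene scores require external
image/annotation datasets and are out of scope for the bundled fixtures.
On the clean square the decoded boundary signs are correct already after
the first iteration (the reported convergence of 1-3 iterations on
fixtures is stimulus-dependent; cluttered inputs need the later passes for
the competition between proto-objects to settle).

## Problem sizes

The default test and reproduction runs use a 128 px square (5 levels, 10
iterations, < 10 s on one core) and 64-96 px squares for the symmetry and
robustness suites; statistical simulations use 1000 bootstrap replications
(500 resamples each) and 500 R^2 recovery simulations.  These sizes were
chosen so the whole suite documents the model's behavior in minutes while
keeping every check at full fidelity.
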