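# bownet

A recurrent proto-object network for **border ownership assignment** —
deciding, for every contour in an image, which side of it belongs to the
object (figure) and which to the background — together with the evaluation
stack used to study such models: contour-detection benchmarking,
figure-ground accuracy, and statistics for comparing model output with the
responses of border-ownership-selective neurons in extrastriate visual
cortex.

It is written for computational neuroscientists and vision researchers who
want a fully image-computable, training-free model of figure-ground
organization whose internal signals (edge cells, border-ownership cells,
grouping cells) can be read out and compared with physiology.

## The model

Three cell populations are simulated on an image pyramid spanning five
octaves (downsampling factor 2, index $k$):

* **S cells** — oriented, contrast-polarity-split edge detectors
  (odd-symmetric Gabor filters at 8 orientations).  Only the best
  orientation per pixel is kept, split into light ($L$) and dark ($D$)
  polarity maps $S^k_{\theta,L}, S^k_{\theta,D}$.
* **B cells** — border ownership cells.  Each S cell drives an opposing
  pair of B cells with the same preferred orientation $\theta$ but opposite
  side-of-figure preferences ($\theta$ vs $\theta+\pi$; the preferred
  figure direction of channel $\theta$ is $\theta + \pi/2$).
* **G cells** — grouping cells with annular ("donut") receptive fields
  that integrate B activity consistent with a convex object:

$$G^k_P(x,y) = \left\lfloor \sum_\theta \big[B^k_{\theta,P} - B^k_{\theta+\pi,P}\big] * v_\theta \right\rfloor_+ , \qquad P \in \{L, D\}$$

with the annulus-slice kernel (radius $R_0 = 2$ px, modified Bessel
function $I_0$, correlation $*$ without kernel flip)

$$v_\theta(x,y) = \frac{\exp\big[(r - R_0)\cos(\phi - \theta + \tfrac{\pi}{2})\big]}{2\pi I_0(r - R_0)}, \quad r = \sqrt{x^2+y^2},\ \phi = \mathrm{atan2}(y, x),$$

max-normalized per orientation.  A pointwise winner-take-all keeps only the
stronger of $G_L, G_D$ at each location (a spot is either a light object on
a dark ground or the reverse).  Feedback then biases the B cells through a
logistic, pooling G activity coarse-to-fine across scales $j \ge k$:

$$B^k_{\theta,L} = 2\,S^k_{\theta,L} \cdot \sigma\!\Big(\sum_{j\ge k} 2^{-(j-k)}\big[v_{\theta+\pi} * G^j_L - v_\theta * G^j_D\big]\Big)$$

(and symmetrically for $D$), so every B cell stays within $[0, 2S]$ and an
opposing pair conserves its summed activity.  One iteration is one
feedforward plus one feedback pass; the network typically settles in two
to three iterations, which at ~10 ms per cortical pass matches the ~20–30 ms
latency of border ownership signals measured in area V2.

The final read-out sums B activity over contrast polarity and converts it
to a population vector per pixel: the magnitude is the border ownership
strength (also used as a contour-detection signal), the direction is a
continuous figure-side label.  Intensity and the two color-opponent
channels (red-green, blue-yellow) are processed identically and fused with
weights 0.8 / 0.1 / 0.1.

## Worked example

```python
import numpy as np
from bownet import (ModelConfig, make_square_stimulus, run_model, normalize_bos,
                    fg_accuracy, sample_scene_points, scene_point_bos,
                    consistency, BOSVector)
from bownet.pipeline import convergence_iteration, latency_ms

img = make_square_stimulus(128, 48, polarity="light")   # bright square, dark ground
out = run_model(img, ModelConfig())

conv = convergence_iteration(out.traces["intensity"], img.fg_orientation)
print(f"converged after {conv} iteration(s)  (~{latency_ms(conv):.0f} ms at 10 ms/pass)")

mask = img.boundary_mask
acc = fg_accuracy(out.field.angle[mask], img.fg_orientation[mask])
print(f"figure-ground accuracy on the square boundary: {100*acc:.1f}%")

signed = normalize_bos(out.field, img.fg_orientation)
pts = sample_scene_points(img, 64)
bos = BOSVector(np.arange(64),
                np.array([scene_point_bos(signed, (p.row, p.col)) for p in pts]))
print(f"consistency over {len(pts)} scene points: {100*consistency(bos):.1f}%")
print(f"normalized BOS range on the boundary: [{np.nanmin(signed):+.2f}, {np.nanmax(signed):+.2f}]")
```

prints

```
converged after 1 iteration(s)  (~10 ms at 10 ms/pass)
figure-ground accuracy on the square boundary: 100.0%
consistency over 64 scene points: 100.0%
normalized BOS range on the boundary: [+0.55, +1.00]
```

Every boundary pixel of the square is owned by the square side
(accuracy and consistency 100%), the decision is made within the first
feedforward/feedback pass on this maximally clean stimulus, and the signed
per-image-normalized border ownership signal lies in $[-1, 1]$ with the
peak at +1.

A thin CLI runs the model on arbitrary raster images:

```bash
bownet run photo.png --iters 10 --levels 5 --out-dir results/
```

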