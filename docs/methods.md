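# Methods

## Measurement model

The pipeline measures food volume as a height field over a flat tray viewed
from directly above. Depth comes from a rectified stereo pair:
`Z = f·B/d` with focal length `f` in pixels, baseline `B` in mm and
disparity `d` in pixels; disparity 0 is the sentinel for "no stereo match"
and becomes an explicitly invalid depth pixel, never a zero depth. All
depth frames carry a boolean validity grid, and no stage reads an invalid
pixel's value — silent zeros would corrupt the volume sum directly.

With a fixed tray-plane reference point of depth RP and a binary per-class
mask `in(s,k)`, each masked pixel contributes a column
`sup(s,k) = in(s,k)·(RP − depth_sat(s,k))` mm tall and `kpix²` mm² in
cross-section, so `V = Σ sup·kpix²`. The sign is chosen so that food, being
closer to the camera than the tray, yields positive heights. Two
conventions are deliberate:

* **Below-plane clamping.** Pixels measuring deeper than RP (concave plate
  interior, noise) are clamped to zero contribution and counted in
  `clamped_negative_count`, not subtracted. Subtracting would let plate
  cavities cancel food volume; clamping is conservative and the count makes
  the condition observable.
* **Dropout accounting.** Masked pixels with no valid depth contribute zero
  and are counted in `invalid_in_mask_count`. Interpolating them would hide
  exactly the low-texture failure mode the counts exist to expose; callers
  can reject frames whose dropout count is excessive.

A single `kpix = Z_tray/f` is applied per scene (evaluated at the tray
reference depth), not per pixel. Under the overhead geometry food sits
30–60 mm above a 1200 mm tray, so the per-pixel scale error is ≤ ~5% on
the tallest items and zero at tray level; a perspective-correct per-pixel
scale would change the integration formula and is out of scope.

## Depth post-processing

The filter chain reproduces a stereo depth camera's standard configuration
surface: confidence gating (threshold 200 of 255), a 7×7 validity-aware
median filter, a per-pixel exponential temporal filter (α = 0.1, invalid
pixels hold their previous state; a never-observed pixel stays invalid),
an edge-aware spatial smoother, temporal frame decimation (factor 2), and
depth saturation to a configured band (defaults 900–1350 mm around a
1200 mm tray, set in the run configuration).

Vendor firmware does not publish its spatial filter's algorithm, so the
spatial smoother here is defined precisely by its configuration surface: per
iteration (default 4), a horizontal then vertical weighted average with
truncated-exponential weights `(1−α)^|offset|` within `radius` (default 2),
excluding neighbours whose depth differs from the centre by more than
`delta` mm (delta 0 disables the edge threshold). α = 1 is the identity;
constant frames are fixed points; validity is never manufactured.
"Decimation factor 2" is read as temporal decimation (keep every second
frame); a spatial reading exists in stereo pipelines but the configured
intent here is frame-rate reduction.

## Calibration

`kpix` follows the pinhole ground-sampling distance `Z/f`. The reference
point is a fixed tray pixel chosen at installation; its depth is the median
of the valid depths in a (2·window+1)² neighbourhood (window default 2),
making RP robust to speckle at a single pixel. A pre-session flatness check
captures a bare surface and reports mean, std and worst absolute residual
against a fronto-parallel plane (no plane fit — the mount is assumed
orthogonal); it refuses captures with under 50% valid pixels.

Coordinates everywhere are 0-based (column u, row v), origin top-left,
pixel centres at (u+0.5, v+0.5); bounding boxes are half-open.

## Segmentation interface

Mask provenance is pluggable: label images, polygon annotations (even-odd
rasterization at pixel centres), or a colour-key segmenter for synthetic
renders. Any provider yields the same binary-mask contract, which is where
the volume computation begins; training an instance segmenter is outside
the package. Detection gating at confidence 0.5 discards a frame (a
recorded state, not an error) when no detection clears the threshold.

## Volume → weight

The primary regressor is exact GP regression on 1-D volume with an
exponential kernel, default `σf²·exp(−‖x−x′‖/(2l²))` with the
Ornstein–Uhlenbeck form `σf²·exp(−‖x−x′‖/l)` behind `kernel_form="ou"` —
the two differ only in length-scale parametrization. Volumes are z-scored
internally (they are O(10⁵) mm³ and would otherwise degenerate length-scale
optimization) and the target is centred, so the prior mean is the training
mean; hyperparameters are reported in standardized and natural units.
Fitting maximizes the exact log marginal likelihood by multi-start L-BFGS
on log-parameters (deterministic given the seed: the supplied init, two
fixed spread starts, plus seeded perturbations), with Cholesky jitter
escalation and a conditioning error if the Gram matrix never factors.
Predictive variance includes the noise term.

Baselines: an ε-insensitive linear SVR (standardized internally,
deterministic libsvm solve; note its solver precision degrades roughly
linearly in C, so very large C buys nothing) and a density look-up
`weight = ρ(class)·V`.

Model assessment is shuffled k-fold cross-validation (default 5), pooling
held-out errors: RMSE = √(Σe²/n), MAPE = (100/n)·Σ|eᵢ|/wᵢ (the package's
definition of "percentage error"), with signed errors retained per record
for error-distribution plots. Per-configuration consistency statistics use
the sample standard deviation (n−1), reported rounded to integer mm³.

## Synthetic study conditions

The generator's defaults define the study conditions and are not tuned per
experiment:

* **Geometry.** Tray at 1200 mm, f = 2400 px, B = 75 mm, 640×480 — giving
  kpix = 0.5 mm/px at the tray. Rendering is orthographic top-down
  (depth = tray − height at each pixel centre), matching the single-kpix
  integration model so the simulator tests the algorithm as defined rather
  than introducing a projection mismatch; a perspective mode is deferred.
* **Solids.** Spherical cap (cap height ≤ sphere radius — deeper cuts
  overhang their footprint and are rejected by the renderer, though the
  voxel oracle handles them up to a full sphere), cylinder, cuboid,
  frustum; exact masks, closed-form volumes, palette colours. Footprints
  must be disjoint; occlusion between foods is out of scope. An optional
  plate renders as a disc with a raised rim annulus so rim pixels exercise
  the in-tray-mask height path.
* **Sensor noise.** Modelled in the disparity domain: depth → disparity,
  add Gaussian matching noise (σ_d = f·B·σ_z/Z²), round to the matcher's
  subpixel step (default 1/8 px ≈ 1 mm at 1200 mm), convert back — which
  reproduces the quadratic growth of depth error with distance. Low-texture
  failure is a dropout region (bbox or class mask) that either invalidates
  pixels or flattens the scene to a fixed height, emulating a matcher
  latching onto surrounding texture over a featureless top.
* **Volume–weight laws.** Linear (rice-like): w = 9·10⁻⁴·V g + N(0, 10 g),
  n = 48, V ∈ [1, 3.5]·10⁵ mm³. Smooth nonlinear (chicken-like):
  w = 0.5·√V·(1 + N(0, 0.02)), n = 72, V ∈ [1, 4]·10⁵ mm³ — both give
  effective densities near 0.001 g/mm³ at typical portion sizes, with the
  concave law encoding bone/void fraction growing with piece size. The
  sample sizes match the chicken (72 images) and rice (48 images)
  validation datasets of the deployed system.

What the generator does **not** emulate: real food texture and BRDF, stereo
block-matching itself (noise is injected parametrically), perspective
projection, inter-food occlusion, specular plates. Passing tests therefore
demonstrate correctness of the measurement algorithm and its failure-mode
accounting under the stated geometry — not end-to-end accuracy on real
captures, which additionally depends on segmentation quality and true
sensor behaviour.

## Numerical and testing choices

* Volume integration runs in float64; integration agrees with closed forms
  to ≲0.04% at kpix = 0.5 (PNG-stored depth rounds to 1 mm and shifts the
  cap example by ~0.004%).
* The brute-force voxel oracle counts voxel centres inside the exact solid,
  slab-by-slab in z; at 0.25 mm voxels it sits within ~0.03% of the closed
  forms and serves as the independent check on the integration path.
* GPR recovery is validated on data simulated from a known OU GP
  (σf² = 1, l = 0.05 on a unit volume interval, noise var 0.0625, n = 200).
  For an OU kernel only σf²/l is consistently estimable under fixed-domain
  asymptotics and the posterior path variance cannot vanish at finite n, so
  the held-out benchmark is the **Bayes predictive floor**: the closed-form
  GP posterior RMSE under the true hyperparameters on the same CV folds.
  The fitted model must land within 15% of that floor and recover l within
  a factor of 2 — both hold with margin across consecutive seeds under
  these conditions.
* The linear/nonlinear model-ordering comparison is a statistical assertion
  over 20 replicate seeds (mean CV RMSE), not per-seed: on linear data the
  linear SVR's flexibility advantage is small but systematic, and on the
  concave law the GPR's bias advantage (~13 g peak deviation from the best
  line vs ~5 g noise) is decisive.
* Serving counting is a debounce: gated detections closer than `gap_s`
  (default 5 s, configurable) merge into one serving event. This is
  operational plumbing — no published counting algorithm exists for this
  setting — and the default gap is a deployment guess, exposed in config.

## Known limitations

Single scalar reference plane (no per-pixel plate-depth correction — dish
depth matters but no correction formula is defined); no perspective
correction; no occlusion reasoning; the spatial filter reproduces a
configuration surface, not any vendor's exact kernel; absolute weight
accuracy on real data is bounded by segmentation quality and sensor texture
sensitivity, which the synthetic suite models only parametrically.
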