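# Methods

This note documents the models implemented in `hemistereo`, the
parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Geometry and conventions

Images are circular: a disc of radius `R` pixels about the optical
axis.  Array coordinates are 0-based `(row, col)` with the row axis
flipped into a mathematical frame (`x = col − c_col`,
`y = c_row − row`), so polar angles run counter-clockwise from +x in
`[0, 360)` degrees and the centre pixel takes `θ = 0` by convention.

The projection is the ideal equidistant fisheye model: incidence angle
`α = (r/R)(π/2)`, i.e. the rim of the disc images rays at 90°
incidence.  The same constant is used in both projection directions so
that image → ray → world → image round trips close to below 1e−9 px at
zero baseline (this closure is property-tested).  No radial-distortion
model is applied.

Epipolar candidate lists sweep the object distance `d` over
`[d_min, d_max] = [0.5, 25] m` with 200 log-spaced samples — the near
field, where the projected point moves fastest, is sampled most
densely, and 25 m comfortably covers the working area of a stereo
inventory rig.  Projected points are rounded to the nearest pixel,
deduplicated preserving depth order, and filtered to pixels the
segmentation left as candidates.  Sub-pixel candidates are out of
scope.

## Segmentation

Two gates run in strict order.

*Contrast gate.*  `Z = 1 − 1/(1 + σ²)` with `σ²` the population
variance of the 3×3 intensity window (intensity `(R+G+B)/3` on the
0–255 scale, edge-replicated at borders).  `Z > T₁ = 0.8` means
`σ² > 4`; on a unit intensity scale `Z` could never reach 0.8, so the
8-bit scale is part of the definition.  High-contrast pixels are
excluded as leaf canopy.

*Colour classifier.*  Remaining pixels are classified on chromatic
coordinates `(R, G, B)/(R+G+B)` (pure black maps to the barycentre
`(⅓, ⅓, ⅓)` by convention), which cancel illumination magnitude so
shaded and sunny grass cluster together.  Two classifiers combine by
the mean rule `m_j = ½(μ_j + P_j)`:

- fuzzy c-means (c = 2, exponent `e = 2.1`, tolerance `ε = 0.1`, at
  most 20 sweeps) trained unsupervised with the pseudorandom centre
  initializer `v = 2M̄∘R + m̄` (R uniform in [0,1] per coordinate;
  degenerate coordinates pin the centre at the mean); cluster ↔
  texture identity is then fixed by majority vote of the labelled
  training samples.  A zero-distance sample takes a crisp membership
  row.
- a Gaussian maximum-likelihood model per texture (mean, unbiased
  covariance).  Because chromatic components sum to 1 the covariance
  is rank-deficient by construction; a ridge starting at 1e−6·I and
  escalating tenfold is added until the density is well defined.  The
  density enters the mean rule as the equal-prior posterior
  `P_j = p(x|c_j)/Σ_h p(x|c_h)` so both operands live on [0, 1].

A pixel is labelled sky or grass only under a strict argmax win with
`m_j > T₂ = 0.8`; otherwise it stays a matching candidate.  Raising
`T₂` can only shrink the sky+grass set (tested).

## Matching

Six attributes describe a pixel: 3×3 window correlation against the
specific candidate (pair-dependent), texture (sample standard
deviation of the window, divisor 8), raw RGB colour, Sobel gradient
magnitude (clamped at 255), gradient direction (degrees), and the
magnitude of the 8-neighbour Laplacian.  Differences are normalized by
the nominal ranges 2, 85, 765, 255, 360 and 2040 and clamped to
[0, 1].  Three choices deserve a note:

- correlation is intrinsically pairwise, so its "difference" is defined
  as `(1 − ρ)/2` — 0 at perfect match, 1 at perfect anti-match — which
  respects the nominal [−1, 1] range; a constant window yields ρ = 0.
- the direction difference is circular (shortest arc) before dividing
  by 360, so wrap-around pairs are not double-counted; its maximum is
  consequently 0.5.
- the texture constant 85 (window of one 0 and eight 255) is a
  normalization constant, not an upper bound — a 0/255 checkerboard
  window reaches ≈134 — hence the clamp.

WFS aggregates `d(A_l, A_i) = (1/6)Σ(1 − w_j|A_lj − A_ij|)`, which
spans [5/6, 1] because `Σw_j = 1`; scores are linearly remapped to
[0, 1].  The default weights derive from the reference relevance
percentages `p = (30, 12, 16, 10, 34, 30)` (correlation, colour,
texture, gradient magnitude, gradient direction, Laplacian) via
`w_h = p_h/Σp_k` — note these percentages are *error rates*, so the
formula gives the noisiest attributes the largest weights; the
implementation follows the published formula literally.  The Yager
baseline folds per-attribute similarities pairwise with
`S = 1 − min(1, ((1−s_h)^p + (1−s_k)^p)^{1/p})`, default `p = 2`.

Uniqueness is enforced left→right only: the strict score maximizer
wins; exact ties are broken by the smaller polar-angle shift (a
minimal-motion prior) and then by candidate order.  Disparity
`Δθ = |θ_l − θ_i|` (circular) is clipped to `θ_max = 6.0°` rather than
rejected, matching the disparity-map range; excluded and unmatched
pixels carry a NaN null.

## Hopfield smoothing

Matched pixels become network nodes with states
`D_i = 2Δθ/θ_max − 1 ∈ [−1, 1]`.  Null pixels are *absent* — they
contribute no edges — because frozen null neighbours would drag trunk
borders toward −1.  For 8-connected active neighbours the data
consistency `w_ik = 1 − |D_i − D_k|` is mapped to the connection
weight `T_ik = [sgn(w_ik)]^{v+1} w_ik` (v = number of negatives among
`{w_ik, D_i, D_k}`, `sgn(0) = −1`), which lowers the energy term
`−½T_ik D_i D_k` exactly when data and states are both consistent and
raises it under any inconsistency (all eight sign patterns are tested
exhaustively).  The diagonal is forced to `T_ii = 0`: a literal
evaluation at i = k conflicts with the zero-self-feedback stability
requirement, which wins.  The bias `U_i = B·D_i` is frozen at each
outer iteration's entry states (it must vary slowly for stability).

Each outer iteration freezes `T` and `U` and integrates
`u̇ = −u/R_i + T·tanh(u/β) + U` with classical fourth-order
Runge–Kutta: `K = 1000` inner steps of `dt = 10⁻³` (total time 1, one
unit of the relaxation time constant).  A single `dt` step would move
states by ~10⁻³, below the convergence tolerance `ε = 0.01`, and halt
the run immediately — hence the configurable `K`.  The run stops when
no node moves by more than `ε` or after `t_max = 20` outer iterations.
Constants: `A = B = R_i = 1`, gain `β⁻¹ = 2.30` (`β = 0.43`) held
fixed; the annealing schedule `β(t) = β₀/log₁₀(t+1)` with
`β₀ = 5⟨ΔE⟩ = 4.35` is implemented behind a flag for completeness
(`β(10¹⁰) ≈ 0.43` reproduces the fixed gain).

Two properties of the dynamics matter in practice:

- *saturation*: `tanh` drives a neighbourhood whose states share a sign
  toward that extreme.  Mid-range disparity plateaus therefore drift to
  0 or `θ_max` over many iterations; the smoothing is most faithful
  where true disparities cluster at the map limits (near trunks clip at
  `θ_max`), which is exactly the near working area the error metric
  evaluates.
- *energy descent*: the monitored energy `E = −½D^T T D − U·D` omits
  the integral term of the full Lyapunov function (its contribution is
  bounded by `β ln 2 ≈ 0.30` per node), so exact within-iteration
  monotonicity is not a theorem; empirically the recorded traces
  descend, and the tests allow a relative slack of 1e−9 of the trace
  range.

## Synthetic scenes

The generator renders, from both camera positions under the same
equidistant model: a blue-dominant homogeneous sky (Gaussian noise
σ = 1.2); a green-dominant grass ring near the horizon (incidence
≥ 78°) with a multiplicatively shaded sector (factor 0.55 — chromatic
coordinates are shading-invariant, which is what the classifier
exploits); leaf-canopy sectors filled with uniform speckle of ±60
intensity levels (no spatial frequency structure, deliberately — the
leaf gate keys on contrast alone); and trunks as vertical cylinders
standing on the ground plane, intersected analytically per ray.
Trunk surfaces carry a cross-width illumination gradient (amplitude
0.08) and bark banding (±1.5 levels, 1 m period) — strong enough to
give the matching attributes structure, weak enough (≲2 levels/px)
that trunk interiors stay below the leaf gate's `σ² > 4`.

Ground truth is analytic: each left trunk pixel's 3-D surface point is
projected into the right camera, giving the exact correspondence and
polar-angle disparity (clipped to `θ_max`, as the map range requires).
The reprojection consistency is property-tested to 1e−6°.

The default regression scene places four trunks 1.4–2.6 m from the
rig — inside the near working area a forest inventory evaluation
targets — at azimuths away from the baseline direction (±90° from it
the polar-angle disparity degenerates to zero regardless of distance,
an intrinsic blind spot of angular disparity).  At these ranges the
true disparities exceed and clip at `θ_max`, so the map is bimodal
(6° or null) and the saturating smoother is in its favourable regime.
One trunk is deliberately placed so that its right-image projection
falls near another trunk's left-image bearing, seeding the candidate
lists with genuine small-disparity false matches that the attributes
must reject — without it every scoring method ties exactly.

What passing tests on these scenes do **not** show: robustness to real
bark texture, occlusion, wind motion between exposures, vignetting or
calibration error; nor the absolute error percentages of a field
evaluation, which depend on real imagery and expert ground truth.  The
scaled-down evaluation checks the *ordering* of methods (smoothed ≤
combined ≤ worst single attribute) and the stabilization of the energy
trace, not absolute error levels.  Because the published weight
formula emphasizes the noisiest attributes, the combined-vs-worst gap
is fractions of a percentage point on these scenes and can invert at
unlucky seeds; the fixed default seed is used throughout.

*Error metric.*  The per-pixel error criterion is an angular
tolerance: a trunk pixel counts as wrong if its estimate is null or
deviates from the true disparity by more than 0.5° (one level of a
12-level colour scale over `[0, 6°]`); the tolerance is configurable
and the error percentage is monotone in it.  Problem sizes used
throughout: 131×131 px images (radius 63), ~1 200 active network
nodes, 200 depth samples — small enough that the full pipeline runs in
seconds while every stage is exercised.

## Known limitations

- Angular (polar-angle) disparity is blind near the baseline azimuths
  and saturates at `θ_max`; object distance is not recovered here.
- The smoothing network's tanh saturation quantizes mid-range
  disparity plateaus toward the map limits.
- The segmentation contrast gate removes one- to two-pixel trunk
  borders (mixed windows), an error floor no matcher can recover;
  interior accuracy is the meaningful quantity.
- Only two smooth-texture clusters (sky, grass) are supported; trunk
  texture classification is deliberately out of scope.
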