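# Methods

## Curvature model

A surface point has two principal curvatures, the extreme normal
curvatures over all tangent directions. The distal femur is, to first
order, a cylinder whose axis runs mediolaterally: on that idealization
the maximal curvature `k_max = 1/r` wraps the condyles and the minimal
curvature `k_min = 0` runs along the axis. The trochlear groove breaks
the idealization as a concave band — with outward normals and the
convention that convexity is positive, the groove carries `k_min < 0`,
and deeper grooves are more negative.

Curvature is scale-dependent on a discrete mesh: the neighborhood over
which the surface is fitted acts as a band-pass. Two scales are used,
both expressed as fractions of condylar width so the maps transfer
across differently sized knees:

| map    | component | factor | radius at 78.0 mm width |
|--------|-----------|--------|-------------------------|
| ridge  | `k_max`   | 0.05   | 3.9 mm                  |
| groove | `k_min`   | 0.13   | 10.1 mm                 |

78.0 ± 6.7 mm is the literature mean adult condylar width; the package
either takes the width as an argument or measures it as the projection
extent (max − min of vertex dot products) onto a mediolateral axis. No
standard measurement procedure for that axis exists for arbitrary mesh
orientations, so two modes are exposed: a user-supplied unit vector, or
the first principal axis of the distal 25% slab of the mesh (on a distal
femur the widest spread of the condylar block is mediolateral). Both are
deliberately simple; on badly cropped or strongly tilted meshes supply
the axis explicitly.

### Estimator

Per vertex: all vertices within a Euclidean ball of the fitting radius
are expressed in the tangent frame of the vertex normal, a quadric
height field `h = a u² + b u v + c v² + d u + e v` is fitted by ordinary
least squares, and the shape operator of the fitted patch at the origin
(full Weingarten map `S = −I⁻¹ II`, first-order terms retained so an
imperfect normal does not bias the result) gives the two eigenvalues,
ordered `k_max ≥ k_min`. Choices and edge cases:

- **Euclidean ball, not geodesic.** At 0.05–0.13 of bone width the two
  neighborhoods nearly coincide on femur-like surfaces; the Euclidean
  ball needs only a k-d tree. On thin structures (ball jumping across a
  slab) this approximation would break — out of scope for femora.
- **< 6 neighbors** (the quadric has 5 parameters): the vertex is
  flagged undefined (NaN, `defined=False`) rather than raising; the
  colormap paints it neutral gray.
- **Boundary vertices**: any vertex whose ball touches an open boundary
  edge is computed normally but flagged `boundary`, since cut planes
  produce exactly the rim artifacts one sees on clipped CT segmentations.
  Validation suites exclude flagged vertices.
- On analytic primitives sampled at a few vertices per fitting radius
  the estimator is well within the 10% relative-error band the test
  suite enforces (2% on cylinder/sphere at the tested resolutions, ~7%
  worst-case on a saddle).

## Rendering

Orthographic software rasterizer: per-triangle z-buffer with barycentric
color interpolation, no GPU context, so output is byte-identical across
machines and runs. The anatomical frame defaults to `view_axis = +Y`
(looking at the femur from anterior) and `up_axis = +Z`
(distal→proximal); both are configurable since scanner frames vary. Every
view records `pixels_per_mm`, the axes, and the model point at pixel
(0, 0), making the image↔model transform invertible in-plane — the
round-trip is exact up to floating point, and landmark clicks in pixels
are therefore metrically interpretable.

Colormaps clamp curvature to a fixed range and map linearly onto a
cold→warm palette (matplotlib's `turbo` by default). Published figures of
this kind state no color-scale numbers, so the defaults were chosen so
cylinder-scale anatomy spans the palette: `k_max` map [0, 0.5] /mm,
`k_min` map [−0.2, +0.05] /mm; both fully configurable. The `k_min`
clamp is asymmetric because the interesting contrast is concave-vs-flat.

## EPTG angle

Landmarks per AP view: lateral and medial condyles, distal trochlear
notch apex, the facing ends of the medial and lateral ridges, and
optionally a transition point (or the explicit statement that none is
visible). The angle is measured at the notch apex between the line to
the *entry point* and the line perpendicular to the transcondylar line.

Two interpretive decisions are made explicit because the click protocol
alone does not pin them down:

1. **Entry-point combiner**: the transition point when marked, otherwise
   the midpoint of the two ridge ends. This is the principal
   interpretive decision of the implementation; `entry_point` is a
   separate function so alternative combiners can be swapped in.
2. **Reference line**: perpendicular to the transcondylar line rather
   than the image vertical. On standardized AP screenshots the two
   coincide; using the transcondylar perpendicular additionally makes
   the angle invariant to in-plane rotation (and to similarity
   transforms generally, which the property tests assert).

Angles are stored signed — positive means the entry point lies on the
side of the clicked lateral condyle — and summarized as magnitudes,
matching how the metric is conventionally reported. Sessions duplicate
every knee across the two aid conditions and shuffle with a seeded
permutation, so a rater works blind to the pairing; re-recording a
completed item is a hard error.

## Statistics

- **Mann-Whitney U** (scipy): exact null for small untied samples,
  tie-corrected normal approximation otherwise. **Fisher exact**
  (scipy) for the 2×2 sex table. **Holm** step-down via statsmodels.
- **ICC.** Two-way ANOVA mean squares (subjects × raters) with
  `A1 = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` and
  `C1 = (MSR − MSE) / (MSR + (k−1)MSE)`; 95% CIs per the McGraw–Wong
  F-based formulas, Satterthwaite degrees of freedom for A1. Inter-rater
  reliability uses A1 (absolute agreement across interchangeable
  raters); intra-rater reliability uses C1, which ignores a rater's
  constant drift between repeated sequences. Estimates are clipped at 1
  against floating-point overshoot in degenerate perfect-agreement
  matrices; missing cells are rejected (the design is complete).
  Classification boundaries (0.5, 0.75, 0.9) go to the higher class,
  since the conventional verbal intervals overlap at their endpoints.
- **Permutation test.** The observed statistic is the with-aid ICC(A,1).
  Each of the (default) 100,000 Monte Carlo replicates reassigns every
  subject's full rater row to the with-aid or without-aid table with
  probability ½ and recomputes the ICC;
  `p = (#{replicate ≥ observed} + 1) / (n + 1)`. The add-one correction
  is a deliberate choice: a raw "proportion better" yields p = 0 in
  degenerate cases, which no Monte Carlo test can support. A
  `statistic="difference"` variant (with-aid minus complement ICC) is
  provided for sensitivity analysis. The replicate ICCs are computed
  vectorized over batches, so 100,000 replicates on a 60 × 3 table take
  about a second.
- **Sample size.** Cohen's d from the pooled SD; the smallest integer n
  with two-sample noncentral-t power ≥ the target is found by iteration,
  then divided by the Mann-Whitney asymptotic relative efficiency 0.955
  (normal parents) and rounded up. For the reference inputs
  (31.8 ± 10.3 vs 16.3 ± 9.4, α = .05, power = .8) the t iteration gives
  8 and the ARE route 9; a plain t-test computation is exposed as
  `method="t-test"` because the two routes genuinely differ and the
  discrepancy matters when comparing against published power analyses.
  Results are floored at 3 per group (ANOVA/CI validity).

## Synthetic data

**Phantom.** A half-shell of a cylinder (axis mediolateral, radius 20 mm,
width 78 mm by default) with a Gaussian-profile groove carved radially
inward along a centerline that starts at the distal notch and deflects
laterally with proximal progression, flanked by two raised Gaussian
ridges. The sweep is windowed with a C² smoothstep so the surface stays
twice differentiable — a requirement for well-posed quadric fitting. The
generator returns the groove centerline, ridge crest polylines, the 3D
positions of the protocol landmarks, and the construction EPTG angle
(arctangent of lateral deflection over proximal rise of the entry point
relative to the notch, in AP projection). The phantom reproduces the
qualitative features the maps must expose — concave band, convex flanks,
controllable depth/width/lateralization — and nothing else: it is not a
statistical femur shape model, and passing tests on it demonstrates
correctness of the geometry pipeline, not segmentation-grade realism on
patient anatomy.

**Rater simulator.** `angle(knee, rater, condition, rep) = group mean +
knee effect + rater bias + noise`, with the knee effect
`Normal(0, subject_sd)`, fixed per-rater biases, and condition-specific
noise SDs. Defaults emulate a 60-knee, three-rater study with patient and
control means 31.8° and 16.3°, between-knee SD 9°, and noise 3.5° with
aid vs 7.0° without — with-aid measurements are modeled as less noisy,
which is the hypothesis the reliability machinery is built to detect.
The implied true ICC(A,1) is returned in closed form as
`(σ_s² + σ_g²) / (σ_s² + σ_g² + σ_b² + σ_e²)`, where the fixed effects
enter through the ddof = 1 sample variances of their realized offsets
(rater biases σ_b², patient/control group means σ_g²) — exactly the
contributions they make to the expected ANOVA mean squares, so the
simulator's implied value is the estimand of the estimator applied to
its tables. All randomness flows through explicit integer seeds; there is
no global RNG state.

## Problem sizes in the validation suite

Primitives are sampled at 0.5–0.8 mm spacing (≥ 12,000 vertices on the
cylinder, ball populations of 30+ per fit); phantoms at 1 vertex/mm
(~7,000 vertices). ICC recovery uses 500 tables of 30 × 3 per
reliability level; permutation validity uses 200 null runs at 1,000
replicates (20 subjects × 3 raters) plus a 60-subject power check at
10,000 replicates. These sizes give estimator standard errors comfortably
inside the asserted bands while keeping the default suite around a
minute of compute.

## Limitations

- The quadric-fit estimator is one member of the family of local-fitting
  curvature estimators; different mesh-processing libraries implement
  variants (different weighting, geodesic neighborhoods, normal cycles)
  that agree on smooth surfaces at matched scales but are not bit-level
  interchangeable.
- The CLI consumes batch landmark JSON; there is no interactive click
  UI, and no automatic landmark detection.
- Rendering is flat-shaded orthographic with per-vertex colors; it is
  built for measurement and testing, not presentation-quality figures.
- The condylar-width auto-axis assumes the mesh is roughly in an
  anatomical frame (distal at low `up_axis`); arbitrary orientations
  require a manual axis.
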