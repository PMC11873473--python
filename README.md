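# trochleamap

Two-scale 3D curvature visualization of the distal femur, landmark-based
measurement of the entry-point-to-trochlear-groove (EPTG) angle, and the
inter-rater reliability statistics needed to evaluate whether curvature
overlays improve that measurement.

## Who this is for

Researchers in orthopaedic morphometry who have segmented distal-femur
surface meshes (STL/PLY/OBJ, millimetres) from CT and want to:

1. **Visualize trochlear dysplasia.** The trochlear groove — the concave
   channel that guides the patella — can be shallow, short, or lateralized
   in patients with patellar instability, which is hard to appreciate in a
   rendering on a flat screen. Overlaying principal curvature at two
   neighborhood scales exposes it: the *maximal* principal curvature
   `k_max` at a small fitting radius (0.05 × condylar width ≈ 3.9 mm on a
   78.0 mm adult femur) highlights the trochlear ridges, while the
   *minimal* principal curvature `k_min` at a large radius (0.13 ×
   condylar width ≈ 10.1 mm) highlights the groove. Sign convention:
   convex regions (condyles, ridges) positive, concave regions (the
   groove) negative — a cylinder of radius *r* has `k_max = 1/r` along its
   circumference and `k_min = 0` along its axis.
2. **Measure the EPTG angle** from clicked landmarks on anteroposterior
   (AP) view renders: the angle at the distal trochlear notch between the
   line to the trochlear entry point (midpoint of the two ridge ends, or
   an explicitly marked transition point) and the perpendicular to the
   transcondylar line. Positive angles mean a lateralized entry point.
3. **Quantify reliability**: two-way single-score intraclass correlation
   coefficients — ICC(A,1), absolute agreement, and ICC(C,1), consistency
   — with McGraw–Wong 95% CIs and the standard classification
   (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent), a
   Monte Carlo permutation test comparing with-aid vs without-aid ICCs,
   Mann-Whitney patient/control comparisons with Bonferroni-Holm
   correction, Fisher's exact test, and a priori Mann-Whitney sample-size
   computation (noncentral-*t* iteration inflated by the ARE 0.955).

Curvature is estimated per vertex by a least-squares quadric fit over a
Euclidean ball of the fitting radius in the tangent frame of the vertex
normal, taking the eigenvalues of the shape operator of the fitted patch.
A built-in phantom generator (grooved cylinder with analytically known
centerline, ridge crests, and construction angle) and a variance-component
rater simulator make the whole pipeline testable without any CT data.

## Worked example

Generate a phantom with an 8 mm lateralized groove, render the AP
triptych, measure the EPTG from scripted landmarks, and run the
statistics on a simulated rater table:

```sh
echo '{"groove_lateral_offset": 6.0, "mesh_resolution": 0.7}' > spec.json
trochleamap phantom --spec spec.json --out phantom.stl --truth truth.json
# wrote phantom.stl (2464 vertices)
trochleamap render --mesh phantom.stl --width-mm 78 --out triptych/
# INFO radii: ridge 3.9 mm, groove 10.14 mm
# wrote triptych to triptych
```

The triptych contains `ap_plain.png`, `ap_ridge.png` (k_max at 3.9 mm)
and `ap_groove.png` (k_min at 10.1 mm), each with a sidecar JSON giving
the camera so pixel clicks map back to millimetres. Landmarking the
phantom's ground-truth features and computing the angle:

```python
>>> import trochleamap as tm
>>> spec = tm.PhantomSpec(groove_lateral_offset=8.0, mesh_resolution=1.0)
>>> mesh, truth = tm.make_trochlea_phantom(spec)
>>> view = tm.render_ap_view(mesh, None, pixels_per_mm=2.0)
>>> px = {k: view.model_to_pixel(v) for k, v in truth.landmarks_3d.items()}
>>> tm.compute_eptg(tm.LandmarkSet(**px))
18.162228931898007
>>> truth.expected_eptg_deg
18.162228931898003
```

The measured angle recovers the construction angle of the phantom's
groove deflection. A full reliability report on a simulated three-rater,
60-knee table:

```text
$ trochleamap stats --measurements sim.csv --seed 11 --n-permutations 20000 --out report.json
EPTG reliability report
==============================================
inter-rater ICC(A,1) with_aid     0.90 [0.85-0.94]  excellent
inter-rater ICC(A,1) without_aid  0.74 [0.63-0.82]  moderate
MWU with_aid     control 15.1±9.0 vs patient 29.8±8.0  p(Holm)=4.057e-07
MWU without_aid  control 16.0±9.7 vs patient 29.6±8.1  p(Holm)=7.599e-07
permutation test: observed ICC 0.903, p = 5e-05 (20000 replicates, seed 11)
```

Here the simulator was configured with rater noise of 3.5° with aid and
7.0° without (between-knee SD 9°), and the report recovers exactly that
structure: excellent with-aid reliability, moderate without, a
significant permutation p for the improvement, and strongly significant
patient/control separation under both conditions.

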