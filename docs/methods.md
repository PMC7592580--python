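# Methods

## Scope and model

`limbvol` implements the measurement chain used in peri-operative
lymphedema surveillance of the arm: circumference-based **truncated-cone
(frustum) volumetry**, an equivalent volume computed from a **3D point
cloud** of the limb, the **percent-difference** screening statistic with
its follow-up rule, capture-**posture validation**, and the
**method-agreement battery** used to compare the two modalities.  No
patient data is involved anywhere: a parametric limb generator with
closed-form ground truth stands in for scans and tape sheets.

### Frustum volumetry

A limb between two tape stations with circumferences `C1`, `C2` and axial
gap `h` is modelled as a conical frustum of circular cross-section:

    V_seg = h (C1² + C1·C2 + C2²) / (12π)

which is the classical `π h (r1² + r1 r2 + r2²)/3` with `C = 2πr`.  The
limb volume is the sum of segments from the wrist (ulnar styloid, station
0) to the axilla, every 4 cm by default, sparing the hand.  Units are cm
and cm³ (≡ mL) throughout.  Uneven gaps are allowed (`h` is taken per
segment) and a trailing segment shorter than the nominal interval is kept
with its true height — discarding it would systematically drop the
thickest part of the arm whenever the limb length is not a station
multiple; `include_partial_end=False` reproduces the truncate-at-last-grid
behaviour.

### Synthetic limbs

A limb is a surface of revolution with piecewise-linear radius profile
`r(s)`, `s ∈ [0, L]` wrist→axilla (default knots 2.5 cm at the wrist, 4 cm
mid-forearm, 4.5 cm at the elbow, 5 cm at the upper arm over `L = 40` cm —
an unremarkable adult arm of ≈ 2.2 L).  Because the profile is piecewise
linear, `π ∫ r(s)² ds` is an exact frustum sum, so every downstream
estimate can be compared to machine-precision ground truth.  Swelling is a
radial factor `γ ≥ 1`, uniform or on a sub-interval; uniform swelling
scales volume by exactly `γ²`, which is what the percent-difference screen
must recover (`γ = 1.1` against a contralateral `γ = 1` gives PD = 21%).

Captures are simulated per view (front/back/left/right sensors on the
±y/±x world axes): points drawn uniformly in axial position and azimuth,
kept when the outward normal faces the sensor, merged assuming perfect
registration (multi-view extrinsic calibration is out of scope and its
perfection here is an idealisation, not a claim about any device).
Imperfections: isotropic Gaussian surface jitter; *clothing occlusion*
that deletes all points on the proximal fraction of the limb; optional
spherical "hand blob" distal to the wrist to exercise hand sparing; tape
noise as Gaussian jitter on circumferences (floored at 0.1 cm).  The
generator never touches global RNG state; one explicit seed per call.

What the generator does **not** emulate: elliptical or concave
cross-sections, elbow crease and musculature, sensor-physics depth noise
(quantisation, edge flare), registration error between views, and soft
tissue deformation with pose.  Passing tests therefore validate the
geometry and statistics of the pipeline, not the behaviour of any
physical scanner on real arms.

### Scan pipeline

1. **Quality gate** — a scan is refused (never guessed at) when the cloud
   has fewer than 1000 points, any station-interval bin between the
   landmarks holds fewer than 30 points, or the axial coverage gap exceeds
   one interval (typical clothing occlusion).  The three thresholds are
   deliberate defaults exposed in `QualityConfig`; "low quality" has no
   universal clinical definition.
2. **Axis** — principal component of the between-landmark points, accepted
   when within 30° of the wrist→axilla chord, otherwise the chord; oriented
   wrist→axilla.  Hand points (axial coordinate < 0) are excluded from the
   fit.
3. **Slicing** — stations every 4 cm from the wrist's axial coordinate,
   half-open slabs `[s − 0.5, s + 0.5)` cm (boundary points belong to the
   distal slab), hand excluded, trailing partial station included.
4. **Circumference per slab** — project slab points onto the plane
   perpendicular to the axis.  A linear radius trend across the slab is
   fitted and removed first (*taper compensation*): without it the slab
   traces a 1-cm-long cone segment whose widest section, not the station's,
   dominates the estimate.  Dense slabs (≥ 60 points) are then summarised
   by an **inscribed polygon through azimuthal-bin mean radii** (bins of
   ~15 points, 24–90 bins).  Sparse slabs fall back to the perimeter of the
   2D convex hull.  The bin-mean polygon was chosen over the plain hull
   after the hull proved outward-biased on sampled data: the hull keeps
   only extreme points, so axis-tilt shadow and any radial scatter inflate
   the perimeter, whereas bin means average scatter out and leave the
   known inscribed-polygon deficit (−(2π/K)²/24, about −0.1% at K = 40) as
   the dominant, *sign-predictable* residual.  Noiseless recovery is
   within ~0.3% and from below, which keeps the scan ≤ tape direction
   testable.
5. **Volume** — the per-station circumference series goes through the same
   frustum integrator as tape, so the modalities differ only in how
   circumferences are obtained.  `area_mode="hull"` instead integrates
   cross-section areas with `h(A1 + √(A1A2) + A2)/3`.

Whether the proximal boundary runs along the limb axis or along the skin
surface is a convention; the axial one is used.

### Posture validation

Compliance per view: abduction ≥ 75° (front/back) or ≥ 45° (sides), and
flexion ≤ 5°, both inclusive — inclusivity at the boundary is a choice,
documented here.  The flexion limit is applied to all views by default
(conservative; the protocol states it anteriorly) and can be restricted
with `flexion_all_views=False`.  `pose_from_landmarks` recovers abduction
as the in-coronal-plane angle of the shoulder→elbow vector to the trunk
axis and flexion as the anterior out-of-plane component; it is a pure
per-frame function with no temporal smoothing.

### Screening

Per visit with bilateral quality-ok volumes of one modality:
`PD = 100 (V_aff − V_unaff)/V_unaff`.  The concern flag fires when the
change in PD from the earliest usable visit exceeds 5 percentage points
*and* the visit is more than 6 weeks post-operative — earlier elevation is
treated as ordinary surgical swelling.  Whether the 5% criterion refers to
the change in inter-limb PD or to within-limb change from baseline is
genuinely ambiguous; the inter-limb reading is the default
(`mode="change"`), `mode="absolute"` flags on raw PD, and the within-limb
change is reported alongside either way.  Follow-up bins are 2–3, 4–6 and
7–12 weeks with fractional weeks rounded half-up.  Tape and scan tracks
are never mixed.

### Agreement statistics

OLS of scan on tape (tape is the reference method, hence the predictor);
Bland-Altman bias `mean(scan − tape)` with limits of agreement
`bias ± 1.96·SD` using the sample SD (ddof 1); per-operator R²; one-way
ANOVA of PD changes across the three follow-up bins; pairwise Welch
t-tests with Welch–Satterthwaite df and Bonferroni correction with `m` =
number of comparisons actually performed (3 for three bins), α = 0.05.
Degenerate conventions: a zero-variance response gives R² = 0; identical
constant groups give F = 0, p = 1; two constant groups with unequal means
give |t| = ∞, p = 0.

Implementation routes are deliberately split from their test oracles:
regression uses `scipy.stats.linregress` (checked against the normal
equations), ANOVA is a manual sum-of-squares decomposition with the F
survival function (checked against `scipy.stats.f_oneway`), Welch is the
direct formula with the t survival function (checked against
`scipy.stats.ttest_ind`), Bland-Altman is direct arithmetic.

## Problem sizes and determinism

Headline checks run at: 1000 random frusta for the closed-form identity;
100 random grid-knot limbs for tape exactness; ~50 000-point noiseless
clouds for scan recovery of the cylinder (640π ≈ 2010.6 mL) and 3→5 cm
taper (≈ 2052.5 mL) references; 50-limb paired cohorts at three noise
conditions — noiseless, (σ_tape, σ_surface) = (0.2, 0.1) cm, and
(0.6, 0.3) cm — with 3000 points per view.  These sizes give stable
statistics (slope and R² move in the fourth decimal across seeds) while
the whole battery completes in seconds.  All randomness flows from
explicit `numpy.random.default_rng` seeds; `scripts/acceptance.py` derives
every sub-seed from its `--seed` argument.

## Known limitations

* Cross-sections are assumed convex and roughly circular; the inscribed
  polygon and the frustum model both under-represent concave or strongly
  elliptical limbs.
* Landmarks are inputs, not detected; landmark placement error propagates
  directly into the station grid.
* View registration is assumed perfect; no ICP or extrinsic calibration.
* The screening thresholds (5%, 6 weeks) are protocol constants, not
  fitted quantities; nothing here estimates their operating
  characteristics on real populations.
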