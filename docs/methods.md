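# Methods

## The measurement problem

OCT records backscatter versus optical delay along each probing ray
(A-scan). Inside the eye the delay accumulates as Σ nᵢ·dᵢ over the media
traversed, so a B-scan shows every structure behind the cornea too deep by
the local refractive index and laterally displaced wherever a ray met a
curved interface obliquely. Quantitative full-eye biometry therefore needs
(i) surface segmentation in image coordinates, (ii) an explicit inversion of
the refractive distortion, and (iii) parameter definitions evaluated on the
corrected geometry. `octeye` implements that chain and a forward model rich
enough to validate it end to end.

## Forward model (phantom)

Surfaces are circular arcs (apex position + signed radius; ∞ = flat). One
ray per A-scan column is traced anterior → posterior: at each arc the ray
refracts by the vector form of Snell's law using the local arc normal, the
optical path advances by n·(geometric segment), and each medium deposits its
mean linear backscatter between its interface crossings at the accumulated
optical depth, with partial-volume weighting at fractional pixels. On the
AP axis this makes interface depths exactly Σ nᵢ·dᵢ — the property the
correction must invert.

The iris is two mirror wings. Each wing's pigment epithelium is a quadratic
Bezier through the root (inserted on the posterior cornea at the
iridocorneal angle, lateral position ±950 μm), the iris–lens contact point
(on the anterior lens at the pupil margin, ±500 μm), and a mid-span apex
offset perpendicular to the root→contact chord by the *sag* (μm, positive
toward the cornea). The iris body is a 40 μm band anterior to that curve
and does not refract (its index is taken as aqueous); where the band would
poke into the cornea near the angle it is clipped at the endothelium —
which is also what an anterior-chamber image of angle closure looks like.

Default mouse baseline: CCT 119, ACD 404, LT 1860, CRD 3080 μm (axial
distances), iris sag 28.6 μm. Curvature radii are plausible free constants,
not measured values: cornea +1500/+1450, lens +1000/−1000, ILM −1700 μm.
Layer intensities (linear, arbitrary units): cornea 0.45, aqueous 0.12,
lens 0.35, vitreous 0.08, retina 0.75, iris 1.00 — ordered so that the iris
and retina are unambiguously the brightest bands and the opacified lens
(multiplier ≤ ~1.3) never reaches them. The calibration model eye uses the
manufacturer anterior segment (0.55 / 3.03 / 3.9 mm) plus a 2.0 mm synthetic
vitreous so the pipeline, which requires a retina, runs unchanged; it has no
iris.

Imaging defaults: 3 μm axial (optical-path) and 10 μm lateral pitch,
1728 × 208 pixels for the mouse (the ~4.9 mm optical depth of the whole eye
fits with margin); 6 μm / 25 μm and 2400 × 192 for the longer model eye.

### Osmotic response

Within each phase every parameter relaxes exponentially toward an asymptote
expressed as a fractional change of baseline,
p(t) = p∞ + (p(t₀) − p∞)·e^(−(t−t₀)/τ), continuous across phases; a phase
with no declared response relaxes back toward baseline (τ = 4 min). CCT
moves the posterior cornea, ACD translates the lens (the iris follows its
contact point and the root follows the endothelium), CRD moves the retina,
the iris sag follows its own response, and the lens-scattering response sets
the opacification multiplier applied anterior to a smooth front (sigmoid of
width 60 μm at 30 % of lens depth) — the gradual surface-to-centre
opacification seen under dehydration.

The packaged scenarios encode the observed response magnitudes as
calibration: the strong hypertonic arm peaks at CCT −20.7 %, ACD −11.5 %,
CRD −2.3 %, LT 0 %, LSI +28.8 %, and the iris sag maps 28.6 → 48.2 μm
(hypertonic) and → −24.6 μm (hypotonic). Time constants (2–2.5 min
hypertonic, 4 min hypotonic/reversal) are chosen so each phase reaches
steady state (rate < 1 % of initial, i.e. ≈ 4.6 τ) within its scheduled
duration — which is how the original phase durations were set. The milder
hypertonic arm is not quantified in the source data and defaults to half the
strong-arm magnitudes at ~25 % slower kinetics; the hypotonic arm uses
CCT +12 %, ACD +6 %, CRD +1.5 %, LSI 0 (no scattering change was seen under
hydration).

### Noise model

Default noise is 8-look unit-mean gamma speckle (contrast 1/√8 ≈ 0.35,
emulating the incoherent frame averaging typical of displayed OCT images)
plus additive Gaussian noise (σ = 0.01) and clipping at zero. All noise is
seeded; a run is bitwise reproducible, and a noiseless render is strictly
deterministic.

## Segmentation

Boundaries are gradient-magnitude peaks per A-scan (Gaussian pre-smoothing
σ = 1.5 px both axes, sub-pixel parabolic interpolation) above a global
noise floor (4× the median gradient magnitude, refined by Otsu's split of
the sub-edge population). Assignment is by intensity level of the
inter-boundary bands (median intensity, classified dark / mid / bright
relative to the brightest band in the image): the leading non-dark run is
the cornea and its end the endothelium; among deeper bright runs (merged
across thin speckle splits) the deepest is the retina — its top edge the
ILM — and the strongest clearly-anterior one the iris body, whose lower
edge is the pigment epithelium; the mid-level run between iris/cornea and
retina bounds the crystalline lens. Traces are cleaned with a rolling-median
outlier rejection (window 9, 4 px tolerance) and anatomical depth order is
enforced, not assumed. Optional seed points re-pin a label to the candidate
nearest the seeded depth, which is the "semiautomatic" mode.

The corneal vertex is the sub-pixel minimum of the anterior corneal trace
(local quadratic fit; flat traces tie-break to the lateral midpoint), and
the AP axis is the vertical line through it. Meridian-slice selection picks
the stack slice with the shallowest corneal apex.

## Refraction correction

Each interface is fitted with a circle (algebraic least squares with one
median-absolute-deviation rejection pass; flat fallback for collinear
points or radii beyond 5·10⁵ μm). Correction proceeds anterior →
posterior: for every surface point, its A-scan ray is propagated through
the already-corrected shallower arcs — bend by Snell at each arc's local
normal, advance by (optical-path increment)/n — and the final advance lands
the corrected point. Total internal reflection excludes a point (counted,
never silent). On the AP axis this reduces exactly to thickness/n per
layer.

Because the crystalline lens converges rays, *all* deep intersection points
end up laterally near the axis; the reliability criterion for lens/retina
points is therefore each ray's lateral position at the anterior-lens (iris)
plane: rays outside 0.95× the pupil half-width (estimated from the
innermost pigment-epithelium points, 5th percentile per wing) are excluded
from the arc fits.

Stress-agent indices (1.344 / 1.342 / 1.337 / 1.333 for 1000 / 500 / 250 /
100 mOsmol/kg) differ pairwise by < 0.82 % (relative to the larger index),
so tissue indices are treated as hydration-independent and no tear-film
layer is modelled.

## Biometry

CCT, ACD, LT, CRD are evaluated at the AP axis on the fitted corrected
arcs (which averages out per-point noise). LSI is the mean linear
intensity of the raw image along the AP-axis A-scan from the anterior lens
capsule to 15 % of the optical lens thickness (the anterior-capsule-to-
anterior-nucleus span; the fraction is configurable), averaged over ±8
columns; it is computed pre-correction because the average runs along the
A-scan itself.

IC per wing: the corrected pigment-epithelium trace is Savitzky–Golay
smoothed (local quadratic, window ≤ 17), a quadratic wing model is fitted on
the trace interior (the outermost 3 points at each end are excluded — the
fading band biases detection there), and the two landmarks are obtained by
extrapolating that model to its crossings with the anterior lens arc
(contact point) and with the corneal endothelium arc (root, the
iridocorneal-angle insertion). The IC is the signed extreme of the
perpendicular distances of the measured points from the root→contact chord
(positive toward the cornea), with local-quadratic smoothing of the distance
profile so a single noisy point cannot set the value; the two wings are
averaged. If a wing never meets the lens, the iris tip serves as the
central landmark and the record is flagged.

## Dynamics

Baseline = arithmetic mean of the pre-challenge repeats (default 5, imaged
once per minute ending at t = 0). Curves are reported as percent change
from baseline. Per phase: the signed extreme change (ties → earliest), a
least-squares fit of A·(1−e^(−Δt/τ)) (the summary also reports the
baseline-relative asymptote, since the first in-phase frame has already
moved), and the steady-state time — centred finite differences of a 3-frame
moving average, first time |rate| < 1 % of the first interior window's rate;
a constant series is steady immediately, a linear ramp never. Run
stability is summarized as the mean SD of the five normalized curve
parameters (CCT, ACD, LT, CRD, LSI); the iris curvature is not a normalized
curve — it is judged in absolute μm, where its frame-to-frame repeatability
(±2–3 μm under default noise) matches what repeated control measurements of
a real iris show.

## What the phantom does and does not emulate

It reproduces the geometry-dependent refractive distortion, layer
contrasts, speckle statistics, occlusion-free iris/lens overlap, and the
full acquisition schedules — so passing tests demonstrate that the
*measurement chain* is unbiased at the scale the physiology moves. It does
not model spectral-domain reconstruction artifacts (complex-conjugate
ghosts, dispersion), depth-dependent sensitivity roll-off, shadowing under
the iris, motion, or biological variability between animals; real-data
performance on those axes is untested by construction.

## Known limitations and numerical notes

- Detection loses the last 1–2 columns of the iris band where lateral
  smoothing dilutes it; landmark extrapolation absorbs this, but IC accuracy
  degrades (≈ +2–6 μm overshoot) in extreme anterior bowing when the wing
  hugs the endothelium over many columns (angle closure).
- The LT estimate can occasionally drop ~30 μm (~1.7 %) on noisy frames when
  anterior-lens detection thins inside the pupil; the arc-fit rejection
  bounds but does not eliminate this.
- Sub-pixel edge localisation assumes locally symmetric edge profiles;
  partial-volume rendering plus Gaussian smoothing satisfies this to
  ≲ 0.5 px.
- Ray–arc intersection takes the first on-branch crossing; rays missing a
  surface (beyond its lateral support) skip it, which merges aqueous and
  vitreous — harmless while both share n = 1.33.
- Problem sizes: the default suite renders single frames at 1728 × 208 and
  full scenario runs of 9–28 frames; these sizes were chosen so a complete
  arm simulates and measures in seconds on one CPU while keeping every
  geometric feature several pixels wide.
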