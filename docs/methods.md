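# Methods

`rhizopet` quantifies how much of a leaf-supplied ¹¹C tracer a pea plant
allocates to each nodule of its root system, from dynamic two-position PET
images, and provides a synthetic 4D-PET generator so that every analysis
stage can be exercised and validated without experimental data.  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic world does and does not establish.

## The measurement being emulated

A pea shoot receives a short ¹¹CO₂ pulse; the tracer (half-life
t½ = 20.4 min, λ = ln 2 / t½ ≈ 0.03398 min⁻¹) is exported to the root
system and accumulates in sinks, most conspicuously in rhizobial nodules.
A vertical small-bore PET scanner images an axial window of 95 voxels
(isotropic 1.15 mm, 61 × 61 × 95 per reconstruction); a moving table
alternates the plant between a lower and an upper position every 5-min
frame, extending the vertical field of view from 11 cm to 19 cm over a
110-min acquisition — 11 lower-position and 11 upper-position frames.

The quantity of interest is the **tracer fraction** of a nodule ROI: its
counts divided by the total belowground counts at the same time.  Numerator
and denominator decay identically, so the fraction needs no decay
correction and is robust to session-to-session differences in labelling
strength and plant uptake.  Each session is summarized by the mean fraction
over a low-variation four-frame window late in the acquisition (nominally
75–105 min), nodule fractions are summed per session, and a treatment
effect appears as a step/slope across the eight sessions (two per day,
four consecutive days, 13–16 DAT).

## Phantom

The phantom is a voxelized label map (default 61 × 61 × 166, so that the
two 95-voxel windows with a 70-voxel shift tile it) plus a structure table.
Structures are capsules (root segments) and spheres (nodules); a voxel
belongs to the structure whose geometry contains its center, with nodules
painted last so they own contested voxels.

Geometry defaults and their reasons:

- **Primary root**: a connected chain of six axial segments, radius 1.5 mm,
  with small lateral jitter.
- **Laterals**: 180 segments, radius 0.9–1.5 mm, length 15–40 mm, branching
  from the primary chain outward and downward.  This density (~14 000 root
  voxels ≈ 22 mL) is deliberately high: it sets the root *specific*
  activity low enough that nodules appear as hot spots roughly 6–20× above
  the root background, which is the regime the real images show and the one
  in which region-growing ROI masks are meaningful.
- **Nodules**: six spheres, radius 1.4–2.2 mm (PET-resolvable), each at the
  tip of a short thin pedicel rootlet (radius 0.6 mm, length 6–10 mm), with
  enforced clearance from all other roots and from each other.  This
  mirrors the experimental ROI selection criteria (distinct anatomy, few
  roots in the ROI, strong signal) — the generator only creates nodules an
  analyst would have accepted.
- **Allocation weights** w_i: dimensionless shares of total belowground
  allocation, Σ w_i = 1 exactly.  Nodules share 0.08 in aggregate (equal
  split with ±20% jitter); root segments share 0.92 in proportion to voxel
  volume.

## Kinetics

Each structure accumulates tracer as a delayed mono-exponential rise and
never re-exports it (terminal sink):

    A_i(t) = S_m · w_i(m) · (1 − e^{−k_i (t − d_i)}) · e^{−λ t},   t > d_i

- **k_i** (accumulation rate): nodules 0.06 min⁻¹, roots 0.07 min⁻¹, ±10%
  lognormal structure-to-structure jitter.  By the 95% convention the
  plateau falls at d + 3/k ≈ 50 min for nodules, the observed plateau time.
  The measurement never constrains the curve's analytic form, only the
  plateau; the mono-exponential is the simplest shape consistent with a
  terminal sink and is flagged as an assumption.
- **d_i** (arrival delay): 2 ± 0.5 min of phloem transport before tracer
  reaches the structure.
- **S_m** (session amplitude, Bq-equivalent): 10⁵ on day 1, growing
  linearly to +50% by day 4 (both sessions of a day share S_m), emulating
  the measured growth in CO₂ uptake.  Fractions are invariant to S_m by
  construction; it matters only for count statistics.
- **Treatment**: from session m* (default 5, the first session after the
  nitrate exchange) every nodule weight is scaled by r (default 0.545) and
  the removed share is redistributed over root segments proportionally to
  their weights, conserving Σ w_i = 1.  Conserving the total — rather than
  shrinking it — encodes that nitrate does not necessarily reduce total
  belowground carbon, it redirects it (nitrate also stimulates root
  growth).  Under this algebra the asymptotic summed nodule fraction drops
  from f₀ to r·f₀, i.e. the relative decrease is exactly 1 − r = 45.5%,
  inside the experimentally observed 40–47% band.

Frame integrals of A_i(t) have a closed form (difference of two
exponential integrals), used both by the renderer and as the analytic
reference in tests; k = ∞ (instantaneous uptake) is supported and reduces
to pure decay.

## Acquisition model

Reconstruction is emulated at the image level (no sinograms): per frame and
structure, expected counts = count_scale · ∫ A_i(t) dt over the frame,
spread uniformly over the structure's voxels inside the active axial
window, convolved with a Gaussian PSF of FWHM 1.4 mm (the positron-range
resolution limit; σ ≈ 0.52 voxel), then Poisson-sampled.  Blur is applied
per position window after cropping (reconstruction is per position) with
reflective edges, which conserves counts to <10⁻³ for structures ≥2 voxels
inside the window.  Frames integrate the *decaying* activity; decay
correction is an analysis-side step, as in real PET.  Frames start at PET
start (end of pulse + flush), the first frame in the lower position (the
ordering is not documented; lower-first is an arbitrary fixed choice).
count_scale defaults to 10 counts/(Bq-eq·min); with S₁ = 10⁵ this puts
late-window nodule ROI counts at a few thousand per frame, so the relative
noise of a four-frame mean fraction is below ~1% — the regime in which the
published per-session SDs were smaller than plot markers.

Non-imaging detector traces mimic the shoot/root scintillation monitors:
per frame, the decay-corrected mean rate of the compartment, flagged
usable only when the moving table puts that compartment in front of the
detector (root ↔ lower frames, shoot ↔ upper frames).

## Quantification

- **Decay correction**: point measurements scale by e^{λt}; frame-integrated
  counts scale by λΔt / (e^{−λt₀} − e^{−λt₁}), referencing all curves to
  PET start.
- **Region growing**: 26-connected component of voxels ≥ rel_threshold ×
  (3³ neighborhood max around the seed), deterministic; a seed below its
  own threshold returns a single-voxel mask with a warning.  The local
  (not global) reference makes the mask invariant to intensity rescaling
  and tolerant of a seed one voxel off the peak.
- **Nodule ROI construction**: seeds at ground-truth nodule centers on the
  summed image of the nodule's position; the grown core (default threshold
  0.3) is dilated by 2 voxels to collect the PSF skirt, then voxels the
  ground-truth label map identifies as root are removed — the phantom's
  label map stands in for the co-registered MRI that guides manual ROI
  drawing.  Eligibility mirrors the experimental criteria: ≥50% overlap
  with the true nodule, ≤20% root contamination (evaluated before root
  exclusion).
- **Totals and interpolation**: the whole-root total of the lower position
  covers its full window; the upper total excludes the 25-voxel overlap
  slab, so the two totals partition the volume and their sum counts every
  voxel once (naively adding two full-window totals would double-count the
  overlap).  The total of the position not being imaged is filled in by a
  local 3-point Lagrange quadratic through the nearest samples (endpoint
  queries use the first/last three points; exact on any global quadratic).
- **Windowing**: session summaries are the mean ± sample SD of the four
  consecutive same-position fraction points with the least variation,
  selected by minimizing the summed coefficient of variation across curves
  (ties to the latest run).  Selection is global across all sessions and
  plants by default (per-plant and fixed-interval modes are provided).
  Window membership uses frame *start* times; with alternating 5-min
  frames the late window is 70–100 min (lower) / 75–105 min (upper) —
  a midpoint-based reading of "75–105 min" would leave only three points
  for one of the positions.

## Statistics

Per session the six nodule mean fractions are summed (percent).  Per plant,
an OLS line over the eight sessions (times in fractional days from the
first session, default clocks 08:00 and 11:00) gives the slope in % day⁻¹,
its standard error, and a two-sided t-test of zero slope with n − 2 df.
The relative change from the first to the last measurement day is, by
default, the ratio of day means (robust to within-day noise); a
regression-endpoint variant is available behind a flag.  Perfectly flat
data report slope 0 with p = 1; an exact linear fit reports SE 0 with p
capped at 0.

## What a green test establishes — and what it does not

The generator emulates: the two-position frame geometry and timing,
physical decay inside frames, PSF blur, Poisson counting noise, day-to-day
amplitude growth, plateau kinetics, and a step reduction of nodule
allocation with conserved totals.  It does not emulate: attenuation or
scatter in soil/water, detector dead time, plant or nodule movement between
sessions (the phantom is rigid), washout or re-export of carbon,
within-session physiological drift, or realistic root-system architecture
beyond what the contrast and separability of ROIs require.  Parameter
recovery therefore validates the *analysis chain* — masking, interpolation,
normalization, windowing, regression — not the biology; a real dataset adds
every confound listed above, co-registration error first among them.

## Known limitations and open choices

- The uptake-curve shape beyond "plateau ≈ 50 min" is an assumption.
- The real acquisition's 1-min flush gap is absorbed into the definition of
  t = 0 (PET start); frame clocks are not shifted.
- Nodule specific-activity contrast is a consequence of the chosen root
  density; much sparser root systems would push the ROI criteria toward
  ineligibility, which is faithful to the experimental situation (nodules
  obscured by roots were excluded there too).
- Printed per-plant p-values in the source experiment are not exactly
  recoverable from slope/SE at 6 df (rounding); they are not used as
  references anywhere.
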