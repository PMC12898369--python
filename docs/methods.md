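# Methods

`canalregen` quantifies how much of a surgically disrupted mandibular canal
has re-formed a bony wall, from a CBCT volume, a canal/nerve centerline and
the two implant apex landmarks that bound the defect. This note records the
model, the parameter choices, the synthetic-data design and the numerical
decisions behind the implementation.

## The measurement model

After inferior alveolar nerve transposition the bony canal is interrupted
between the mesial apex of the mesial implant and the distal apex of the
distal implant. One year later, CBCT shows a spectrum from no wall through
early mineralising bone (400–800 HU) to mature bone (>800 HU). A regenerated
segment is only counted as *canal* — rather than incidental radiopacity —
when four criteria hold simultaneously:

1. **Continuity** across sequential cross-sections (a linear canal, not an
   isolated hypodense or irregular area).
2. **Wall density** above a threshold: >800 HU (mature) or >400 HU (early),
   evaluated separately so maturation state can be distinguished.
3. **Enclosure**: ≥270° of circumferential bony coverage around the
   neurovascular bundle in cross-section.
4. **Morphology**: a tubular/circular configuration in cross-section.

The per-case statistic is

    Regeneration (%) = length of regenerated canal / defined defect length × 100

with the defect length being the straight-line apex-to-apex distance.

### Sections

The volume is resampled into planes orthogonal to the centerline at
arc-length stations 0, Δs, 2Δs, …; Δs defaults to 0.3 mm, one native voxel
of the standardized imaging protocol, so "sequential sections" means
scanner-resolution slices. Tangents are central differences of the polyline
(one-sided at the ends); the in-plane frame is transported with minimal
rotation, which guarantees frame continuity — enclosure is
rotation-invariant, so the absolute in-plane orientation is irrelevant.
Sampling is trilinear; out-of-volume samples are filled with −1024 HU and
counted per section.

### Enclosure by ray casting

From each section centre, `ray_count` (default 360) equally spaced rays are
cast. Along each ray, HU is sampled at half the in-plane resolution within a
radial search annulus `[band_inner, band_outer]` (defaults 1.2 and 4.5 mm:
0.8 × the nominal 1.5 mm canal radius, and canal radius + 3 mm, tolerating
modest centerline error while excluding distant cortex). A ray is *walled*
when it crosses at least `min_wall_mm` (default: one in-plane sample) of
contiguous samples inside the bone range `(threshold, 3071)`. The enclosure
angle is 360° × walled / (rays − occluded).

Metal handling: implants saturate the 12-bit ceiling and clamp to exactly
3071 HU on load, so bone is taken as *strictly below* 3071 and samples at
the ceiling are metal. Interpolated samples adjacent to metal are blooming
rather than bone and are excluded (the metal mask is dilated by one radial
sample). Rays that meet metal before completing a bone crossing are
*occluded* and leave the denominator; a section whose occluded fraction
exceeds 10% is flagged low-confidence.

The ≥270° criterion is applied to the *total* angular coverage (the union of
walled rays); the longest contiguous walled arc is recorded alongside in
every verdict for sensitivity analysis, since a strictly contiguous reading
of the criterion is also defensible.

### Morphology score

Circularity is 1 − (robust coefficient of variation of the inner wall radii
of walled rays), where the robust CV is 1.4826 × MAD / median, clipped to
[0, 1]; fewer than three walled rays score 0. The formula and its default
cut-off of 0.6 are this package's operationalisation of the qualitative
"tubular or circular configuration" requirement; both are configurable and
recorded in the output provenance. A perfect annulus scores ≳ 0.97; a 2:1
ellipse scores ≈ 0.7; scattered debris scores near 0. Circularity is
evaluated once per section on the inclusive bone range (>400 HU, the lower
bound of bone in CT) and shared by both threshold verdicts — this preserves
the structural guarantee that the early-threshold percentage can never fall
below the mature-threshold one.

### Continuity and length accounting

Per threshold, maximal runs of passing sections are formed; consecutive
passing blocks may be bridged across at most `max_gap_sections` failing
sections (default 0). A run qualifies only when its passing stations span at
least `min_run_mm` = 0.9 mm (three sections at the default step — the
minimal plural reading of "sequential sections"; the criterion itself fixes
no number). A single section is never a run.

For the *reported* length, each passing station contributes its cell
[s − Δs/2, s + Δs/2] truncated at the defect interval, and tolerated gap
stations contribute nothing. With every station passing, the cells tile the
defect span exactly, so a fully regenerated straight canal reports exactly
100% without clipping; counting whole steps per station instead would
overcount by one fencepost step and always clip.

### Defect interval and clipping

The defect interval on the centerline runs between the vertices nearest the
two apices (ties to the smaller arc length); the *denominator* of the
percentage is the straight apex-to-apex chord. On a curved axis the
regenerated length is measured along the axis and can exceed the chord; the
percentage is then clipped at 100 and the report carries a `clipped` flag.
Measuring along the 3D axis (rather than on a single 2D sagittal projection)
is a deliberate design choice of this package.

## The synthetic phantoms

No public CBCT dataset of post-transposition canals exists, so validation
uses phantoms with analytic truth. A phantom is a background of trabecular
density (300 HU) containing a low-density lumen tube (40 HU, radius 1.5 mm)
along a straight or sinusoidal axis, wrapped by a partial annular wall
(thickness 1.2 mm) whose angular arc and HU follow a station table; 0.3 mm
isotropic voxels match the standardized imaging protocol. Implants are
y-axis cylinders at saturating HU whose canal-side end-caps define the
landmarks; without implants, landmarks sit on the axis at the ends of an
explicit defect span. Noise is additive Gaussian (default 30 HU in the
validation regime), seeded.

Ground truth is integrated from the station table (fraction of the defect
span with arc ≥ 270° and HU above the threshold), never from the rendered
grid, so it is exact and provably invariant to noise and implants. Voxels
belong to a structure when their centre is inside the analytic surface; no
anti-aliasing. Walls are a single contiguous arc per station, matching the
single-enclosure criterion and keeping truth analytic.

What the phantoms deliberately do **not** emulate: real mandibular anatomy
(cortex, trabecular texture), beam hardening and streak artifacts, CBCT
gray-value/HU miscalibration (inputs are treated as HU; an affine
gain/offset rescale is available at load), centerline extraction error, and
multi-arc wall topologies. Passing the phantom battery therefore shows the
*measurement chain* is correct at known geometry and noise, not that the
criteria themselves are clinically optimal.

The cohort generator draws true regeneration fractions from a normal
distribution truncated to [0, 1] with mean 0.727 and SD 0.13 — the regime of
the clinical cohort this pipeline is designed for — plus a uniform 3–8%
early-bone surplus per case, mirroring the reported gap between the two
thresholds.

## Numerical choices

- **Enclosure fidelity phantoms** (for the oracle-equivalence check) use
  0.15 mm voxels, a 3 mm lumen and 1200 HU walls over a 400 HU background so
  the 800 HU threshold crossing falls exactly midway between the two tissue
  values; this removes the systematic edge bias that an asymmetric crossing
  induces and lets a 269°/271° arc pair straddle the 270° boundary cleanly.
- **Validation problem sizes**: single cases use 48×48×64 voxel volumes
  (≈14×14×19 mm) with a 15.9 mm defect; the cohort demo uses 22 such cases;
  the monotonicity suite uses 20 randomized phantoms. These sizes make every
  result reproducible on a laptop in seconds while keeping ≥ 50 stations per
  defect.
- Station counts follow floor(L/Δs) + 1 with a 1e-9 relative guard against
  floating-point shortfall.
- NIfTI headers store geometry in float32; spacing and origin are snapped to
  1e-6 mm on load so a nominal 0.3 mm voxel stays exactly 0.3.
- Shapiro–Wilk p-values are reported only for n ≥ 3 and non-constant
  samples, via the standard scipy implementation (reporting only; no
  decision is made on it).
- Cohort counts are reported at all three clinically used cutoffs (>70%,
  <50%, <40%).

## Known limitations

- The pipeline assumes the supplied centerline passes near the true lumen
  centre; it does not auto-trace the nerve. Enclosure tolerates offsets up
  to roughly the search-band margin (~1 mm at defaults).
- Total-coverage enclosure can pass a wall split into several arcs that sum
  to ≥270°; the recorded longest-arc diagnostic lets users re-analyse under
  the stricter contiguous reading.
- Sub-voxel wall thickness is not estimated; walls thinner than one voxel
  diagonal are outside the phantom's validity.
- Curved axes make chord and arc denominators diverge; the clipping guard
  handles the >100% side but percentages on strongly curved defects should
  be interpreted with the `clipped` flag in view.
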