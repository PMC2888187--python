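# Methods

This note documents the models and procedures implemented in `hep2`, the
assumptions behind them, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## 1. Pipeline overview

A sample is a set of two-channel fields of view: a DAPI channel carrying
chromatin (used for focusing, object detection and mitosis identification)
and a FITC channel carrying the autoantibody signal. Each field passes
through quality control → exposure normalization → nucleus segmentation →
per-cell description; sample-level interpretation then proceeds through the
expert-reading hierarchy: (a) positivity, (b) localization of staining,
(c) nuclear pattern. Every rule evaluation is logged to a rule trace so a
call can be audited.

## 2. Synthetic fields: what they emulate and what they do not

No public image set accompanies the system being re-implemented, so all
image-level validation runs on a seeded generator (`hep2.synthetic`).

**Geometry.** Interphase nuclei are ellipses with semi-axes drawn from
U(7.5, 15) px (U(13, 16) px for dot-bearing and nucleolar patterns so that
the requested foci physically fit); mitotic figures are bars (length
20–28 px, width 6–9 px) standing in for condensed metaphase plates.
Placement is rejection sampling under a ≤ 20 % pairwise overlap budget with
a 1000-attempt cap; infeasible geometry raises a `PlacementError` rather
than silently truncating the cell count. Default field: 320×320 px, 16-bit,
15 interphase + 2 mitotic cells.

**Intensities.** Background 500, interphase DAPI ≈ 12 000 (±15 % per-cell
jitter), mitotic DAPI 2.2× interphase — a documented contrast the mitosis
detector can key on. FITC pattern amplitude is `intensity_level × 30 000`,
where `intensity_level ∈ [0, 1]` is a dimensionless stand-in for titer
strength. Gaussian read noise (default sd 300 ≈ 0.5 % of range) and
Gaussian defocus blur are applied last; the noiseless FITC intermediate is
kept in the ground truth so dot-placement invariants can be checked
exactly.

**Patterns.** Homogeneous fills nuclei and stains the metaphase plate
(at 1.15×: mitotic chromatin stains slightly stronger); fine/coarse
speckles are Gaussian bumps (σ = 1 / σ = 2.5 px) over a diffuse base
(0.30 / 0.50), with the plate left dark; nucleolar paints 2–4 disk blobs
(radius 4–5 px) over a weak (0.12) diffuse nucleus; centromere places
`dot_count` (default 45) σ ≈ 0.9 px foci at ≥ 2.2 px separation inside the
nucleus eroded by 3 px, plus 8 foci on each metaphase plate; multiple
nuclear dots places `dot_count` (default 6) larger foci on an otherwise
dark nucleoplasm; cytoplasmic stains a union annulus (dilation by 8 px
minus all nuclei) at 0.9 with a dark (0.08) nucleus. Two extra patterns
exist solely to reproduce documented reader confusions: a nuclear-membrane
rim (2–3 px band, interior 0.10) and a Golgi crescent (a 240° perinuclear
arc). The *negative* pattern renders faint **nonspecific** whole-cell
staining (nucleus + cytoplasm, painted once over the union so overlapping
cells do not double up) scaled by `intensity_level`, which for a
normal-donor population is drawn from U(0, 0.1): real negative sera show
faint unselective residual binding, not blank fields, and the calibration
would be meaningless against a blank population.

**Not emulated:** photorealistic cytology, optical PSFs beyond Gaussian
blur, uneven illumination, cell-cycle heterogeneity beyond the binary
mitotic flag, mixed-pattern sera (except by explicit compositing in
tests). Passing tests therefore demonstrate that the *decision logic*
recovers known ground truth under controlled morphology and noise — not
performance on clinical material.

## 3. Imaging: focus, QC, exposure

**Focus score** is the contrast moment of the symmetric unit-offset
grey-level co-occurrence matrix after quantization to 64 levels (computed
directly as the mean squared difference of neighbouring quantized pixels,
which is the same quantity): zero for constant images, `(Q−1)²` for a
two-level checkerboard, and monotonically decreasing under defocus blur.
Which co-occurrence statistic the original autofocus maximizes is not
public; the contrast moment is the natural reading of sharpness as
grey-scale transition. Autofocus selection takes the arg-max over a focal
stack, breaking ties toward the stack centre.

**Tile QC** divides the image into a grid (default 4×4) of near-equal
tiles. A tile is *empty* below 0.5 % foreground fraction, where foreground
is above-Otsu intensity floored at a robust background bound (Otsu alone
splits the noise band when true signal is sparse). The primary artifact
detector is near-saturation: > 1 % of tile pixels at ≥ 95 % of the dtype
range — real streaks and debris burn toward saturation. A secondary
relative rule flags a tile whose 99th-percentile intensity exceeds the
non-empty tiles' median 99th percentile by k = 5 MADs (MAD floored at
25 % of that median) *and* exceeds the whole image's 99.9th percentile.
The guard terms are deliberate: without them, legitimately uneven
staining — sparse cells, discrete dot patterns, bright mitotic figures —
triggers the percentile-outlier rule, which was designed for fields whose
stained tiles are statistically exchangeable. All criteria are ratios of
image statistics, hence invariant to global linear rescaling. A field is
unusable above 25 % artifact tiles.

**Exposure normalization** stands in for the camera's adaptive exposure
control, which keys on the highest image signal after artifact exclusion.
The maximum non-artifact pixel is mapped to 90 % of the dtype range; the
multiplier is accumulated in `exposure_gain`, pixels stay floating-point,
and the operation is exactly idempotent. Keying on the maximum rather than
a high percentile is essential for sparse patterns: a percentile reference
would clip the few-pixel foci of nuclear-dot staining, which are precisely
the signal the exposure control exists to preserve.

## 4. Segmentation

Otsu threshold (triangle available by config) → hole filling → removal of
objects < 100 px² → marker-controlled watershed on the negated Euclidean
distance transform. Markers are peaks of the (lightly smoothed, σ = 1)
distance transform separated by ≥ 0.6 × the median equivalent radius; any
foreground component left without a marker (elongated mitotic bars have
shallow distance maxima) receives one at its distance peak, so watershed
never drops a component, and fragments the split leaves below the minimum
area are re-absorbed into the neighbour with the longest shared boundary.
This marker rule replaced a plain h-maxima seeding (h tied to the median
radius): the fixed h merges deeply interpenetrating small-nucleus pairs
that are still within the generator's ≤ 20 % overlap budget, because
their distance-transform saddle is shallower than h. Border-touching
objects and objects overlapping artifact tiles are removed; labels are
relabelled consecutively.

Mitotic classification: mean DAPI ≥ 1.8× the median object intensity AND
condensed morphology (eccentricity ≥ 0.85 or area ≤ 0.5× median). The
1.8 factor sits between the renderer's documented 2.2× mitotic contrast
and the interphase jitter ceiling. Single-object fields fall back to an
absolute intensity criterion (logged). The cytoplasmic measurement ring is
a 5-px dilation band around each nucleus minus *all* nuclei.

## 5. Descriptors

Per interphase cell: FITC summary statistics in nucleus and ring;
nucleolus-candidate blobs; boundary statistics (perimeter, circularity,
2-px rim/core ratio); discrete dot count and positions; the Euler number
of the thresholded intra-nuclear signal; masked co-occurrence texture
(contrast, correlation, energy, homogeneity at offsets 1 and 2 px,
64 levels, pairs restricted to the nucleus so a uniform nucleus has energy
exactly 1); and the coefficient of variation. The vendor system reports
"more than 1 400" descriptors; this set is the discriminative subset the
six-pattern rule cascade needs, and the dataclass extends additively.

**Dot detection** must work in two regimes: sparse foci on dark
nucleoplasm *and* dense centromere fields where foci cover much of the
nucleus (there, any outlier threshold on the top-hat saturates, because
the median itself sits on dots). Foci are local maxima of the
white-top-hat (disk radius 3) exceeding
`median + 0.25 × (max − median)`, floored at 8 % of the field's intensity
span (so read noise in unstained regions — e.g. a dark metaphase plate in
a speckled field — never registers); all terms are ratios of image
statistics, so the count is invariant to linear rescaling. The search region is the nucleus eroded by 3 px:
continuous rim staining (nuclear-envelope sera) would otherwise register
as chains of spurious maxima; the renderer places its foci inside the same
erosion. Foci closer than ~2 px merge — the tests allow ±2 on 45.

**Nucleolus candidates** threshold halfway between the nuclear median and
its 99th percentile and keep regions that are large (≥ 20 px² but < half
the nucleus) and compact (solidity ≥ 0.8, which rejects annular rim
shapes). Point-like dots fall below the area window; diffuse staining
exceeds it.

**Metaphase signal**: plate/interphase mean-FITC ratio (positive at ≥ 1),
and dotted-chromatin when a strict majority of plates carries ≥ 5 detected
foci — majority voting because a single plate may legally overlap a
speckled nucleus under the 20 % overlap budget and inherit its speckles.
Fields without mitoses return an indeterminate record and the
homogeneous/speckled decision falls back to texture, flagged as reduced
confidence in the rule trace.

## 6. Reactivity index and calibration

`RI = 100 · intensity · contrast · richness`, all components in [0, 1]; the
multiplicative combination makes a blank image score exactly 0 and no
component bypassable.

- **intensity** = (highest non-artifact foreground pixel on the absolute,
  exposure-corrected scale / range) ^ γ. The maximum — not a percentile —
  is what the exposure controller keys on, and it is what keeps sparse
  discrete patterns visible. The exponent γ = ln r / ln 4 ≈ 0.66 maps the
  multiplicative titer scale onto the calibration's linear threshold
  ratio: the weakly-positive band spans a factor-4 titer range (1:80 to
  1:320) that the two RI thresholds cover with a factor r = 2.5.
- **contrast** = RMS deviation of the stained crest (top percentile of
  foreground pixels) from the background mean, / range, on the normalized
  image. Crest- rather than area-weighting stops dark nucleoplasm or
  cytoplasm inside the measurement masks from diluting sparse foci.
- **richness** = occupied integer grey levels / total levels.

**Calibration**: `negative_threshold` = 99th percentile of the RI of a
negative population (200 synthetic normal donors at U(0, 0.1) strength;
≥ 30 required, < 200 warns); `positive_threshold = r ×` that, r = 2.5.
Boundary values classify upward. Both choices are config keys recorded in
the model's method string. The three classes correspond to the titer bands
negative < 1:80, weak 1:80–1:160, positive ≥ 1:320.

On the generator's conditions this recovers, for uniformly (homogeneously)
stained cohorts, the three bands at intensity levels 0.05 / 0.3 / 0.9 with
≥ 90 % per-level accuracy. Sparse dot patterns score systematically lower
RI at equal `intensity_level` — their stained area is two orders of
magnitude smaller — so nuclear-dot samples sit closest to the
weak/positive boundary and can dip into the weak band at moderate
intensities. This is an inherent property of any global-statistic RI and
mirrors the discrete/weak patterns being the hard cases in practice;
accordingly the end-to-end positivity metric reported by the acceptance
script is positive-vs-negative *detection* (weak counts as detected),
which is also the primary endpoint of the comparison statistics (the
published kappa/McNemar values all collapse weak+positive into one
group). The strict three-class accuracy is computed and reported alongside
it.

## 7. Localization and pattern rules

Localization: cytoplasmic when the median ring FITC exceeds α = 1.2 × the
median intra-nuclear FITC (the deliberate cytoplasm-over-nucleus emphasis
of the emulated reader); mitotic-chromatin when only the plate stains;
else nuclear. Pattern cascade, in fixed order, over medians across
interphase cells:

1. dots ≥ 30 AND dotted metaphase → **centromere** (the boundary value 30
   goes to centromere only with metaphase confirmation);
2. 2 ≤ dots ≤ 30, punctate (diffuse nuclear signal < 15 % of dot peak,
   background-subtracted) and no large blobs → **nuclear dots**;
   an *unconfirmed* count > 30 falls through as dense speckling;
3. 1–6 compact blobs at ≥ 2× relative intensity → **nucleolar**;
4. stained metaphase chromatin → **homogeneous** (even when the interphase
   texture is speckled);
5. CV ≥ 0.25 → **speckled**; else homogeneous.

Ties between nucleolar and speckled resolve toward speckled through the
blob-count cap in rule 3 (dense speckle fields produce > 6 candidates).
The two documented failure modes are intentionally reproduced, not fixed:
nuclear-membrane rim staining classifies as speckled, Golgi staining as
cytoplasmic.

Aggregation: median RI across usable fields; localization and pattern by
majority over per-field calls. Samples whose every field fails QC raise a
distinct unevaluable status — never "negative".

## 8. Numerical choices and degenerate inputs

Quantization for co-occurrence statistics: 64 levels over the dtype range
(focus) or the masked min–max (texture); constant regions define
correlation = 0, energy = 1. Percentiles use linear interpolation.
Calibration rejects constant populations and n < 30. Empty DAPI foreground
yields zero labels (not an error); empty rings fall back to nuclear
localization with a reduced-confidence trace entry. All randomness flows
from explicit integer seeds; identical spec + seed renders bit-identical
fields.

## 9. Known limitations

- The descriptor bank is a ~25-descriptor subset, not the vendor's 1 400.
- The RI component definitions and the calibration statistic are
  reconstructions; the originals are proprietary and unrecoverable.
- Titer prediction, mixed-pattern multi-label output, and hardware control
  are out of scope.
- The paired-difference CI uses Newcombe's score method; the original
  statistics package (MedCalc) prints slightly different intervals for
  the same tables, so the CIs agree only approximately, while every other
  statistic reproduces exactly. The two published per-cohort agreement
  percentages (93.0 %, 90.6 %) are inconsistent with the printed tables
  they cite (which sum to 856/924 and 268/298) and are therefore not
  reproduced; the tables are treated as ground truth.
- Problem sizes in tests and the acceptance script (320² px fields,
  15–22 cells, 120-sample cohorts, 200-donor calibration) are the
  package's chosen study scale for the synthetic conditions; they are
  far below the published cohort sizes (924 + 298 sera), whose images do
  not exist publicly at any scale.
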