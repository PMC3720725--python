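# Methods

`chromofold` quantifies two readouts of protein-induced chromatin
remodelling at a tagged (lacO/lacR) chromosomal array: the 3D shape of the
array domain in confocal image stacks, and the exchange kinetics of
array-associated proteins (e.g. HP1γ) measured by photobleaching. Because
the quantities are defined on data no public repository provides, the
package ships a synthetic-data generator whose outputs carry exact ground
truth; every analysis step is validated against that truth or against a
closed form.

## Domain morphometry

### Surface factor

The shape statistic is sphericity with the orientation fixed so that a
perfect sphere scores 1 and furrowed or fibrillar domains score less:

    SF = S_sphere(V) / S = π^(1/3) · (6V)^(2/3) / S

where `V` is the segmented domain volume and `S` its surface area.
Closed-form anchors: sphere → 1, unit cube → (π/6)^(1/3) ≈ 0.806, a 1×1×4
box → ≈ 0.677. The statistic is scale invariant (volume ~ k³, surface ~
k²).

### Segmentation

Stacks are smoothed with a Gaussian specified in physical units (default
0.1 µm, converted per axis to voxels so anisotropy is respected), Otsu
thresholded **within the nucleus support** (provided mask, or a first Otsu
pass that separates nucleus from dark background), decomposed into
26-connected components, filtered by a minimum volume (default 0.05 µm³),
and the largest surviving component is returned. This replaces the
unspecified commercial pipeline with a deterministic, parameter-light and
auditable equivalent.

### Volume and surface measurement

Volume is voxel count × voxel volume. Surface area offers two estimators:

* **marching cubes** (default): iso-level 0.5 on the binary mask after a
  one-voxel Gaussian anti-aliasing step, meshed with the physical voxel
  spacing. The anti-aliasing is essential on anisotropic grids — raw
  binary meshing of a 1 µm sphere at 200×60×60 nm voxels overestimates
  the area by ~18% (z-staircase), while the anti-aliased mesh is accurate
  to a fraction of a percent.
* **voxel faces**: the exact sum of exposed voxel-face areas. It is the
  brute-force oracle: exact for axis-aligned boxes, but it converges to
  3/2 of the true area of any smooth surface (the staircase never
  flattens), so it upper-bounds the mesh estimate on curved bodies and
  agrees with it only on box-like shapes. Cross-method agreement is
  therefore asserted on boxes; on spheres only the ordering
  (faces ≥ mesh) holds.

Masks are zero-padded by one voxel before meshing so surfaces stay closed
at the grid edge. Measured surface factors can exceed 1 by a small
discretization slack that shrinks with resolution (≈ 0.004 at the 200×60×60
nm acquisition grid).

### Condensation classification

A cell is called *decondensed* when its surface factor falls below the
`q`-quantile (default 0.20, linear interpolation) of the control cohort —
i.e. the threshold is anchored to the fraction of control cells that show a
mildly decondensed array. Ties at the threshold count as condensed,
conservative toward the null. The control cohort must have ≥ 10 cells for
the quantile to be meaningful.

### Intensity

Total and mean channel intensity over the domain mask; a user-supplied
linear calibration factor stands in for the detector (PMT) gain/offset
standard curve, which instruments report but publications rarely include.
`enrichment_ratio` (in-domain mean ÷ nucleoplasm mean) quantifies factor
accumulation at the array; an optional margin erodes the domain and
excludes a rim around it and inside the nuclear envelope so PSF blur at
region boundaries does not dilute the ratio.

## Photobleaching kinetics

### Normalization

Both FLIP and FRAP series normalize identically:

    I(t) = (spot(t) − background(t)) / (spot(0) − background(0))

The t = 0 reference is the mean over all pre-bleach frames (default 10),
which is robust to frame noise; the returned curve carries one t = 0
sample equal to exactly 1 followed by the post-bleach samples, so the
normalization identity holds by construction and re-normalizing is a
no-op. An affine min→0/max→1 rescale is provided for recovery-plot display.

### Two-pool decomposition

Normalized decays are modelled as

    I(t) = N1·e^(−λ1 t) + N2·e^(−λ2 t),   N_i ≥ 0, λ1 > λ2 ≥ 0,

fast component → freely diffusing pool, slow component → transiently
chromatin-bound pool; fractions are amplitude shares `N_i/(N1+N2)` (robust
to imperfect normalization) and half-times `t½ = ln2/λ`. FRAP curves are
fitted through their un-recovered fraction, which is 1 immediately after
the bleach and decays with the same kernel. The exponents are decays by
convention (recorded on every result).

Bi-exponential least squares is both initialization-sensitive and, near
the mono-exponential boundary, unidentifiable: when one pool is small, a
"phantom" solution that relabels the dominant rate as the slow component
fits noisy data as well as the correct one, and the reported pool split
becomes arbitrary. The fitter therefore layers four safeguards, all fixed
a priori:

1. **Rate separation.** The fit is parameterized as λ1 = ratio·λ2 with
   ratio ≥ 4. Exponentials with closer rates cannot be resolved from
   sampled noisy decays (the classical resolvability limit of
   multi-exponential analysis), so decompositions below that separation
   are excluded from the model space.
2. **Multi-start with peeling starts.** A 3×3 grid of half-time guesses
   (fast 1/3/10 s × slow 30/60/120 s) crossed with three amplitude splits
   (0.5/0.5, 0.9/0.1, 0.1/0.9), plus two data-adaptive starts seeded from
   a mono-exponential fit (dominant component at the mono rate plus a
   small slower or faster partner). Starts that exhaust their evaluation
   budget (500 per start, ftol 1e-10) still contribute their best point.
3. **Parsimony selection.** Among multi-start optima whose residual sum of
   squares lies within the noise-equivalence band of the best
   (rss ≤ rss_best·(1 + 4/dof)), the solution assigning the least
   amplitude to its minor component is selected; exact ties break on the
   smaller fast rate, so the result is independent of start order.
4. **Mono-exponential collapse.** An F-test (α = 0.05, 2 extra
   parameters) compares the selected fit against the mono-exponential
   competitor; an unsupported second component collapses the fit, reported
   as a single pure fast pool. The collapse also triggers when both models
   fit to numerical precision, or when the two rates end up within 5%
   relative. A collapsed fit with no detectable decay over the record
   reports λ = 0 and an infinite half-time.

With these safeguards, cohorts of 50 simulated curves recover generating
bound fractions within ±0.5 percentage points and half-times within a few
percent across every study condition, including the extreme 99.9%-free
case — without them, label switching biases small bound fractions by tens
of points.

Cohort aggregation defaults to fit-then-average (per-curve fits, mean ± sd
over converged fits, unconverged fits counted and excluded);
average-then-fit is available when replicate curves share a time grid.

## Synthetic data

### Image stacks

A nucleus is a sphere (default radius 3 µm — small for a mammalian
nucleus but comfortably larger than the domain, keeping stacks tractable)
with uniform nucleoplasmic signal, containing an array domain that is
either a **sphere** (compact phenotype, default radius 1 µm) or a
**fiber** (unfolded phenotype): a persistent random walk (step = tube
radius, direction correlation 0.7) confined to the nucleus and kept ≥ 2.2
tube radii from its own earlier path so the dilated tube does not
self-overlap, dilated to a capsule of the tube radius. Sphere and fiber
defaults have equal nominal volume (tube radius solves L·π·r² =
(4/3)·π·R³), so shape — not size — separates the classes. The stack is
blurred with a separable anisotropic Gaussian PSF (σ 0.1 µm lateral /
0.25 µm axial), sampled at 200 nm axial × 60 nm lateral voxels, and
corrupted with additive Gaussian noise (default sd 5% of the array
amplitude), clipped at zero. Extra channels scale the in-domain level by
per-channel enrichment factors.

Ground truth comes from the pre-blur geometry: closed forms for the
sphere; for the fiber, a distance-to-centreline field on a grid refined
4-fold per axis (rasterized transform refined by exact point-to-polyline
distances near the tube wall), counted for volume and meshed at the tube
radius for surface. Fiber ground-truth volume lands within ~2% of nominal
(the excess is the two capsule end caps).

What the generator does **not** emulate: textured chromatin, nuclear
envelope irregularity, depth-dependent aberrations, Poisson photon noise,
or segmentation-confounding neighbouring structures. Passing tests
therefore demonstrate correctness of the measurement chain under the
stated imaging model, not robustness to every real-microscope artifact.

### Bleach curves

ROI-level simulation: the expected spot trace follows the two-pool
bi-exponential survival (FLIP) or its complement scaled to the pre-bleach
plateau (FRAP), with `n_prebleach` frames at the pre-bleach level, 2 s
sampling, 80 (FLIP) / 60 (FRAP) post-bleach frames, and additive Gaussian
noise proportional to the pre-bleach amplitude. No spatial
diffusion–bleach computation is performed — the fitting operates on ROI
time series, and ROI-level simulation keeps the generating parameters
exact ground truth. The bundled study-condition table records, per
condition, which parameters are reported measurements and which are
assumed (taken from the matching control when the source does not state
them); noise is 2% of amplitude for control conditions and 1% for the
displacement conditions whose minor pool is small.

## Statistics

* **Normality gate**: Shapiro–Wilk per cohort (α = 0.05) plus a
  Levene-type variance-equivalence check (median-centred); nonparametric
  testing is recommended when either rejects. The exact flavour of
  "variance equivalence" used in prior art is rarely stated; Levene is the
  standard robust choice and is labelled as a stand-in.
* **Cohort contrasts**: two-sided Wilcoxon rank-sum (Mann–Whitney) of each
  construct cohort against the control — exact null distribution for
  combined n ≤ 10 without ties, normal approximation with tie correction
  otherwise — Bonferroni-corrected with m = 7 contrasts by default, i.e.
  cutoff 0.05/7 ≈ 0.007. A brute-force enumeration oracle over all rank
  assignments backs the exact branch in tests. Under equal-distribution
  simulations the 0.007 cutoff rejects in ≤ 1.5% of replicates.
* **Correlation**: Pearson r between calibrated array intensity and
  surface factor (the expression-level control: unfolding should not be
  an overexpression artifact).
* **Contingency**: Pearson χ² (1 df) without continuity correction by
  default (Yates by flag) for condensation state × cell-cycle phase.
* **Assay helpers**: comparative-Ct fold change 2^(−ΔΔCt) with replicate
  standard errors propagated in Ct space; reporter repression
  100·(1 − activity_sample/activity_control) after internal-reference
  normalization; population intensity ratio with a seeded 1000-resample
  bootstrap CI.

All resampling is seeded and seeds are recorded in outputs.

## Problem sizes and determinism

The test suite runs the image pipeline on a scaled-down grid (120 nm
lateral spacing, 2.2 µm nucleus, 30+30 cells) and the kinetics recovery at
the full published acquisition geometry (50 curves per condition, 80
frames at 2 s); the acceptance script uses the full acquisition grid for
the shape target and 50 curves per kinetic condition. All outputs are pure
functions of (spec, seed); per-cell and per-curve seeds derive from a
single master seed via a seed sequence.

## Known limitations

* The fiber generator's self-avoidance is soft: a long fiber confined to
  a small nucleus may accept mild self-proximity rather than stall, which
  lowers the true volume slightly below nominal.
* The voxel-face surface estimator is an oracle, not a measurement — on
  curved bodies it converges to 1.5× the true area by construction.
* The decondensation threshold interprets the control subpopulation as a
  quantile; if the underlying convention was a fixed surface-factor cut,
  percentages shift for cohorts whose control distribution is skewed.
* The bi-exponential model has no offset term (curves decay to the
  background-corrected zero); incomplete FRAP recovery or an uncorrected
  background pedestal would bias the slow pool.
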