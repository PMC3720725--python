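# chromofold

3D morphometry of tagged chromatin arrays and FRAP/FLIP pool kinetics.

Targeting a protein to a lacO repeat array via a lacR fusion makes a
single chromosomal domain visible in live cells. Two quantitative
questions follow: *does the protein unfold the chromatin domain?* and
*does it change the binding of array-associated factors such as HP1γ?*
`chromofold` answers both on 3D confocal stacks and photobleaching time
series, and ships a ground-truthed synthetic-data generator so the whole
chain is testable end to end. It is aimed at imaging groups quantifying
chromatin decondensation phenotypes and protein exchange at tagged loci.

## The statistics at its core

**Surface factor** (sphericity). For a segmented domain with volume *V*
and surface area *S*:

    SF = π^(1/3) · (6V)^(2/3) / S

the surface of the equal-volume sphere divided by the measured surface: 1
for a perfect sphere, lower for unfolded, fibrillar chromatin. Cohorts are
compared with Shapiro–Wilk/Levene gating, Wilcoxon rank-sum tests against
the control with Bonferroni correction (cutoff 0.05/7 ≈ 0.007), and a
control-quantile rule (20th percentile) that classifies cells as
decondensed.

**Two-pool photobleaching decomposition.** Background-corrected FLIP/FRAP
curves, normalized to 1 at the pre-bleach reference,

    I(t) = (spot(t) − background(t)) / (spot(0) − background(0)),

are decomposed by bounded, multi-start nonlinear least squares into

    I(t) = N1·e^(−λ1 t) + N2·e^(−λ2 t),   λ1 > λ2,

where the fast component is the freely diffusing pool and the slow
component the transiently chromatin-bound pool; fractions are
N_i/(N1+N2) and half-times t½ = ln 2/λ. The fitter enforces a minimum
rate separation and collapses statistically unsupported second components
(see `docs/methods.md`), which keeps pool percentages meaningful down to
bound fractions of a few percent.

## Worked example

```python
from chromofold import (SceneSpec, generate_array_stack, measure_domain,
                        KineticsSpec, simulate_bleach_curve, normalize,
                        fit_biexponential, pool_summary)

# a compact (spherical) array domain, imaged at 200x60x60 nm voxels
stack, truth = generate_array_stack(SceneSpec(shape_kind="sphere", seed=1))
dom = measure_domain(stack, "lacR")
print(f"volume {dom.volume:.2f} um^3  surface {dom.surface_area:.2f} um^2  "
      f"surface factor {dom.surface_factor:.3f} (truth {truth.true_surface_factor:.3f})")

# one FLIP curve at a 37%-bound condition, decomposed into pools
spec = KineticsSpec(f_bound=0.37, thalf_fast=3.0, thalf_slow=52.0,
                    noise_sigma=0.02, seed=4)
fit = fit_biexponential(normalize(simulate_bleach_curve(spec, mode="FLIP")))
print(pool_summary(fit))
```

prints

```
volume 4.49 um^3  surface 13.11 um^2  surface factor 1.004 (truth 1.000)
{'converged': True, 'free_percent': 64.05, 'free_thalf_s': 3.26,
 'bound_percent': 35.95, 'bound_thalf_s': 53.01}
```

The measured surface factor of the digitized sphere is 1 up to
discretization (ground truth exactly 1); the single noisy curve, generated
with a 37% bound pool (t½ = 52 s) and a free pool with t½ = 3 s, fits back
to 36% bound with t½ ≈ 53 s and a free pool at t½ ≈ 3.3 s — averaging 50
such curves recovers the generating values to a fraction of a percentage
point.

A CLI wraps the pipeline for shell use:

```sh
chromofold simulate-curves --scenario AO3_lacR_control -n 50 --out curves
chromofold fit curves/AO3_lacR_control --out fits.csv
chromofold run-all --seed 1 --out results_dir   # both bundled experiments
```

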