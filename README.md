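# brainsym

Global brain asymmetry from structural MRI, in two stages:

1. **Per-slice asymmetry.** The bilateral symmetry axis of a 2D brain
   slice is found by exhaustive search — centroid recentering, small
   integer center perturbations (±2 px), and rotations in 0.5° steps up
   to ±5° — scoring each candidate by the **Gradient Magnitude
   Similarity Deviation (GMSD)** between the aligned slice and its
   mirror image.  The minimal GMSD is the slice's *asymmetry index*
   (0 = perfectly mirror-symmetric; larger = more asymmetric).
2. **Global asymmetry.** Eleven slice indices per subject — one
   diagonal slice, five axial (68–108) and five coronal (84–124) — are
   indicators of a latent *Global Asymmetry* factor in a **MIMIC
   structural equation model** regressed on socioeconomic status
   (Hollingshead index), age and sex, estimated by maximum likelihood
   on the sample covariance matrix.

The package is aimed at researchers quantifying hemispheric asymmetry
on skull-stripped, atlas-aligned T1 volumes (e.g. OASIS
cross-sectional data, shape 176×208×176), and at methodologists who
want a fully synthetic, seeded test bed for the whole pipeline: brain
phantoms with controlled symmetry and cohort simulators for the
latent-variable model ship as first-class modules.

## The model

For images $A, B$ with gradient-magnitude maps
$G_A = \sqrt{G_x^2 + G_y^2}$ (3×3 Prewitt pair by default),

$$\mathrm{GMS}(i,j) = \frac{2\,G_A G_B + C}{G_A^2 + G_B^2 + C}, \qquad
\mathrm{GMSD} = \sqrt{\tfrac1N \textstyle\sum (\mathrm{GMS} - \mathrm{GMSM})^2},$$

with $C > 0$ a stability constant and GMSM the map mean.  Identical
images give GMS ≡ 1 and GMSD = 0.

The MIMIC model couples a measurement part
$y_j = \lambda_j \eta + \varepsilon_j$ (diagonal residual covariance
plus four adjacent-slice residual covariances: c94–c104, c104–c114,
c114–c124, a68–a78) with a structural part
$\eta = \gamma_1\,\mathrm{SES} + \gamma_2\,\mathrm{age} +
\gamma_3\,\mathrm{sex} + \zeta$.  Fitting minimizes
$F_{\mathrm{ML}} = \ln|\Sigma(\theta)| - \ln|S| +
\mathrm{tr}(S\Sigma^{-1}) - p$, with $\chi^2 = (n-1)F_{\mathrm{ML}}$,
and reports CFI, TLI, RMSEA (with 90% CI and close-fit probability),
SRMR, score-test modification indices and the standardized solution.
The full 11-indicator model has df = 70; the measurement-only (CFA)
step has df = 40.

## Worked example

Per-slice axis search on a phantom built with a 2° tilt, a 2 px
horizontal offset and a one-sided blob:

```python
from brainsym import PhantomParams, make_phantom, find_symmetry_axis

img, truth = make_phantom(PhantomParams(true_angle_deg=2.0,
                                        true_offset_px=(2, 0),
                                        asymmetry_amplitude=25.0))
res = find_symmetry_axis(img)
print(f"axis tilt: {res.angle_deg:+.1f} deg   center offset: {res.center_offset}")
print(f"asymmetry index (GMSD at optimum): {res.asymmetry_index:.4f}")
```

```
axis tilt: +2.0 deg   center offset: (0, 0)
asymmetry index (GMSD at optimum): 0.0123
```

The injected tilt is recovered exactly on the 0.5° grid (the offset is
absorbed by centroid recentering), and the one-sided blob leaves a
nonzero residual asymmetry of 0.0123 — a symmetric phantom scores 0.

A full SEM round trip on a simulated 132-subject cohort drawn at the
default generating values:

```python
from brainsym import (CohortParams, simulate_cohort, SampleMoments,
                      default_mimic_spec, two_step_fit, standardized_solution)

table, _ = simulate_cohort(CohortParams(n_subjects=132, seed=1))
spec = default_mimic_spec()
moments = SampleMoments.from_dataframe(table, list(spec.observed))
res = two_step_fit(spec, moments)
ix = res.structural_indices
print(f"chisq = {ix.chisq:.1f} (df = {ix.df}), p = {ix.pvalue:.3f}")
std = standardized_solution(res.structural_fit)
print({k: round(v, 2) for k, v in std["paths"].items()})
```

```
chisq = 71.1 (df = 70), p = 0.442
{'ses': -0.25, 'age': 0.66, 'sex': 0.37}
```

The standardized paths land near the generating values (−0.22, 0.57,
0.40) up to sampling noise at n = 132; SES carries a negative sign
because higher Hollingshead scores mean fewer socioeconomic resources.

A command-line interface wraps the same pipeline:

```sh
brainsym simulate-cohort --n 132 --seed 1 --out cohort.csv
brainsym sem-fit cohort.csv --out report.json
brainsym run --volume-dir volumes/ --covariates covariates.csv --out-dir out/
```

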