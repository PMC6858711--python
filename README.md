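# immunocontext

Margin-referenced quantification of the tumor immune contexture, and its
association with treatment response and survival.

In metastatic melanoma treated with MAPK-pathway inhibitors (BRAFi ±
MEKi), the balance between cytotoxic CD8⁺ T cells and protumor CD163⁺
(M2-skewed) macrophages — and *where* those cells sit relative to the
invasive tumor margin — is predictive of response and outcome. This
package implements that analysis as a tested, reusable pipeline for
digital-pathology and translational-research groups:

1. **Cell detection** — RGB channel-dominance classification of
   hematoxylin (blue nuclei) and fast-red (marker-positive) staining,
   connected-component extraction with area gating, and five-field
   hotspot densitometry (fields of 10⁻³ mm², density in cells/mm²).
2. **Spatial profiling** — signed Euclidean distance of every cell to the
   invasive margin (negative inside the tumor), intratumoral /
   peritumoral compartment assignment (peritumoral = 500 µm band outside
   the margin), and the 20 µm distance-class density histogram within
   ±100 µm, with band areas computed by polygon offsetting.
3. **Scoring** — ordinal 0/1+/2+/3+ grading of the positive-cell
   fraction (0; <10 %; 10–50 %; 50–100 %), high (2+/3+) vs low (0/1+)
   dichotomization, PD-L1/PD-L2 positivity at ≥5 %, β-catenin
   overexpression above the cohort median, and the three-group
   CD8×CD163 / CD8×PD-L1 / CD8×β-catenin combination schemes
   (group 1 immune-favorable … group 3 immune-hostile).
4. **Association** — multivariable logistic models of overall response
   (odds ratios, Wald 95 % CI), Cox proportional-hazards models of
   PFS/OS (Efron ties; OS additionally adjusted for subsequent
   immunotherapy), Kaplan–Meier curves with median/quartile times, and
   χ²/Kruskal–Wallis auxiliary tests.
5. **Synthetic data** — because clinical images and cohorts are not
   publicly available, the package ships first-class generators:
   inhomogeneous Poisson marked point patterns whose intensity
   λ(p) = max(0, λ_base + slope·d(p)) follows the signed margin distance,
   pseudo-IHC renderings (blue nuclei, fast-red positives, Gaussian
   noise), and patient cohorts with known logistic / proportional-hazards
   structure for end-to-end validation by parameter recovery.

## Worked example

```python
from immunocontext import (SceneConfig, generate_tissue_scene,
                           compartment_densities, score_density,
                           dichotomize_score, combine_cd8_cd163,
                           CohortConfig, generate_cohort,
                           fit_response_model, fit_survival_model,
                           km_estimate)
from immunocontext.association import derive_endpoints

# A 1 mm^2 tissue scene with a circular margin of radius 400 um
scene = generate_tissue_scene(SceneConfig(seed=1))
comp = compartment_densities(scene.cells, scene.geometry)
print(comp.densities_per_mm2.round(0))
#                 CD8  CD163     NEG
# intratumoral  316.0  617.0  1514.0
# peritumoral   611.0  394.0  1584.0

cd8 = dichotomize_score(score_density(comp.fraction("CD8", "intratumoral")))
cd163 = dichotomize_score(score_density(comp.fraction("CD163", "intratumoral")))
print(cd8, cd163, combine_cd8_cd163(cd8, cd163))
# high high 2     (12.9% -> 2+, 25.2% -> 2+, both-high -> group 2)

# A simulated cohort of 800 patients, refit with the multivariable models
cohort = derive_endpoints(generate_cohort(CohortConfig(n_patients=800, seed=1)))
print(fit_response_model(cohort, "group").table.round(2).head(2))
#          estimate  ci_low  ci_high    p
# group=1      6.27    4.02     9.76  0.0     (odds ratio, group 1 vs 3)
# group=2      2.60    1.84     3.67  0.0
print(fit_survival_model(cohort, "os", "group").table.round(2).head(2))
#          estimate  ci_low  ci_high    p
# group=1      0.35    0.27     0.46  0.0     (hazard ratio, group 1 vs 3)
km = km_estimate(cohort, "os")
print(f"median OS {km.median:.1f} months (IQR {km.q25:.1f}-{km.q75:.1f})")
# median OS 22.6 months (IQR 9.3-45.8)
```

The intratumoral high-CD8/low-CD163 phenotype (group 1, versus the
immune-hostile group 3 reference) carries a large odds ratio for
response and a hazard ratio well below 1 for death, as encoded in the
generator's ground truth.

A command-line interface mirrors the library
(`immunocontext simulate-scene | render | detect | profile | score |
simulate-cohort | associate | run-all | make-fixtures`); `run-all`
executes the full pipeline from a YAML config and writes a manifest with
per-file checksums so runs are reproducible from their seeds.

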