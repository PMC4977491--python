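# craniomorph

3D landmark-based geometric morphometrics for biodistance analysis of
crania and mandibles: missing-landmark estimation, generalized Procrustes
superimposition with extraction of the symmetric shape component, size and
shape statistics, between-group ordination, Mahalanobis distances, and
bootstrapped Neighbor-Joining trees.

The package is aimed at bioarchaeologists comparing skeletal series across
cultural or dietary groups — for example hunter-gatherer versus farming
populations along a chronological sequence — from homologous 3D landmarks
(39 cranial, 33 mandibular in the default configuration) digitized on bone
surfaces. It ships a synthetic landmark generator with closed-form ground
truth so every pipeline stage is testable without access to original scan
data.

## The method

Given n specimens with k landmarks each:

1. **Imputation.** Missing bilateral landmarks with a present partner are
   recovered by reflection across the least-squares midsagittal plane;
   the remainder are mapped from a complete reference by the 3D thin-plate
   spline (kernel U(r) = −r) that interpolates the shared landmarks with
   minimal bending energy. Specimens with ≥ 20% missing landmarks are
   excluded.
2. **Superimposition.** Generalized Procrustes analysis: translate to a
   common centroid, scale to unit centroid size CS = √Σᵢ‖xᵢ − x̄‖², rotate by
   least squares onto the iteratively updated mean; project into the tangent
   space at the mean. Each configuration is then averaged with its
   reflected, relabelled and re-superimposed mirror image, leaving the
   symmetric component of shape that all downstream statistics use.
3. **Statistics.** ANOVA + Tukey HSD on centroid size; between-group PCA
   (eigenvectors of the group-means covariance, all specimens projected);
   MANOVA (Wilks' Λ, Rao's F, effect size R² = tr B / tr T) on the PC scores
   retaining 95% of total variance; Mahalanobis distances
   D = √((m̄ᵢ − m̄ⱼ)ᵀW⁻¹(m̄ᵢ − m̄ⱼ)) with pooled within-group covariance W;
   allometric regressions of PC scores on CS.
4. **Trees.** Saitou–Nei Neighbor-Joining on the distance matrix, with
   support from 1000 stratified specimen-bootstrap replicates rerunning
   PCA → Mahalanobis → NJ.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

```bash
craniomorph simulate --unit cranium --seed 3 --missing-rate 0.05 --out synth
craniomorph run --input synth.csv --unit cranium --reps 200 --seed 0 --out out/
```

The `run` subcommand prints the MANOVA grouping table, the Mahalanobis
matrix and the Newick tree. On the simulated cranial dataset above it ends
with (abridged):

```
       grouping                    subset  r_squared      p_value
Cultural groups               All samples   0.199751 1.852944e-15
Cultural groups Without Mesolithic sample   0.104859 3.447722e-08
 Dietary groups    All groups (HG, EF, F)   0.148905 5.345484e-13
 ...
            A-group  C-group  Meroitic  Mesolithic  Pharaonic
A-group      0.0000   6.7370    6.3585     12.2629     8.6790
C-group      6.7370   0.0000    5.7292     11.5904     6.2429
...
(C-group:2.49,(Meroitic:2.04,Pharaonic:3.69)50:0.63,(A-group:3.60,Mesolithic:8.67)43:0.54);
```

Reading: shape differs significantly among the five simulated cultural
horizons (R² ≈ 0.20), the displaced hunter-gatherer (Mesolithic) group is
11–14 Mahalanobis units from every farming group while farmers sit 5–9
units apart, and the tree isolates it on a long terminal branch with
moderate bootstrap support at these sample sizes. Estimated distances
exceed their generating values at n = 69 because the plug-in Mahalanobis
estimator is inflated when many PCs are retained (see the methods note).

The equivalent library calls are `simulate_dataset(table1_design(...))`,
`symmetric_gpa`, `total_pca`/`retain_for_variance`/`between_group_pca`,
`manova`, `mahalanobis_matrix`, and `bootstrap_supports`. The numbered
scripts under `analysis/` run the same sequence as a narrated analysis,
writing tables, trees and scatter data under `results/`.

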