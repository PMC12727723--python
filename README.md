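# metconn

Construction and analysis of **within-subject brain metabolic connectomes**
from parcellated magnetic-resonance-spectroscopic-imaging (MRSI) metabolite
maps.

Proton MRSI quantifies, per voxel, the concentrations of a handful of brain
metabolites — here tNAA (neuronal integrity), tCr (energy metabolism), Glx
(excitatory neurotransmission), Cho (membrane turnover) and Ins (glial
activity) — together with Cramér–Rao-lower-bound (CRLB) variance estimates.
`metconn` turns such maps into a network object and analyzes its geometry:

1. **Metabolic profiles.** Regions smaller than 8 voxels (or poorly covered
   across a cohort) are discarded; each retained region gets a 5-metabolite
   profile (parcel median, z-scored across regions). Quantification
   uncertainty is propagated by Monte-Carlo perturbation: each voxel signal
   is resampled as Y′ ~ 𝒩(Y, 3σ²) with σ² the CRLB variance, K_pert times
   (replicate 1 is the unperturbed data).
2. **MetSiM.** The metabolic similarity matrix w_ij is the pairwise Spearman
   rank correlation between the concatenated, per-replicate z-scored
   regional profiles — a symmetric region × region matrix in [−1, 1].
3. **MS mode.** The rows of the MetSiM are reduced to a one-dimensional
   *metabolic similarity mode* μ_i by PCA (50 components) followed by 1-D
   t-SNE with PCA initialization (perplexity 30, early exaggeration 12).
   A Student-t kernel reconstruction
   q_ij = (1+|μ_i−μ_j|²)⁻¹ / Σ_{k≠l}(1+|μ_k−μ_l|²)⁻¹ recovers a filtered
   similarity matrix, and an ISOMAP spectrum reports intrinsic
   dimensionality.
4. **Principal paths.** The mode defines a gradient field
   (∇μ)_ij = (μ_j−μ_i)/‖r_j−r_i‖ on the gray-matter adjacency graph. A
   *metabolic principal path* is the simple path γ between two endpoints
   minimizing ℒ(γ) = 𝒢̃_μ(γ)/H̃(γ), where 𝒢̃_μ is the mean edge gradient
   normalized by the maximum over uniformly random mode sequences with the
   same endpoints, and H̃ is the Rice-rule-binned normalized Shannon entropy
   of the mode values along the path. The search enumerates all simple
   paths by depth-first backtracking and filters implausible detours.
5. **Spatial null models and statistics.** Distance-matched surrogate
   matrices (RandGeom: linear weight-vs-distance trend plus per-2 mm-bin
   residual resampling, with within-hemisphere / mirrored / gray-matter-
   adjacent variants), adjacency-constrained permutations (AdjPerm),
   Maslov–Sneppen degree-preserving rewiring, rich-club coefficients
   φ(k) = 2E_{>k}/(N_{>k}(N_{>k}−1)), matrix-power higher-order
   connectivity, the
   communicability model M = exp(g·S) fitted to structural connectivity,
   Hungarian inter-class overlap and normalized mutual information for
   cross-modal label comparison.

A first-class **synthetic data generator** emulates the statistical
structure this analysis assumes (≈210 bilaterally symmetric parcels, a
planted monotone caudal-to-rostral axis carrying a tNAA/Cho
cortical/subcortical reversal, spatially autocorrelated fields,
heteroscedastic voxel noise, a distance-decaying structural backbone), so
every stage is testable without scanner data and parameter recovery can be
verified against ground truth.

## Worked example

```python
import numpy as np
from scipy import stats
import metconn as mc

scheme = mc.generate_parcel_scheme(105, seed=7)            # 210 parcels
vox, truth = mc.generate_voxel_metabolites(scheme, seed=8)
retained = mc.filter_regions(vox, scheme, min_voxels=1)
reps = mc.perturb_voxels(vox, K_pert=50, seed=9)           # Monte-Carlo
profiles = mc.compute_profiles(reps, scheme, retained)
metsim = mc.compute_metsim(profiles)

mode = mc.reduce_mode(metsim.W, region_ids=metsim.region_ids,
                      scheme=scheme, seed=10)
rho = stats.spearmanr(mode.mu, truth.planted_axis).statistic
print(f"MS mode vs planted axis: Spearman rho = {rho:.3f}")

dd = mc.distance_density(metsim, scheme)
print(f"median distance of positive weights: "
      f"{dd['positive']['median_distance_mm']:.1f} mm")
print(f"median distance of negative weights: "
      f"{dd['negative']['median_distance_mm']:.1f} mm")

bg = mc.binarize(metsim.W, 0.18, node_ids=metsim.region_ids)
phi = mc.rich_club(bg, k=60)
null_phi = [mc.rich_club(g, 60)
            for g in mc.maslov_sneppen(bg.graph(), n_rand=99, seed=11)]
print(f"rich club at 18% density, k=60: phi = {phi:.3f} "
      f"(degree-preserving null p = "
      f"{mc.empirical_pvalue(phi, null_phi, tail='ge'):.2f})")
```

prints

```
MS mode vs planted axis: Spearman rho = 0.915
median distance of positive weights: 69.3 mm
median distance of negative weights: 80.9 mm
rich club at 18% density, k=60: phi = 0.773 (degree-preserving null p = 0.01)
```

The mode recovers the planted caudo-rostral axis (ρ = 0.92); positively
correlated region pairs sit at shorter inter-centroid distances than
negatively correlated ones (69 vs 81 mm medians), the signature of local
metabolic similarity with a long-range cortical/subcortical anticorrelation;
and high-degree similarity hubs interconnect more densely than
degree-matched rewired networks expect.

A command-line interface mirrors the library:

```bash
metconn generate --n-per-hemisphere 105 --seed 7 --out data/
metconn metsim --voxels data/voxels.tsv --scheme data/scheme.tsv \
        --adjacency data/adjacency.tsv --kpert 50 --seed 7 --out metsim.csv
metconn mode --metsim metsim.csv --perplexity 30 --seed 7 --out mode.tsv
metconn path --mode mode.tsv --scheme data/scheme.tsv \
        --adjacency data/adjacency.tsv --start 17 --end 4 \
        --hemisphere L --seed 7 --out path.json
metconn run --out results/          # full pipeline with a manifest
```

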