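"""Augmented-RCBD trial analysis on a simulated breeding population.

Simulates a field trial shaped like a cassava single-row trial (9
blocks, 5 replicated commercial checks, 29 unreplicated test genotypes),
then runs the statistics layer: Federer-adjusted means, ANOVA,
broad-sense heritability, trait correlations and PCA.
"""

import numpy as np

from crownpheno import (augmented_rcbd_adjust, broad_sense_heritability,
                        correlation_matrix, make_trial_dataset,
                        normality_check, pca_traits)

df = make_trial_dataset(
    n_test_genotypes=29, n_checks=5, n_blocks=9,
    variance_components={"sigma2_G": 7.0, "sigma2_block": 2.0,
                         "sigma2_e": 3.0},
    trait_means={"crown_volume_cm3": 2500.0, "crown_diameter_cm": 35.0,
                 "compactness_pct": 12.0},
    seed=42)

trait = "crown_volume_cm3"
adj = augmented_rcbd_adjust(df, trait)
print("ANOVA for", trait)
print(adj.anova.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

h = broad_sense_heritability(df, trait)
print(f"\nbroad-sense heritability: H2 = {h.H2:.3f} "
      f"(sigma2_G = {h.sigma2_G:.2f}, sigma2_e = {h.sigma2_e:.2f}; "
      "injected H2 = 0.70)")

qq = normality_check(adj.means.to_numpy())
print(f"Shapiro-Wilk W of adjusted means: {qq['shapiro_w']:.4f}")

wide = df.groupby("genotype")[["crown_volume_cm3", "crown_diameter_cm",
                               "compactness_pct"]].mean()
corr = correlation_matrix(wide)
print("\ntrait correlations (independent traits, so r should be small):")
print(corr.r_matrix.round(2).to_string())

pca = pca_traits(wide)
print("\nPCA eigenvalues:", np.round(pca.eigenvalues, 3),
      "(sum equals the 3 traits)")
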