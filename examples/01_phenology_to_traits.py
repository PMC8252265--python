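"""From ordinal stage scores to clone-level trait values.

Simulates a small clonal trial scored every 2-5 days, converts the ordinal
observations to transition days with the running-maximum rule, imputes the
transitions missed between visits by per-individual LOESS, and averages
ramets into clone phenotypes.
"""

import numpy as np

from slopescan import (
    SimulationConfig,
    TraitCatalog,
    TraitModel,
    clone_summary,
    default_cross_design,
    impute_loess,
    make_crosses,
    simulate_population,
    simulate_phenology,
    transitions_from_stages,
)

cfg = SimulationConfig(seed=42, N_e=100, L=500_000, mu=4e-7, r=2e-7)
founders, variants, gmap, _ = simulate_population(cfg)
design = default_cross_design(founders.samples, seed=42)
offspring, pedigree = make_crosses(founders, variants, gmap, design, seed=42)
genotypes = offspring.to_dosages()

model = TraitModel(trait="LS", causal_idx=(10,), effects=(2.0,), h2=0.4,
                   reversal_error=0.03, missing_visit=0.05)
obs, truth, g = simulate_phenology(genotypes, model, seed=42, ramets_per_clone=3)
print(f"{len(obs)} visit records for {genotypes.n_samples} clones x 3 ramets")

transitions = transitions_from_stages(obs)
n_missing = 4 * genotypes.n_samples * 3 - (transitions["stage"] >= 2).sum()
transitions = impute_loess(transitions)
imputed = (transitions["provenance"] == "imputed").sum()
print(f"{imputed} stage transitions imputed by LOESS "
      "(stages crossed between two visits)")

catalog = TraitCatalog.parse(["LS2-17", "LS5-17"])
values, counts = clone_summary(transitions, catalog)
print(values.head().round(1))
print("Each cell is a clone's mean Julian day of reaching that leaf-shed "
      "stage, the phenotype used for association.")
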