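#!/usr/bin/env python
"""Generate the study-scale synthetic dataset.

Thirty populations (26 invasive in three lineages, four native, one of them
a diverse mostly-outcrossing population), ~6,000 unlinked SNPs,
right-skewed individual missingness, and planted recent and historical
inter-lineage hybrids. The genotype matrix goes to scratch/ (it is bulky
and fully reproducible from the seed); the truth table and scenario config
go to results/analysis/.
"""

from pathlib import Path

from selfkit.genotypes import write_genotypes
from selfkit.simulate import simulate_study

SEED = 1
OUT = Path("results/analysis")
SCRATCH = Path("scratch")

gm, truth, config = simulate_study("paper_like", seed=SEED, n_loci=6000)

OUT.mkdir(parents=True, exist_ok=True)
SCRATCH.mkdir(exist_ok=True)
write_genotypes(gm, SCRATCH / "study_genotypes.tsv", "matrix012")
truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
config.to_yaml(OUT / "scenario.yaml")

miss = (gm.genotypes == -1).mean(axis=1)
print(f"simulated {gm.n_individuals} individuals in "
      f"{len(set(gm.population_labels))} populations x {gm.n_loci} loci")
print(f"missingness per individual: mean {miss.mean():.3f}, "
      f"median {float(__import__('numpy').median(miss)):.3f}")
print(truth["category"].value_counts().to_string())
print(f"wrote {SCRATCH / 'study_genotypes.tsv'}, {OUT / 'truth.tsv'}, "
      f"{OUT / 'scenario.yaml'}")
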