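#!/usr/bin/env python
"""Per-population multilocus selfing rates (the Table-1 analogue).

For every population with n >= 3: subsample 1,000 loci, estimate g2 and the
selfing rate, permutation p-value against the no-identity-disequilibrium
null, and an individual-bootstrap SD. The table is written next to the
generator's true rates for direct comparison.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from selfkit.genotypes import filter_loci, observed_heterozygosity
from selfkit.selfing import estimate_selfing
from selfkit.simulate import simulate_study

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

gm, truth, config = simulate_study("paper_like", seed=1, n_loci=6000)
gm = filter_loci(gm, max_missing_frac=0.1)
true_s = {p.label: p.selfing_rate for p in config.populations}
ho = observed_heterozygosity(gm)
rng = np.random.default_rng(2)

rows = []
for pop, idx in gm.population_indices().items():
    if len(idx) < 3:
        continue
    est = estimate_selfing(gm, idx, max_loci=1000, n_perm=1000, n_boot=400,
                           seed=rng)
    rows.append({
        "population": pop, "n": len(idx),
        "h_obs": float(np.nanmean(ho[idx])),
        "s_true": true_s.get(pop, np.nan),
        "s_hat": est.s_hat, "sd_s": est.sd_s, "p_value": est.p_value,
        "g2_hat": est.g2_hat, "n_loci_used": est.n_loci_used,
    })
table = pd.DataFrame(rows)
table.to_csv(OUT / "selfing_rates.tsv", sep="\t", index=False,
             float_format="%.4g")

ok = table.dropna(subset=["s_true", "s_hat"])
err = (ok["s_hat"] - ok["s_true"]).abs()
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\n{len(ok)} populations estimated; median |s_hat - s_true| = "
      f"{err.median():.3f}")
nonsig = table[table["p_value"] > 0.05]["population"].tolist()
print(f"populations without significant identity disequilibrium: {nonsig}")
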