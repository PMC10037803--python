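"""Broad-sense heritability of expression and GO-level shift testing.

Estimates per-gene H2 = sigma_G^2 / (sigma_G^2 + sigma_E^2) by REML on
replicated genotypes, compares the estimates with the simulated targets,
and runs the Kolmogorov-Smirnov GO-shift test on a term planted to contain
one co-expression module (whose genes were given elevated H2).
"""

import numpy as np
import pandas as pd

from heritex import (
    SimulationConfig, boxcox_transform, build_default_fixture,
    go_heritability_shift, h2_table,
)

fx = build_default_fixture(
    seed=7,
    config=SimulationConfig(n_genotypes=120, replicates_per_genotype=3, n_markers=1000, seed=7),
    n_genes=400, n_introns=40, n_cis=8, n_trans=2, n_modules=1, module_size=30, n_sqtl=5,
)

fpkm = fx.expression.fpkm
transformed = pd.DataFrame(
    {g: boxcox_transform(fpkm[g].to_numpy())[0] for g in fpkm.columns},
    index=fpkm.index,
)
h2 = h2_table(transformed, fx.expression.replicate_map)

targets = pd.Series(fx.truth.per_gene_target_H2)
err = (h2["h2"] - targets.loc[h2.index]).abs()
print(f"genes fit            : {len(h2)}")
print(f"mean |H2 - target|   : {err.mean():.3f}   (REML recovery of the planted values)")
print(f"mean H2 (est/target) : {h2['h2'].mean():.3f} / {targets.mean():.3f}")

shift = go_heritability_shift(h2["h2"], fx.go_annotations)
planted = shift[shift["term"] == "GO:1000001"]
print("\nGO H2-shift test (planted module term GO:1000001):")
print(planted[["term", "n_genes", "median_term", "median_background", "p", "fdr", "direction", "significant"]]
      .to_string(index=False))
print(f"significant terms overall: {int(shift['significant'].sum())} of {len(shift)}")
# The planted term's member genes carry a genotype-driven module factor, so
# the KS test finds their H2 distribution shifted "higher" at a strong FDR.
# Note the two-part criterion: a term is only flagged significant when the
# FDR holds AND the term median differs from the background median by at
# least 20% - a distribution shift with a modest median displacement (as
# here) is reported but not flagged.
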