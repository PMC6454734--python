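"""Simulate a multi-study disease and run the random-effects meta-analysis.

Four case-control studies with planted effects are combined per gene into
mu_hat (combined standardized mean difference), z, p and FDR q; the printed
correlation says how well the combined effects track the planted truth.
"""

import numpy as np
import pandas as pd

from cometa import SyntheticConfig, generate_disease, meta_analyze

studies, truth = generate_disease(SyntheticConfig(seed=7), disease_id="demo")
meta = meta_analyze(studies, disease_id="demo")

n_de = (meta.table["q"] < 0.05).sum()
up = ((meta.table["q"] < 0.05) & (meta.table["mu_hat"] > 0)).sum()
planted = pd.Series(truth.true_effects).reindex(meta.table.index).fillna(0.0)
corr = np.corrcoef(meta.mu_hat, planted)[0, 1]

print(f"genes tested: {meta.n_genes_tested}")
print(f"differentially expressed at q<0.05: {n_de} ({up} up, {n_de - up} down)")
print(f"planted DE genes: {len(truth.de_genes)}")
print(f"corr(mu_hat, planted effects): {corr:.3f}")
print("-> a correlation near 1 means the meta-analysis recovers the planted",
      "per-gene effects despite between-study heterogeneity (tau=0.2).")
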