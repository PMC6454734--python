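"""Cluster disease deregulation profiles: PAM + silhouette and a discrete tree.

Five diseases are simulated: an index disease, two partners sharing its DE
genes (same direction), and two independent ones.  PAM over the correlation
distance of mu_hat profiles should group the related diseases; the discrete
status matrix is also clustered hierarchically to ask which diseases join
the index first.
"""

import pandas as pd

from cometa import (
    SyntheticConfig,
    classify_genes,
    co_clustering_report,
    generate_disease,
    generate_related_disease,
    meta_analyze,
    profile_distance_matrix,
    select_k,
)

cfg = dict(n_genes=1000, n_studies=2, n_cases_per_study=12, n_controls_per_study=12)
studies, truth = generate_disease(SyntheticConfig(seed=1, **cfg), disease_id="index")
metas = {"index": meta_analyze(studies, disease_id="index")}
plan = {"partner1": 0.7, "partner2": 0.7, "lone1": 0.0, "lone2": 0.0}
for i, (name, frac) in enumerate(plan.items()):
    st, _ = generate_related_disease(truth, SyntheticConfig(**cfg), frac, 0.0, 100 + i,
                                     disease_id=name)
    metas[name] = meta_analyze(st, disease_id=name)

mu = pd.concat({n: m.mu_hat for n, m in metas.items()}, axis=1)
dist = profile_distance_matrix(mu, "correlation")
best_k, results = select_k(dist, range(2, 5))
print("avg silhouette per k:",
      {k: round(r.avg_silhouette, 3) for k, r in results.items()})
print(f"best k = {best_k}; assignment = {results[best_k].assignment}")

status = pd.concat({n: classify_genes(m).status for n, m in metas.items()}, axis=1)
status = status.fillna(0).astype(int)
print(co_clustering_report(status, "index").to_string(index=False))
print("-> a planted partner disease joins the index disease first under every",
      "discrete metric, and PAM separates related from independent profiles.")
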