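"""Directional comparison of two diseases' differential-expression profiles.

Given two per-gene meta-analysis tables, genes are classified up / down /
unchanged at an FDR threshold, and the four directional intersections are
tested for excess overlap with one-tailed Fisher (hypergeometric upper
tail) tests against the background of genes jointly tested in both
meta-analyses:

    A = up in both,  B = down in both,
    C = up in disease 1 and down in disease 2,
    D = down in disease 1 and up in disease 2.

After FDR correction across a batch of comparisons a disease pair is
labeled SDDC (same-direction deregulation: A and B significant, C and D
not), ODDC (the mirror case), "mixed", or "none".  A complementary
continuous comparison is the Pearson correlation of the combined effects
(mu_hat) over jointly tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meta_de import MetaTable, bh_fdr

INTERSECTIONS = ["A", "B", "C", "D"]


@dataclass
class DEProfile:
    """Per-gene direction calls plus continuous effect and z vectors."""

    disease_id: str
    status: pd.Series  # gene -> {+1, -1, 0}
    mu_hat: pd.Series
    z: pd.Series

    @property
    def up_genes(self) -> list[str]:
        return list(self.status.index[self.status == 1])

    @property
    def down_genes(self) -> list[str]:
        return list(self.status.index[self.status == -1])


def classify_genes(meta: MetaTable, fdr_threshold: float = 0.05) -> DEProfile:
    """Call genes up (+1) / down (-1) at ``q < fdr_threshold``, else 0."""
    t = meta.table
    status = pd.Series(0, index=t.index, dtype=int)
    sig = t["q"] < fdr_threshold
    status[sig] = np.sign(t.loc[sig, "mu_hat"]).astype(int)
    return DEProfile(meta.disease_id, status, t["mu_hat"].copy(), t["z"].copy())


def fisher_one_tailed(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Population ``N`` with ``K`` successes, ``n`` draws, ``k`` observed
    successes — the one-tailed Fisher exact test for overlap enrichment.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need K, n <= N and all non-negative")
    if k < 0 or k > min(K, n):
        raise ValueError("overlap k must satisfy 0 <= k <= min(K, n)")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class IntersectionResult:
    """Directional intersection counts and tests for one disease pair."""

    pair: tuple[str, str]
    background_n: int
    counts: dict[str, int]
    genes: dict[str, list[str]]
    p: dict[str, float]
    q: dict[str, float] = field(default_factory=dict)
    label: str | None = None

    def as_row(self) -> dict:
        row = {
            "disease_1": self.pair[0],
            "disease_2": self.pair[1],
            "background_n": self.background_n,
        }
        row.update({i: self.counts[i] for i in INTERSECTIONS})
        row.update({f"p{i}": self.p[i] for i in INTERSECTIONS})
        if self.q:
            row.update({f"q{i}": self.q[i] for i in INTERSECTIONS})
        row["label"] = self.label
        return row


def intersection_test(profile1: DEProfile, profile2: DEProfile) -> IntersectionResult:
    """Test the four directional intersections of two DE profiles.

    The background is the set of genes jointly tested in both
    meta-analyses.  FDR correction and SDDC/ODDC labeling happen later, in
    :func:`adjust_and_label`, across a batch of comparisons.
    """
    shared = profile1.status.index.intersection(profile2.status.index)
    if len(shared) == 0:
        raise ValueError("no jointly tested genes")
    s1 = profile1.status.loc[shared]
    s2 = profile2.status.loc[shared]
    up1, dn1 = set(shared[s1 == 1]), set(shared[s1 == -1])
    up2, dn2 = set(shared[s2 == 1]), set(shared[s2 == -1])
    genes = {
        "A": sorted(up1 & up2),
        "B": sorted(dn1 & dn2),
        "C": sorted(up1 & dn2),
        "D": sorted(dn1 & up2),
    }
    sizes = {"A": (up1, up2), "B": (dn1, dn2), "C": (up1, dn2), "D": (dn1, up2)}
    N = len(shared)
    p = {
        i: fisher_one_tailed(len(genes[i]), len(a), len(b), N)
        for i, (a, b) in sizes.items()
    }
    counts = {i: len(genes[i]) for i in INTERSECTIONS}
    return IntersectionResult((profile1.disease_id, profile2.disease_id), N, counts, genes, p)


def adjust_and_label(
    results: list[IntersectionResult],
    alpha: float = 0.05,
    scope: str = "batch",
) -> list[IntersectionResult]:
    """FDR-correct intersection p-values and attach SDDC/ODDC labels.

    ``scope="batch"`` corrects jointly across the 4 x n_pairs p-values of
    the whole batch (conservative default); ``scope="pair"`` corrects the
    four tests of each pair separately.  Labels: SDDC iff qA and qB < alpha
    while qC and qD >= alpha; ODDC for the converse; "mixed" when at least
    one same-direction and one cross-direction intersection are
    significant; "none" otherwise.
    """
    if not results:
        raise ValueError("no results to adjust")
    if scope not in ("batch", "pair"):
        raise ValueError("scope must be 'batch' or 'pair'")
    if scope == "batch":
        flat = np.array([r.p[i] for r in results for i in INTERSECTIONS])
        q = bh_fdr(flat).reshape(len(results), 4)
        qs = [{i: float(qr[j]) for j, i in enumerate(INTERSECTIONS)} for qr in q]
    else:
        qs = [
            dict(zip(INTERSECTIONS, bh_fdr([r.p[i] for i in INTERSECTIONS])))
            for r in results
        ]
    labeled = []
    for r, qmap in zip(results, qs):
        same = (qmap["A"] < alpha, qmap["B"] < alpha)
        cross = (qmap["C"] < alpha, qmap["D"] < alpha)
        if all(same) and not any(cross):
            label = "SDDC"
        elif all(cross) and not any(same):
            label = "ODDC"
        elif any(same) and any(cross):
            label = "mixed"
        else:
            label = "none"
        labeled.append(
            IntersectionResult(
                r.pair, r.background_n, r.counts, r.genes, r.p, {k: float(v) for k, v in qmap.items()}, label
            )
        )
    return labeled


@dataclass
class CorrelationResult:
    """Pearson correlation of two diseases' combined effects."""

    pair: tuple[str, str]
    r: float
    n: int
    p: float


def profile_correlation(profile1: DEProfile, profile2: DEProfile) -> CorrelationResult:
    """Pearson correlation of mu_hat over all jointly tested genes."""
    shared = profile1.mu_hat.index.intersection(profile2.mu_hat.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 jointly tested genes")
    a = profile1.mu_hat.loc[shared].to_numpy(float)
    b = profile2.mu_hat.loc[shared].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(
        (profile1.disease_id, profile2.disease_id), float(r), len(shared), float(p)
    )


def overall_profile(mu_tables: list[MetaTable | pd.Series]) -> pd.Series:
    """Unweighted per-gene mean of mu_hat across diseases where tested."""
    if not mu_tables:
        raise ValueError("no profiles")
    series = [
        (t.mu_hat if isinstance(t, MetaTable) else pd.Series(t)) for t in mu_tables
    ]
    return pd.concat(series, axis=1).mean(axis=1, skipna=True)


def results_table(
    results: list[IntersectionResult],
    correlations: list[CorrelationResult] | None = None,
) -> pd.DataFrame:
    """Flatten labeled intersection (and optional correlation) results."""
    df = pd.DataFrame([r.as_row() for r in results])
    if correlations:
        cor = pd.DataFrame(
            [
                {"disease_1": c.pair[0], "disease_2": c.pair[1], "r": c.r, "r_p": c.p}
                for c in correlations
            ]
        )
        df = df.merge(cor, on=["disease_1", "disease_2"], how="left")
    return df
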