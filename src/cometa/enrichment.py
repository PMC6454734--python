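"""Preranked gene-set enrichment, overrepresentation, and drug ranking.

Three related analyses share this module:

* preranked GSEA — the weighted Kolmogorov–Smirnov-like running-sum
  statistic over a list ranked by the meta-analysis z-values, with a
  gene-label permutation null, sign-class NES normalization and FDR;
* hypergeometric overrepresentation (ORA) of a query gene list, sharing
  its p-value core with the comorbidity module's one-tailed Fisher test;
* connectivity-style drug analysis — cosine similarity between a disease
  z-vector and perturbation signatures ranks drugs from mimicking
  (positive cosine) to reversing (negative cosine), and drug sets are then
  tested for enrichment at either extreme of that ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comorbidity import fisher_one_tailed
from .genesets import GeneSetCollection
from .meta_de import bh_fdr


@dataclass
class RankedList:
    """Items ordered by decreasing score, ties broken by item id."""

    items: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.items) != len(self.scores):
            raise ValueError("items and scores differ in length")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate items in ranked list")
        if (np.diff(self.scores) > 0).any():
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_scores(cls, scores: dict[str, float] | pd.Series) -> "RankedList":
        s = pd.Series(scores).dropna()
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return cls(np.array(order, dtype=object), s.loc[order].to_numpy(float))

    def positions(self, members: list[str]) -> np.ndarray:
        """Sorted rank positions of the members present in the list."""
        lookup = {g: i for i, g in enumerate(self.items)}
        return np.array(sorted(lookup[m] for m in members if m in lookup), dtype=int)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _es_from_positions(
    pos: np.ndarray, weights_abs: np.ndarray, n: int, return_extremum: bool = False
):
    """Signed maximum deviation of the GSEA running sum.

    ``pos`` are sorted hit positions (2-D: permutations x hits, or 1-D);
    ``weights_abs`` is |score|^weight over the whole list.  The running sum
    only needs evaluating just before and just after each hit, which keeps
    the cost O(hits) instead of O(list length).
    """
    squeeze = pos.ndim == 1
    pos2 = pos[None, :] if squeeze else pos
    b, m = pos2.shape
    if m == 0:
        raise ValueError("no members present in the ranked list")
    if m >= n:
        es = np.ones(b)
        return (es[0], 0, True) if squeeze and return_extremum else (es[0] if squeeze else es)
    h = weights_abs[pos2]
    denom = h.sum(axis=1, keepdims=True)
    flat = denom[:, 0] == 0
    if flat.any():  # all member scores zero under this weight: equal steps
        h[flat] = 1.0
        denom = h.sum(axis=1, keepdims=True)
    cum = np.cumsum(h, axis=1) / denom
    miss = 1.0 / (n - m)
    drop = (pos2 - np.arange(m)[None, :]) * miss  # misses accumulated before each hit
    after = cum - drop
    before = np.concatenate([np.zeros((b, 1)), cum[:, :-1]], axis=1) - drop
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    # signed maximum deviation; ties (within rounding, 1e-9) resolve to the
    # positive side so the statistic is deterministic
    take_pos = np.abs(es_pos) >= np.abs(es_neg) - 1e-9
    es = np.where(take_pos, es_pos, es_neg)
    if not return_extremum:
        return es[0] if squeeze else es
    assert squeeze
    if take_pos[0]:
        return float(es_pos[0]), int(np.argmax(after[0])), True
    return float(es_neg[0]), int(np.argmin(before[0])), False


def gsea_es(
    ranked: RankedList, members: list[str], weight: float = 1.0
) -> tuple[float, list[str]]:
    """Enrichment score and leading edge of one set on a ranked list.

    The running sum gains ``|score|^weight / sum_members |score|^weight``
    at member positions and loses ``1/(N - m)`` elsewhere; ES is the signed
    maximum deviation.  The leading edge contains the members at or before
    the extremum (at or after it, for negative ES).
    """
    pos = ranked.positions(members)
    if pos.size == 0:
        raise ValueError("no set member present in the ranked list")
    wabs = np.abs(ranked.scores) ** weight
    es, j, positive = _es_from_positions(pos, wabs, len(ranked), return_extremum=True)
    if positive:
        leading = [str(ranked.items[p]) for p in pos[: j + 1]]
    else:
        leading = [str(ranked.items[p]) for p in pos[j:]]
    return float(es), leading


def _null_es(
    n: int, m: int, weights_abs: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution by permuting set membership labels."""
    pos = np.empty((n_perm, m), dtype=int)
    for b in range(n_perm):
        pos[b] = rng.choice(n, size=m, replace=False)
    pos.sort(axis=1)
    return _es_from_positions(pos, weights_abs, n)


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a set collection with a gene-permutation null.

    For each set: ES and leading edge from :func:`gsea_es`; the null is
    built by drawing random member positions of the same size (one shared
    null per set size); NES = ES / mean(|null ES| of matching sign);
    p = (1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign
    nulls); q = Benjamini–Hochberg within each sign class.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    restricted = collection.restrict(list(ranked.items)).filter_size(min_size, max_size)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    wabs = np.abs(ranked.scores) ** weight

    sizes = sorted({len(m) for _n, m in restricted})
    nulls = {m: _null_es(n, m, wabs, n_perm, rng) for m in sizes}

    rows = []
    for name, members in restricted:
        es, leading = gsea_es(ranked, members, weight)
        null = nulls[len(members)]
        same = null[null > 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            warnings.warn(f"{name}: degenerate null (no same-sign permutation ES)", stacklevel=2)
            nes, p = np.nan, 1.0
        else:
            nes = es / np.abs(same).mean()
            p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + same.size)
        rows.append(
            {
                "set_name": name,
                "size": len(members),
                "ES": es,
                "NES": nes,
                "p": p,
                "leading_edge": leading,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(columns=["set_name", "size", "ES", "NES", "p", "q", "leading_edge"])
    result["q"] = np.nan
    for mask in (result["ES"] >= 0, result["ES"] < 0):
        if mask.any():
            result.loc[mask, "q"] = bh_fdr(result.loc[mask, "p"].to_numpy())
    return result[["set_name", "size", "ES", "NES", "p", "q", "leading_edge"]]


# ---------------------------------------------------------------------------
# overrepresentation
# ---------------------------------------------------------------------------

def ora(
    query_genes: list[str],
    background: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of a query list in each set.

    Shares its p-value computation with the comorbidity module's
    one-tailed Fisher test.  Empty queries give p = 1 for every set.
    """
    bg = list(dict.fromkeys(background))
    query = set(query_genes)
    if not query <= set(bg):
        raise ValueError("query genes must be a subset of the background")
    restricted = collection.restrict(bg)
    n_bg, n_query = len(bg), len(query)
    rows = []
    for name, members in restricted:
        k = len(query & set(members))
        p = 1.0 if n_query == 0 else fisher_one_tailed(k, len(members), n_query, n_bg)
        rows.append({"set_name": name, "set_size": len(members), "overlap": k, "p": p})
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q"] = bh_fdr(result["p"].to_numpy())
    return result


# ---------------------------------------------------------------------------
# connectivity-style drug analysis
# ---------------------------------------------------------------------------

def cosine_similarity(
    query: dict[str, float] | pd.Series, signature: dict[str, float] | pd.Series
) -> float:
    """Cosine similarity over the genes shared by query and signature."""
    q = pd.Series(query).dropna()
    s = pd.Series(signature).dropna()
    shared = q.index.intersection(s.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared genes")
    a = q.loc[shared].to_numpy(float)
    b = s.loc[shared].to_numpy(float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("zero-norm vector; cosine undefined", stacklevel=2)
        return float("nan")
    return float(a @ b / (na * nb))


def rank_drugs(
    query: dict[str, float] | pd.Series, signatures: pd.DataFrame
) -> RankedList:
    """Rank perturbations by cosine similarity with the query, descending.

    ``signatures`` is genes x drugs.  Positive cosine = the perturbation
    mimics the query profile; negative = it reverses it.  Ties break by
    drug id; drugs with undefined cosine (zero norm) are dropped with a
    warning.
    """
    if signatures.shape[1] < 1:
        raise ValueError("no signatures")
    q = pd.Series(query).dropna()
    shared = q.index.intersection(signatures.index)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared genes")
    a = q.loc[shared].to_numpy(float)
    mat = signatures.loc[shared].to_numpy(float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(mat, axis=0)
    if na == 0:
        raise ValueError("zero-norm query")
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (a @ mat) / (na * nb)
    ok = nb > 0
    if not ok.all():
        warnings.warn(f"dropping {(~ok).sum()} zero-norm signatures", stacklevel=2)
    return RankedList.from_scores(pd.Series(cos[ok], index=signatures.columns[ok]))


def drug_set_enrichment(
    ranked_drugs: RankedList,
    drug_sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """GSEA-style enrichment of drug sets along the cosine ranking.

    Significant sets (q < ``alpha``) at the top of the ranking (NES > 0)
    are labeled ``"mimics"``; at the bottom (NES < 0), ``"reverses"``.
    """
    result = gsea_preranked(
        ranked_drugs, drug_sets, n_perm=n_perm, seed=seed, weight=weight,
        min_size=min_size, max_size=max_size,
    )
    if result.empty:
        result["label"] = []
        return result
    sig = result["q"] < alpha
    result["label"] = ""
    result.loc[sig & (result["NES"] > 0), "label"] = "mimics"
    result.loc[sig & (result["NES"] < 0), "label"] = "reverses"
    return result


def write_enrichment_tsv(result: pd.DataFrame, path) -> None:
    """Serialize an enrichment table; leading edges are pipe-joined."""
    out = result.copy()
    if "leading_edge" in out.columns:
        out["leading_edge"] = out["leading_edge"].map(
            lambda le: "|".join(le) if isinstance(le, (list, tuple)) else le
        )
    out.to_csv(path, sep="\t", index=False)
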