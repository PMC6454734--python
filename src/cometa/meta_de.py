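"""Per-gene random-effects differential-expression meta-analysis.

For every gene, each study contributes a small-sample-corrected standardized
mean difference (Hedges g) with its sampling variance.  Between-study
variance tau^2 is estimated by the DerSimonian–Laird moment estimator, and
the per-study effects are combined by inverse-variance weighting with
weights 1/(var + tau^2), yielding the combined effect mu_hat, its standard
error, a z statistic, a two-sided normal p-value, and a Benjamini–Hochberg
FDR q-value across all tested genes.

Direction convention: positive mu_hat means upregulated in cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .studies import ExpressionStudy

#: Columns of a meta-analysis result table.
META_COLUMNS = ["k", "Q", "tau2", "mu_hat", "se", "z", "p", "q"]


def effect_size(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Small-sample-corrected standardized mean difference and its variance.

    d = J * (mean_case - mean_control) / s_pooled with the bias correction
    J = 1 - 3 / (4(n1+n2) - 9); var(d) = (n1+n2)/(n1*n2) + d^2/(2(n1+n2)).
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    n = n1 + n2
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    d = j * (case.mean() - control.mean()) / np.sqrt(sp2)
    var_d = n / (n1 * n2) + d * d / (2.0 * n)
    return float(d), float(var_d)


def dl_tau2(effects: np.ndarray, variances: np.ndarray) -> float:
    """DerSimonian–Laird moment estimate of between-study variance.

    With fixed-effect weights w = 1/var: Q = sum w (d - d_w)^2 and
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)).
    """
    effects = np.asarray(effects, dtype=float)
    variances = np.asarray(variances, dtype=float)
    k = len(effects)
    if k < 2:
        if k == 1:
            import warnings

            warnings.warn("tau2 undefined for a single study; returning 0", stacklevel=2)
            return 0.0
        raise ValueError("need >= 1 study")
    w = 1.0 / variances
    d_w = np.sum(w * effects) / np.sum(w)
    q = float(np.sum(w * (effects - d_w) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def combine(
    effects: np.ndarray, variances: np.ndarray, tau2: float
) -> tuple[float, float, float, float]:
    """Random-effects inverse-variance combination.

    Returns ``(mu_hat, se, z, p)`` with weights 1/(var + tau2) and a
    two-sided normal p-value.
    """
    effects = np.asarray(effects, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if len(effects) < 1:
        raise ValueError("need >= 1 study")
    if (variances <= 0).any():
        raise ValueError("variances must be > 0")
    w = 1.0 / (variances + tau2)
    mu = float(np.sum(w * effects) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = mu / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return mu, se, z, p


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MetaTable:
    """Meta-analysis summary for one disease.

    ``table`` holds one row per tested gene (columns :data:`META_COLUMNS`);
    ``untested_genes`` lists genes seen in fewer than ``min_studies``
    studies; ``per_study_d`` / ``per_study_var`` keep the study-level inputs
    (genes x studies, NaN where a study contributed nothing).
    """

    disease_id: str
    table: pd.DataFrame
    untested_genes: list[str] = field(default_factory=list)
    per_study_d: pd.DataFrame | None = None
    per_study_var: pd.DataFrame | None = None

    @property
    def n_genes_tested(self) -> int:
        return self.table.shape[0]

    @property
    def mu_hat(self) -> pd.Series:
        return self.table["mu_hat"]

    @property
    def z(self) -> pd.Series:
        return self.table["z"]

    def write(self, path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_meta_table(path, disease_id: str | None = None) -> MetaTable:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return MetaTable(disease_id or str(path), table)


def study_effect_sizes(study: ExpressionStudy) -> tuple[pd.Series, pd.Series]:
    """Vectorized per-gene Hedges g and sampling variance for one study.

    Genes with zero pooled variance get NaN (excluded from the
    meta-analysis for this study).
    """
    cases = study.values[study.case_ids].to_numpy(dtype=float)
    controls = study.values[study.control_ids].to_numpy(dtype=float)
    n1, n2 = cases.shape[1], controls.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"{study.study_id}: need >= 2 samples per group")
    sp2 = (
        (n1 - 1) * cases.var(axis=1, ddof=1) + (n2 - 1) * controls.var(axis=1, ddof=1)
    ) / (n1 + n2 - 2)
    n = n1 + n2
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = j * (cases.mean(axis=1) - controls.mean(axis=1)) / np.sqrt(sp2)
    d = np.where(sp2 > 0, d, np.nan)
    var_d = n / (n1 * n2) + d * d / (2.0 * n)
    idx = study.values.index
    return pd.Series(d, index=idx), pd.Series(var_d, index=idx)


def meta_analyze(
    studies: list[ExpressionStudy],
    min_studies: int | None = None,
    disease_id: str = "disease",
    fdr_method: str = "fdr_bh",
) -> MetaTable:
    """Random-effects meta-analysis of several studies of one disease.

    ``min_studies`` defaults to the number of input studies (complete-case
    genes only).  Genes whose pooled standard deviation is zero in a study
    are excluded from that study but may still be tested if they reach
    ``min_studies`` elsewhere.
    """
    if not studies:
        raise ValueError("no studies")
    if min_studies is None:
        min_studies = len(studies)
    genes = sorted(set().union(*(st.values.index for st in studies)))
    d_mat = pd.DataFrame(np.nan, index=genes, columns=[st.study_id for st in studies])
    v_mat = d_mat.copy()
    for st in studies:
        d, v = study_effect_sizes(st)
        d_mat.loc[d.index, st.study_id] = d
        v_mat.loc[v.index, st.study_id] = v

    d = d_mat.to_numpy()
    v = v_mat.to_numpy()
    valid = ~np.isnan(d)
    k = valid.sum(axis=1)
    tested = k >= min_studies
    if not tested.any():
        raise ValueError("no gene passes the min_studies filter")

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(valid, 1.0 / v, 0.0)
        sw = w.sum(axis=1)
        d0 = np.where(valid, d, 0.0)
        d_w = (w * d0).sum(axis=1) / sw
        q_stat = (w * (d0 - d_w[:, None]) ** 2 * valid).sum(axis=1)
        denom = sw - (w**2).sum(axis=1) / sw
        tau2 = np.where(
            (k >= 2) & (denom > 0), np.maximum(0.0, (q_stat - (k - 1)) / denom), 0.0
        )
        w_star = np.where(valid, 1.0 / (v + tau2[:, None]), 0.0)
        sws = w_star.sum(axis=1)
        mu = (w_star * d0).sum(axis=1) / sws
        se = sws**-0.5
        z = mu / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "k": k,
            "Q": q_stat,
            "tau2": tau2,
            "mu_hat": mu,
            "se": se,
            "z": z,
            "p": p,
        },
        index=pd.Index(genes, name="gene_id"),
    )[tested]
    table["q"] = bh_fdr(table["p"].to_numpy())
    untested = [g for g, t in zip(genes, tested) if not t]
    return MetaTable(disease_id, table, untested, d_mat, v_mat)
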