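"""Normalization, probe collapsing, outlier and redundancy filtering.

The stages here mirror how multi-study expression compendia are prepared
before effect-size meta-analysis: quantile between-sample normalization and
log2 transform for continuous platforms, a library-size-normalized log
transform for counts, max-variance probe collapsing to a gene namespace,
iterative removal of samples with low mean inter-array correlation, pooling
of external control samples under covariate balance constraints, a
location-scale batch adjustment, and removal of samples from patients
profiled by more than one study (keeping the highest-quality study's copy).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .studies import ExpressionStudy


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile between-sample normalization (genes x samples).

    After normalization every column's sorted values equal, exactly, the
    across-column mean of sorted values (the defining property, which also
    makes the operation idempotent).  Tied values within a column receive
    distinct adjacent reference values in stable row order, so the result
    is deterministic.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if matrix.isna().any().any():
        raise ValueError("missing values not supported")
    x = matrix.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        out[order, j] = reference
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log2(value + offset)``; rejects non-positive arguments."""
    x = matrix.to_numpy(dtype=float) + offset
    if (x <= 0).any():
        raise ValueError("log2_transform requires value + offset > 0")
    return pd.DataFrame(np.log2(x), index=matrix.index, columns=matrix.columns)


def stabilize_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Turn raw counts into a continuous log2 scale, normalized for library size.

    Size factors are median-of-ratios to the per-gene geometric mean (genes
    with any zero count are excluded from factor estimation but retained in
    the output); the output is ``log2(count / size_factor + 1)``.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if (x.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene with nonzero counts in every sample")
    logx = np.log(x[all_nonzero])
    log_geomean = logx.mean(axis=1)
    size_factors = np.exp(np.median(logx - log_geomean[:, None], axis=0))
    out = np.log2(x / size_factors[None, :] + 1.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe rows to genes, keeping the max-variance probe per gene.

    Probes absent from the mapping are dropped.  Variance ties are broken by
    the lexicographically smallest probe id so collapsing is deterministic.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = [p for p in matrix.index if p in probe_to_gene]
    sub = matrix.loc[mapped]
    variances = sub.var(axis=1, ddof=1)
    frame = pd.DataFrame(
        {"gene": [probe_to_gene[p] for p in mapped], "var": variances.to_numpy()},
        index=sub.index,
    )
    keep: list[str] = []
    for _gene, grp in frame.groupby("gene", sort=True):
        grp = grp.sort_index()  # lexicographic probe order for ties
        keep.append(grp["var"].idxmax())
    out = sub.loc[keep]
    out.index = [probe_to_gene[p] for p in keep]
    return out.sort_index()


# ---------------------------------------------------------------------------
# outlier and redundancy filtering
# ---------------------------------------------------------------------------

def _mean_intercorrelations(values: np.ndarray) -> np.ndarray:
    """Per-sample mean Pearson correlation with the other samples (columns)."""
    c = np.corrcoef(values, rowvar=False)
    n = c.shape[0]
    return (c.sum(axis=1) - 1.0) / (n - 1)


def detect_outliers(
    study: ExpressionStudy, threshold: float = 0.9
) -> tuple[ExpressionStudy, list[str]]:
    """Iteratively remove low-correlation samples, per group.

    Cases and controls are processed independently: while the group's mean
    pairwise Pearson correlation is below ``threshold``, the sample with the
    lowest mean correlation to the rest is removed and the correlations
    recomputed.  A group is never reduced below 2 samples.
    """
    removed: list[str] = []
    kept: dict[str, list[str]] = {}
    for group in ("case", "control"):
        ids = study.sample_ids(group)
        if len(ids) < 2:
            raise ValueError(f"need >= 2 {group} samples for outlier detection")
        while len(ids) > 2:
            means = _mean_intercorrelations(study.values[ids].to_numpy(dtype=float))
            if means.mean() >= threshold:
                break
            worst = int(np.argmin(means))
            removed.append(ids[worst])
            ids = ids[:worst] + ids[worst + 1 :]
        else:
            if len(ids) == 2:
                means = _mean_intercorrelations(study.values[ids].to_numpy(dtype=float))
                if means.mean() < threshold:
                    warnings.warn(
                        f"{study.study_id}/{group}: floor of 2 samples reached below "
                        f"correlation threshold {threshold}",
                        stacklevel=2,
                    )
        kept[group] = ids
    order = [s for s in study.sample_ids() if s not in set(removed)]
    return study.subset_samples(order), removed


def rank_study_quality(studies: list[ExpressionStudy]) -> list[str]:
    """Order study ids by decreasing mean inter-sample Pearson correlation.

    Ties break by lexicographic study id.
    """
    if not studies:
        raise ValueError("no studies")
    scores = {}
    for st in studies:
        means = _mean_intercorrelations(st.values.to_numpy(dtype=float))
        scores[st.study_id] = float(means.mean())
    return sorted(scores, key=lambda sid: (-scores[sid], sid))


def remove_redundant_samples(
    studies: list[ExpressionStudy], quality_order: list[str] | None = None
) -> list[ExpressionStudy]:
    """Drop samples whose patient already appears in a higher-quality study.

    The highest-quality study keeps all its samples; each study further down
    the quality order loses the samples of patients already seen above it.
    Output preserves the input list order.
    """
    if quality_order is None:
        quality_order = rank_study_quality(studies)
    by_id = {st.study_id: st for st in studies}
    seen: set[str] = set()
    trimmed: dict[str, ExpressionStudy] = {}
    for sid in quality_order:
        st = by_id[sid]
        keep = [s for s in st.sample_ids() if st.samples.loc[s, "patient_id"] not in seen]
        seen.update(st.samples.loc[keep, "patient_id"])
        trimmed[sid] = st.subset_samples(keep)
    return [trimmed[st.study_id] for st in studies]


# ---------------------------------------------------------------------------
# control augmentation and batch adjustment
# ---------------------------------------------------------------------------

def _balance_pvalues(samples: pd.DataFrame) -> dict[str, float]:
    """Two-sided case-vs-control balance tests on sex, age and PMI."""
    cases = samples[samples["group"] == "case"]
    ctrls = samples[samples["group"] == "control"]
    table = [
        [(cases["sex"] == "M").sum(), (cases["sex"] == "F").sum()],
        [(ctrls["sex"] == "M").sum(), (ctrls["sex"] == "F").sum()],
    ]
    p_sex = float(stats.fisher_exact(table)[1])
    out = {"sex": p_sex}
    for col in ("age", "pmi"):
        a, b = cases[col].to_numpy(float), ctrls[col].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            out[col] = 1.0
        else:
            out[col] = float(stats.ttest_ind(a, b, equal_var=False)[1])
    return out


def augment_controls(
    study: ExpressionStudy,
    control_pool: ExpressionStudy,
    n_add: int,
    seed: int = 0,
    max_attempts: int = 200,
    alpha: float = 0.05,
) -> ExpressionStudy:
    """Add ``n_add`` pool controls while keeping covariates balanced.

    Random draws from the pool are retried until the merged study shows no
    significant case/control difference in sex (Fisher exact), age or PMI
    (Welch t-test) at ``alpha``; if no balanced draw is found within
    ``max_attempts`` the best-balanced draw is used and a warning emitted.
    The merged matrix is re-quantile-normalized and batch-adjusted with
    sample origin as batch.
    """
    if n_add == 0:
        return study
    if not (control_pool.samples["group"] == "control").all():
        raise ValueError("control pool contains non-control samples")
    pool_ids = control_pool.sample_ids()
    if n_add > len(pool_ids):
        raise ValueError("control pool smaller than n_add")
    rng = np.random.default_rng(seed)
    best: tuple[float, list[str]] | None = None
    chosen: list[str] | None = None
    for _ in range(max_attempts):
        draw = list(rng.choice(pool_ids, size=n_add, replace=False))
        meta = pd.concat(
            [study.samples, control_pool.samples.loc[draw]]
        )
        ps = _balance_pvalues(meta)
        score = min(ps.values())
        if best is None or score > best[0]:
            best = (score, draw)
        if all(p > alpha for p in ps.values()):
            chosen = draw
            break
    if chosen is None:
        assert best is not None
        warnings.warn(
            "augment_controls: no covariate-balanced draw found within "
            f"{max_attempts} attempts (best min p = {best[0]:.3g}); using best draw",
            stacklevel=2,
        )
        chosen = best[1]

    shared = study.values.index.intersection(control_pool.values.index)
    merged_values = pd.concat(
        [study.values.loc[shared], control_pool.values.loc[shared, chosen]], axis=1
    )
    merged_meta = pd.concat([study.samples, control_pool.samples.loc[chosen]]).copy()
    merged_meta["batch"] = [study.study_id] * study.values.shape[1] + [
        control_pool.study_id
    ] * len(chosen)
    normalized = quantile_normalize(merged_values)
    adjusted = batch_adjust(normalized, merged_meta["batch"].tolist())
    return ExpressionStudy(study.study_id, adjusted, merged_meta, study.platform)


def batch_adjust(matrix: pd.DataFrame, batches: list[str]) -> pd.DataFrame:
    """Location-scale batch adjustment per gene.

    Every batch is centered and scaled, gene by gene, to the gene's pooled
    mean and pooled standard deviation.  A batch with zero variance for a
    gene is only re-centered.  With a single batch the matrix is returned
    unchanged.
    """
    batches = list(batches)
    if len(batches) != matrix.shape[1]:
        raise ValueError("one batch label per sample required")
    labels = pd.unique(pd.Series(batches))
    if len(labels) < 2:
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    pooled_mean = x.mean(axis=1)
    pooled_sd = x.std(axis=1, ddof=1)
    out = x.copy()
    barr = np.asarray(batches)
    for b in labels:
        cols = np.flatnonzero(barr == b)
        if cols.size < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        sub = x[:, cols]
        bmean = sub.mean(axis=1)
        bsd = sub.std(axis=1, ddof=1)
        scale = np.where((bsd > 0) & (pooled_sd > 0), pooled_sd / np.where(bsd > 0, bsd, 1.0), 1.0)
        out[:, cols] = (sub - bmean[:, None]) * scale[:, None] + pooled_mean[:, None]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# study-level convenience pipeline
# ---------------------------------------------------------------------------

def preprocess_study(
    study: ExpressionStudy, outlier_threshold: float = 0.9
) -> tuple[ExpressionStudy, list[str]]:
    """Platform-appropriate normalization followed by outlier removal.

    Counts are stabilized to a library-size-normalized log2 scale; continuous
    values are quantile-normalized.  Outlier detection runs on the normalized
    values.
    """
    if study.platform == "counts":
        values = stabilize_counts(study.values)
    else:
        values = quantile_normalize(study.values)
    normalized = replace(study, values=values, platform="continuous")
    return detect_outliers(normalized, threshold=outlier_threshold)
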