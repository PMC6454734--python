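"""Seeded generators for multi-study expression data with planted truth.

These generators emulate the statistical structure of public case-control
expression compendia: several small studies per disease, a fraction of genes
with a planted standardized effect, between-study heterogeneity of those
effects, per-study batch offsets, occasional grossly noisy (outlier) samples,
patients whose tissue was profiled by more than one study, and two platform
families (continuous log2-scale intensities and Poisson counts).  Every
downstream stage of the pipeline can therefore be tested against known truth
without downloading anything.

Effect sizes are in standardized units: the within-group noise standard
deviation is 1 on the latent scale, so a planted effect of 1.0 is a
one-standard-deviation mean shift in cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection
from .studies import METADATA_COLUMNS, ExpressionStudy

# Latent-scale constants shared by both platforms.  The gene baseline spread
# (sd 4 on log2 scale) against unit within-group noise puts the inter-sample
# Pearson correlation of well-behaved samples near 16/17 ~ 0.94, comfortably
# above the 0.9 outlier threshold; outlier samples get noise sd 8, dropping
# their correlation with the rest of the group to ~0.2.
BASELINE_MEAN = 8.0
BASELINE_SD = 4.0
NOISE_SD = 1.0
OUTLIER_NOISE_SD = 8.0
SHARED_PATIENT_NOISE_SD = 0.1

# Counts platform: latent log2 means are compressed so Poisson rates stay in a
# realistic range (roughly 1..1e5 counts per gene).
COUNTS_BASELINE_MEAN = 6.0
COUNTS_BASELINE_SD = 2.0


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic disease.

    Defaults are the study conditions used throughout the test-suite:
    4 studies of 20 cases / 20 controls over 2000 genes, 10% of genes
    differentially expressed with mean |effect| ~1.0 and
    between-study effect sd (tau) 0.2; effect magnitudes are |N(1.0, 0.6)|,
    a right-skewed spread (many weak effects, a few strong ones).
    """

    n_genes: int = 2000
    n_studies: int = 4
    n_cases_per_study: int = 20
    n_controls_per_study: int = 20
    frac_de: float = 0.10
    effect_mean: float = 1.0
    effect_sd: float = 0.6
    tau: float = 0.2
    batch_sd: float = 0.3
    frac_outliers: float = 0.0
    frac_shared_patients: float = 0.0
    platform: str = "continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_studies", "n_cases_per_study", "n_controls_per_study"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_de", "frac_outliers", "frac_shared_patients"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_sd < 0 or self.tau < 0 or self.batch_sd < 0:
            raise ValueError("effect_sd, tau and batch_sd must be >= 0")
        if self.platform not in ("continuous", "counts"):
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator call."""

    de_genes: dict[str, int]  # gene -> +1 / -1
    true_effects: dict[str, float]  # gene -> signed standardized effect
    outlier_samples: list[str]
    shared_patients: dict[tuple[str, str], list[str]]  # (study_a, study_b) -> patients
    flags: list[str] = field(default_factory=list)


def gene_universe(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def _draw_effects(
    rng: np.random.Generator,
    genes: list[str],
    config: SyntheticConfig,
    forced_de: dict[str, int] | None,
) -> tuple[dict[str, int], dict[str, float], list[str]]:
    """Choose DE genes and their signed effects, honoring forced signs."""
    flags: list[str] = []
    n_de = int(round(config.n_genes * config.frac_de))
    if n_de < 1:
        if config.frac_de > 0:
            flags.append("no_de_genes: n_genes * frac_de < 1")
        n_de = 0
    forced_de = dict(forced_de or {})
    unknown = set(forced_de) - set(genes)
    if unknown:
        raise ValueError(f"forced DE genes outside universe: {sorted(unknown)[:5]}")
    n_free = max(0, n_de - len(forced_de))
    free_pool = [g for g in genes if g not in forced_de]
    free = list(rng.choice(free_pool, size=n_free, replace=False)) if n_free else []
    de_genes = dict(forced_de)
    for g in free:
        de_genes[g] = int(rng.choice([-1, 1]))
    magnitudes = np.abs(rng.normal(config.effect_mean, config.effect_sd, size=len(de_genes)))
    true_effects = {
        g: sign * mag for (g, sign), mag in zip(de_genes.items(), magnitudes)
    }
    return de_genes, true_effects, flags


def generate_disease(
    config: SyntheticConfig,
    disease_id: str = "disease",
    forced_de: dict[str, int] | None = None,
) -> tuple[list[ExpressionStudy], PlantedTruth]:
    """Generate one disease: a list of case-control studies plus its truth.

    Per study ``s`` and DE gene ``g`` the case mean is shifted by
    ``theta_gs = theta_g + eta_gs`` with ``eta_gs ~ N(0, tau^2)`` — the
    random-effects structure that the meta-analysis stage is built to
    estimate.  ``forced_de`` pins the sign of selected genes (used to build
    related disease pairs); remaining DE genes are drawn at random.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config.n_genes)
    de_genes, true_effects, flags = _draw_effects(rng, genes, config, forced_de)

    counts_platform = config.platform == "counts"
    base_mean = COUNTS_BASELINE_MEAN if counts_platform else BASELINE_MEAN
    base_sd = COUNTS_BASELINE_SD if counts_platform else BASELINE_SD
    baseline = rng.normal(base_mean, base_sd, size=config.n_genes)

    theta = np.zeros(config.n_genes)
    de_idx = np.array([genes.index(g) for g in de_genes], dtype=int)
    if de_idx.size:
        theta[de_idx] = [true_effects[g] for g in de_genes]
    de_mask = np.zeros(config.n_genes, dtype=bool)
    de_mask[de_idx] = True

    studies: list[ExpressionStudy] = []
    outlier_samples: list[str] = []
    shared_patients: dict[tuple[str, str], list[str]] = {}
    patient_counter = 0
    # latent case profiles of the previous study, for patient sharing
    prev_case_latent: np.ndarray | None = None
    prev_case_patients: list[str] = []

    for s in range(config.n_studies):
        study_id = f"{disease_id}_s{s}"
        nc, nk = config.n_cases_per_study, config.n_controls_per_study

        eta = np.zeros(config.n_genes)
        if config.tau > 0 and de_idx.size:
            eta[de_idx] = rng.normal(0.0, config.tau, size=de_idx.size)
        theta_s = theta + eta * de_mask
        batch = rng.normal(0.0, config.batch_sd, size=config.n_genes)

        # latent profile = baseline + shift (+ per-sample noise); batch offset
        # added afterwards so shared patients can carry their latent profile
        # into another study's batch.
        case_latent = (
            baseline[:, None]
            + theta_s[:, None] * NOISE_SD
            + rng.normal(0.0, NOISE_SD, size=(config.n_genes, nc))
        )
        ctrl_latent = baseline[:, None] + rng.normal(0.0, NOISE_SD, size=(config.n_genes, nk))

        case_patients = [f"{disease_id}_p{patient_counter + i}" for i in range(nc)]
        patient_counter += nc
        ctrl_patients = [f"{disease_id}_p{patient_counter + i}" for i in range(nk)]
        patient_counter += nk

        # patient sharing: the first k cases of this study re-profile patients
        # from the previous study (same latent expression, small extra noise)
        if s > 0 and config.frac_shared_patients > 0 and prev_case_latent is not None:
            k = int(round(config.frac_shared_patients * nc))
            k = min(k, prev_case_latent.shape[1], nc)
            if k:
                dup = prev_case_latent[:, :k] + rng.normal(
                    0.0, SHARED_PATIENT_NOISE_SD, size=(config.n_genes, k)
                )
                case_latent[:, :k] = dup
                case_patients[:k] = prev_case_patients[:k]
                prev_id = f"{disease_id}_s{s - 1}"
                shared_patients[(prev_id, study_id)] = list(prev_case_patients[:k])

        prev_case_latent = case_latent.copy()
        prev_case_patients = list(case_patients)

        latent = np.concatenate([case_latent, ctrl_latent], axis=1) + batch[:, None]
        sample_ids = [f"{study_id}_case{i}" for i in range(nc)] + [
            f"{study_id}_ctrl{i}" for i in range(nk)
        ]
        groups = ["case"] * nc + ["control"] * nk

        # planted outliers: per group, replace the last samples' noise with
        # grossly inflated independent noise
        n_out_case = int(round(config.frac_outliers * nc))
        n_out_ctrl = int(round(config.frac_outliers * nk))
        out_cols: list[int] = []
        out_cols += list(range(nc - n_out_case, nc))
        out_cols += list(range(nc + nk - n_out_ctrl, nc + nk))
        for j in out_cols:
            mean = baseline + batch + (theta_s * NOISE_SD if groups[j] == "case" else 0.0)
            latent[:, j] = mean + rng.normal(0.0, OUTLIER_NOISE_SD, size=config.n_genes)
            outlier_samples.append(sample_ids[j])

        if counts_platform:
            values = rng.poisson(np.exp2(latent)).astype(np.int64)
        else:
            values = latent

        meta = pd.DataFrame(
            {
                "patient_id": case_patients + ctrl_patients,
                "group": groups,
                "age": np.round(np.clip(rng.normal(30.0, 10.0, nc + nk), 2.0, 90.0), 1),
                "sex": rng.choice(["M", "F"], size=nc + nk),
                "pmi": np.round(np.clip(rng.normal(15.0, 5.0, nc + nk), 1.0, 60.0), 1),
                "batch": study_id,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )[METADATA_COLUMNS]
        studies.append(
            ExpressionStudy(
                study_id,
                pd.DataFrame(values, index=genes, columns=sample_ids),
                meta,
                config.platform,
            )
        )

    truth = PlantedTruth(de_genes, true_effects, outlier_samples, shared_patients, flags)
    return studies, truth


def generate_related_disease(
    truth_a: PlantedTruth,
    config_b: SyntheticConfig,
    frac_same_direction: float,
    frac_opposite_direction: float,
    seed: int,
    disease_id: str = "diseaseB",
) -> tuple[list[ExpressionStudy], PlantedTruth]:
    """Generate a disease sharing planted DE genes with an existing truth.

    ``frac_same_direction`` / ``frac_opposite_direction`` of the reference
    disease's DE genes are planted in the new disease with equal / flipped
    signs; the remainder of the new disease's DE genes are drawn
    independently.
    """
    if frac_same_direction < 0 or frac_opposite_direction < 0:
        raise ValueError("shared-direction fractions must be >= 0")
    if frac_same_direction + frac_opposite_direction > 1 + 1e-12:
        raise ValueError("frac_same_direction + frac_opposite_direction must be <= 1")
    rng = np.random.default_rng(seed)
    a_genes = sorted(truth_a.de_genes)
    n_same = int(round(frac_same_direction * len(a_genes)))
    n_opp = int(round(frac_opposite_direction * len(a_genes)))
    n_opp = min(n_opp, len(a_genes) - n_same)
    picked = list(rng.choice(a_genes, size=n_same + n_opp, replace=False)) if a_genes else []
    forced = {g: truth_a.de_genes[g] for g in picked[:n_same]}
    forced.update({g: -truth_a.de_genes[g] for g in picked[n_same:]})
    cfg = replace(config_b, seed=int(rng.integers(2**31)))
    return generate_disease(cfg, disease_id=disease_id, forced_de=forced)


def generate_disease_pair(
    config_a: SyntheticConfig,
    config_b: SyntheticConfig,
    frac_same_direction: float,
    frac_opposite_direction: float,
    seed: int,
) -> tuple[list[ExpressionStudy], list[ExpressionStudy], PlantedTruth, PlantedTruth]:
    """Generate two diseases with a controlled fraction of shared DE genes."""
    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(x) for x in rng.integers(2**31, size=2))
    studies_a, truth_a = generate_disease(replace(config_a, seed=seed_a), disease_id="diseaseA")
    studies_b, truth_b = generate_related_disease(
        truth_a, config_b, frac_same_direction, frac_opposite_direction, seed_b
    )
    return studies_a, studies_b, truth_a, truth_b


def generate_gene_sets(
    gene_universe: list[str],
    n_sets: int,
    set_size: int,
    planted_set: list[str] | None = None,
    seed: int = 0,
    planted_name: str = "planted_set",
) -> GeneSetCollection:
    """Random gene sets over a universe, optionally plus one planted set."""
    if set_size > len(gene_universe):
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        sets[f"random_set_{i:03d}"] = list(
            rng.choice(gene_universe, size=set_size, replace=False)
        )
    if planted_set:
        outside = set(planted_set) - set(gene_universe)
        if outside:
            raise ValueError("planted_set contains genes outside the universe")
        sets[planted_name] = list(planted_set)
    return GeneSetCollection(sets, list(gene_universe))


def generate_perturbation_library(
    gene_universe: list[str],
    n_drugs: int,
    n_drug_sets: int,
    set_size: int,
    planted_mimickers: int,
    planted_reversers: int,
    disease_z: dict[str, float] | pd.Series,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Genes x drugs signature matrix plus drug-set collection.

    Mimicker drugs get signatures positively proportional to the disease
    z-vector (unit-normalized, scaled to per-gene variance 1) plus Gaussian
    noise of sd ``noise_sd``; reversers are negatively proportional; the
    remaining drugs are independent noise.  The planted drugs form the drug
    sets ``"mimicker_set"`` and ``"reverser_set"``; ``n_drug_sets`` additional
    random sets of ``set_size`` drugs are drawn from the unplanted drugs.
    """
    if not gene_universe:
        raise ValueError("empty gene universe")
    if planted_mimickers + planted_reversers > n_drugs:
        raise ValueError("more planted drugs than n_drugs")
    rng = np.random.default_rng(seed)
    z = pd.Series(disease_z).reindex(gene_universe)
    if z.isna().any():
        raise ValueError("disease_z missing genes of the universe")
    zv = z.to_numpy(dtype=float)
    norm = np.linalg.norm(zv)
    if norm == 0:
        raise ValueError("disease_z has zero norm")
    signal = zv / norm * math.sqrt(len(zv))  # unit per-gene variance scale

    n_genes = len(gene_universe)
    drug_ids = [f"drug_{i:04d}" for i in range(n_drugs)]
    mim = drug_ids[:planted_mimickers]
    rev = drug_ids[planted_mimickers : planted_mimickers + planted_reversers]
    other = drug_ids[planted_mimickers + planted_reversers :]

    sig = rng.normal(0.0, 1.0, size=(n_genes, n_drugs))
    for j, d in enumerate(drug_ids):
        if d in mim:
            sig[:, j] = signal + noise_sd * rng.normal(0.0, 1.0, size=n_genes)
        elif d in rev:
            sig[:, j] = -signal + noise_sd * rng.normal(0.0, 1.0, size=n_genes)
    matrix = pd.DataFrame(sig, index=gene_universe, columns=drug_ids)

    sets: dict[str, list[str]] = {}
    if mim:
        sets["mimicker_set"] = mim
    if rev:
        sets["reverser_set"] = rev
    pool = other if other else drug_ids
    size = min(set_size, len(pool))
    for i in range(n_drug_sets):
        sets[f"random_drug_set_{i:03d}"] = list(rng.choice(pool, size=size, replace=False))
    return matrix, GeneSetCollection(sets, drug_ids)
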