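"""End-to-end orchestration: simulate -> preprocess -> meta -> compare ->
enrich -> drugs -> cluster, from a single seeded configuration.

Every stage writes plain TSV/GMT artifacts into its own subdirectory so any
stage can be inspected, or rerun independently through the CLI, and a run
manifest (JSON) records parameters, derived seeds and SHA-256 checksums of
all outputs.  Reruns with the same configuration produce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clustering, comorbidity, enrichment, meta_de, preprocess
from .genesets import GeneSetCollection
from .synthetic_data import (
    SyntheticConfig,
    generate_disease,
    generate_gene_sets,
    generate_perturbation_library,
    generate_related_disease,
)

log = logging.getLogger("cometa.pipeline")


@dataclass
class ComparatorSpec:
    name: str
    frac_same: float = 0.0
    frac_opposite: float = 0.0
    config: dict[str, Any] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (one index disease + comparators)."""

    seed: int = 0
    index_name: str = "index_disease"
    index_config: dict[str, Any] = field(default_factory=dict)
    comparators: list[ComparatorSpec] = field(
        default_factory=lambda: [
            ComparatorSpec("same_dir_disease", frac_same=0.5),
            ComparatorSpec("opposite_dir_disease", frac_opposite=0.5),
            ComparatorSpec("independent_disease"),
        ]
    )
    outlier_threshold: float = 0.9
    min_studies: int | None = None
    fdr_threshold: float = 0.05
    compare_alpha: float = 0.05
    compare_scope: str = "batch"
    n_gene_sets: int = 50
    gene_set_size: int = 40
    gsea_n_perm: int = 500
    n_drugs: int = 200
    n_drug_sets: int = 20
    drug_set_size: int = 10
    n_mimickers: int = 10
    n_reversers: int = 10
    drug_n_perm: int = 500
    cluster_k_range: list[int] = field(default_factory=lambda: [2, 3])
    cluster_metric: str = "correlation"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        comps = [ComparatorSpec(**c) for c in raw.pop("comparators", [])]
        cfg = cls(**raw)
        if comps:
            cfg.comparators = comps
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _prepare_disease(
    name: str,
    studies,
    truth,
    outdir: Path,
    cfg: RunConfig,
) -> meta_de.MetaTable:
    """Preprocess (normalize, outlier-filter, de-duplicate) and meta-analyze."""
    sdir = outdir / "studies" / name
    for st in studies:
        st.write(sdir)
    cleaned = []
    for st in studies:
        kept, removed = preprocess.preprocess_study(st, cfg.outlier_threshold)
        if removed:
            log.info("stage=preprocess disease=%s study=%s removed=%s", name, st.study_id, removed)
        cleaned.append(kept)
    cleaned = preprocess.remove_redundant_samples(cleaned)
    meta = meta_de.meta_analyze(cleaned, min_studies=cfg.min_studies, disease_id=name)
    (outdir / "meta").mkdir(parents=True, exist_ok=True)
    meta.write(outdir / "meta" / f"{name}.meta.tsv")
    log.info("stage=meta disease=%s genes_tested=%d", name, meta.n_genes_tested)
    return meta


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the whole pipeline; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    seeds = {
        "index": int(master.integers(2**31)),
        "comparators": [int(master.integers(2**31)) for _ in config.comparators],
        "gene_sets": int(master.integers(2**31)),
        "gsea": int(master.integers(2**31)),
        "drug_library": int(master.integers(2**31)),
        "drug_gsea": int(master.integers(2**31)),
    }

    # -- simulate + preprocess + meta per disease ---------------------------
    index_cfg = SyntheticConfig(**{**config.index_config, "seed": seeds["index"]})
    index_studies, index_truth = generate_disease(index_cfg, disease_id=config.index_name)
    metas: dict[str, meta_de.MetaTable] = {}
    metas[config.index_name] = _prepare_disease(
        config.index_name, index_studies, index_truth, outdir, config
    )
    for comp, cseed in zip(config.comparators, seeds["comparators"]):
        ccfg = SyntheticConfig(**comp.config) if comp.config else SyntheticConfig()
        studies, truth = generate_related_disease(
            index_truth, ccfg, comp.frac_same, comp.frac_opposite, cseed, disease_id=comp.name
        )
        metas[comp.name] = _prepare_disease(comp.name, studies, truth, outdir, config)

    # -- compare ------------------------------------------------------------
    profiles = {
        n: comorbidity.classify_genes(m, config.fdr_threshold) for n, m in metas.items()
    }
    index_profile = profiles[config.index_name]
    inter = [
        comorbidity.intersection_test(index_profile, profiles[c.name])
        for c in config.comparators
    ]
    inter = comorbidity.adjust_and_label(inter, config.compare_alpha, config.compare_scope)
    cors = [
        comorbidity.profile_correlation(index_profile, profiles[c.name])
        for c in config.comparators
    ]
    cdir = outdir / "compare"
    cdir.mkdir(parents=True, exist_ok=True)
    comorbidity.results_table(inter, cors).to_csv(cdir / "intersections.tsv", sep="\t", index=False)
    for r in inter:
        GeneSetCollection(
            {f"intersection_{i}": r.genes[i] for i in comorbidity.INTERSECTIONS}
        ).write_gmt(cdir / f"{r.pair[0]}_vs_{r.pair[1]}.genes.gmt")
    overall = comorbidity.overall_profile([metas[c.name] for c in config.comparators])
    overall.rename("mu_hat_mean").rename_axis("gene_id").to_csv(
        cdir / "overall_comparator_profile.tsv", sep="\t"
    )
    for r in inter:
        log.info("stage=compare pair=%s label=%s", "/".join(r.pair), r.label)

    # -- gene-set enrichment -------------------------------------------------
    index_meta = metas[config.index_name]
    universe = list(index_meta.table.index)
    planted_up = sorted(
        g for g, s in index_truth.de_genes.items() if s > 0 and g in set(universe)
    )
    gene_sets = generate_gene_sets(
        universe, config.n_gene_sets, config.gene_set_size,
        planted_set=planted_up, seed=seeds["gene_sets"],
    )
    edir = outdir / "enrichment"
    edir.mkdir(parents=True, exist_ok=True)
    gene_sets.write_gmt(edir / "gene_sets.gmt")
    ranked = enrichment.RankedList.from_scores(index_meta.z)
    gsea = enrichment.gsea_preranked(
        ranked, gene_sets, n_perm=config.gsea_n_perm, seed=seeds["gsea"]
    )
    enrichment.write_enrichment_tsv(gsea, edir / "gsea.tsv")
    de_genes = list(index_profile.status.index[index_profile.status != 0])
    ora = enrichment.ora(de_genes, universe, gene_sets)
    ora.to_csv(edir / "ora.tsv", sep="\t", index=False)
    log.info("stage=enrich sets=%d", len(gsea))

    # -- drug analysis -------------------------------------------------------
    signatures, drug_sets = generate_perturbation_library(
        universe, config.n_drugs, config.n_drug_sets, config.drug_set_size,
        config.n_mimickers, config.n_reversers, index_meta.z,
        seed=seeds["drug_library"],
    )
    ddir = outdir / "drugs"
    ddir.mkdir(parents=True, exist_ok=True)
    signatures.rename_axis("gene_id").to_csv(ddir / "signatures.tsv", sep="\t")
    drug_sets.write_gmt(ddir / "drug_sets.gmt")
    ranked_drugs = enrichment.rank_drugs(index_meta.z, signatures)
    pd.DataFrame({"drug": ranked_drugs.items, "cosine": ranked_drugs.scores}).to_csv(
        ddir / "drug_ranking.tsv", sep="\t", index=False
    )
    dse = enrichment.drug_set_enrichment(
        ranked_drugs, drug_sets, n_perm=config.drug_n_perm, seed=seeds["drug_gsea"],
        min_size=min(5, config.n_mimickers or 5),
    )
    enrichment.write_enrichment_tsv(dse, ddir / "drug_enrichment.tsv")
    log.info("stage=drugs sets=%d", len(dse))

    # -- clustering ----------------------------------------------------------
    mu = pd.concat({n: m.mu_hat for n, m in metas.items()}, axis=1)
    dist = clustering.profile_distance_matrix(mu, config.cluster_metric)
    kdir = outdir / "cluster"
    kdir.mkdir(parents=True, exist_ok=True)
    dist.to_csv(kdir / "distances.tsv", sep="\t")
    ks = [k for k in config.cluster_k_range if 2 <= k < mu.shape[1]]
    best_k, results = clustering.select_k(dist, ks)
    pd.DataFrame(
        [
            {"k": k, "avg_silhouette": r.avg_silhouette, "medoids": "|".join(r.medoids)}
            for k, r in results.items()
        ]
    ).to_csv(kdir / "silhouette.tsv", sep="\t", index=False)
    assign = results[best_k].assignment
    pd.Series(assign, name="medoid").rename_axis("disease").to_csv(
        kdir / "assignments.tsv", sep="\t"
    )
    status = pd.concat({n: profiles[n].status for n in metas}, axis=1).fillna(0).astype(int)
    hres = clustering.hclust_discrete(status, metric="hamming")
    (kdir / "dendrogram.nwk").write_text(hres.newick() + "\n")
    log.info("stage=cluster best_k=%d", best_k)

    # -- manifest ------------------------------------------------------------
    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": config.to_dict(),
        "seeds": seeds,
        "best_k": int(best_k),
        "labels": {"/".join(r.pair): r.label for r in inter},
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
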