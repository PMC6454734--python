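"""Case-control expression study container and its on-disk TSV representation.

A study is a genes x samples expression matrix plus per-sample metadata
(patient, group, age, sex, post-mortem interval, batch) and a platform tag
telling downstream code whether the values are raw counts (RNA-seq style)
or continuous intensities (microarray style, log2 scale after transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

#: Columns required in the sample-metadata table, in canonical order.
METADATA_COLUMNS = ["patient_id", "group", "age", "sex", "pmi", "batch"]

VALID_GROUPS = {"case", "control"}
VALID_PLATFORMS = {"continuous", "counts"}


@dataclass
class ExpressionStudy:
    """One case-control dataset.

    Parameters
    ----------
    study_id
        Name of the study (unique within a disease).
    values
        Expression matrix, genes in rows (index = gene ids), samples in
        columns (column names = sample ids).
    samples
        Sample metadata indexed by sample id with columns
        ``patient_id, group, age, sex, pmi, batch``.
    platform
        ``"continuous"`` or ``"counts"``.
    """

    study_id: str
    values: pd.DataFrame
    samples: pd.DataFrame
    platform: str = "continuous"

    def __post_init__(self) -> None:
        if self.platform not in VALID_PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("expression columns and metadata rows disagree")
        bad = set(self.samples["group"]) - VALID_GROUPS
        if bad:
            raise ValueError(f"invalid group labels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_ids(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["group"] == group])

    @property
    def case_ids(self) -> list[str]:
        return self.sample_ids("case")

    @property
    def control_ids(self) -> list[str]:
        return self.sample_ids("control")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionStudy":
        """Return a copy restricted to ``sample_ids`` (order preserved)."""
        return replace(
            self,
            values=self.values[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionStudy":
        return replace(self, values=values)

    # -- TSV round trip --------------------------------------------------------

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        """Write ``<study_id>.matrix.tsv`` and ``<study_id>.metadata.tsv``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mpath = outdir / f"{self.study_id}.matrix.tsv"
        spath = outdir / f"{self.study_id}.metadata.tsv"
        self.values.rename_axis("gene_id").to_csv(mpath, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(spath, sep="\t")
        return mpath, spath


def read_study(
    matrix_path: str | Path,
    metadata_path: str | Path,
    study_id: str | None = None,
    platform: str = "continuous",
) -> ExpressionStudy:
    """Load an :class:`ExpressionStudy` from its matrix + metadata TSV pair."""
    matrix_path = Path(matrix_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [c for c in METADATA_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    if study_id is None:
        study_id = matrix_path.name.removesuffix(".matrix.tsv")
    return ExpressionStudy(study_id, values, samples[METADATA_COLUMNS], platform)
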