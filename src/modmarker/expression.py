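"""Expression-level eligibility filter for targeted-assay candidates.

Genes destined for a targeted RT-PCR-style panel must be abundant enough to
measure reliably.  A gene is eligible in a dataset when its median normalized
count across all samples is at least ``median_min`` (default 50) AND it
exceeds the detection level (default 15 counts, strictly greater) in at least
``detection_fraction_min`` percent of samples (default 50%).  Genes failing
either criterion are flagged as potentially challenging to measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from modmarker.errors import GeneLookupError, SchemaError, ValidationError


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples matrix of non-negative normalized counts.

    ``annotations`` is indexed by sample id and carries a ``cohort`` label
    (condition / time point / disease group) and an optional ``cell_type``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    dataset_id: str

    def __post_init__(self) -> None:
        df = self.values
        upper = df.index.astype(str).str.upper()
        if upper.duplicated().any():
            dups = sorted(upper[upper.duplicated()].unique())
            raise ValidationError(f"duplicate gene symbols: {dups}")
        df = df.set_axis(upper, axis=0)
        df.index.name = "gene"
        arr = df.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError(
                f"dataset {self.dataset_id} contains missing expression values"
            )
        if (arr < 0).any():
            raise ValidationError(f"dataset {self.dataset_id} contains negative values")
        ann = self.annotations
        if "cohort" not in ann.columns:
            raise SchemaError("sample annotations need a 'cohort' column")
        missing = [s for s in df.columns if s not in ann.index]
        if missing:
            raise ValidationError(f"samples without annotation: {missing[:10]}")
        if "cell_type" not in ann.columns:
            ann = ann.assign(cell_type="")
        object.__setattr__(self, "values", df.astype(float))
        object.__setattr__(self, "annotations", ann.loc[df.columns])

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def cohorts(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.annotations["cohort"]:
            seen.setdefault(str(c))
        return tuple(seen)

    def gene_values(self, gene: str) -> pd.Series:
        gene = gene.upper()
        if gene not in self.values.index:
            raise GeneLookupError(
                f"gene {gene} not found in dataset {self.dataset_id}"
            )
        return self.values.loc[gene]

    def subset(
        self, cohort: str | None = None, cell_type: str | None = None
    ) -> "ExpressionDataset":
        """Restrict to samples matching the given cohort and/or cell type."""
        keep = pd.Series(True, index=self.annotations.index)
        if cohort is not None:
            keep &= self.annotations["cohort"].astype(str) == cohort
        if cell_type is not None:
            keep &= self.annotations["cell_type"].astype(str) == cell_type
        samples = list(self.annotations.index[keep])
        if not samples:
            raise ValidationError(
                f"no samples match cohort={cohort!r}, cell_type={cell_type!r}"
            )
        return ExpressionDataset(
            values=self.values[samples],
            annotations=self.annotations.loc[samples],
            dataset_id=self.dataset_id,
        )


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    matrix_path: str | Path,
    annotations_path: str | Path,
    dataset_id: str,
) -> ExpressionDataset:
    """Load a TSV/CSV expression matrix (first column = gene) + annotations."""
    matrix_path, annotations_path = Path(matrix_path), Path(annotations_path)
    values = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    ann = pd.read_csv(annotations_path, sep=_sep_for(annotations_path))
    if "sample_id" not in ann.columns:
        raise SchemaError(f"{annotations_path}: missing 'sample_id' column")
    ann = ann.set_index("sample_id")
    return ExpressionDataset(values=values, annotations=ann, dataset_id=dataset_id)


class EligibilityThresholds(BaseModel):
    """Thresholds of the expression-eligibility filter."""

    median_min: float = Field(default=50.0, gt=0)
    detection_level: float = Field(default=15.0, gt=0)
    detection_fraction_min: float = Field(default=50.0, gt=0, le=100)


@dataclass(frozen=True)
class EligibilityRecord:
    gene: str
    dataset_id: str
    median_expression: float
    pct_samples_above_level: float
    meets_criteria: bool


def median_expression(ds: ExpressionDataset, gene: str) -> float:
    """Median of a gene's values across all samples (even n: mean of the
    two central order statistics)."""
    return float(ds.gene_values(gene).median())


def detection_fraction(ds: ExpressionDataset, gene: str, level: float) -> float:
    """Percentage of samples with expression strictly greater than ``level``."""
    v = ds.gene_values(gene)
    return float(100.0 * (v > level).sum() / len(v))


def decide_eligibility(
    median: float, pct_above_level: float, thresholds: EligibilityThresholds
) -> bool:
    """The eligibility conjunction: median >= median_min AND the detection
    percentage >= detection_fraction_min."""
    return bool(
        median >= thresholds.median_min
        and pct_above_level >= thresholds.detection_fraction_min
    )


def flag_low_expression(
    ds: ExpressionDataset,
    genes: Sequence[str],
    thresholds: EligibilityThresholds | None = None,
) -> list[EligibilityRecord]:
    """Summarize each candidate gene's measurability in ``ds``.

    Output order follows the input gene order; a missing gene raises a lookup
    error naming it.
    """
    thresholds = thresholds or EligibilityThresholds()
    records = []
    for gene in genes:
        med = median_expression(ds, gene)
        pct = detection_fraction(ds, gene, thresholds.detection_level)
        records.append(
            EligibilityRecord(
                gene=gene.upper(),
                dataset_id=ds.dataset_id,
                median_expression=med,
                pct_samples_above_level=pct,
                meets_criteria=decide_eligibility(med, pct, thresholds),
            )
        )
    return records


def eligibility_frame(records: Sequence[EligibilityRecord]) -> pd.DataFrame:
    """Tabular report mirroring the step-5a summary table."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "dataset_id": r.dataset_id,
                "median_expression": r.median_expression,
                "pct_above_level": r.pct_samples_above_level,
                "meets_criteria": r.meets_criteria,
            }
            for r in records
        ]
    )
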