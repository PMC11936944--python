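"""Module-representativeness filter.

A candidate marker should track the behaviour of its whole module.  For each
candidate we correlate its expression with the module-average expression
(per-sample mean over the module's genes) within every reference cohort, then
summarize per gene: the median correlation across cohorts, the percentage of
cohorts above a cutoff (default 0.5), and a Tukey low-outlier flag on the
distribution of per-gene median correlations (below Q1 - 1.5*IQR).  A gene is
representative when its median clears the cutoff, at least half the cohorts
clear it, and it is not a low outlier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from modmarker.errors import GeneLookupError, ValidationError
from modmarker.expression import ExpressionDataset
from modmarker.modules import ModuleDefinition

#: reasons an individual (gene, cohort) correlation can be undefined
REASON_TOO_FEW = "too_few_samples"
REASON_ZERO_VARIANCE = "zero_variance"


class RepresentativenessConfig(BaseModel):
    """Knobs of the representativeness filter."""

    corr_cutoff: float = Field(default=0.5, gt=-1, lt=1)
    pct_min: float = Field(default=50.0, gt=0, le=100)
    outlier_fence_multiplier: float = Field(default=1.5, ge=0)
    min_samples_per_cohort: int = Field(default=3, ge=2)
    method: Literal["pearson", "spearman"] = "pearson"
    leave_one_out: bool = False
    log_transform: bool = False


@dataclass(frozen=True)
class CorrelationProfile:
    """Gene x cohort matrix of correlations with the module average.

    Undefined entries are NaN in ``values``; ``reasons`` records why each is
    undefined.
    """

    values: pd.DataFrame
    reasons: dict[tuple[str, str], str]

    @property
    def cohort_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass(frozen=True)
class RepresentativenessRecord:
    gene: str
    median_correlation: float
    pct_cohorts_above_cutoff: float
    is_low_outlier: bool
    meets_both_criteria: bool
    insufficient_data: bool = False


def _transform(values: pd.DataFrame, config: RepresentativenessConfig) -> pd.DataFrame:
    return np.log2(values + 1.0) if config.log_transform else values


def module_average(ds: ExpressionDataset, module: ModuleDefinition) -> pd.Series:
    """Per-sample arithmetic mean over the module genes present in ``ds``.

    Module genes absent from the matrix are dropped with a warning.
    """
    present = [g for g in module.genes if g in ds.values.index]
    missing = [g for g in module.genes if g not in ds.values.index]
    if not present:
        raise ValidationError(
            f"no gene of module {module.module_id} is present in {ds.dataset_id}"
        )
    if missing:
        warnings.warn(
            f"module {module.module_id}: {len(missing)} gene(s) absent from "
            f"{ds.dataset_id} and dropped: {missing}",
            stacklevel=2,
        )
    avg = ds.values.loc[present].mean(axis=0)
    avg.name = f"{module.module_id}_average"
    return avg


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.pearsonr(x, y).statistic)


def _cohort_correlation(
    gene_vec: pd.Series,
    avg_vec: pd.Series,
    samples: Sequence[str],
    config: RepresentativenessConfig,
) -> tuple[float, str | None]:
    if len(samples) < config.min_samples_per_cohort:
        return np.nan, REASON_TOO_FEW
    x = gene_vec.loc[samples].to_numpy(dtype=float)
    y = avg_vec.loc[samples].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, REASON_ZERO_VARIANCE
    return _correlate(x, y, config.method), None


def gene_module_correlation(
    ds: ExpressionDataset,
    gene: str,
    module: ModuleDefinition,
    cohort: str,
    config: RepresentativenessConfig | None = None,
) -> float:
    """Correlation of one gene with the module average over one cohort.

    Returns NaN (undefined) when the cohort has fewer than
    ``min_samples_per_cohort`` samples or either vector has zero variance.
    """
    config = config or RepresentativenessConfig()
    if cohort not in ds.cohorts:
        raise GeneLookupError(f"cohort {cohort!r} not found in {ds.dataset_id}")
    values = _transform(ds.values, config)
    tds = ExpressionDataset(values=values, annotations=ds.annotations, dataset_id=ds.dataset_id)
    gene = gene.upper()
    gene_vec = tds.gene_values(gene)
    if config.leave_one_out and gene in module.genes and len(module) > 1:
        module = ModuleDefinition(
            module_id=module.module_id,
            genes=tuple(g for g in module.genes if g != gene),
            aggregate_id=module.aggregate_id,
        )
    avg_vec = module_average(tds, module)
    samples = list(ds.annotations.index[ds.annotations["cohort"].astype(str) == cohort])
    r, _ = _cohort_correlation(gene_vec, avg_vec, samples, config)
    return r


def correlation_profile(
    ds: ExpressionDataset,
    genes: Sequence[str],
    module: ModuleDefinition,
    config: RepresentativenessConfig | None = None,
) -> CorrelationProfile:
    """Correlations of each requested gene with the module average, per cohort."""
    config = config or RepresentativenessConfig()
    cohorts = ds.cohorts
    if not cohorts:
        raise ValidationError("dataset has no cohorts")
    values = _transform(ds.values, config)
    tds = ExpressionDataset(values=values, annotations=ds.annotations, dataset_id=ds.dataset_id)
    ann = ds.annotations["cohort"].astype(str)
    cohort_samples = {c: list(ann.index[ann == c]) for c in cohorts}

    full_avg = None
    if not config.leave_one_out:
        full_avg = module_average(tds, module)

    genes = [g.upper() for g in genes]
    out = pd.DataFrame(np.nan, index=genes, columns=list(cohorts))
    reasons: dict[tuple[str, str], str] = {}
    for gene in genes:
        gene_vec = tds.gene_values(gene)
        if config.leave_one_out and gene in module.genes and len(module) > 1:
            loo = ModuleDefinition(
                module_id=module.module_id,
                genes=tuple(g for g in module.genes if g != gene),
                aggregate_id=module.aggregate_id,
            )
            avg_vec = module_average(tds, loo)
        else:
            avg_vec = full_avg if full_avg is not None else module_average(tds, module)
        for cohort in cohorts:
            r, reason = _cohort_correlation(
                gene_vec, avg_vec, cohort_samples[cohort], config
            )
            out.loc[gene, cohort] = r
            if reason is not None:
                reasons[(gene, cohort)] = reason
    out.index.name = "gene"
    return CorrelationProfile(values=out, reasons=reasons)


def decide_representativeness(
    median_correlation: float,
    pct_cohorts_above_cutoff: float,
    is_low_outlier: bool,
    config: RepresentativenessConfig | None = None,
) -> bool:
    """The representativeness conjunction: median >= cutoff, percentage of
    cohorts above cutoff >= pct_min, and not a low outlier."""
    config = config or RepresentativenessConfig()
    return bool(
        median_correlation >= config.corr_cutoff
        and pct_cohorts_above_cutoff >= config.pct_min
        and not is_low_outlier
    )


def summarize_representativeness(
    profile: CorrelationProfile,
    config: RepresentativenessConfig | None = None,
) -> list[RepresentativenessRecord]:
    """Per-gene summary of a correlation profile, mirroring the step-5b table.

    Undefined cohort entries are excluded from both the median and the
    percentage (the denominator is the number of defined cohorts).  The
    low-outlier fence Q1 - multiplier*IQR is computed over the per-gene median
    correlations of all summarizable genes (linear-interpolation quartiles);
    with fewer than four such genes the flag is forced False with a warning.
    Output is sorted by median correlation, descending (ties by gene symbol);
    genes with no defined cohort at all come last, flagged insufficient_data.
    """
    config = config or RepresentativenessConfig()
    medians: dict[str, float] = {}
    pcts: dict[str, float] = {}
    no_data: list[str] = []
    for gene in profile.values.index:
        row = profile.values.loc[gene].dropna()
        if row.empty:
            no_data.append(gene)
            continue
        medians[gene] = float(row.median())
        pcts[gene] = float(100.0 * (row > config.corr_cutoff).sum() / len(row))

    outliers: dict[str, bool] = {g: False for g in medians}
    if len(medians) >= 4 and config.outlier_fence_multiplier >= 0:
        med_values = np.array(list(medians.values()))
        q1, q3 = np.percentile(med_values, [25, 75])
        fence = q1 - config.outlier_fence_multiplier * (q3 - q1)
        outliers = {g: bool(m < fence) for g, m in medians.items()}
    elif 0 < len(medians) < 4:
        warnings.warn(
            "fewer than 4 genes summarized; quartiles unstable, "
            "low-outlier flag forced False",
            stacklevel=2,
        )

    records = [
        RepresentativenessRecord(
            gene=g,
            median_correlation=medians[g],
            pct_cohorts_above_cutoff=pcts[g],
            is_low_outlier=outliers[g],
            meets_both_criteria=decide_representativeness(
                medians[g], pcts[g], outliers[g], config
            ),
        )
        for g in medians
    ]
    records.sort(key=lambda r: (-r.median_correlation, r.gene))
    records.extend(
        RepresentativenessRecord(
            gene=g,
            median_correlation=float("nan"),
            pct_cohorts_above_cutoff=float("nan"),
            is_low_outlier=False,
            meets_both_criteria=False,
            insufficient_data=True,
        )
        for g in sorted(no_data)
    )
    return records


def representativeness_frame(
    records: Sequence[RepresentativenessRecord],
) -> pd.DataFrame:
    """Tabular report mirroring the step-5b summary table."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "median_correlation": r.median_correlation,
                "pct_above_cutoff": r.pct_cohorts_above_cutoff,
                "is_low_outlier": r.is_low_outlier,
                "meets_both_criteria": r.meets_both_criteria,
                "insufficient_data": r.insufficient_data,
            }
            for r in records
        ]
    )
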