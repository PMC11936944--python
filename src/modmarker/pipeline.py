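"""End-to-end prioritization pipeline and report model.

The pipeline turns replicate knowledge-score tables plus expression datasets
into a tiered prioritization of one module's genes:

1. per scorer: average replicate runs, rank by cumulative score, take top-k;
2. pool candidates across scorers; build a consensus score table;
3. optionally apply expert score revisions;
4. per dataset: expression-eligibility filter on the pool;
5. representativeness filter (correlation with the module average across
   reference cohorts);
6. tier assignment — representativeness is a hard gate, eligibility a
   configurable gate (``any`` dataset suffices by default, ``all`` requires
   every dataset), and the consensus cumulative score orders the survivors:
   the best unflagged gene is the ``top_candidate``, remaining unflagged
   genes are ``alternative``, gated genes are ``flagged``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from modmarker.errors import ValidationError
from modmarker.expression import (
    EligibilityRecord,
    EligibilityThresholds,
    eligibility_frame,
    flag_low_expression,
    read_expression,
)
from modmarker.modules import read_gmt
from modmarker.representativeness import (
    RepresentativenessConfig,
    RepresentativenessRecord,
    correlation_profile,
    representativeness_frame,
    summarize_representativeness,
)
from modmarker.scores import (
    CandidatePool,
    EvidenceRecord,
    apply_revisions,
    average_replicates,
    average_scorers,
    cumulative_scores,
    load_score_table,
    pool_candidates,
    rank_genes,
    top_k,
)

TIERS = ("top_candidate", "alternative", "flagged")


class ScorerRuns(BaseModel):
    scorer_id: str
    runs: list[str] = Field(min_length=1)


class DatasetRef(BaseModel):
    dataset_id: str
    matrix: str
    annotations: str
    cell_type: str | None = None  # optional annotation-based subsetting
    use_for_eligibility: bool = True
    use_for_representativeness: bool = True


class PipelineConfig(BaseModel):
    """Full configuration of a pipeline run (YAML-serializable)."""

    module_gmt: str
    scorers: list[ScorerRuns] = Field(min_length=1)
    expression_datasets: list[DatasetRef] = Field(min_length=1)
    k: int = Field(default=5, ge=1)
    eligibility: EligibilityThresholds = Field(default_factory=EligibilityThresholds)
    representativeness: RepresentativenessConfig = Field(
        default_factory=RepresentativenessConfig
    )
    eligibility_rule: Literal["any", "all"] = "any"
    revisions: str | None = None
    #: batch size of a hypothetical live scoring adapter; kept for interface
    #: fidelity, unused by the file/mock scorers
    scoring_batch_size: int = Field(default=10, ge=1)
    criterion_weights: dict[str, float] | None = None
    outdir: str = "modmarker_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        config = cls.model_validate(yaml.safe_load(path.read_text()))
        return config.resolve_paths(path.parent)

    def resolve_paths(self, base: Path) -> "PipelineConfig":
        """Resolve relative file paths against ``base`` (the config's dir)."""

        def r(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        update = self.model_copy(deep=True)
        update.module_gmt = r(self.module_gmt)
        for s in update.scorers:
            s.runs = [r(p) for p in s.runs]
        for d in update.expression_datasets:
            d.matrix = r(d.matrix)
            d.annotations = r(d.annotations)
        if update.revisions:
            update.revisions = r(update.revisions)
        return update


@dataclass(frozen=True)
class ReportRow:
    gene: str
    consensus_score: float
    eligibility_by_dataset: dict[str, bool]
    eligible: bool
    representative: bool
    tier: str
    rationale: str

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "consensus_score": self.consensus_score,
            "eligibility_by_dataset": dict(self.eligibility_by_dataset),
            "eligible": self.eligible,
            "representative": self.representative,
            "tier": self.tier,
            "rationale": self.rationale,
        }


@dataclass(frozen=True)
class PrioritizationReport:
    """Tiered result of a pipeline run.

    Rows are ordered top candidate first, then alternatives, then flagged
    genes, each by consensus score descending.
    """

    rows: tuple[ReportRow, ...]
    metadata: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        tops = [r for r in self.rows if r.tier == "top_candidate"]
        if len(tops) > 1:
            raise ValidationError("at most one top_candidate is allowed")
        unflagged = [r for r in self.rows if r.tier != "flagged"]
        if unflagged and not tops:
            raise ValidationError("a top_candidate is required when genes pass")
        if any(r.tier not in TIERS for r in self.rows):
            raise ValidationError(f"tiers must be among {TIERS}")

    @property
    def top_candidate(self) -> str | None:
        for r in self.rows:
            if r.tier == "top_candidate":
                return r.gene
        return None

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "note": self.note,
            "rows": [r.to_dict() for r in self.rows],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PrioritizationReport":
        rows = tuple(
            ReportRow(
                gene=r["gene"],
                consensus_score=float(r["consensus_score"]),
                eligibility_by_dataset=dict(r["eligibility_by_dataset"]),
                eligible=bool(r["eligible"]),
                representative=bool(r["representative"]),
                tier=r["tier"],
                rationale=r["rationale"],
            )
            for r in payload["rows"]
        )
        return cls(rows=rows, metadata=payload.get("metadata", {}), note=payload.get("note", ""))

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec = {
                "gene": r.gene,
                "tier": r.tier,
                "consensus_score": r.consensus_score,
                "representative": r.representative,
                "eligible": r.eligible,
            }
            for ds_id in sorted(r.eligibility_by_dataset):
                rec[f"eligible_{ds_id}"] = r.eligibility_by_dataset[ds_id]
            rec["rationale"] = r.rationale
            records.append(rec)
        return pd.DataFrame(records)


def assign_tiers(
    pool: CandidatePool,
    consensus: Mapping[str, float],
    eligibility: Mapping[str, Mapping[str, EligibilityRecord]],
    representativeness: Mapping[str, RepresentativenessRecord],
    rule: Literal["any", "all"] = "any",
) -> PrioritizationReport:
    """Combine knowledge and data-driven evidence into tiers.

    ``eligibility`` maps dataset_id -> gene -> record; ``representativeness``
    maps gene -> record.  A gene is flagged when it fails representativeness
    or fails eligibility under ``rule`` (``any``: passing one dataset
    suffices; ``all``: every dataset must pass).
    """
    genes = pool.sorted_genes()
    for g in genes:
        if g not in consensus:
            raise ValidationError(f"pool gene {g} has no consensus score")
        if g not in representativeness:
            raise ValidationError(f"pool gene {g} has no representativeness record")
        for ds_id, records in eligibility.items():
            if g not in records:
                raise ValidationError(
                    f"pool gene {g} has no eligibility record for dataset {ds_id}"
                )
    if not genes:
        raise ValidationError("candidate pool is empty")

    rows = []
    for g in genes:
        by_ds = {ds_id: eligibility[ds_id][g].meets_criteria for ds_id in eligibility}
        if not by_ds:
            eligible = True
        elif rule == "any":
            eligible = any(by_ds.values())
        else:
            eligible = all(by_ds.values())
        representative = representativeness[g].meets_both_criteria
        reasons = []
        if not representative:
            reasons.append("fails module-representativeness filter")
        if not eligible:
            failing = sorted(d for d, ok in by_ds.items() if not ok)
            reasons.append(
                f"fails expression eligibility (rule={rule}; failing: {failing})"
            )
        rows.append(
            ReportRow(
                gene=g,
                consensus_score=float(consensus[g]),
                eligibility_by_dataset=by_ds,
                eligible=eligible,
                representative=representative,
                tier="flagged" if reasons else "alternative",
                rationale="; ".join(reasons) or "passes all filters",
            )
        )

    unflagged = [r for r in rows if r.tier != "flagged"]
    note = ""
    if unflagged:
        best = max(unflagged, key=lambda r: (r.consensus_score, r.gene))
        # ties on score resolve lexicographically: max() above prefers the
        # later symbol, so re-pick the smallest symbol among score ties
        tied = [r for r in unflagged if r.consensus_score == best.consensus_score]
        best = min(tied, key=lambda r: r.gene)
        rows = [
            ReportRow(
                gene=r.gene,
                consensus_score=r.consensus_score,
                eligibility_by_dataset=r.eligibility_by_dataset,
                eligible=r.eligible,
                representative=r.representative,
                tier="top_candidate" if r.gene == best.gene else r.tier,
                rationale=(
                    "passes all filters; highest consensus score"
                    if r.gene == best.gene
                    else r.rationale
                ),
            )
            for r in rows
        ]
    else:
        note = "all candidates are flagged; no top candidate could be assigned"

    order = {t: i for i, t in enumerate(TIERS)}
    rows.sort(key=lambda r: (order[r.tier], -r.consensus_score, r.gene))
    return PrioritizationReport(rows=tuple(rows), note=note)


def _load_revisions(path: str) -> list[tuple[str, str, float, EvidenceRecord]]:
    """Revision CSV: columns gene, criterion, score, justification[, references].

    References use ';' as an in-cell separator.
    """
    df = pd.read_csv(path)
    needed = {"gene", "criterion", "score", "justification"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: revision file missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        refs = ()
        if "references" in df.columns and isinstance(row.get("references"), str):
            refs = tuple(s.strip() for s in row["references"].split(";") if s.strip())
        out.append(
            (
                str(row["gene"]),
                str(row["criterion"]).strip().upper(),
                float(row["score"]),
                EvidenceRecord(
                    justification=str(row["justification"]), references=refs
                ),
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> PrioritizationReport:
    """Execute the full workflow and write all artifacts into
    ``config.outdir``.

    Writes per-scorer averaged tables, the consensus ranking, per-dataset
    eligibility reports, the representativeness report, the final report
    (CSV + JSON) and a deterministic decision log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    module = read_gmt(config.module_gmt)[0]
    log.append(
        f"module {module.module_id} ({len(module)} genes; aggregate "
        f"{module.aggregate_id or 'n/a'}) loaded from {Path(config.module_gmt).name}"
    )

    selections: list[tuple[str, list[str]]] = []
    averaged_tables = []
    for scorer in config.scorers:
        tables = [
            load_score_table(p, scorer_id=scorer.scorer_id, run_id=i + 1)
            for i, p in enumerate(scorer.runs)
        ]
        averaged = average_replicates(tables)
        averaged.to_csv(outdir / f"scores_{scorer.scorer_id}_averaged.csv")
        ranked = rank_genes(cumulative_scores(averaged, config.criterion_weights))
        picks = top_k(ranked, config.k)
        selections.append((scorer.scorer_id, picks))
        averaged_tables.append(averaged)
        log.append(
            f"scorer {scorer.scorer_id}: {len(tables)} run(s) averaged; "
            f"top-{config.k} = {picks}"
        )

    pool = pool_candidates(selections)
    if not pool.genes:
        raise ValidationError("candidate pool is empty")
    log.append(f"candidate pool ({len(pool.genes)} genes): {pool.sorted_genes()}")

    consensus_table = (
        average_scorers(averaged_tables)
        if len(averaged_tables) > 1
        else averaged_tables[0]
    )
    if config.revisions:
        revisions = _load_revisions(config.revisions)
        consensus_table = apply_revisions(consensus_table, revisions)
        log.append(f"applied {len(revisions)} expert revision(s)")
    consensus = cumulative_scores(consensus_table, config.criterion_weights)
    ranked_consensus = rank_genes(consensus)
    ranked_consensus.to_frame().to_csv(outdir / "consensus_ranking.csv", index=False)
    log.append("consensus ranking written (cumulative scores, descending)")

    pool_genes = pool.sorted_genes()
    missing_scores = [g for g in pool_genes if g not in consensus.index]
    if missing_scores:
        raise ValidationError(f"pool genes missing from consensus table: {missing_scores}")

    eligibility: dict[str, dict[str, EligibilityRecord]] = {}
    repr_frames = []
    for ref in config.expression_datasets:
        ds = read_expression(ref.matrix, ref.annotations, dataset_id=ref.dataset_id)
        if ref.cell_type is not None:
            ds = ds.subset(cell_type=ref.cell_type)
            log.append(f"dataset {ref.dataset_id}: restricted to cell_type={ref.cell_type}")
        if ref.use_for_eligibility:
            records = flag_low_expression(ds, pool_genes, config.eligibility)
            eligibility[ref.dataset_id] = {r.gene: r for r in records}
            eligibility_frame(records).to_csv(
                outdir / f"eligibility_{ref.dataset_id}.csv", index=False
            )
            failing = sorted(r.gene for r in records if not r.meets_criteria)
            log.append(
                f"dataset {ref.dataset_id}: eligibility "
                f"(median>={config.eligibility.median_min}, "
                f">{config.eligibility.detection_level} in >="
                f"{config.eligibility.detection_fraction_min}% of samples); "
                f"failing: {failing or 'none'}"
            )
        if ref.use_for_representativeness:
            profile = correlation_profile(
                ds, pool_genes, module, config.representativeness
            )
            renamed = profile.values.rename(
                columns=lambda c: f"{ref.dataset_id}:{c}"
            )
            repr_frames.append(renamed)
            profile.values.to_csv(outdir / f"correlations_{ref.dataset_id}.csv")

    if not repr_frames:
        raise ValidationError(
            "no dataset is marked use_for_representativeness; the filter needs one"
        )
    from modmarker.representativeness import CorrelationProfile

    combined = CorrelationProfile(values=pd.concat(repr_frames, axis=1), reasons={})
    repr_records = summarize_representativeness(combined, config.representativeness)
    representativeness_frame(repr_records).to_csv(
        outdir / "representativeness.csv", index=False
    )
    repr_by_gene = {r.gene: r for r in repr_records}
    failing = sorted(g for g, r in repr_by_gene.items() if not r.meets_both_criteria)
    log.append(
        f"representativeness (cutoff {config.representativeness.corr_cutoff}, "
        f">={config.representativeness.pct_min}% of cohorts, Tukey fence x"
        f"{config.representativeness.outlier_fence_multiplier}); failing: "
        f"{failing or 'none'}"
    )

    consensus_pool = {g: float(consensus[g]) for g in pool_genes}
    report = assign_tiers(
        pool, consensus_pool, eligibility, repr_by_gene, config.eligibility_rule
    )
    metadata = {
        "module_id": module.module_id,
        "k": config.k,
        "eligibility_rule": config.eligibility_rule,
        "eligibility_thresholds": config.eligibility.model_dump(),
        "representativeness_config": config.representativeness.model_dump(),
        "scorers": [s.scorer_id for s in config.scorers],
        "datasets": [d.dataset_id for d in config.expression_datasets],
        "seed": config.seed,
    }
    report = PrioritizationReport(rows=report.rows, metadata=metadata, note=report.note)
    log.append(
        f"top candidate: {report.top_candidate or 'none'}"
        + (f" ({report.note})" if report.note else "")
    )
    write_report(report, outdir)
    (outdir / "pipeline_log.txt").write_text("\n".join(log) + "\n")
    return report


def write_report(report: PrioritizationReport, outdir: str | Path) -> None:
    """Write ``report.csv`` and ``report.json`` deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    if frame.empty:
        frame = pd.DataFrame(
            columns=["gene", "tier", "consensus_score", "representative", "eligible", "rationale"]
        )
    frame.to_csv(outdir / "report.csv", index=False)
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
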