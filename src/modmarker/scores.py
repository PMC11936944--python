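"""Knowledge-score tables: ingestion, aggregation, ranking, pooling.

A :class:`ScoreTable` holds one scorer's 0-10 scores for a set of genes on the
six criteria (see :mod:`modmarker.criteria`).  Scoring runs are replicated and
averaged; multiple scorers are combined into a consensus table; genes are
ranked by cumulative score and each scorer's top-k candidates are pooled for
downstream expression-based filtering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from modmarker.criteria import CRITERION_CODES, CSV_COLUMNS, SCORE_MAX, SCORE_MIN
from modmarker.errors import SchemaError, ValidationError

#: sentinel run_id of a replicate-averaged table
AVERAGED_RUN = "averaged"
#: sentinel scorer_id of a cross-scorer consensus table
CONSENSUS_SCORER = "consensus-mean"

RunId = Union[int, str]


@dataclass(frozen=True)
class EvidenceRecord:
    """Justification and citations attached to one (gene, criterion) score."""

    justification: str = ""
    references: tuple[str, ...] = ()
    verification_status: str = "unverified"

    _STATUSES = ("unverified", "verified", "revised")

    def __post_init__(self) -> None:
        if self.verification_status not in self._STATUSES:
            raise ValidationError(
                f"verification_status must be one of {self._STATUSES}, "
                f"got {self.verification_status!r}"
            )
        if self.verification_status == "revised" and not self.justification.strip():
            raise ValidationError("a revised score requires a non-empty justification")


@dataclass(frozen=True)
class ScoreTable:
    """Gene x criterion knowledge scores from a single scorer/run.

    ``scores`` is a DataFrame indexed by upper-case gene symbol with the six
    criterion codes A-F as columns; every cell lies in [0, 10].  Raw scores
    from a single run are integers, but averaged tables are real-valued and
    all downstream operations accept fractional scores.
    """

    scorer_id: str
    run_id: RunId
    scores: pd.DataFrame
    evidence: dict[tuple[str, str], EvidenceRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.scores
        if list(df.columns) != list(CRITERION_CODES):
            raise SchemaError(
                f"score columns must be {list(CRITERION_CODES)}, got {list(df.columns)}"
            )
        upper = df.index.astype(str).str.upper()
        if upper.duplicated().any():
            dups = sorted(upper[upper.duplicated()].unique())
            raise ValidationError(f"duplicate gene symbols: {dups}")
        df = df.set_axis(upper, axis=0)
        df.index.name = "gene"
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            gene, code = self._first_offender(df, np.isnan(values))
            raise ValidationError(f"missing score for gene {gene}, criterion {code}")
        bad = (values < SCORE_MIN) | (values > SCORE_MAX)
        if bad.any():
            gene, code = self._first_offender(df, bad)
            raise ValidationError(
                f"score out of range [0, 10] for gene {gene}, criterion {code}: "
                f"{df.loc[gene, code]}"
            )
        object.__setattr__(self, "scores", df.astype(float))

    @staticmethod
    def _first_offender(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(df.index[i]), str(df.columns[j])

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.scores.index)

    @property
    def label(self) -> str:
        return f"{self.scorer_id}:{self.run_id}"

    def flatten(self) -> np.ndarray:
        """Vector over (gene, criterion) cells in canonical order.

        Genes sorted lexicographically, criteria A-F within each gene.
        """
        return self.scores.sort_index().to_numpy(dtype=float).ravel()

    def to_csv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.columns = list(CSV_COLUMNS)
        out.to_csv(path, index_label="gene")
        if self.evidence:
            sidecar = Path(path).with_suffix(".evidence.json")
            payload = {
                f"{g}.{c}": {
                    "justification": rec.justification,
                    "references": list(rec.references),
                    "verification_status": rec.verification_status,
                }
                for (g, c), rec in sorted(self.evidence.items())
            }
            sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_score_table(path: str | Path, scorer_id: str, run_id: RunId) -> ScoreTable:
    """Read a score CSV (``gene,crit_a,...,crit_f``) into a validated table."""
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "gene" not in df.columns:
        raise SchemaError(f"{path}: missing 'gene' column")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing criterion column(s) {missing}")
    scores = df.set_index("gene")[list(CSV_COLUMNS)]
    try:
        scores = scores.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: non-numeric score value ({exc})") from exc
    scores.columns = [CSV_COLUMNS[c] for c in scores.columns]
    return ScoreTable(scorer_id=scorer_id, run_id=run_id, scores=scores)


def _check_same_genes(tables: Sequence[ScoreTable]) -> None:
    ref = set(tables[0].genes)
    for t in tables[1:]:
        other = set(t.genes)
        if other != ref:
            diff = sorted(ref.symmetric_difference(other))
            raise ValidationError(f"gene sets differ between tables: {diff}")


def average_replicates(tables: Sequence[ScoreTable]) -> ScoreTable:
    """Cell-wise mean over replicate runs of a single scorer."""
    if not tables:
        raise ValidationError("need at least one table")
    scorers = {t.scorer_id for t in tables}
    if len(scorers) > 1:
        raise ValidationError(f"tables come from multiple scorers: {sorted(scorers)}")
    _check_same_genes(tables)
    order = tables[0].scores.index
    mean = (
        sum(t.scores.loc[order] for t in tables) / len(tables)
        if len(tables) > 1
        else tables[0].scores
    )
    return ScoreTable(scorer_id=tables[0].scorer_id, run_id=AVERAGED_RUN, scores=mean)


def average_scorers(tables: Sequence[ScoreTable]) -> ScoreTable:
    """Consensus table: cell-wise mean across scorers on the shared gene set.

    Gene sets are restricted to their intersection; no score is imputed for a
    gene a scorer did not evaluate.
    """
    if len(tables) < 2:
        raise ValidationError("consensus requires at least two scorer tables")
    shared = set(tables[0].genes)
    for t in tables[1:]:
        shared &= set(t.genes)
    if not shared:
        raise ValidationError("scorer tables share no genes")
    order = [g for g in tables[0].genes if g in shared]
    mean = sum(t.scores.loc[order] for t in tables) / len(tables)
    return ScoreTable(scorer_id=CONSENSUS_SCORER, run_id=AVERAGED_RUN, scores=mean)


def cumulative_scores(
    table: ScoreTable, weights: Mapping[str, float] | None = None
) -> pd.Series:
    """Per-gene sum of the six criterion scores (range [0, 60]).

    ``weights`` optionally reweights criteria (default: equal unit weights).
    """
    if weights is None:
        total = table.scores.sum(axis=1)
    else:
        w = pd.Series({c: float(weights.get(c, 1.0)) for c in CRITERION_CODES})
        total = (table.scores * w).sum(axis=1)
    total.name = "cumulative_score"
    return total


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by cumulative score, descending; ties broken by symbol."""

    entries: tuple[tuple[str, float], ...]
    tie_rule: str = "descending score, ties by ascending gene symbol"

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValidationError("cumulative scores must be non-increasing")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene", "cumulative_score"])


def rank_genes(cum: Mapping[str, float] | pd.Series) -> RankedList:
    """Rank genes by cumulative score, descending; exact ties by gene symbol."""
    items = list(dict(cum).items())
    if not items:
        raise ValidationError("cannot rank an empty score mapping")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return RankedList(entries=tuple((g, float(s)) for g, s in items))


def top_k(ranked: RankedList, k: int) -> list[str]:
    """First ``k`` genes of a ranked list."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(ranked.entries):
        raise ValueError(f"k={k} exceeds the {len(ranked.entries)} ranked genes")
    return list(ranked.genes[:k])


@dataclass(frozen=True)
class CandidatePool:
    """Union of the scorers' top-k selections, with per-gene provenance."""

    genes: frozenset[str]
    provenance: dict[str, tuple[str, ...]]

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


def pool_candidates(selections: Sequence[tuple[str, Sequence[str]]]) -> CandidatePool:
    """Pool per-scorer selections into one candidate set.

    ``selections`` is a list of (scorer_id, ordered gene list) pairs; the pool
    is their union and ``provenance`` records which scorers picked each gene.
    """
    if not selections:
        raise ValidationError("need at least one selection")
    provenance: dict[str, list[str]] = {}
    for scorer_id, genes in selections:
        for g in genes:
            provenance.setdefault(g, []).append(scorer_id)
    return CandidatePool(
        genes=frozenset(provenance),
        provenance={g: tuple(v) for g, v in provenance.items()},
    )


@dataclass(frozen=True)
class ConsistencyMatrix:
    """Pairwise correlation between full scoring outputs of several runs."""

    labels: tuple[str, ...]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValidationError("consistency matrix must be square")
        defined = ~np.isnan(v)
        if not np.allclose(v[defined], v.T[defined.T], atol=1e-12):
            raise ValidationError("consistency matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValidationError("correlations must lie in [-1, 1]")


def run_consistency(tables: Sequence[ScoreTable]) -> ConsistencyMatrix:
    """Pairwise Pearson correlation between flattened score tables.

    Each table is flattened over (gene, criterion) cells in canonical order
    (genes sorted, criteria A-F).  A zero-variance table yields undefined
    (NaN) off-diagonal entries with a warning, never a silent 0.
    """
    if len(tables) < 2:
        raise ValidationError("consistency needs at least two tables")
    _check_same_genes(tables)
    vectors = np.vstack([t.flatten() for t in tables])
    labels = tuple(t.label for t in tables)
    n = len(tables)
    sd = vectors.std(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                warnings.warn(
                    f"zero-variance score vector; correlation between "
                    f"{labels[i]} and {labels[j]} is undefined",
                    stacklevel=2,
                )
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = np.corrcoef(vectors[i], vectors[j])[0, 1]
    return ConsistencyMatrix(
        labels=labels, values=pd.DataFrame(out, index=labels, columns=labels)
    )


Revision = tuple[str, str, float, EvidenceRecord]


def apply_revisions(table: ScoreTable, revisions: Iterable[Revision]) -> ScoreTable:
    """Apply expert revisions to individual cells, attaching evidence.

    Each revision is ``(gene, criterion code, new score, evidence)``; the
    returned table has the revised cells overwritten and their evidence
    records marked ``revised``.  Unrevised cells are untouched.
    """
    scores = table.scores.copy()
    evidence = dict(table.evidence)
    for gene, code, new_score, record in revisions:
        gene = gene.upper()
        if gene not in scores.index:
            raise ValidationError(f"revision for unknown gene {gene}")
        if code not in CRITERION_CODES:
            raise ValidationError(f"unknown criterion code {code!r}")
        if not SCORE_MIN <= new_score <= SCORE_MAX:
            raise ValidationError(
                f"revised score for {gene}/{code} out of range: {new_score}"
            )
        scores.loc[gene, code] = float(new_score)
        evidence[(gene, code)] = replace(record, verification_status="revised")
    return ScoreTable(
        scorer_id=table.scorer_id, run_id=table.run_id, scores=scores, evidence=evidence
    )
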