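"""The six knowledge-scoring criteria.

Each candidate gene is scored 0-10 on six fixed criteria covering its biology
(plasma cell responses, circulating leukocyte biology), its clinical standing
(biomarker use, blood transcriptional biomarker potential) and its therapeutic
standing (drug target status, therapeutic relevance for immune diseases).
Scores of 0 mean "no evidence found", 10 "strong, validated evidence".
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class Criterion:
    code: str
    label: str


CRITERIA: tuple[Criterion, ...] = (
    Criterion("A", "association with plasma cell responses"),
    Criterion("B", "relevance to circulating leukocyte immune biology"),
    Criterion("C", "current use as a clinical biomarker"),
    Criterion("D", "potential value as a blood transcriptional biomarker"),
    Criterion("E", "known drug target status"),
    Criterion("F", "therapeutic relevance for immune-mediated diseases"),
)

CRITERION_CODES: tuple[str, ...] = tuple(c.code for c in CRITERIA)

#: CSV column name for each criterion (``crit_a`` ... ``crit_f``).
CSV_COLUMNS: dict[str, str] = {f"crit_{c.code.lower()}": c.code for c in CRITERIA}

SCORE_MIN = 0.0
SCORE_MAX = 10.0
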