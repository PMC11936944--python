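"""Synthetic data with known ground truth for every pipeline stage.

Two generators stand in for the study inputs that cannot ship with a package:

* :func:`simulate_expression` — multi-cohort count matrices with an embedded
  co-expressed module.  Each sample carries a latent module activity
  ``a_s ~ Normal(mean_c, sd)`` whose cohort means span low to high, emulating
  condition-varying module abundance across 16 reference cohorts; gene g's
  expected count is ``baseline_g * exp(loading_g * a_s)`` (loading 0 for
  background genes) and observed counts are negative-binomial.
* :func:`simulate_score_tables` — replicate knowledge-score tables: each cell
  is the true score plus Gaussian noise, rounded to an integer and clamped to
  [0, 10], emulating triplicate 0-10 chat-scoring runs.

The default scenario embeds two designed decoys in the 17-gene module: the
top-scoring gene by knowledge criteria has loading 0 (not representative of
the module) and another high scorer has a near-zero baseline (too dim to
measure), so the end-to-end winner is the best-scoring gene that survives
both data-driven filters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from modmarker.criteria import CRITERION_CODES
from modmarker.errors import ValidationError
from modmarker.expression import ExpressionDataset
from modmarker.modules import ModuleDefinition, read_gmt
from modmarker.scores import ScoreTable

# --------------------------------------------------------------------------
# packaged module fixture


def fixture_m1215() -> ModuleDefinition:
    """The 17-gene plasma-cell module M12.15 (aggregate A27), from the
    packaged GMT fixture."""
    with resources.as_file(
        resources.files("modmarker").joinpath("data/m12_15.gmt")
    ) as path:
        return read_gmt(path)[0]


# --------------------------------------------------------------------------
# ground-truth knowledge scores

#: Designed true cumulative scores (0-60) for the 17 module genes.  UBE2C is
#: deliberately the top scorer but a module-representativeness decoy; ABCB9
#: scores highly but is an expression decoy.  The gap between ranks 5 and 6
#: (47 vs 40) keeps the true top-5 set recoverable under replicate noise.
TRUE_CUMULATIVE: dict[str, int] = {
    "UBE2C": 59,
    "CD38": 55,
    "TNFRSF17": 53,
    "ABCB9": 50,
    "IGJ": 47,
    "TOP2A": 40,
    "TYMS": 38,
    "CCNB2": 35,
    "CDC20": 33,
    "CDCA5": 31,
    "KIAA0101": 29,
    "TXNDC5": 26,
    "UHRF1": 24,
    "MGC29506": 22,
    "IGLL3": 19,
    "LOC649923": 16,
    "LOC652775": 13,
}


def _split_six(total: int) -> list[int]:
    base, rem = divmod(total, 6)
    return [base + 1] * rem + [base] * (6 - rem)


def default_true_scores() -> pd.DataFrame:
    """True per-criterion scores for the 17 module genes (rows sum to
    :data:`TRUE_CUMULATIVE`)."""
    rows = {g: _split_six(c) for g, c in TRUE_CUMULATIVE.items()}
    rows["CD38"] = [9, 8, 9, 9, 10, 10]  # canonical CD38 profile, sums to 55
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(CRITERION_CODES))
    return df.sort_index()


# --------------------------------------------------------------------------
# specs


def _default_cohorts() -> list[tuple[str, int, float]]:
    means = np.linspace(-2.0, 2.0, 16)
    return [(f"cohort_{i + 1:02d}", 10, float(m)) for i, m in enumerate(means)]


def _default_loadings(module: ModuleDefinition) -> dict[str, float]:
    loadings = {g: 1.0 for g in module.genes}
    if "UBE2C" in loadings:
        loadings["UBE2C"] = 0.0  # representativeness decoy
    return loadings


def _default_baselines(module: ModuleDefinition) -> dict[str, float]:
    baselines = {g: 300.0 for g in module.genes}
    if "ABCB9" in baselines:
        baselines["ABCB9"] = 2.0  # expression decoy
    return baselines


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the expression simulator (defaults = the package's
    standard study-like scenario: 16 cohorts x 10 samples, 17-gene module,
    183 background genes)."""

    n_background_genes: int = 183
    module: ModuleDefinition = field(default_factory=fixture_m1215)
    cohorts: tuple[tuple[str, int, float], ...] = field(
        default_factory=lambda: tuple(_default_cohorts())
    )
    activity_sd: float = 0.5
    loadings: dict[str, float] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes must be >= 0")
        if not self.cohorts:
            raise ValidationError("need at least one cohort")
        if any(n < 1 for _, n, _ in self.cohorts):
            raise ValidationError("every cohort needs >= 1 sample")
        if self.activity_sd < 0:
            raise ValidationError("activity_sd must be >= 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if not self.loadings:
            object.__setattr__(self, "loadings", _default_loadings(self.module))
        if not self.baselines:
            object.__setattr__(self, "baselines", _default_baselines(self.module))
        for g in self.module.genes:
            load = self.loadings.get(g)
            if load is None or not 0.0 <= load <= 1.0:
                raise ValidationError(f"module gene {g} needs a loading in [0, 1]")
            if self.baselines.get(g, 0.0) <= 0:
                raise ValidationError(f"module gene {g} needs a baseline > 0")


@dataclass(frozen=True)
class ScoreSimSpec:
    """Parameters of the replicate score simulator."""

    true_scores: pd.DataFrame = field(default_factory=default_true_scores)
    noise_sd: float = 1.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if list(self.true_scores.columns) != list(CRITERION_CODES):
            raise ValidationError(
                f"true_scores columns must be {list(CRITERION_CODES)}"
            )
        v = self.true_scores.to_numpy(dtype=float)
        if (v < 0).any() or (v > 10).any():
            raise ValidationError("true scores must lie in [0, 10]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters and derived expectations of a simulation."""

    loadings: dict[str, float]
    baselines: dict[str, float]
    expected_pass_expression: dict[str, bool | None]
    expected_representative: dict[str, bool | None]
    true_cumulative: dict[str, float]
    designed_winner: str | None

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings,
            "baselines": self.baselines,
            "expected_pass_expression": self.expected_pass_expression,
            "expected_representative": self.expected_representative,
            "true_cumulative": self.true_cumulative,
            "designed_winner": self.designed_winner,
        }


# thresholds used only to derive truth labels; deliberately far from the
# filter thresholds so labelled genes sit well inside pass/fail territory
_BASELINE_PASS = 200.0
_BASELINE_FAIL = 3.0
_LOADING_PASS = 0.8


def _expectation_labels(
    loadings: dict[str, float], baselines: dict[str, float]
) -> tuple[dict[str, bool | None], dict[str, bool | None]]:
    pass_expr: dict[str, bool | None] = {}
    representative: dict[str, bool | None] = {}
    for g, baseline in baselines.items():
        if baseline >= _BASELINE_PASS:
            pass_expr[g] = True
        elif baseline <= _BASELINE_FAIL:
            pass_expr[g] = False
        else:
            pass_expr[g] = None
        load = loadings.get(g, 0.0)
        if load >= _LOADING_PASS and baseline >= _BASELINE_PASS:
            representative[g] = True
        elif load == 0.0:
            representative[g] = False
        else:
            representative[g] = None
    return pass_expr, representative


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Draw a cohort-structured count matrix with an embedded module.

    Counts are negative-binomial with mean ``baseline_g * exp(loading_g *
    a_s)`` and gene-level dispersion ``spec.dispersion`` (variance
    ``mu + dispersion * mu^2``; dispersion 0 degrades to Poisson).  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    module_genes = list(spec.module.genes)
    bg_genes = [f"BG{i + 1:03d}" for i in range(spec.n_background_genes)]
    clash = set(bg_genes) & set(module_genes)
    if clash:
        raise ValidationError(f"background gene names clash with module: {clash}")
    genes = module_genes + bg_genes

    # background baselines: log-uniform over [5, 500); loadings 0
    bg_baselines = dict(
        zip(bg_genes, np.exp(rng.uniform(np.log(5.0), np.log(500.0), len(bg_genes))))
    )
    baselines = {**{g: float(spec.baselines[g]) for g in module_genes}, **bg_baselines}
    loadings = {
        **{g: float(spec.loadings[g]) for g in module_genes},
        **{g: 0.0 for g in bg_genes},
    }

    sample_ids, cohort_labels, activities = [], [], []
    for label, n, mean in spec.cohorts:
        a = rng.normal(mean, spec.activity_sd, size=n)
        activities.append(a)
        sample_ids.extend(f"{label}_s{j + 1:02d}" for j in range(n))
        cohort_labels.extend([label] * n)
    a_s = np.concatenate(activities)

    base = np.array([baselines[g] for g in genes])[:, None]
    load = np.array([loadings[g] for g in genes])[:, None]
    mu = base * np.exp(load * a_s[None, :])
    if spec.dispersion > 0:
        size = 1.0 / spec.dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)

    values = pd.DataFrame(counts.astype(float), index=genes, columns=sample_ids)
    annotations = pd.DataFrame(
        {"sample_id": sample_ids, "cohort": cohort_labels, "cell_type": "whole_blood"}
    ).set_index("sample_id")
    ds = ExpressionDataset(values=values, annotations=annotations, dataset_id="synthetic")

    pass_expr, representative = _expectation_labels(loadings, baselines)
    truth = SyntheticTruth(
        loadings={g: float(v) for g, v in loadings.items()},
        baselines={g: float(v) for g, v in baselines.items()},
        expected_pass_expression=pass_expr,
        expected_representative=representative,
        true_cumulative={},
        designed_winner=None,
    )
    return ds, truth


def simulate_score_tables(spec: ScoreSimSpec, scorer_id: str) -> list[ScoreTable]:
    """Replicate noisy score tables for one scorer.

    Each cell is ``clamp(round(true + Normal(0, noise_sd)), 0, 10)``.  The
    random stream is derived from ``(seed, scorer_id)`` so distinct scorers
    get independent noise while staying reproducible.
    """
    seq = np.random.SeedSequence([spec.seed, zlib.crc32(scorer_id.encode())])
    rng = np.random.default_rng(seq)
    true = spec.true_scores.to_numpy(dtype=float)
    tables = []
    for rep in range(spec.n_replicates):
        noisy = np.clip(np.round(true + rng.normal(0.0, spec.noise_sd, true.shape)), 0, 10)
        scores = pd.DataFrame(
            noisy, index=spec.true_scores.index, columns=list(CRITERION_CODES)
        )
        tables.append(ScoreTable(scorer_id=scorer_id, run_id=rep + 1, scores=scores))
    return tables


def default_scenario(seed: int = 0) -> tuple[ExpressionSimSpec, ScoreSimSpec, SyntheticTruth]:
    """The package's standard end-to-end scenario with full ground truth.

    The designed winner is the gene with the highest true cumulative score
    among genes expected to pass both data-driven filters.
    """
    expr_spec = ExpressionSimSpec(seed=seed)
    score_spec = ScoreSimSpec(seed=seed)
    pass_expr, representative = _expectation_labels(
        dict(expr_spec.loadings), dict(expr_spec.baselines)
    )
    cumulative = score_spec.true_scores.sum(axis=1).to_dict()
    eligible = [
        g
        for g in cumulative
        if pass_expr.get(g) is True and representative.get(g) is True
    ]
    winner = max(eligible, key=lambda g: (cumulative[g], g)) if eligible else None
    truth = SyntheticTruth(
        loadings={g: float(v) for g, v in expr_spec.loadings.items()},
        baselines={g: float(v) for g, v in expr_spec.baselines.items()},
        expected_pass_expression=pass_expr,
        expected_representative=representative,
        true_cumulative={g: float(v) for g, v in cumulative.items()},
        designed_winner=winner,
    )
    return expr_spec, score_spec, truth
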