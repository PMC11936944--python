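import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from modmarker.criteria import CRITERION_CODES
from modmarker.expression import ExpressionDataset
from modmarker.scores import ScoreTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_table(values: dict[str, list[float]], scorer_id="s", run_id=1, **kw) -> ScoreTable:
    """Build a ScoreTable from {gene: [six scores]}."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=list(CRITERION_CODES))
    return ScoreTable(scorer_id=scorer_id, run_id=run_id, scores=df, **kw)


def make_dataset(
    values: dict[str, list[float]],
    cohorts: list[str] | None = None,
    dataset_id: str = "test",
) -> ExpressionDataset:
    """Build an ExpressionDataset from {gene: sample values}."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    samples = [f"s{i + 1}" for i in range(df.shape[1])]
    df.columns = samples
    if cohorts is None:
        cohorts = ["c1"] * len(samples)
    ann = pd.DataFrame({"sample_id": samples, "cohort": cohorts}).set_index("sample_id")
    return ExpressionDataset(values=df, annotations=ann, dataset_id=dataset_id)


@pytest.fixture
def score_csv(tmp_path):
    """A valid six-criterion score CSV with three genes."""
    path = tmp_path / "scores.csv"
    path.write_text(
        "gene,crit_a,crit_b,crit_c,crit_d,crit_e,crit_f\n"
        "CD38,9,8,9,9,10,10\n"
        "TNFRSF17,9,8,9,9,9,9\n"
        "IGJ,10,6,5,7,3,4\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
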