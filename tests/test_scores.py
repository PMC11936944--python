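"""Knowledge-score ingestion, aggregation, ranking, pooling, consistency."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modmarker.criteria import CRITERION_CODES
from modmarker.errors import SchemaError, ValidationError
from modmarker.scores import (
    EvidenceRecord,
    apply_revisions,
    average_replicates,
    average_scorers,
    cumulative_scores,
    load_score_table,
    pool_candidates,
    rank_genes,
    run_consistency,
    top_k,
)

from conftest import make_table

genes_strategy = st.lists(
    st.text(alphabet="ABCDEFGHIJ", min_size=2, max_size=6), min_size=1, max_size=8, unique=True
)
score_row = st.lists(
    st.floats(min_value=0, max_value=10, allow_nan=False), min_size=6, max_size=6
)


@st.composite
def score_values(draw, min_genes=1, max_genes=8):
    genes = draw(genes_strategy.filter(lambda g: min_genes <= len(g) <= max_genes))
    return {g: draw(score_row) for g in genes}


class TestLoadScoreTable:
    def test_parses_values(self, score_csv):
        table = load_score_table(score_csv, scorer_id="gpt", run_id=1)
        assert list(table.scores.loc["CD38"]) == [9, 8, 9, 9, 10, 10]
        assert table.scorer_id == "gpt" and table.run_id == 1
        assert table.genes == ("CD38", "TNFRSF17", "IGJ")

    def test_missing_criterion_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("gene,crit_a,crit_b,crit_c,crit_d,crit_e\nCD38,1,2,3,4,5\n")
        with pytest.raises(SchemaError, match="crit_f"):
            load_score_table(path, scorer_id="s", run_id=1)

    def test_out_of_range_score_names_gene_and_criterion(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "gene,crit_a,crit_b,crit_c,crit_d,crit_e,crit_f\nGENE1,11,0,0,0,0,0\n"
        )
        with pytest.raises(ValidationError, match="GENE1.*A"):
            load_score_table(path, scorer_id="s", run_id=1)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "gene,crit_a,crit_b,crit_c,crit_d,crit_e,crit_f\n"
            "CD38,1,1,1,1,1,1\ncd38,2,2,2,2,2,2\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_score_table(path, scorer_id="s", run_id=1)

    def test_symbols_upper_cased(self, tmp_path):
        path = tmp_path / "lc.csv"
        path.write_text("gene,crit_a,crit_b,crit_c,crit_d,crit_e,crit_f\ncd38,1,1,1,1,1,1\n")
        table = load_score_table(path, scorer_id="s", run_id=1)
        assert table.genes == ("CD38",)

    def test_roundtrip_to_csv(self, score_csv, tmp_path):
        table = load_score_table(score_csv, scorer_id="s", run_id=1)
        out = tmp_path / "out.csv"
        table.to_csv(out)
        again = load_score_table(out, scorer_id="s", run_id=1)
        pd.testing.assert_frame_equal(table.scores, again.scores)


class TestAveraging:
    def test_replicate_mean(self):
        tables = [make_table({"CD38": [s, 0, 0, 0, 0, 0]}) for s in (9, 10, 8)]
        avg = average_replicates(tables)
        assert avg.scores.loc["CD38", "A"] == 9.0
        assert avg.run_id == "averaged"

    def test_single_table_identity(self):
        t = make_table({"CD38": [1, 2, 3, 4, 5, 6]})
        avg = average_replicates([t])
        pd.testing.assert_frame_equal(avg.scores, t.scores)

    def test_midpoint(self):
        tables = [make_table({"X": [0] * 6}), make_table({"X": [10] * 6})]
        assert (average_replicates(tables).scores.loc["X"] == 5.0).all()

    def test_mismatched_gene_sets_list_difference(self):
        with pytest.raises(ValidationError, match="\\['B', 'C'\\]"):
            average_replicates(
                [make_table({"A": [1] * 6, "B": [1] * 6}), make_table({"A": [1] * 6, "C": [1] * 6})]
            )

    def test_mixed_scorers_rejected(self):
        with pytest.raises(ValidationError, match="multiple scorers"):
            average_replicates(
                [make_table({"A": [1] * 6}, scorer_id="x"), make_table({"A": [1] * 6}, scorer_id="y")]
            )

    @given(score_values(min_genes=2, max_genes=5), st.permutations(range(3)))
    def test_replicate_average_permutation_invariant(self, values, order):
        tables = [
            make_table({g: [min(10, v + i) for v in row] for g, row in values.items()})
            for i in range(3)
        ]
        base = average_replicates(tables).scores
        shuffled = average_replicates([tables[i] for i in order]).scores
        pd.testing.assert_frame_equal(base, shuffled)

    def test_scorer_consensus_mean_and_id(self):
        a = make_table({"X": [8] * 6}, scorer_id="a")
        b = make_table({"X": [9] * 6}, scorer_id="b")
        consensus = average_scorers([a, b])
        assert (consensus.scores.loc["X"] == 8.5).all()
        assert consensus.scorer_id == "consensus-mean"

    def test_scorer_consensus_identical_inputs_idempotent(self):
        a = make_table({"X": [3, 4, 5, 6, 7, 8]}, scorer_id="a")
        b = make_table({"X": [3, 4, 5, 6, 7, 8]}, scorer_id="b")
        pd.testing.assert_frame_equal(average_scorers([a, b]).scores, a.scores)

    def test_scorer_consensus_restricts_to_intersection(self):
        a = make_table({"X": [1] * 6, "Y": [2] * 6}, scorer_id="a")
        b = make_table({"Y": [4] * 6, "Z": [5] * 6}, scorer_id="b")
        consensus = average_scorers([a, b])
        assert consensus.genes == ("Y",)
        assert (consensus.scores.loc["Y"] == 3.0).all()

    def test_scorer_consensus_empty_intersection_rejected(self):
        a = make_table({"X": [1] * 6}, scorer_id="a")
        b = make_table({"Y": [1] * 6}, scorer_id="b")
        with pytest.raises(ValidationError, match="no genes"):
            average_scorers([a, b])

    def test_scorer_consensus_needs_two_tables(self):
        with pytest.raises(ValidationError):
            average_scorers([make_table({"X": [1] * 6})])


class TestCumulativeAndRanking:
    @pytest.mark.parametrize(
        "row,expected",
        [([10] * 6, 60.0), ([0] * 6, 0.0), ([9, 8, 9, 9, 10, 10], 55.0)],
    )
    def test_cumulative_sum(self, row, expected):
        assert cumulative_scores(make_table({"G": row}))["G"] == expected

    def test_cumulative_weights_hook(self):
        table = make_table({"G": [1, 1, 1, 1, 1, 1]})
        weighted = cumulative_scores(table, weights={"A": 2.0})
        assert weighted["G"] == 7.0

    @given(score_values(min_genes=1, max_genes=6), st.sampled_from(CRITERION_CODES))
    def test_cumulative_monotone_in_any_criterion(self, values, code):
        # cap at 9 so a +1 bump stays inside the score range
        table = make_table({g: [min(v, 9.0) for v in row] for g, row in values.items()})
        gene = table.genes[0]
        bumped = table.scores.copy()
        bumped.loc[gene, code] += 1.0
        higher = make_table({g: list(bumped.loc[g]) for g in table.genes})
        assert cumulative_scores(higher)[gene] > cumulative_scores(table)[gene]

    def test_rank_two_elements(self):
        assert rank_genes({"A": 10, "B": 20}).genes == ("B", "A")

    def test_rank_tie_breaks_lexicographic(self):
        assert rank_genes({"B": 10, "A": 10}).genes == ("A", "B")

    def test_rank_matches_brute_force_sort(self, rng):
        scores = {f"G{i:02d}": float(s) for i, s in enumerate(rng.choice(600, 17, replace=False))}
        oracle = [g for g, _ in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))]
        assert list(rank_genes(scores).genes) == oracle

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValidationError):
            rank_genes({})

    def test_top_k_prefix(self):
        ranked = rank_genes({"B": 3, "A": 2, "C": 1})
        assert top_k(ranked, 2) == ["B", "A"]
        assert top_k(ranked, 3) == ["B", "A", "C"]

    def test_top_k_bounds(self):
        ranked = rank_genes({"A": 1})
        with pytest.raises(ValueError):
            top_k(ranked, 2)
        with pytest.raises(ValueError):
            top_k(ranked, 0)

    @given(score_values(min_genes=1, max_genes=8))
    def test_rank_then_full_top_k_is_permutation(self, values):
        table = make_table(values)
        ranked = rank_genes(cumulative_scores(table))
        assert sorted(top_k(ranked, len(values))) == sorted(values)


class TestPooling:
    def test_identical_selections_keep_provenance(self):
        picks = ["CD38", "TNFRSF17", "IGJ", "TOP2A", "TYMS"]
        pool = pool_candidates([("gpt", picks), ("claude", picks)])
        assert pool.genes == frozenset(picks)
        assert all(pool.provenance[g] == ("gpt", "claude") for g in picks)

    def test_disjoint_union(self):
        pool = pool_candidates([("a", ["G1", "G2", "G3", "G4", "G5"]),
                                ("b", ["H1", "H2", "H3", "H4", "H5"])])
        assert len(pool.genes) == 10

    def test_single_selection_identity(self):
        pool = pool_candidates([("a", ["X", "Y"])])
        assert pool.genes == frozenset({"X", "Y"})

    @given(
        st.lists(
            st.lists(st.sampled_from([f"G{i}" for i in range(12)]), min_size=3,
                     max_size=3, unique=True),
            min_size=1,
            max_size=5,
        )
    )
    def test_pool_size_bounds(self, selections):
        k, n = 3, len(selections)
        pool = pool_candidates([(f"s{i}", sel) for i, sel in enumerate(selections)])
        assert k <= len(pool.genes) <= k * n


class TestConsistency:
    def test_identical_tables_correlate_perfectly(self):
        t = make_table({"A": [1, 2, 3, 4, 5, 6], "B": [6, 5, 4, 3, 2, 1]})
        m = run_consistency([t, t]).values.to_numpy()
        assert m[0, 1] == pytest.approx(1.0)

    def test_reflection_anticorrelates(self):
        t = make_table({"A": [1, 2, 3, 4, 5, 6]})
        reflected = make_table({"A": [10 - v for v in [1, 2, 3, 4, 5, 6]]}, run_id=2)
        m = run_consistency([t, reflected]).values.to_numpy()
        assert m[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_pair_undefined_with_warning(self):
        flat = make_table({"A": [5] * 6})
        varied = make_table({"A": [1, 2, 3, 4, 5, 6]}, run_id=2)
        with pytest.warns(UserWarning, match="zero-variance"):
            m = run_consistency([flat, varied]).values.to_numpy()
        assert math.isnan(m[0, 1]) and m[0, 0] == 1.0

    @given(st.lists(score_values(min_genes=2, max_genes=5), min_size=2, max_size=4))
    def test_matches_brute_force_pairwise_correlation(self, tables_values):
        genes = sorted(tables_values[0])
        tables_values = [{g: tv.get(g, [1, 2, 3, 4, 5, 6]) for g in genes} for tv in tables_values]
        tables = [make_table(tv, run_id=i + 1) for i, tv in enumerate(tables_values)]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # constant tables
            matrix = run_consistency(tables).values.to_numpy()

        def brute_pearson(x, y):
            mx, my = sum(x) / len(x), sum(y) / len(y)
            cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
            vx = sum((a - mx) ** 2 for a in x)
            vy = sum((b - my) ** 2 for b in y)
            if vx == 0 or vy == 0:
                return float("nan")
            return cov / math.sqrt(vx * vy)

        vectors = [
            [v for g in sorted(tv) for v in tv[g]] for tv in tables_values
        ]
        for i in range(len(tables)):
            for j in range(len(tables)):
                expected = 1.0 if i == j else brute_pearson(vectors[i], vectors[j])
                got = matrix[i, j]
                if math.isnan(expected):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-10)


class TestRevisions:
    def test_empty_revision_list_is_identity(self):
        t = make_table({"CD38": [1, 2, 3, 4, 5, 6]})
        pd.testing.assert_frame_equal(apply_revisions(t, []).scores, t.scores)

    def test_point_update_touches_only_target_cell(self):
        t = make_table({"CD38": [9, 8, 9, 9, 10, 10], "IGJ": [1] * 6})
        revised = apply_revisions(
            t, [("CD38", "A", 10, EvidenceRecord(justification="curated"))]
        )
        assert revised.scores.loc["CD38", "A"] == 10
        diff = (revised.scores != t.scores).to_numpy().sum()
        assert diff == 1
        assert revised.evidence[("CD38", "A")].verification_status == "revised"

    def test_out_of_range_revision_rejected(self):
        t = make_table({"CD38": [1] * 6})
        with pytest.raises(ValidationError, match="out of range"):
            apply_revisions(t, [("CD38", "A", 12, EvidenceRecord(justification="x"))])

    def test_unknown_gene_rejected(self):
        t = make_table({"CD38": [1] * 6})
        with pytest.raises(ValidationError, match="unknown gene"):
            apply_revisions(t, [("NOPE", "A", 5, EvidenceRecord(justification="x"))])

    def test_revision_requires_justification(self):
        t = make_table({"CD38": [1] * 6})
        with pytest.raises(ValidationError, match="justification"):
            apply_revisions(t, [("CD38", "A", 5, EvidenceRecord())])


def test_evidence_record_status_vocabulary():
    with pytest.raises(ValidationError):
        EvidenceRecord(verification_status="maybe")
    assert EvidenceRecord(verification_status="verified").verification_status == "verified"
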