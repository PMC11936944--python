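# modmarker

Selection of a representative marker gene from a blood transcriptional
co-expression module, combining knowledge-driven criterion scoring with
data-driven expression filters.

## The problem

Targeted transcriptional profiling assays measure small panels of transcripts
instead of whole transcriptomes. When a panel slot is meant to represent a
whole co-expression module — for example the plasma-cell-associated module
M12.15 (aggregate A27) of the BloodGen3 blood-transcriptome repertoire — one
gene must stand in for the coordinated behaviour of all of the module's
members. Picking that gene requires balancing two very different kinds of
evidence:

1. **Knowledge-driven** — each candidate gene is scored 0–10 on six fixed
   criteria (association with plasma cell responses; circulating-leukocyte
   biology; clinical biomarker use; blood transcriptional biomarker
   potential; drug-target status; therapeutic relevance for immune-mediated
   disease). Scoring runs are replicated and averaged, genes are ranked by
   their cumulative score `S_g = Σ_c s_{gc}` (range 0–60), each scorer's
   top-k candidates are pooled, and a consensus score orders the pool.
2. **Data-driven** — two filters applied to reference expression datasets:
   * *expression eligibility*: a gene is measurable in a targeted assay when
     its median normalized count is ≥ 50 and it exceeds 15 counts in ≥ 50 %
     of samples;
   * *module representativeness*: within each reference cohort the gene's
     expression is correlated (Pearson) with the per-sample module-average
     expression; a gene passes when its median correlation across cohorts is
     ≥ 0.5, at least 50 % of cohorts exceed 0.5, and its median is not a
     Tukey low outlier (below Q1 − 1.5·IQR of the per-gene medians).

The final tiering makes representativeness a hard gate and eligibility a
configurable gate (by default passing in *any* one dataset suffices); the
consensus knowledge score then orders the survivors into one
`top_candidate` and `alternative`s, with gated genes `flagged`.

Because the original study inputs (LLM score tables, GEO cohort datasets)
cannot ship with a package, `modmarker` includes a first-class synthetic-data
generator: negative-binomial count matrices with an embedded co-expressed
module driven by a latent per-sample activity, and replicate noisy score
tables — both with known ground truth, so every stage is testable end to end.

## Worked example

```bash
modmarker simulate --outdir study --seed 1
modmarker prioritize --config study/config.yaml --outdir study/pipe
```

prints

```
wrote synthetic study (200 genes x 160 samples) to study
top candidate: CD38
alternatives: TNFRSF17, IGJ
flagged: UBE2C, ABCB9
report written to study/pipe
```

The simulated study embeds the 17-gene M12.15 module across 16 cohorts of 10
samples. By design, UBE2C carries the highest true knowledge score but has
zero module loading (its expression ignores the module activity), and ABCB9
scores highly but is simulated at a baseline of ~2 counts: the pipeline
flags UBE2C at the representativeness gate and ABCB9 at the eligibility
gate, leaving CD38 — the best-scoring gene that passes both filters — as the
top candidate, with TNFRSF17 and IGJ as alternatives. `study/pipe/` contains
the per-scorer averaged tables, consensus ranking, per-dataset eligibility
and correlation reports, the final `report.csv`/`report.json`, and a
deterministic decision log.

The same subcommands work on real data: a TSV expression matrix (genes ×
samples), a sample-annotation TSV (`sample_id, cohort, cell_type`), a GMT
module file and score CSVs (`gene,crit_a,…,crit_f`). See also
`filter-expression`, `filter-correlation`, `aggregate-scores` and `report`.

## Layout

- `src/modmarker/scores.py` — score tables, replicate/scorer averaging,
  ranking, pooling, run-consistency, expert revisions
- `src/modmarker/expression.py` — expression datasets and the eligibility
  filter
- `src/modmarker/representativeness.py` — module-average correlation
  profiles and the representativeness filter
- `src/modmarker/simulate.py` — synthetic expression and score generators
  with ground truth
- `src/modmarker/pipeline.py`, `src/modmarker/cli.py` — orchestration,
  tiering, reports, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
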