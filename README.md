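# sensbias

Simulation and estimation pipeline for feedback-driven self-evaluation
updating. An agent holds a self-evaluation `a` on a 1–100 scale and, on
receiving a feedback `f`, moves a fraction `h(a)` of the gap:
`a' = a + h(a) (f - a)`. When the sensitivity `h` decreases with `a`,
balanced pairs of opposite feedbacks drift the self-evaluation upward — a
purely statistical positive bias that adds to any asymmetry between the
reactions to positive and negative feedbacks. This package provides:

- **`sensbias.model`** — sensitivity curves (linear / constant / logistic)
  and closed-form bias predictions: exact and first-order pair bias,
  enhancement gap, order-averaged drift, and the noisy-feedback drift
  `-h' h² · var`, with a seeded Monte-Carlo simulator to check them.
- **`sensbias.cohort`** — a synthetic cohort generator following the
  experimental protocol: low/high anchors (1/3 vs 2/3), the six balanced
  sign sequences, feedbacks `a ± (13 ± 1)` truncated to [1, 100], responses
  constrained between the previous self-evaluation and the feedback, rank
  and score scale conditions, and participant/group-level curve variation.
- **`sensbias.data`** — triples CSV I/O with invariant validation, the
  rank→score transform (`100 - r`), the exclusion filter for participants
  with truncated (unbalanced) feedback series, and subset selection by
  trust / time step / scale / gender / self-esteem / interview time.
- **`sensbias.estimators`** — OLS and mixed-effects (random intercept, ML)
  regressions of `|Δa|/δ` on `a/100`, and the bias decomposition: total
  bias `B`, enhancement bias `E`, measured sensitivity bias `S = B - E`,
  and its closed-form counterpart `S'`, all as percent of feedback
  intensity.
- **`sensbias.resampling`** — triple-level and participant-level (series
  preserving) bootstrap, and effect sizes `|m1 - m2| / σ1`.
- **`sensbias.cli`** — `simulate`, `analyze`, `validate` subcommands.

## CLI

```sh
# simulate a cohort (config is optional YAML with CohortConfig fields)
sensbias simulate --config config.yaml --seed 1 --out data/

# slope tables (trust x time-step grids, OLS + mixed), per-step slopes,
# and the bootstrap bias decomposition
sensbias analyze --data data/ --out results/ --seed 0

# schema/invariant checks and exclusion counts
sensbias validate --data data/
```

`analyze` accepts `--criteria criteria.yaml`, a YAML list of subset blocks,
e.g. `- {name: score_women, scale: score, gender: female}`.

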