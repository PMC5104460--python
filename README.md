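# infoseek

Exact model, optimal-policy solver and bias analyses for a paid
information-sampling card game, plus the companion approach-avoidance
risky-choice model.

The task: two rows of two cards (values uniform on 1–10, dealt with
replacement; tied boards are re-dealt). The first card is free; its row is
"row A". Subjects then either buy further cards at escalating costs
(10/15/20 points) or gamble on the winning row (+60 correct / −50 wrong, net
of costs). Six conditions cross three row scores (sum, product, single
card) with two goals (biggest, smallest).

## What is in here

| module | contents |
|---|---|
| `infoseek.task_engine` | states, actions, transitions, payoffs, exact win probabilities (tie-excluded enumeration) |
| `infoseek.optimal_dp` | backward-induction Q-tables per condition, expected sampling depth, optimal-policy replay, subjective-cost variant |
| `infoseek.bias_statistics` | aggregate choice tables; positive-evidence-approach, rejecting-unsampled-options and sampling-the-favorite statistics; gameplay-level bootstrap CIs; sampling-depth trait measure with retest correlation |
| `infoseek.parametric_model` | reduced (β1–β3, τ) and full (+β4–β6) softmax choice models: prediction, multi-start SSE fitting, 10-fold cross-validation, hierarchical (empirical Bayes) population fit with β4/β5/β6 correlations |
| `infoseek.pavlovian_gamble` | biased-softmax risky-choice model (β_gain, β_loss), per-subject ML fitting, approach-index median split |
| `infoseek.synthetic_data` | agent populations (optimal / always-guess / parametric) playing the exact task, gamble populations, and linked populations sharing an approach factor |
| `infoseek.cli_io` | trial-level CSV schema with validation, readers/writers, config-driven pipeline, CLI |

## CLI

```bash
infoseek solve --condition multiply_big --extra-cost 0 --out qtable.csv
infoseek simulate --n 1000 --policy PARAMETRIC_FULL --pair multiply \
    --seed 42 --out plays.csv
infoseek stats --input plays.csv --pair multiply --stat pea \
    --trial-type AB --boot 1000 --seed 1
infoseek fit --input plays.csv --pair add --stage 1 --model full \
    --restarts 50 --seed 7
infoseek cv --input plays.csv --pair multiply --stage 1 --folds 10
infoseek hierfit --input plays.csv --pair multiply
infoseek gamble-fit --input gambles.csv --seed 3
infoseek report --config config.yaml --out-dir out/
```

`report` runs simulate/load → solve → aggregate → statistics (+bootstrap) →
fits from a YAML config and writes a fully reproducible bundle (tables,
statistics, fits, config echo).

## Conventions worth knowing

- **Ties**: every probability is conditional on the final board being
  non-tied (tied deals are re-dealt). This convention is what reproduces
  the worked-example numbers exactly.
- **Row A** is always the row of the first revealed card; the stage-1 offer
  is uniform over the three face-down cards (P(AA) = 1/3).
- **Softmax gain**: choice probabilities are ∝ exp(V·τ), τ ≥ 0. Model
  predictions identify the products τ·β almost exactly, so recovery is
  assessed on those products; fits are canonicalized to τ ≥ 0.
- The statistics and fits cover the ADD and MULTIPLY pairs only; the
  single-card conditions are not matched for information content and are
  rejected explicitly.
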