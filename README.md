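# impa — Improved Marine Predators Algorithm for CNN hyperparameter optimization

`impa` implements the **Improved Marine Predators Algorithm** (IMPA): the
marine predators metaheuristic (MPA) augmented with **opposition-based
learning** (OBL), packaged as a reusable optimizer for bounded mixed-type
hyperparameter spaces, together with the transfer-learning classification
harness and metric suite it was designed to drive. The motivating
application is two-class mammography screening (normal/abnormal), where the
optimizer tunes eight hyperparameters of a fine-tuned convolutional
classifier; a seeded synthetic image generator lets the whole pipeline run
end to end on a laptop in seconds.

It is intended for researchers who want a reproducible, well-tested
reference implementation of the IMPA — either as a black-box optimizer for
their own objectives, or as a complete hyperparameter-search pipeline for
small two-class image problems.

## The algorithm

MPA evolves a population of `N` candidate *prey* positions against an
*Elite* matrix that replicates the best position found so far. The
iteration budget `it_max` is split into three velocity regimes:

1. **High velocity** (first third, exploration) — Brownian steps:
   `step = R_B ⊙ (Elite − R_B ⊙ prey)`, `prey += P·R ⊙ step`;
2. **Unit velocity** (middle third) — the first half of the population
   takes Lévy-flight steps around its own positions while the second half
   takes Brownian steps anchored at the Elite, damped by
   `CF = (1 − it/it_max)^(2·it/it_max)`;
3. **Low velocity** (final third, exploitation) — Lévy steps anchored at
   the Elite: `prey = Elite + P·CF·R_L ⊙ (R_L ⊙ Elite − prey)`.

Each iteration ends with a FADs (fish-aggregating-devices) perturbation —
an occasional long jump with probability 0.2 — plus rowwise *memory
saving* (keep the better of each row's current and previous position) and
an Elite update. Lévy steps use Mantegna's construction with tail index
1.5; `P = 0.5`.

The *improved* variant adds OBL: the mirror image `lb + ub − x` of every
candidate is scored at initialization and after every iteration, and each
row keeps the fitter of the pair. This costs `N·(3·it_max + 2)` objective
evaluations per run versus `N·(2·it_max + 1)` for plain MPA — the extra
cost buys faster convergence from poor initializations.

For CNN tuning the search space is 8-dimensional: learning rate
(`[1e−7, 1e−3]`, searched in log10), batch size (`[1, 64]`), three dropout
rates (`[0.1, 0.9]`) and three dense-layer widths (`[50, 500]`). The
fitness of a position is `1 − validation accuracy` of a two-stage transfer
training run (frozen backbone first, last two convolutional blocks
unfrozen afterwards) under a reduced epoch budget.

## Worked example

Optimize the 8-D sphere with the published parameter settings
(population 30, 50 iterations):

```bash
$ impa optimize-bench --objective sphere --dimension 8 \
      --n-agents 30 --it-max 50 --seed 1 --out-dir demo_run
impa on sphere: best fitness 9.55534e-06 (4560 evaluations)
```

The best sphere value after 4560 evaluations is ~1e−5 (the optimum is 0),
and `demo_run/convergence.csv` traces the best-so-far fitness per
iteration. The evaluation count is exactly `30·(3·50 + 2) = 4560` — the
IMPA schedule's closed form, asserted on every run.

The metric suite reproduces the improvement arithmetic used when
comparing an optimized model against a manually configured baseline:

```python
>>> from impa.metrics import MetricsReport, improvement
>>> opt  = MetricsReport(0.9832, 0.9661, 0.9856, 0.9868, 0.9765, 0.9788)
>>> base = MetricsReport(0.9011, 0.8980, 0.9033, 0.8901, 0.9000, 0.9188)
>>> improvement(opt, base)
{'accuracy': 8.21, 'sensitivity': 6.81, 'specificity': 8.23, 'precision': 9.67, 'f1': 7.65, 'auc': 6.0}
```

i.e. the optimized model is 8.21 accuracy percentage points better than
its baseline, 6.00 points better in AUC, and so on.

The full pipeline on synthetic images — generate a blob-vs-texture image
set, search the 8-D space with IMPA, train the best configuration, report
the six test-set metrics:

```bash
impa optimize-cnn --seed 0 --out-dir cnn_run
```

## Package layout

| module | contents |
| --- | --- |
| `impa.search_space` | mixed-type bounded dimensions, uniform sampling, position decoding, clamping |
| `impa.mpa_core` | Brownian/Lévy step samplers, the three velocity phases, CF schedule, FADs, memory saving, Elite update |
| `impa.opposition` | opposite points/populations, greedy fitness merge |
| `impa.driver` | IMPA/MPA/random-search loops, evaluation accounting, optimizer comparison harness |
| `impa.classifier` | surrogate backbone, 8-layer head, augmentation, two-stage transfer training, fitness function |
| `impa.nn` | minimal numpy conv/dense network engine with manual backprop |
| `impa.metrics` | confusion counts, Acc/Sn/Sp/Pr, macro F-score, rank-sum AUC, improvement tables, dataset accounting |
| `impa.synthetic` | benchmark objectives, seeded two-class image generator, PNG directory layout IO |
| `impa.cli` | `impa optimize-bench / optimize-cnn / evaluate / report` |

See `docs/methods.md` for the scientific background, modelling choices and
limitations.
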