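# histotune

Metaheuristic hyperparameter search for transfer-learning image
classifiers, built around the binary histopathology task of telling
normal oral tissue from oral squamous cell carcinoma (OSCC) in stained
patch images.

Manually tuning a transfer-learning (TL) classifier means choosing a loss
function, batch size, dropout rate, how much of the pretrained network to
adapt, a weight optimizer, an intensity scaling, and whether/how to augment
the data — a mixed categorical/continuous space far too large for grid
search. `histotune` encodes that space on the unit hypercube and searches
it with two population-based optimizers:

* the **Aquila Optimizer (AO)**, whose four hunting-inspired moves switch
  from exploration to exploitation at `t ≤ (2/3)·T_max`, and
* the **artificial Gorilla Troops Optimizer (GTO)**, with migration,
  follow-a-gorilla and dimension-mix exploration plus silverback-following
  and competition exploitation.

Each candidate solution `x ∈ [0,1]^D` (D = 7, or 15 when the augmentation
operators are searched too) is decoded by the span-index mapping
`index = clamp(⌈x_d · L_d⌉, 1, L_d)` over each hyperparameter's ordered
options (continuous spans map linearly), evaluated by a pluggable fitness
backend, and scored with a 12-metric suite — accuracy, F1, precision,
recall, specificity, AUC, sensitivity, IoU, Dice, cosine similarity,
Youden index (sensitivity + specificity − 100%), NPV — combined by an
equal-weight sum `WS = (1/12) Σ metrics`. Metrics are computed from
micro-averaged confusion counts (for two classes this forces TP = TN and
FP = FN).

Two fitness backends ship with the package, so the optimizer stack is
fully testable at desk scale with no downloads:

* a **surrogate backend** — a deterministic analytic landscape peaked at a
  designated optimal configuration, for validating the optimizers against
  a known ground truth;
* a **tiny trainable backend** — a small built-in convolutional softmax
  classifier (fixed random "pretrained" backbone, partially trainable
  hidden layer) that honors the decoded batch size, dropout, loss
  function, weight optimizer (all 11 searched rules) and TL learn ratio.

A seeded synthetic image generator produces two-class RGB patch sets with
a controllable class signal, emulating the shape/label contract of the
histopathology data.

## Worked example

Search the 7-dimensional core space with GTO on a synthetic imageset,
using the surrogate backend (3 independent restarts):

```sh
histotune --algorithm GTO --backend surrogate \
          --n-solutions 15 --t-max 100 --repetitions 3 \
          --seed 0 --n-per-class 12 --output-dir out/demo
```

prints

```
best fitness: 98.5714
best configuration: {"loss_function": "kl_divergence", "batch_size": 24,
  "dropout": 0.3, "tl_learn_ratio": 50, "parameter_optimizer": "ftrl",
  "scaling_technique": "standard", "apply_augmentation": false}
```

The surrogate's designated optimum is KL divergence / batch 24 /
dropout 0.3 / learn ratio 50 / SGD-Nesterov / standardization / no
augmentation, worth fitness 100. The run above recovers every
hyperparameter except the weight optimizer, which lands one option away
(fitness 98.57 = 100 − (1/7)·(1/10)·100). `out/demo/` contains the best
configuration JSON, a metric report CSV (12 metrics + weighted sum as
rows), the per-iteration best-fitness history, and a per-repetition
summary (`summary.csv`: best fitness 90.76 / 97.14 / 98.57 for seeds
0/1/2).

The same search as a scikit-learn style estimator:

```python
from histotune import MetaheuristicSearch, SyntheticImageSpec, make_synthetic_imageset
import numpy as np

records = make_synthetic_imageset(SyntheticImageSpec(n_per_class=(60, 60), size=(32, 32), seed=11))
X = np.stack([r.pixels for r in records]).astype(float)
y = np.array([r.label for r in records])
search = MetaheuristicSearch(algorithm="AO", backend="tiny", n_solutions=5,
                             t_max=2, epochs=5, random_state=1).fit(X, y)
search.best_config_    # decoded winning configuration
search.best_score_     # its test-partition accuracy (%)
search.predict(X)      # predictions from the refit best classifier
```

Decoding worked example: a normalized element of 0.75 over the batch-size
span 4→48 (step 4, 12 options) gives index ⌈0.75·12⌉ = 9, i.e. batch
size 36:

```python
>>> from histotune import build_default_space, decode_element
>>> decode_element(0.75, build_default_space(True).span("batch_size"))
36
```

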