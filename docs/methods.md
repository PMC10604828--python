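# Methods

## Problem setting

`histotune` frames transfer-learning configuration for a binary
histopathology classifier (normal vs OSCC patches) as a continuous
optimization problem. Every hyperparameter is a *span*: an ordered option
list (categorical, stepped-numeric, boolean) or a continuous interval. A
candidate is a vector on the unit hypercube; population-based
metaheuristics move candidates, and a decode step turns each coordinate
into a concrete hyperparameter value before evaluation.

## The search space and decode rule

The default space, in order: loss function (6 options), batch size
(4→48 step 4, 12 options), dropout ([0, 0.6]), TL learn ratio (1→100
step 1), weight optimizer (11 options), intensity scaling (4 options),
augmentation on/off — 7 dimensions; with the searched augmentation block
(rotation 0–45°, width/height shift, shear, zoom in [0, 0.25], two flip
booleans, brightness) it is 15.

Discrete decode uses a 1-based ceiling with clamping:
`index = clamp(⌈v·L⌉, 1, L)`. The rounding rule is chosen because it
reproduces the only fully worked mapping available for this space
(0.75 over 12 options → index 9 → batch 36) exactly; a value of exactly 0
clamps to index 1. Continuous spans map linearly,
`lower + v·(upper − lower)`. Boolean spans decode in order [yes, no], so
all-zero vectors enable every boolean. Out-of-bounds vectors are repaired
by clamping to [0, 1] (idempotent, deterministic); resampling repair was
rejected as needlessly stochastic.

The brightness coordinate must yield a `(low, high)` multiplier pair from
one element. We use `low = 0.5 + v·1.5`, `high = low + v·(2.0 − low)`:
deterministic, reproducing the degenerate `(0.5, 0.5)` pair at `v = 0`.
Any single-element rule is a projection of a two-degree-of-freedom pair;
reported pairs from runs elsewhere suggest an extra random draw that we
deliberately do not emulate, favoring reproducibility.

In the 7-D space the augmentation gate is still searched; when it decodes
to "yes" the fixed balancing magnitudes (rotation 30°, shifts/shear/zoom
0.2, brightness [0.8, 1.2], both flips) are used.

## Optimizers

Both algorithms maximize fitness over `[0,1]^D`, use greedy acceptance
(a candidate replaces its member only when strictly better) and clipping
repair. Greedy acceptance makes the best-so-far fitness monotone; ranking
(stable, best first) precedes every update sweep.

**Aquila Optimizer.** Exploration while `t ≤ (2/3)·T_max`, exploitation
after; within each phase the two moves are chosen by a fair coin per
member (the choice rule is unspecified in the source formulations; a fair
coin is the natural uninformative default). Moves:

* expanded exploration `X1 = X_best·(1 − t/T) + (X_M − X_best·r)`;
* narrowed exploration `X2 = X_best·Levy(D) + X_R + (y − x)·r`, with the
  spiral terms `x = r_s·sin θ`, `y = r_s·cos θ`, `r_s = r1 + U·d`,
  `θ = −ω·d + 3π/2` over dimension index `d`, `U = 0.00565`, `ω = 0.005`,
  `r1 = 10`;
* expanded exploitation `X3 = (X_best − X_M)·α − r + ((UB−LB)·r′ + LB)·δ`
  with `α = δ = 0.1` (one widely printed variant of this move is
  dimensionally inconsistent; the consistent original form is used);
* narrowed exploitation `X4 = QF·X_best − G1·X·r − G2·Levy(D) + r·G1`,
  `QF = t^((2r−1)/(1−T)²)` (set to 1 when `T = 1`), `G1 = 2r − 1`,
  `G2 = 2(1 − t/T)`.

Lévy steps use the Mantegna algorithm with stability index `β = 1.5`
(σ ≈ 0.6966) and scale `s = 0.01`.

**Gorilla Troops Optimizer.** Per iteration an exploration sweep — with
probability `p = 0.03` migration to a fresh uniform point; else, on a fair
coin, a move toward a random member (`L·H + (r2 − C)·X_r`, `H = Z·X`,
`Z ~ U(−C, C)`) or a dimension mix
(`X − L·(L·(X − X_r) + r3·(X − X_r))`) — followed by an exploitation
sweep: follow the silverback (`L·M·(X − X_sb) + X`,
`M = (|mean X|^g)^{1/g}`, `g = 2^L`) when `C ≥ W = 0.8`, otherwise
competition (`X_sb − (X_sb·Q − X·Q)·A`, `Q = 2r − 1`, `A = β·E`,
`β = 3`, `E` a normal vector or scalar with probability ½ each). Here
`C = F·(1 − t/T)` with `F = cos(2r4) + 1` and `L = C·l`, `l ~ U(−1, 1)`.
GTO therefore evaluates `2N` candidates per iteration where AO evaluates
`N`; comparisons against random search always use the actually consumed
evaluation count.

Only the headline update equations of the two algorithms are fixed by the
problem statement; all auxiliary quantities above follow the original
published formulations and defaults.

Empirically (see the test suite) both optimizers drive the 5-D sphere
below 1e-2 in median over 10 seeds and beat an equal-budget random search
on sphere and Rastrigin. GTO's late-phase moves contract much harder than
AO's: on the surrogate landscape GTO recovers the designated optimum to
within one option per span in ≥ 8/10 seeds at N = 15, T = 100, while AO —
including a literal transcription of its reference implementation —
reliably reaches only the optimum's neighborhood (each coordinate within
a few hundredths), because its exploitation moves couple all coordinates
through scalar random factors. The end-to-end optimum-recovery check
therefore uses GTO; AO is validated on the benchmark landscapes and
coarse-span optimum location.

## Preprocessing

Images are ingested as RGB, resized to 128×128×3 with bicubic
interpolation. Four per-image intensity scalings are provided —
`X/max(X)`, `(X−μ)/σ`, `(X−min)/(max−min)`, `X/|max(X)|` — with
statistics over the single image's pixels (the transform definitions are
written for a single input image; per-dataset statistics would leak
between splits). Degenerate denominators (constant tiles are legitimate
in synthetic fixtures) yield an all-zero image plus a warning rather than
an error.

Augmentation draws each operator uniformly within its magnitude
(rotation ± angle, shifts ± fraction, shear ± fraction, zoom in
[1−z, 1+z], brightness in [low, high], enabled flips with probability ½)
and fills exposed borders with nearest-edge values; labels and shapes are
never changed. Class balancing raises every class to the largest class's
size by appending augmented copies of uniformly resampled originals —
originals are always retained — e.g. (2494, 2698) → (2698, 2698), 5396
total.

Partitioning is a nested seeded split: ratio 0.85 to a train+validation
pool and the rest to test, then 0.85 of the pool to train — 72.25% /
12.75% / 15%. Assignment is class-agnostic (plain ratio splits);
balancing the training part per decoded configuration happens inside the
evaluation pathway so each candidate sees the preprocessing it asked for.

## Fitness backends

`evaluate_solution` decodes, applies the decoded scaling to all parts,
balances the training part when the decoded gate is on, runs the backend,
and assembles the metric report. The fitness scalar defaults to
test-partition accuracy; the equal-weight 12-metric sum is available as
an alternative and changes only the scalar, never the report. Evaluation
on the full dataset (train ∪ validation ∪ test) is supported but not the
default — fitness from the held-out test part is the statistically
defensible choice.

The **surrogate backend** scores
`100·(1 − mean_d dist_d)` over the seven core dimensions, with
`dist_d` = option-index distance / (L−1) for discrete spans and
range-normalized distance for continuous ones; the designated optimum is
KL divergence / batch 24 / dropout 0.3 / learn ratio 50 / SGD-Nesterov /
standardization / no augmentation. It also fabricates deterministic
confusion counts and probability rows consistent with its score so the
full report pathway is exercised; its analytic score, not the
discretized accuracy, is used as fitness (the count discretization would
mask sub-0.25% fitness differences).

The **tiny trainable backend** is a small numpy convolutional classifier:
block-mean downsample to 16×16, one fixed random 3×3×3 convolution
(8 filters — the frozen stand-in for a pretrained backbone), ReLU, 4×4
adaptive average pooling plus channel means, feature standardization, a
32-unit hidden layer with ReLU and dropout, and a softmax head
(zero-initialized, so an untrained model predicts one class everywhere —
exactly chance on balanced data). The TL learn ratio maps to the
percentage of hidden units whose incoming weights are trainable; the head
is always trainable. All six losses are implemented as gradients through
the softmax (for one-hot targets the KL divergence gradient coincides
with cross-entropy; the hinge family operates on ±1-coded targets against
the softmax outputs), and all eleven weight-update rules are implemented
with their conventional constants (momentum 0.9, Adam β = (0.9, 0.999),
RMSProp/Adadelta ρ = 0.9/0.95, FTRL-proximal without regularization).
Default learning rates per rule were chosen once so that every rule
trains this small head above chance in five epochs on separable data
(SGD family 0.1, Adam family 0.02, Adagrad 0.1, Adadelta 1.0, RMSProp
0.01, FTRL 0.5). Large pretrained architectures are deliberately out of
scope; the backend contract (`evaluate(configuration, data, epochs,
seed) → counts, scores`) is the extension point for heavyweight
frameworks.

## Metrics

All ratios are computed on exact integer counts and rounded half-up to
two decimals only for display. Micro-averaging sums one-vs-rest counts
over classes; for two classes TP = TN and FP = FN, which makes accuracy,
F1, precision, recall, specificity and NPV coincide exactly — a useful
internal consistency check. AUC uses the rank-sum (Mann–Whitney)
statistic with ties at ½; cosine similarity is the mean per-sample cosine
between one-hot truth and predicted probability rows. Undefined ratios
(zero denominators) are reported as missing rather than raising, and the
weighted sum is undefined unless all 12 components are present. IoU and
Dice are computed from the counts as `TP/(TP+FP+FN)` and
`2TP/(2TP+FP+FN)` (`Dice = 2·IoU/(1+IoU)` identically); probability- or
pixel-level variants of these scores are not modeled.

## Synthetic data

The generator emulates the *contract* of the histopathology set, not its
appearance: 8-bit RGB patches, two classes with sizes defaulting to
(2494, 2698). Class 0 is a smooth low-frequency texture around a pinkish
base tone with Gaussian pixel noise (sd 8 by default); class 1 adds 8–16
dark elliptical blobs with a basophilic (green-absorbing) color cast,
amplitude 70·separability. At separability 0 the classes are draws from
the same distribution (a held-out linear probe scores at chance); at
separability ≥ 0.3 a linear probe on channel means exceeds 95%. Passing
tests on this data demonstrate that the search and evaluation machinery
work — they say nothing about stain variability, tissue morphology or
scanner artifacts in real slides.

## Experiment driver

`run_experiment` / the `histotune` CLI run ingest → partition → optimize →
final re-evaluation, writing best-configuration JSON, a metric report CSV,
the optimization history, a split manifest and run metadata. "Repetitions"
are independent restarts with derived seeds (`seed + index`), separate
from the iteration budget `t_max` — the two are distinct knobs because a
repetition count can mean either in common experiment summaries.
Defaults: population 10, 10 repetitions, 5 training epochs per
evaluation. Everything is driven by a single integer seed; equal
configurations produce identical results.

Problem sizes in the shipped tests are chosen for desk-scale runs: 5-D
benchmark landscapes with N = 20, T = 200 over 10 seeds for convergence
checks; N = 15, T = 100 for surrogate optimum recovery; 32×32 or 128×128
synthetic sets of tens of images per class for the trainable backend.

## Known limitations

* The brightness pair and the 7-D gate fallback are pragmatic decode
  conventions; other projections of the same element are equally valid.
* AO's exploitation precision bounds how finely it can resolve the
  100-option learn-ratio span (see Optimizers above); this is a property
  of the algorithm, not of the implementation.
* The tiny backend's frozen random backbone is a stand-in for pretrained
  features: adequate for exercising the search, not a statement about
  real transfer learning quality.
* Per-image scaling statistics mean the "standard" scaling always
  produces zero-mean unit-variance images regardless of class — class
  signal must survive within-image structure, as it does for the
  synthetic blobs.
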