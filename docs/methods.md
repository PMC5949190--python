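# Methods

## Problem setting

The package targets the recognition stage of lung-CT computer-aided
detection: candidate regions of interest (ROIs) arrive as numeric feature
vectors with binary labels, +1 for true pulmonary nodules and −1 for
false positives, in a strongly imbalanced ratio (the reference protocol
has 80 positives against 190 negatives, split 170 train / 100 test).
Everything upstream of the feature table — CT acquisition, lung
segmentation, ROI extraction and feature engineering — is out of scope;
the table itself is the interface.

## Classifier

The kernel is the convex mix `K = m·K_poly(d) + (1−m)·K_rbf(g)` with
`K_poly(x,y) = (xᵀy + 1)^d` and `K_rbf(x,y) = exp(−‖x−y‖²/(2g²))`.
Convexity (weights in (0,1), summing to 1) guarantees positive
semidefiniteness of every Gram matrix, hence a valid Mercer kernel; the
`combine_kernels` operation generalizes the mix to more than two
components under the same constraint. Two conventions for the RBF
parameter coexist in practice: a width `g` (as in the formula above) and
a libsvm-style `gamma` multiplying the squared distance directly. The
width form is canonical here; `rbf_param_convention="gamma"` selects the
other reading, with the conversion `gamma = 1/(2g²)`. Published optima
quoted with an SVM toolbox's "g" may be on either convention, so both are
first-class rather than guessed.

The dual soft-margin program is solved by an SMO-type working-set method
over the precomputed Gram matrix: maximal-violating-pair selection with a
second-order gain heuristic for the second index, analytic two-variable
updates, a cached gradient refreshed from the two affected Gram rows, and
termination when the maximal KKT violation falls below `kkt_tol`
(default 1e−3; the unit and acceptance tests solve at 1e−8 when comparing
against a quadratic-programming oracle). `max_iter` defaults to
`10·l²` pair updates; exhausting it raises a `ConvergenceError` that
carries the best iterate. The offset `b` averages `yⱼ − Σᵢ yᵢαᵢK(xᵢ,xⱼ)`
over unbounded support vectors (`0 < α < C` with a relative margin of
1e−8), falling back to the midpoint of the feasible interval implied by
the bounded points. Multipliers above `1e−8·C` count as support vectors.
The decision tie `g(x) = 0` maps to +1 — the recall-favouring choice for
a screening application, where a missed nodule is costlier than a false
alarm.

## Fitness

A hyperparameter point is scored by k-fold (default 5) cross-validated
accuracy on the training table, in percent. Design choices:

* **Stratified folds.** With an 80/190 imbalance, unstratified folds make
  the fitness needlessly noisy; folds are stratified per class and
  balanced to within one sample overall, deterministically per seed.
* **Pooled counts.** Confusion counts are pooled across the k out-of-fold
  predictions before the ratio is taken, so the fitness is a rational
  number with the table size as denominator (160/170 = 94.1176%), not a
  mean of per-fold accuracies. A unit test asserts the algebraic identity
  between the pooled value and the sample-weighted fold mean.
* **Per-fold z-scoring.** Features are standardized with training-fold
  statistics only, applied unchanged to the validation fold; constant
  columns get unit scale. The protocol source is silent on scaling, and
  fold-local scaling is the leakage-free default.
* **d is enumerated, not searched.** The polynomial order takes only the
  values 2 and 3; the runner loops over them and keeps the better fitness,
  ties resolved toward d = 2.

Accuracy is undefined (an error, not zero) on empty input, as is
sensitivity without positive samples.

## Swarm optimizer

Canonical PSO with inertia weight: per-dimension fresh uniforms r₁, r₂,
acceleration factors c₁ = c₂ = 1.49445 (the standard constriction-derived
values; the protocol source does not state its own), velocities clamped
to `vmax = 0.2·(upper − lower)` per dimension, positions clamped to the
box with the clamped component's velocity zeroed. Personal/global best
ties keep the first achiever. `V_best(k)` is the running maximum of every
evaluation through generation k (hence monotone), `V_ave(k)` the mean
fitness of the current swarm. Protocol defaults: n = 20 particles,
maxgen = 200.

Schedules, with ω_start = 0.9, ω_end = 0.4, T = maxgen:

| id | ω(k) | note |
|---|---|---|
| constant | 1 | no decay; never localizes finely |
| lin_a, lin_b | ω_s − (ω_s−ω_e)·k/T | the two printed linear forms are algebraically identical; both ids are kept because they are reported as separate experimental arms |
| quad_late | ω_s − (ω_s−ω_e)(k/T)² | slow early decay (the best performer) |
| quad_early | ω_s − (ω_s−ω_e)(2k/T − (k/T)²) | fast early decay |
| exp_ratio | ω_e·(ω_s/ω_e)^(1/(1+c·k/T)) | c defaults to 10 (not stated by the source); never reaches ω_e (0.4306 at k = T with c = 10) |

For 0 < k < T the ordering quad_late > linear > quad_early is strict.

**Search scale.** The swarm moves through `(log10 C, log10 g, m)` by
default (`log_scale_cg`): the box is unchanged — C ∈ [0.1, 100],
g ∈ [0.01, 50], m ∈ [0.01, 0.99] — but particle dynamics happen on the
scale on which SVM hyperparameter landscapes are approximately smooth,
the same reason grid axes for C and g are conventionally log-spaced. A
linear-scale search wastes most of its trajectory in the large-C,
large-g corner of the box.

## Grid baseline

Exhaustive evaluation of the same CV fitness over log-spaced default axes
(C: 2⁻¹…2⁷, g: 2⁻³…2⁵, m: 0.1…0.9, d ∈ {2,3}), ties broken toward
smaller C, then g, m, d. The baseline exists to anchor the swarm's
results: with matched evaluation budgets the swarm should reach at least
the grid's best fitness.

## Diagnostics

`convergence_generation` returns the smallest t such that `V_ave` stays
within `epsilon` (default 0.01) of its final value, relative to the
trace's range, from t to the end; if only the last generation qualifies
the trace is still oscillating and no convergence generation exists —
the typical outcome under a constant inertia weight. `F_gy` is the RMS of
`V_best − V_ave` from t onward; dividing by the window length inside the
root is what makes runs with different convergence generations
comparable, which a plain Euclidean norm of the post-convergence error
vector is not. The global error norm (no normalization, all generations)
is also reported. Boxplot statistics follow the Tukey convention with
type-7 (linear-interpolation) quartiles and 1.5·IQR fences; adjacent
values are always actual data points.

## Synthetic data

Two generators emulate the shape of the clinical table, which is not
public:

* `generate_gaussian_classes` — spherical unit-variance Gaussians
  (default 10 features) separated along the first axis by a configurable
  shift in pooled-SD units; separation 0 gives chance-level structure,
  large separation a nearly separable table.
* `generate_ring_classes` — 2-D inner disc (+1, unit radius) versus
  annulus (−1, radii 1.4–2.2) with Gaussian radial noise (default
  sd 0.2, leaving a small class overlap across the 0.4 gap). The boundary
  is a circle, so no linear rule works and the RBF-dominant mix is
  genuinely needed — this is the benchmark table.

Both default to 80 positives / 190 negatives; `split_train_test` performs
the 170/100 split with largest-remainder stratification. What the
generators do **not** emulate: correlated or heavy-tailed radiomic
features, label noise from inter-reader disagreement, and batch effects
between scanners. Passing benchmarks on these tables therefore validates
the optimization and evaluation machinery, not clinical performance.

## Benchmark problem sizes

The swarm-versus-grid benchmark runs the full 270-sample protocol with
matched evaluation budgets chosen in the optimizer's preferred regime of
generations ≫ particles: a 5×5×5×2 grid (250 CV evaluations) against a
swarm with n = 6, maxgen = 20, d ∈ {2,3} (252 evaluations), repeated over
10 seeds. The trace-diagnostics run uses n = 6 over 60 generations at
d = 2 so `V_ave` has room to settle. `scripts/acceptance.py` averages
three seeded repeats of the pipeline and additionally reports the
constant-ω swarm fitness for contrast with the dynamic schedules.

## Known limitations

* The SMO solver is plain Python/numpy; it is comfortable at a few
  hundred training points (one CV evaluation on the 170-sample table
  costs tens of milliseconds) but has no caching/shrinking for the
  thousands-of-points regime.
* The expected gap between the maximized CV fitness and held-out accuracy
  (winner's curse of selecting the maximum over hundreds of candidate
  configurations on 170 samples) is roughly 1–2 points on these tables;
  the reference protocol itself shows a comparable optimism (94.12% CV
  vs 91% test).
* The convergence-generation rule is declared (band of the final value),
  not inferred from any published detection rule; reported convergence
  generations are only comparable under the same epsilon.
* Fitness ties are pervasive because accuracy is quantized in units of
  100/l percent; tie-breaking rules (first achiever, smaller d, smaller
  grid coordinates) are therefore part of the contract and tested.
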