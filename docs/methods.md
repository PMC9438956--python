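# Methods

This note documents the models, the synthetic study designs, the
numerical choices, and the known limitations of `gipredict`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Models and assumptions

All three viability models (single gene, pair, triplet) are multinomial
logistic regressions parameterised as per-class linear scores with the
reference class (normal growth for single-gene fitness; neutral for
GIs) pinned at zero. This is exactly the log-odds-vs-reference
presentation: softmax of the scores reproduces each class's odds
against the reference as `exp(score)`. The models are first-order —
no interaction terms — so every feature contributes additively to each
class's log odds and each coefficient exponentiates to an
interpretable odds factor.

Assumptions inherited from this form:

* outcome classes are mutually exclusive and exhaustive;
* features act additively on the log-odds scale;
* pair/triplet symmetry is carried by the features, which are
  symmetric functions of the genes (sums, unordered combination
  indicators, distances), making predictions order-invariant by
  construction rather than by augmentation.

### Feature encodings

* **LID** — density of edges among a gene's PPI neighbours: count of
  neighbour–neighbour edges divided by C(k, 2) for degree k, hence in
  [0, 1]; degree < 2 yields 0 by convention. The raw (unnormalised)
  neighbour-edge count is available behind a flag for users replicating
  centrality composites built on counts. Normalisation was chosen so
  the feature is bounded — this stabilises SGD and makes coefficients
  comparable across genes of different degree.
* **SPL / SCL** — breadth-first shortest path length for pairs; for
  triplets the circuit length, defined here as the sum of the three
  pairwise SPLs (the closed triangle through all three proteins). A
  Steiner-tree-style minimum would be an alternative reading; the
  triangle sum was chosen because it is symmetric, cheap, and reduces
  to the intuitive value 3 for a connected triangle. Disconnected
  tuples are encoded as value 0 plus an explicit unreachable-indicator
  column — never as an arbitrary large distance, which would distort a
  linear model. A `binned_distance` flag swaps the raw value for a
  "< 8 steps" indicator, the coarse encoding sometimes used for
  circuit lengths.
* **Fitness combinations** — unordered multisets of single-mutant
  fitness classes: 6 categories for pairs (LL, LR, LN, RR, RN, NN) and
  10 for triplets, one-hot encoded.
* **sGO sharing** — per-term sums of membership bits over the tuple
  (0–2 for pairs, 0–3 for triplets).
* **Pident** — kept on its native [0, 100] scale (no rescaling), so
  its odds factor is "per percentage point"; genes without a homolog
  carry 0. Standardisation, when enabled, happens inside the trainer
  and coefficients are mapped back to the original scale.

Genes absent from the PPI network impute LID = 0 and unreachable
distances (logged): real screens routinely contain genes missing from
interaction data, and dropping them would bias the label distribution.

### Identifiability gauge

The intercept plus a complete fitness-combo one-hot block is
overparameterised: adding a constant to all combo coefficients while
subtracting it from the intercept leaves every prediction unchanged.
Similarly, the unreachable-flag column is identically zero on a
connected network, so its coefficient is arbitrary. Ground-truth
coefficient sets adopt the gauge "all-normal combo (NN / NNN) = 0,
flag = 0", and `canonicalize_gauge` maps any fitted model into the
same gauge before coefficient comparison. This is an alignment of
equivalent parameterisations, not a change of the model.

## Training

`fit_mn` minimises class-weighted categorical cross-entropy plus an L2
penalty on non-intercept weights by mini-batch SGD. Defaults: learning
rate 0.05 decayed as 1/(1 + 0.02·epoch), 200 epochs, batch 128, L2
1e-4, features standardised internally, probability clipping at 1e-12
in the loss. The returned coefficients are the average of the
end-of-epoch iterates over the last 25% of epochs (tail averaging):
plain SGD endpoints carry noise of the same order as the statistical
error at these sample sizes, and averaging removes most of it while
staying a first-order method. On convex problems the trainer reaches
the same loss as a quasi-Newton solver to ~1e-6 (tested against an
independent implementation on a toy problem).

Class weights default to inverse frequency, w_c = N/(K·N_c) (mean
weight one per example), which is appropriate for *prediction* under
imbalance. For *parameter recovery* the benchmarks use uniform
weights: weighting is equivalent to resampling class frequencies and
provably shifts the fitted intercepts away from the generating values.

The neural baselines are small numpy networks with hand-written
backpropagation and Adam: a one-hidden-layer perceptron (default 32
tanh units) for single genes, and a Siamese architecture for tuples —
one weight-shared tower per gene, a separate sub-network for the
pairwise block (SPL/SCL and flag), tower embeddings combined by
summation, then one combiner hidden layer before the softmax readout.
The combiner layer matters: summed tower outputs expose the *counts*
of each fitness class, and a nonlinear layer is needed to express
per-combination (non-additive) effects. Sum-pooling makes predictions
permutation-invariant for every weight setting; the implementation
sorts the tower outputs before summing so the invariance is bitwise
exact, not merely up to floating-point associativity. Encoders
likewise canonicalise tuples by sorted gene ID.

## Evaluation

Balanced accuracy is the mean of per-class recalls; a classifier that
ignores its input scores 1/K in expectation regardless of imbalance.
Multi-class predictions are argmax of predicted probabilities; a
fixed-threshold binary report (default 0.5) is available for
comparison with published binary predictors. Per-class AUC is
one-vs-rest with the Mann–Whitney tie convention (ties count 1/2).
Repeated stratified cross-validation defaults to 5 folds × 10
repetitions (50 fold evaluations), each repetition reshuffled with a
derived seed; model comparison uses Welch t-tests over
repetition-level BAs with Bonferroni correction.

Feature-set selection enumerates all non-empty subsets of the named
feature categories (guarded at m ≤ 16) and picks the smallest subset
whose mean cross-validated BA is within tolerance of the best. The
tolerance defaults to one standard deviation of the best subset's CV
BA — "achieves the highest performance" needs an operational
definition and a 1-sd band is the conventional one; an absolute
epsilon can be supplied instead. Selection on the same folds used for
reporting can be optimistic; the benchmarks use a fresh seed for final
evaluation.

## Synthetic study designs

The generator emulates the statistical shape of the real inputs:

* **Network** — preferential attachment with triad closure
  (Holme–Kim), n = 1000 genes, m = 3 edges per arrival, triad
  probability 0.6. Plain preferential attachment has vanishing
  clustering, which collapses LID onto zero (74% exact zeros in a
  1000-node graph); real PPI networks are both heavy-tailed and
  clustered, and with triad closure LID spreads over [0, 1]
  (sd ≈ 0.24). An Erdős–Rényi variant exists for null checks.
* **Annotations** — 45 independent Bernoulli sGO bits per gene at
  prevalence 0.3 (slim terms are broad, hence common); percent
  identity is 0 with probability 0.4 (no homolog) and Uniform(10, 100)
  otherwise.
* **Labels** — single-gene fitness sampled from the ground-truth S-MN
  softmax; those classes then feed the pair/triplet encoders, whose
  labels are sampled from the D-MN/T-MN ground truths. Coefficient
  magnitudes are moderate (|β| ≤ 2) with a handful of informative
  terms per class.
* **Imbalance** — a common offset on all non-reference intercepts is
  found by bisection (bracket [−30, 30], 60 iterations) so the
  *expected* non-neutral fraction over the sampled tuples equals the
  target; the default target is 0.008, the empirical rarity of
  negative GIs among double knockouts. Realized fractions then differ
  from the target only by binomial noise.
* **Complexes** — random membership units (default sizes 3–8, possibly
  overlapping); a within-unit log-odds bonus on the non-neutral
  classes makes within/across enrichment recoverable. The enrichment
  benchmark uses a 4.5% baseline GI rate and a bonus of 2.5, giving
  within/across fractions of the same order as real
  complex-concentrated GI data (tens of percent vs a few percent).
* For triplets, "within-complex" means all three genes share at least
  one unit; a relaxed "≥ 2 of 3" rule is available behind a flag,
  since the strict reading is a design choice.

What the generator does **not** emulate: GO-term correlation structure
(real slim terms are hierarchical and co-occur), degree-annotation
coupling, pident's bimodality beyond a zero mass, measurement noise in
fitness calls, and non-linear or epistatic feature effects. Passing
tests therefore demonstrate correctness of the machinery and
recoverability under the models' own assumptions — not performance on
real screens.

### Recovery design and its power

The parameter-recovery benchmark draws n = 20 000 training examples
(singles and pairs) from ground truths whose intercepts are set for
roughly balanced classes (`recovery_ground_truth`), with uniform
single-mutant fitness for the pair design — the information-optimal
configuration for estimating every coefficient. Fits use uniform
class weights and are compared in the canonical gauge; a further
20 000 held-out draws give the balanced-accuracy comparison between
the fitted model and the generating (Bayes plug-in) model.

A power analysis against the exact maximum-likelihood solution (the
SGD trainer matches its loss to six decimals) shows what n = 20 000
can and cannot determine. Slope coefficients on common features are
recovered to ±0.05 or better (median absolute error ≈ 0.02–0.03). Two
coefficient families are intrinsically noisier: raw intercepts, which
extrapolate the score to the all-zero feature origin far outside the
data cloud (empirical SE 0.10–0.18), and rare fitness-combo
indicators, whose minimum frequency is 1/9 even under the optimal
uniform fitness marginal (SE ≈ 0.05). The maximum error over the
~100–165 coefficients of the full models therefore concentrates
around 0.12–0.3 at this sample size — a property of the Fisher
information, not of the optimizer — while the held-out BA gap between
fitted and generating models is two orders of magnitude smaller
(≈ 0.002). The benchmark reports both the maximum and the median
absolute coefficient error so the two regimes stay visible.

## Numerical choices

* Softmax computed with row-max subtraction; probabilities clipped at
  1e-12 only inside the loss.
* Divergence (non-finite coefficients) raises immediately with
  guidance to reduce the step size.
* Stratified splitting assigns singleton classes to the development
  set with a warning (they cannot be split).
* AUC for a class absent from the truth is reported as missing (NaN),
  never silently dropped.
* Tie-breaks in feature-set selection: subset size, then lexicographic
  order of category names.
* All generators and trainers take explicit seeds; two runs with the
  same seed are bit-identical.

## Limitations

* The LID normalisation and the circuit-length definition are
  documented conventions; alternative readings (raw counts,
  Steiner-like circuits) are supported or noted but not default.
* The trainer is plain SGD by design (interpretability work rarely
  needs more); ill-conditioned feature sets without standardisation
  can require manual step-size tuning.
* The Siamese implementation targets small tabular blocks, not large
  architectures: single hidden layer per module, CPU only.
* Within-complex analysis treats membership as given; no inference of
  complexes from the network.
* Real-data curation (systematic screens, literature GI databases,
  CRISPR viability sets) is out of scope; the hybrid-dataset and
  negative-sampling utilities operate on user-supplied tables.
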