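# Methods

This note documents the models implemented in `graphgwp`, the choices
made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Genomic neighbor graphs

Individuals are vertices; edges connect each individual to its K nearest
neighbors in Euclidean distance over allele dosages (0/1/2 per marker).
Construction details:

* **Distances** are computed on raw dosages by default. A
  `standardize` flag scales each marker to zero mean / unit variance
  first; with thousands of markers the two choices give very similar
  graphs, and raw dosages keep the graph a pure function of the data.
* **Symmetrization by union**: vertex i and j are connected if either
  lists the other among its K nearest. This is standard KNN-graph
  practice and keeps the normalized propagation operator symmetric.
* **Ties** in distance (common with integer dosages) are broken by lower
  vertex index after sorting (distance, index) lexicographically, so the
  graph is a deterministic function of the input. A consequence worth
  knowing: with exact ties the edge set is *not* invariant under row
  permutation; with tie-free (continuous) coordinates it is, and the
  test suite asserts exactly that.
* Per-edge Euclidean distances are retained on the graph object for
  reporting and export, but propagation is binary — no edge weighting.

The propagation operator of the whole-graph model is the symmetric
normalization D̃^{-1/2} (A + I) D̃^{-1/2}; its spectral radius is ≤ 1,
which keeps repeated propagation contractive.

## Data splitting and leakage control

A test set (a fixed count or a fraction of individuals) is held out
first; the remainder is split 80/20 into training and validation. Before
training, **every edge whose endpoints lie in different partitions is
removed**, making the graph block-diagonal over the three partitions.
Training therefore cannot move label information across partition
boundaries through propagation; the test suite verifies that permuting
withheld test labels leaves the trained weights bit-identical.

The block-diagonal structure has a consequence the implementation
exploits: propagation restricted to one partition block equals
propagation on the whole zeroed graph. The training loop runs on induced
blocks, which is cheaper and makes the degenerate one-sub-graph ensemble
(below) reproduce whole-graph training bit-for-bit.

It also has a scientific consequence: a *small* test block keeps almost
none of its K-NN edges. With 100 test individuals out of 4080, 81% of
test vertices retain no edge at all, so "graph" prediction for them
degenerates to the learned feature map at a shifted normalization scale.
This is inherent to the zeroing design, which the package follows
literally; see the benchmark design below for how the evaluation
protocol avoids the degenerate regime. An `inductive`-style retention of
test→train edges is deliberately not the default.

## The two models

**Whole-graph GCN.** Two graph-convolution layers (widths 64 → 32 by
default), ReLU after the first convolution, dropout (p = 0.5) between
the convolutions, a linear head to one scalar per vertex. Loss is MSE
over training vertices only. Optimization is full-batch Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning rate 0.0025 for up to 250
epochs — the tuned operating point shipped as the default configuration —
with early stopping after 10 epochs without validation improvement; the
returned weights are those of the best validation epoch. Features and
labels are internally standardized using training-partition statistics
only, and predictions are returned on the original phenotype scale.

**GCN-RS (sub-sampling ensemble).** The training vertices are shuffled
and partitioned into N = 10 near-equal disjoint units; each unit's
induced sub-graph and labels train one member network, early-stopped on
the shared validation set. Member i draws its initialization and dropout
stream from seed key (seed, i), so members are independent but the whole
ensemble is reproducible, and an N = 1 ensemble is bit-identical to
whole-graph training when the same propagation mode is forced. Test
predictions average the members' outputs (`mean_prediction`); averaging
the members' final-layer embeddings through the averaged linear head
(`mean_embedding_then_linear`) is available as an alternative
aggregation.

Member networks default to mean-aggregator propagation
(h_v = σ(W·mean{h_u} + B·h_v)), the whole-graph model to the
symmetric-normalized convolution; both are selectable, and a third
concatenating sampled-neighborhood mode (mean or max aggregation over a
neighbor subset, concatenated with the self embedding) is implemented
for the layer-level API. A vertex left with no neighbors falls back to
its own embedding in the aggregation slot. Gradients for all modes are
closed-form (no autograd); a finite-difference check in the test suite
covers every parameter of every mode.

Random sub-graphs of a sparse K-NN graph are themselves very sparse
(a random tenth of the training vertices keeps few internal edges), so
ensemble members operate closer to feature-map regression than the
whole-graph model does. This matches how the ensemble behaves at
prediction time on sparse test blocks, and is consistent with the
ensemble's systematically better held-out error in the benchmark.

## Hyper-parameter search

`tune()` minimizes validation MSE over a declared search space by random
search or a TPE-style density-ratio sampler (random warm-up, then
candidates drawn near the top quartile of completed trials and scored by
a Parzen good/bad density ratio). A median rule prunes trials whose
reported intermediate value exceeds the running median at the same step.
Per-trial seeds derive from the master seed by trial index. The shipped
defaults (learning rate 0.0025, 250 epochs, K = 3, 10 sub-graphs) are
the tuned operating point and are what the benchmarks use; the tuner
exists to re-derive such settings on new data.

## GBLUP comparator

VanRaden method-1 relationship matrix G = ZZ′ / 2Σpⱼ(1−pⱼ) with Z the
allele-frequency-centered dosages, and mixed-model prediction on the
training block: û = (G_tt + λI)⁻¹(y_tr − μ̂), ŷ_te = μ̂ + G_te,tr û. The
shrinkage λ is supplied directly or derived from a heritability target
as (1−h²)/h²; no REML or Bayesian variance-component estimation is
performed, keeping the comparator deterministic and dependency-free. By
RR-BLUP duality the predictions equal ridge regression on centered
markers at penalty λ·2Σp(1−p), which the test suite verifies to 1e-8.

## Evaluation metrics

Test MSE, sample Pearson correlation (error on constant input), and
distance correlation computed from double-centered pairwise-distance
matrices — the biased V-statistic sample definition, matching the
default of the standard R implementation, with dcor ≡ 0 when either
distance variance is zero. An independently written naive O(n²) oracle
in the test suite agrees to 1e-12.

## Synthetic populations

The generator emulates a livestock-style workshop simulation: discrete
generations of 20 sires and 1000 dams (20 × 50 harems), founders in
Hardy-Weinberg proportions at allele frequencies ~ Uniform(0.05, 0.5),
5 chromosomes × 2000 equally spaced SNPs over 100 Mb each, Mendelian
transmission with Haldane (Poisson, no-interference) recombination at
1 cM/Mb, 50 additive QTLs with standard-normal effects, and a single
trait y = g + e with environmental variance set to
Var(g)·(1−h²)/h² from the **realized** sample Var(g), so small
populations still match the h² = 0.35 target in expectation. A desk
preset (2 generations of 10 × 10, 2 × 200 SNPs, 20 QTLs; 220
individuals) keeps unit tests fast.

What the generator does *not* emulate: selection, non-additive
(dominance/epistatic) effects, multi-trait pleiotropy, sequence-level
mutation, or the exact effect-size distribution of the original workshop
simulator (which is not publicly specified). Passing benchmarks on these
populations therefore demonstrate correct mechanics and the additive-
signal behavior of the methods, not their performance on real panels
with non-additive architecture or preprocessing artifacts.

## Benchmark design

The replicate comparison (ensemble vs whole-graph vs null) uses the full
workshop mating design — 4 generations × 1020 = 4080 individuals,
50 QTLs, h² = 0.35 — with the marker panel reduced to 2 chromosomes ×
500 SNPs so ten replicates complete in minutes on one CPU; at 220
individuals no method (including GBLUP) reliably beats a null
mean-predictor at h² = 0.35, so the small preset cannot separate
methods. Splits use the 80/20 train+validation/test protocol (the same
protocol used for comparator fitting and the proportion sweep) rather
than a fixed 100-individual test set: as noted above, a 100-of-4080
test block retains almost no internal edges after cross-partition
zeroing, which makes graph-based evaluation degenerate. Under these
conditions the ensemble's test MSE is below the whole-graph model's and
below the test-phenotype variance in all ten replicate seeds, with
typical margins of 5–10% against the null.

## Numerical choices and degenerate inputs

* Constant marker columns get unit scale in standardization (no 0/0).
* A constant training label vector gets unit y-scale; training then
  regresses toward the constant.
* Monomorphic panels are rejected by the GRM (zero denominator) and by
  MAF filtering with any positive threshold.
* Early stopping uses strict improvement; patience 0 stops at the first
  non-improving epoch.
* NaN appearing in any activation aborts training with the epoch index.
* Imputation: deterministic column-mean by default; genotype-frequency
  sampling (seeded) as the probabilistic alternative. The provenance of
  probability-score imputation in real pig panels is not reconstructible
  from public descriptions; both modes are approximations.
* All randomness flows from named integer seed keys through
  `numpy.random.default_rng`; every fitted object is bit-reproducible
  given its configuration.

## Known limitations

* Transductive by design: predictions require the individual to be a
  vertex of the graph at fit time. The ensemble mitigates but does not
  remove this (its members still standardize and propagate within the
  fitted graph).
* Full-batch training: one Adam step per epoch. Adequate at the sizes
  benchmarked here (≤ ~5000 individuals); beyond that, the dense
  per-epoch forward pass and the O(n²) distance matrix in graph
  construction become the bottlenecks.
* The GBLUP comparator fixes λ from a stated heritability instead of
  estimating variance components, so its accuracy is slightly
  conservative when the stated h² is off.
* On purely additive simulated traits the linear GBLUP remains the
  strongest predictor; the graph models' advantage claimed on real data
  (non-additive structure, precorrected phenotypes) is not testable from
  the simulator alone.
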