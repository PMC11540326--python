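# graphgwp

Graph convolutional networks for genome-wide prediction (GWP) of
quantitative phenotypes.

## The problem

In animal and plant breeding, an individual's phenotype (milk yield,
grain yield, body length, ...) is predicted from genome-wide SNP markers.
The classical tool is GBLUP: a linear mixed model in which the covariance
of random genetic effects is the genomic relationship matrix **G**
computed from allele sharing. Realized genomic relationships, however,
form a *graph* over individuals — a structure linear covariance models
and grid-based neural networks both flatten away.

`graphgwp` implements two graph-native regression models over that
structure, plus everything needed to benchmark them offline:

* **GCN** — a whole-graph graph convolutional network. Individuals are
  vertices of a K-nearest-neighbor graph built from Euclidean distance on
  allele dosages (K = 3 by default). With Ã = A + I and D̃ its degree
  matrix, each layer propagates

  H⁽ˡ⁺¹⁾ = σ( D̃^{-1/2} Ã D̃^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾ ),

  two such layers followed by ReLU, dropout and a linear head mapping
  each vertex to its predicted phenotype ŷᵥ, trained with Adam on
  training-vertex MSE with validation-based early stopping. Edges
  crossing the train/validation/test partition are zeroed before
  training so no label information leaks through propagation.

* **GCN-RS** — a sub-sampling ensemble: the training vertices are
  randomly partitioned into N sub-graphs (N = 10 by default), one network
  with mean-aggregator propagation
  h_v = σ( W · mean{h_u : u ∈ N(v)} + B · h_v ) is trained per
  sub-graph, each early-stopped on the shared validation set, and test
  predictions are averaged over the ensemble.

* **GBLUP** — a deterministic ridge-type comparator using the VanRaden
  method-1 relationship matrix, G = ZZ′ / 2Σpⱼ(1−pⱼ), solved on the
  training block with shrinkage λ = σ²ₑ/σ²_g = (1−h²)/h².

Evaluation reports test MSE, Pearson correlation, and distance
correlation (implemented from the double-centering definition). A
synthetic-data module generates multi-generation sire/dam populations
with equally spaced SNPs, Haldane recombination and additive QTL
architecture calibrated to a target heritability, so the whole pipeline
runs without any external download.

## Worked example

Simulate a workshop-style population (4 generations of 20 sires + 1000
dams each generation, 2 chromosomes x 500 SNPs, 50 QTLs, target
h² = 0.35), fit the sub-sampling ensemble, and compare with GBLUP:

```python
import graphgwp as g

pop = g.simulate_population(g.SimConfig(n_chromosomes=2, snps_per_chromosome=500, seed=0))
print(g.realized_heritability(pop))          # 0.336

cfg = g.GCNConfig(seed=0)                    # lr 0.0025, 250 epochs, K=3, 10 sub-graphs
res = g.GCNEnsemble(pop.markers, pop.phenotype_vector(), config=cfg).fit(
    test_fraction=0.2, seed=0)
print(res.summary())
```

```
Sub-sampling GCN ensemble (GCN-RS) regression
=============================================
No. individuals:            4080
No. markers:                1000
Neighbors K:                3
Sub-graphs:                 10
Propagation:                mean_aggregator
Aggregation:                mean_prediction
Best member val MSE:        46.3811
--------------------------------------------
partition        n       MSE       r    dcor
train         2611   36.9633   0.397   0.359
val            653   38.6602   0.374   0.342
test           816   41.4186   0.285   0.271
```

The held-out phenotypes have variance 45.06, so the ensemble's test MSE
of 41.42 improves on a null mean-predictor by about 8%, and its test
correlations (r = 0.285, dcor = 0.271) quantify how much of the
heritable signal the 1000-marker panel recovers at this population size.
The GBLUP comparator on the same split reaches test MSE 35.40
(r = 0.464) — on purely additive simulated traits the linear mixed model
is the stronger predictor, and the interesting comparison is the
consistent ordering GCN-RS < GCN in test MSE, which the test suite
checks across replicate simulations.

The same pipeline is scriptable from the shell:

```bash
graphgwp simulate --scale desk --seed 1 --out pop/
graphgwp train --genotypes pop/genotypes.tsv --phenotypes pop/phenotypes.tsv \
         --mode gcn-rs --test-fraction 0.2 --seed 1 --out run/
graphgwp baseline --genotypes pop/genotypes.tsv --phenotypes pop/phenotypes.tsv \
         --h2 0.35 --test-n 44
graphgwp benchmark --data-dir pop/ --methods gcn,gcn-rs,gblup \
         --proportions 0.1,0.2,0.3,0.4,0.5 --seeds 0,1,2 --out manifest.json
```

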