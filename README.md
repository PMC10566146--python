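# sigmanet

Estimate the mean per-generation dispersal distance σ of a population from
georeferenced SNP data.

Limited dispersal leaves a spatial footprint in genomes: nearby individuals
are genetically more similar than distant ones (isolation by distance).
`sigmanet` turns that footprint into an estimate of the effective dispersal
rate — the root-mean-square single-axis displacement between a child and a
randomly chosen parent — with two estimators:

- **A pairwise convolutional network.**  Instead of convolving the full
  n × m genotype matrix, a shared extractor visits every pair of
  individuals: conv blocks (kernel spanning 2 SNPs, average pooling over
  10) reduce the pair's genotype slab, the pair's geographic distance is
  concatenated, and a dense layer emits a per-pair feature vector.  The
  stacked features of all C(n, 2) pairs feed one linear unit that outputs
  σ̂.  Training is simulation-based: a continuous-space, individual-based
  forward simulator with known σ generates labelled data.  A
  **k_extract** gate optionally limits extractor-weight gradients to a
  random subset of pairs per batch — the forward pass, the loss, and the
  head gradients still use every pair — which bounds memory at large n
  without changing predictions.
- **Rousset's regression** (the classical baseline): the pairwise
  differentiation statistic â regressed on log distance has slope
  1/(4πDσ²) in two dimensions, so σ̂ = √(1/(4πD·slope)) given the density
  D.  A non-positive slope leaves σ̂ undefined; the undefined fraction is
  reported.

The intended users are population geneticists benchmarking
dispersal-inference methods, and developers of simulation-based inference
who need a self-contained, single-CPU reproduction of the
pairwise-extractor architecture; everything — simulator, network,
training, baseline — is plain NumPy/SciPy plus tskit/msprime, with no deep
learning framework required.

## Worked example

Simulate training data (desk scale), fit the network, evaluate, and compare
with the Rousset baseline — all from Python:

```python
from sigmanet import (SimParams, generate_training_set, NetworkSpec,
                      PairwiseDispersalNet, TrainingConfig)

tmpl = SimParams.desk_training()       # reduced-scale benchmark conditions
train = generate_training_set(50, 10, n=10, m=500, params_template=tmpl,
                              rng_seed=11, path="train.store")
test  = generate_training_set(12, 4, n=10, m=500, params_template=tmpl,
                              rng_seed=99, path="test.store")

model = PairwiseDispersalNet(NetworkSpec(n=10, m=500,
                                         filters_per_block=(16, 32),
                                         pair_feature_width=64))
fit = model.fit(train, TrainingConfig(learning_rate=1e-3, batch_size=16,
                                      max_epochs=120, patience=120,
                                      lr_patience=10, k_extract=16, seed=1))
print(fit.summary())
print(fit.evaluate(test))
```

On one CPU this runs in roughly ten minutes and prints, after the summary
table, held-out metrics of the form

```
MRAE=0.410  RMSE=0.718  r2=0.544  (n=48, undefined=0.0%)
```

(the numbers shown are from the acceptance run described below, which
executes exactly this pipeline; they move by roughly ±0.1 with the seed,
since both the simulations and the training trajectory are stochastic).
MRAE is the mean relative absolute error `mean(|σ̂ − σ|/σ)`, RMSE the root
mean squared error in map units, and r² the squared Pearson correlation
between true and estimated σ.  Desk-scale error is far higher than
full-scale published figures, which use orders of magnitude more training
data and ten times more SNPs per dataset.  For comparison, Rousset's
method on matched desk simulations reaches MRAE ≈ 0.44 at n = 10 with a
third of runs undefined — the network is both more accurate and always
defined.

The same workflow is available from the shell:

```sh
sigmanet simulate --out sim/ --n-sims 50 --draws-per-sim 10 --n 10 --m 500
sigmanet train    --out fit/ --store sim/datasets.store --learning-rate 1e-3 \
                  --k-extract 16 --filters 16,32 --pair-feature-width 64
sigmanet predict  --out pred/ --store sim/datasets.store --weights fit/weights.npz
sigmanet validate --out val/  --store sim/datasets.store --weights fit/weights.npz
sigmanet rousset  --out rou/  --store sim/datasets.store --density 3.5
```

Empirical data enter through `sigmanet preprocess --vcf data.vcf
--locations coords.tsv`, which encodes biallelic SNPs as minor-allele
counts, aligns the coordinate table to the VCF sample order, and projects
latitude/longitude onto a local plane (equirectangular about the centroid,
km).  Every subcommand writes a provenance JSON (config echo, version,
seed) beside its outputs.

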