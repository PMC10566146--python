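# Methods

`sigmanet` estimates the effective dispersal rate σ — the root-mean-square
single-axis displacement between a child and a randomly chosen parent, per
generation — from georeferenced SNP data.  Two estimators are provided:

1. a **pairwise convolutional network** trained on continuous-space
   individual-based simulations, and
2. **Rousset's isolation-by-distance regression**, the classical method,
   used as the baseline.

This note records the models, their assumptions, the numerical choices, and
what the package's tests do and do not demonstrate.

## The spatial simulation model

Hermaphroditic diploids live on a square habitat of width `W` map units with
carrying capacity `K` individuals per square map unit.  Generations do not
overlap.  A single interaction scale `sigma_f` governs all three spatial
processes, matching the standard continuous-space benchmark model:

- **Dispersal** — each offspring is displaced from its mother by independent
  per-axis Gaussian noise of scale `sigma_f`.
- **Mating** — each reproducing individual chooses one mate per generation
  among neighbours within `4 sigma_f`, with probability proportional to a
  Gaussian kernel of scale `sigma_f` in distance.  The truncation at four
  rather than three standard deviations keeps the realized mating variance
  within 0.1% of `sigma_f²` (a 3σ cutoff biases it ~2.7% low, which would
  shift the effective-σ calibration) and widens the support of the mating
  graph, which matters for persistence at low density (below).
- **Competition** — fecundity is damped by the local density `d_i`,
  measured as the number of neighbours in a square window of half-width
  `3 sigma_f`, divided by the window's area clipped to the habitat.

Expected offspring per individual is Beverton–Holt shaped,
`λ_i = λ0 K / (K + (λ0 − 1) d_i)` with baseline fecundity `λ0 = 2`, so the
equilibrium local density is `K` and the census stays near `K W²`.  The
window area is clipped exactly at habitat edges, which keeps the equilibrium
unbiased at the boundary (the test suite checks census within ±25% of
`K W²`).

Because a random parent is the mother or the father with equal probability,
and the father adds the mating displacement on top of offspring dispersal,
the per-axis variance of the child-to-random-parent displacement is
`(sigma_f² + 2 sigma_f²)/2`, so the **effective dispersal rate** is

    σ = sigma_f · sqrt(3/2).

This is the label attached to every simulated dataset, and the quantity both
estimators target.

### Why the competition kernel is uniform, not Gaussian

A Gaussian competition kernel of scale `sigma_f` peaks at
`1/(2π sigma_f²)` per neighbour.  When `K · 2π sigma_f²` is small (low
density or short interaction scale), a single co-located sibling already
pushes the perceived density past `K`, and family clumps systematically
self-extinguish — the classic clumping instability of spatial logistic
models.  A uniform window with the same truncation support regulates the
same quantity (local density at scale `sigma_f`) without the singular peak,
and admits an exact boundary correction.  Dispersal and mating kernels
remain Gaussian; only the density *measurement* is uniform.

### Demographic stability limits

The mating graph (neighbours within the mating truncation radius) must stay
connected for the population to persist: its mean degree is
`K π (4 sigma_f)²`, and below the continuum-percolation threshold (≈ 4.5)
the population fragments into independent family clumps, each of which is a
critical branching process and dies out regardless of fecundity.  At
`sigma_f = 0.2` this requires `K ≳ 2.2` with the 4σ radius (K ≳ 4 with a
3σ radius); somewhat higher density is needed before the census also stops
sagging below `K W²` from clumping.  The simulator raises an explicit
extinction error rather than returning an empty population, and the
training-set generator redraws an extinct replicate (logged, bounded)
because a single unlucky replicate should not void a whole training build;
strict propagation is available via ``retry_extinct=False``.

### Genealogy recording, recapitation, mutations

The forward pass records every gamete as a recombinant of its parent's two
haplotypes (crossovers Poisson with the per-bp rate, uniform breakpoints)
into tskit tables.  After the final generation the tables are simplified to
the final census, remaining founder lineages are closed with a neutral
coalescent (msprime, population size set to the realized census), and
infinite-sites mutations are overlaid at a rate auto-tuned from the total
branch area to deliver at least the requested number of SNPs (the rate is
recorded in the output; it doubles and retries on shortfall).

At large map lengths the exact coalescent-with-recombination used for
recapitation dominates run time.  Since the forward pass records the recent
history — which carries essentially all of the spatial signal — exactly,
the scaled recombination rate of the *deep* phase is capped
(`recap_rho_cap`, default 4·N·r·L ≤ 1000).  The approximation leaves deep
trees more correlated along the genome than they should be; it does not
touch the recent pedigree.  Training and evaluation data are generated by
the same process, so the comparison between estimators is unaffected.

### Edge handling

Offspring displacements that leave the habitat are redrawn (default) or
reflected (`edge="reflect"`); after 100 failed redraws a pathological draw
(σ comparable to the habitat) is clamped to the boundary.  Redrawing
slightly truncates the realized kernel for mothers near edges, which is why
kernel-fidelity diagnostics use interior mothers only.

## The pairwise network

The network never sees the full n × m genotype matrix.  For each of the
C(n, 2) sample pairs, the pair's two genotype rows (minor-allele counts,
SNPs in genomic order; four haplotype rows when phased) form a slab, and a
shared **extractor** maps slab + pair distance to a feature vector:

- conv blocks: 1-D convolution with a kernel spanning **2 SNPs**, ReLU,
  then average pooling over **10 SNPs**; blocks repeat until the SNP axis
  is shorter than the pool width (2 blocks for m = 500, 3 for m = 5000),
  with filter counts doubling from 32 by default;
- the flattened output is concatenated with the pair's Euclidean distance
  (divided by the maximum training distance, recorded in the weights);
- one dense ReLU layer produces the pair feature (width 128 by default).

Pair features are stacked in canonical lexicographic pair order and a
single linear unit (the **head**) produces the estimate on the normalized
target scale.  Targets are z-scored over the training split; the constants
ride along with the weights and are inverted at prediction.  Estimates are
not clipped; a negative prediction signals an under-trained model and is
reported as-is with a warning left to the caller.

Within a pair, the lower-index individual's rows come first; the
architecture is not symmetric under swapping them, and the order is frozen
at training time.  The model sees location data only through pairwise
Euclidean distances, so predictions are invariant under rigid motions of
the sample map (tested).

### Gradient gating (k_extract)

Training can restrict extractor-weight gradients to `k_extract` randomly
re-drawn pairs per batch, while (a) features are still extracted from all
pairs in the forward pass, (b) the loss uses all pairs, and (c) the head
receives gradients from all pairs.  On GPU frameworks this bounds memory;
here the semantics are reproduced exactly in NumPy and verified against
finite differences of a frozen-weight surrogate.  The forward pass is
provably independent of `k_extract` (tested to machine precision).

### Training

Mean squared error on normalized targets, Adam (default learning rate
1e-4; desk-scale presets use 1e-3 — with a few hundred rather than 50,000
training datasets the loss surface is traversed in correspondingly fewer
steps), shuffled batches, optional early stopping on validation loss with
best-checkpoint restore, and a plateau schedule that halves the learning
rate after `lr_patience` epochs without validation improvement.  The
desk-scale benchmark runs a fixed epoch count instead of early stopping:
with a validation split of only a handful of simulations, stopping noise
adds run-to-run variance without improving the fit (the best checkpoint is
still chosen by validation loss).  The validation split defaults to the
tail of the store: stores are written simulation-major, so the tail is
simulation-disjoint from the training datasets — a random split would leak
simulations across the boundary, because all draws from one simulation
share a label.  Training computes in float32 by default (halves CPU time;
switchable to float64).  Runs are bit-reproducible for a fixed seed, BLAS
and thread configuration.

Two symmetry devices improve data efficiency substantially at small
training-set sizes:

- **Relabel augmentation** (`augment_relabel`, on by default): relabelling
  the n individuals of a dataset permutes the canonical pair order and
  swaps some within-pair orientations while leaving the data physically
  identical.  Each training batch applies a fresh random relabelling, so
  the position-specific head cannot overfit arbitrary pair-slot
  identities.
- **Symmetrized prediction**: batch prediction averages the estimate over
  several random relabellings (default 8), removing residual
  slot-assignment noise from the estimator.  Single-dataset
  ``predict``/``forward`` remain the plain canonical-order pass.

## Rousset's baseline

For individuals i, j with per-locus allele frequencies `p_il` (half the
minor-allele dosage), per-locus identity probabilities are

    Q_ij,l = p_il p_jl + (1 − p_il)(1 − p_jl)
    Q_w,l  = fraction of homozygous individuals at locus l

and the pairwise statistic is the multilocus ratio estimator
`â_ij = Σ_l (Q_w,l − Q_ij,l) / Σ_l (1 − Q_w,l)`, an individual-level
analogue of F_ST/(1−F_ST).  In two dimensions `E[â]` grows linearly in log
distance with slope `1/(4π D σ²)`; ordinary least squares of `â_ij` on
`log d_ij` (zero-distance pairs excluded with a logged count) yields the
slope, and

    σ̂ = sqrt(1 / (4π D · slope))

with the density `D` supplied externally (benchmarks use the realized
census divided by habitat area — the true density, the same courtesy the
published comparisons extend to the method).  A non-positive slope makes
the inversion impossible: the run is reported as UNDEFINED, and batch
evaluation tracks the undefined fraction, which is how such runs are
accounted for in published comparisons (they are excluded from error
metrics).  Undefined output becomes more common as samples shrink and as
isolation by distance weakens.

## Desk-scale study conditions

The package's benchmark ("desk") presets are chosen so that every study
runs on a single CPU in minutes, while keeping σ identifiable:

- `SimParams.desk()` — 10 × 10 habitat, K = 5 (census ≈ 500): used for
  simulator diagnostics and the Rousset sample-size comparison.
- `SimParams.desk_training()` — network-training conditions: 16 × 16
  habitat at density K = 3.5 (census ≈ 900), a 10-Morgan genome (1 Gbp at
  1e-8 crossovers/bp), up to 250 generations of forward history.
  Identifiability requires Wright's neighbourhood size `4π D σ²` to stay
  well below the census across the whole σ range; at a 10-wide habitat
  with K = 5 the upper half of the `sigma_f ∈ U(0.2, 3)` range is
  effectively panmictic and carries no signal about σ.  Density cannot be
  lowered below the percolation/clumping limits (above), so the training
  preset sits just above them and gains the rest through habitat size and
  genome length: a longer map decorrelates the recent genealogies of the
  m = 500 SNPs and sharpens the isolation-by-distance signal per SNP.

Training stores draw each simulation's `sigma_f` uniformly from (0.2, 3),
sample n individuals uniformly without replacement per draw, drop sites
with minor-allele count below 2 in the subset (with n = 10, roughly half
of the segregating sites are singletons, which carry almost no pairwise
relatedness information — filtering them concentrates the information in
the fixed-size SNP panel), and subsample SNP columns uniformly; draws from
one simulation differ in individuals and SNPs but share the σ label.

At these conditions a strong nonparametric regression on hand-crafted
sufficient statistics (isolation-by-distance slope, Mantel correlation,
pairwise-statistic moments, site-frequency summaries) reaches a held-out
r² around 0.7 — a practical information ceiling for a single
(n = 10, m = 500) dataset; the pairwise network approaches this ceiling
when trained on a few hundred datasets.  Desk-scale benchmark runs size
the training set and epoch budget so that the complete cycle (simulate,
train, evaluate) stays within a commodity-CPU coffee break; the network's
accuracy is data-limited in this regime and improves steadily with more
training simulations.

## What the tests show — and what they do not

The synthetic generator emulates a homogeneous, equilibrium population with
a single dispersal scale and no demographic history, selection, habitat
heterogeneity, genotyping error, or missingness.  Passing the recovery
tests shows that the architecture and training loop can extract the
spatial signal the model family contains at desk scale; it does not show
that a model trained on these simulations transfers to any empirical
population — for real data the training simulations must be tailored to
the study system, and misspecified nuisance parameters (density,
demography, range shape) will inflate error.  Desk-scale error rates are
not comparable to full-scale published figures: they use two to three
orders of magnitude fewer training datasets, ten times fewer SNPs per
dataset, and a far smaller habitat.

## Numerical choices and degenerate inputs

- `sigma_f = 0` collapses every kernel to a point mass: offspring sit on
  their mothers, the only possible mate is co-located (selfing), and
  density regulation falls back to the global census density.
- Minor-allele polarization ties at frequency exactly 0.5 keep the
  VCF's ALT orientation (REF stays the reference allele).
- Sites with > 10% missing genotypes are dropped; remaining missing
  entries are imputed to the rounded per-site mean count with a logged
  total (the network needs dense input).
- Coordinates: latitude/longitude are projected equirectangularly about
  the sample centroid (`x = R cos(lat0) Δlong`, `y = R Δlat`, km); the
  error against great-circle distance is < 1% for clusters under ~100 km
  at mid-latitudes, adequate for dispersal scales.
- The dataset store is fixed-width little-endian binary with a versioned
  header (magic, version, n, m, count, phased); truncation and version
  mismatches raise distinct, offset-bearing errors.
- Average pooling drops a trailing remainder shorter than the pool width;
  the corresponding conv outputs receive zero gradient.
- Conv biases initialize at zero, so all-zero genotype windows sit exactly
  on the ReLU kink; the backward pass uses the subgradient 0 there.

## Known limitations

- One mate per mother per generation (full-sib broods within a
  generation); many continuous-space simulators redraw the mate for every
  offspring.  The child-to-random-parent displacement variance is
  identical under both conventions.
- The recapitation ρ cap (above) biases deep-time linkage; irrelevant for
  within-model comparisons, but the stored genotypes should not be used to
  study long-range LD.
- The network requires every dataset to share one (n, m) shape; empirical
  inputs must be subsampled to the trained shape.
- Bit-level reproducibility across differing BLAS builds is not promised;
  per-machine reproducibility is.
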