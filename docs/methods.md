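# Methods

## The problem

Plant GWAS panels are small (hundreds of individuals) while plant genomes
carry long stretches of strong linkage disequilibrium (LD), so SNP-by-SNP
mixed-model scans suffer both from low power on polygenic traits and from
mapping intervals that sprawl across whole LD blocks.  `hapfm` addresses
both by changing the unit of inference from the SNP to the *haplotype
block*: the genome is partitioned into blocks with limited haplotype
diversity, the haplotypes within each block are collapsed into a few
clusters, and a single genome-wide sparse regression is fit over all
cluster-count variables at once.  The output is a posterior probability of
causality per block, and the mapping interval of a hit is the block itself.

## Block partition

Partitioning is two-step, for speed and resolution:

1. **Independent blocks.**  A greedy left-to-right scan keeps extending the
   current block while at least one SNP pair bridging the proposed
   boundary — within a lookahead window of `ld_window` SNPs and a maximum
   pair distance `max_pair_bp` — has r² ≥ `r2_threshold` (default 0.1).
   r² is the squared Pearson correlation of the two columns of the phased
   2n×p haplotype matrix.  A break is also forced when a block would span
   more than `max_span_bp`.  The bridging ("chain") condition was chosen
   over a minimum-over-all-pairs ("clique") condition: at r² = 0.1 a clique
   condition shatters realistic blocks, since distant SNPs inside one
   haplotype block routinely decay below any fixed threshold.
2. **Sub-partition.**  Inside each independent block, either uniform
   windows (`uniform_size` SNPs) or the LD-gap method: every internal
   boundary is scored by the mean r² of bridging pairs within the window,
   and the block splits recursively at the minimizing boundary (leftmost on
   ties) whenever that mean falls below `split_r2` and both
   halves keep `min_sub_size` ≥ 5 SNPs.  `split_r2` defaults to the step-1
   independence threshold (0.1): a boundary is treated as a genuine gap
   when even the *mean* bridging LD falls below the criterion that defines
   block independence.  Larger values shatter real blocks — on simulated
   panels three quarters of the boundaries inside true blocks have mean
   bridging r² below 0.35 while true gaps sit near zero — which dilutes
   multi-SNP causal signals across fragments.  External partitions (BED)
   can be imported instead; uncovered SNP runs become filler blocks.

Defaults `ld_window = 50`, `max_pair_bp = 500 kb`, `max_span_bp = 1 Mb` are
conservative for dense plant panels and all configurable.  Raising
`r2_threshold` can only break blocks further (monotonicity), which the test
suite checks.

## Haplotype clustering

Within a block the distinct haplotypes among the 2n phased sample
haplotypes form a binary h×s indicator matrix Z.  Blocks with h at most the
cluster threshold (default 10) keep one variable per unique haplotype;
larger blocks are clustered to cap the variable count:

- **X-means** (default): weighted k-means that starts at k = 2 and greedily
  applies whichever 2-means split most improves the *global*
  spherical-Gaussian BIC, stopping when no split helps or `k_max` (default:
  the cluster threshold) is reached.  Two adaptations matter on binary
  rows.  First, the split decision uses the global BIC rather than a local
  parent-versus-children comparison: local comparisons on tiny,
  near-discrete subsets systematically over-split.  Second, the pooled
  variance is floored at `var_floor = 0.04`; without a floor the Gaussian
  likelihood diverges as clusters collapse onto single rows and BIC then
  prefers to shatter every mutation into its own cluster.  The default
  floor treats per-site variation below about 4% (the Bernoulli variance
  of a rare flip) as within-cluster noise.
- **KNN-spectral**: a symmetrized k-nearest-neighbour graph on Hamming
  distance with Gaussian edge weights exp(−d²/2σ²), σ set to the median
  3rd-neighbour distance.  Distance-decaying weights are required for the
  regime n_neighbors ≥ h−1, where a pure connectivity graph is complete and
  structureless.  The cluster count is the eigengap of the normalized
  Laplacian (capped at `k_max`); if the graph has more connected components
  than `k_max` the components are returned directly.

Clustering treats the unique haplotypes as equally weighted rows by
default.  Count-weighting is available but off: weighting by haplotype
frequency inflates the BIC's effective sample size roughly tenfold
relative to its parameter penalty, and then even an exhaustive search over
k shatters founder groups, defeating the purpose of clustering.

The design matrix H (n×m) counts, per sample, how many of its two
haplotypes fall in each cluster; per-block row sums are exactly 2.  All
clusters are kept (no reference-cluster drop): the columns of a block are
collinear with the intercept, but the proper spike-and-slab prior keeps the
posterior proper, and dropping a cluster would make block effects depend on
an arbitrary reference choice.

## Fine-mapping model

    y = C a + H b + e,
    b_i | g_i ~ N(0, d0²) if g_i = 0 else N(0, d1²),
    g_i ~ Bernoulli(pi_i),    d1⁻² ~ Gamma(a, b),    e ~ N(0, s² I).

The spike variance d0² is fixed near zero (default 1e-4, matching the
scale of background polygenic effects in the simulator); covariate effects
a carry a flat prior; the residual precision gets a Gamma(0.01, 0.01)
prior.  Inference is a systematic-scan Gibbs sampler; per sweep:

1. a | rest — Gaussian, from the regression of the current residual on C;
2. for each coefficient in fresh random order: g_i from the *collapsed*
   marginal likelihood ratio (b_i integrated out under slab vs spike), then
   b_i from its Gaussian conditional — collapsing is what lets the chain
   move between inclusion states in one step;
3. d1⁻² | included effects — conjugate Gamma (defaults a = b = 0.1);
4. s⁻² — conjugate Gamma;
5. the inclusion prior (below).

Block PIP = posterior frequency of the event "any of the block's clusters
is in the slab".  Per-coefficient inner loops run in a numba kernel; all
random draws are pre-generated each sweep from the run's single numpy
generator, so results are reproducible bit-for-bit per seed.

**The inclusion prior is defined at the block level.**  pi_B is the prior
probability that *block* B is causal; the member clusters get Bernoulli
probabilities 1 − (1 − pi_B)^(1/m_B) so that the prior probability of any
member being included equals pi_B.  This detail is load-bearing: applying a
block-level estimate of pi directly to each of ~6 clusters per block
amplifies the feedback in the pi update by the cluster/block ratio, and the
sampler then ratchets into a degenerate mode (pi ≈ 0.45, slab collapsed
onto the noise scale) that fits the phenotype as hundreds of tiny effects.
With the corrected link the default Beta(1, 99) hyperprior on a shared pi_B
(prior mean 0.01, bracketing realistic polygenicity) is stable.  pi can
also be fixed, or driven by annotations:

**Annotation-informed priors.**  With block features A (standardized, with
intercept), Phi⁻¹(pi_B) = A_Bᵀ θ, inferred by the classic truncated-normal
data augmentation: z_B ~ N(A_Bᵀθ, 1) truncated to (0, ∞) for blocks
currently included and (−∞, 0] otherwise, then θ from its Gaussian
conditional under a N(m₀, τ² I) prior (τ² = 1).  The intercept prior mean
m₀ is Φ⁻¹ of the prior inclusion rate, not 0 — a zero-centred intercept
would start the chain at pi_B ≈ 0.5 and invite the same degenerate mode.

A `group_gamma` option replaces per-cluster indicators with one indicator
per block that switches all member effects jointly (multivariate collapsed
update via Woodbury); it is exact but slower and not the default.

**Numerical hygiene.**  Inclusion odds are computed in log space; the slab
variance is kept at least 10× the spike and at most 100× var(y) (the
diffuse Gamma prior otherwise wanders to astronomical slab values whenever
nothing is included); a non-finite sampler state aborts with a state dump.

**Significance.**  Bayesian FDR on block PIPs: rank blocks by PIP
descending and take the largest prefix whose mean (1 − PIP) ≤ q (default
q = 0.05).  A fixed PIP cutoff is available as an alternative.

## Simulators

The genotype simulator emulates a diverse inbred-style panel with known
block structure: independent parent blocks, each split into sub-blocks of
s ~ U(10, 100) SNPs; each sub-block carries h_c ~ U(2, 4) founder
haplotypes with d mutated descendants each (per-site rate mu = 0.02);
haplotype frequencies solve f_s = Zᵀ f_h against target allele frequencies
f_s ~ U(0.05, 0.95) by simplex-constrained least squares; individuals draw
two haplotypes per sub-block i.i.d. from f_h (Multinomial(2, f_h)).
Positions are synthetic (1 SNP / 100 bp, 50 kb gaps between parent
blocks).  Because the linear system is overdetermined (s SNP constraints,
h ≪ s unknowns) an exact solution rarely exists; the solver accepts any
fit with RMS residual ≤ 0.40 and otherwise resamples the targets.  Each
haplotype frequency is floored at 0.02 (and founders are kept column-wise
polymorphic, with mutation-induced constant columns repaired) so that
every unique haplotype survives sampling and every SNP stays polymorphic
at realistic sample sizes.

The phenotype simulator draws covariates U(−5, 5) with effects U(−1, 1),
flags blocks causal i.i.d. Bernoulli(pi_B) (or an exact count), gives each
causal block a total effect |η_B| ~ U(0.5, 3) with random sign, and
distributes it over causal SNPs by architecture: (1) one SNP; (2) 5–10
SNPs with symmetric-Dirichlet shares; (3) one SNP with a U(0.5, 0.8) share
plus 5–10 small ones.  For architectures 2–3 the chosen causal-allele set
is resampled until no single unique haplotype of the block carries all
causal alleles — otherwise the "many small effects" case degenerates into
a one-haplotype effect.  Non-causal SNPs get N(0, 1e-4) effects; a zero
heritability target zeroes all genetic effects.  The residual is drawn,
orthogonalized against the genetic value, and scaled so the realized
heritability — var(Xη) / (var(Xη) + var(e)) on the realized sample,
covariates excluded — hits the target exactly; in per-locus mode each
causal block's contribution is normalized to unit variance first, so its
variance share of var(Xη) + var(e) equals the per-locus target.

What the simulator does *not* emulate: coalescent genealogies,
recombination gradients within blocks, LD between sub-blocks of a parent
block (drawn independently; documented, since the real analogue is
unknown), population structure and kinship, genotyping error.  Passing
tests therefore demonstrate correctness of the algorithms under
block-exchangeable, structure-free data, not robustness to confounding.

## Evaluation utilities

A significant block is a true positive iff it physically contains a truth
causal SNP; mapping power is the fraction of truth causal blocks whose
causal SNPs are covered by significant blocks; the mapping interval of a
hit is its block's genomic span.  With an empty significant set the
true-positive rate is reported as 1.0 with an explicit flag (no claims
made, none false).  For SNP-level methods the per-SNP budget |S|·q/M makes
block- and SNP-level FDR comparable (|S| representative SNPs, M total
SNPs), and greedy LD clumping (index SNP absorbs unclaimed SNPs with
r² ≥ 0.2 within 250 kb; leftmost on ties) delimits SNP-level loci.

## Problem sizes in the shipped checks

The test suite and the acceptance script run everything from scratch on
synthetic data sized for a single CPU: null-calibration uses ten panels of
20 parent blocks × 300 individuals at the full 20 000-sweep schedule;
sampler-vs-enumeration checks use m = 8 variables against exact 2^m
enumeration; recovery checks use 6-parent-block panels at n = 500; FDR
calibration pools 200 panels of 3 parent blocks × 150 individuals at a
4 000-sweep schedule.  These sizes are the package's own choice of a
desk-scale experiment; all of them are parameters, not constants.

## Known limitations

- Sub-blocks of a parent block are simulated LD-free, so the partitioner's
  step-1/step-2 division of labour is exercised less than on real panels.
- The Gibbs sampler is single-chain; convergence diagnostics are limited
  to effective sample sizes of the variance parameters and the gamma flip
  rate.
- Structural rearrangements can put the functional variant outside the
  mapped block; nothing in the model detects this.
- Multi-allelic sites and missing genotypes are rejected, not handled;
  imputation and phasing are upstream concerns.
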