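# Methods

## The model

spotfactor models a spatial transcriptomics (ST) count matrix — non-negative
integer counts x_gs for gene g in barcoded array spot s — as a superposition
of T latent factors ("cell types" or tissue programs):

    x_gs  = Σ_t x_gts
    x_gts ~ Pois(μ_gts)
    μ_gts = φ_gt · θ_ts · σ_s

φ (genes × T) holds the **expression profiles**: how strongly each gene is
expressed within a factor, independent of location.  θ (T × spots) holds the
**spatial activity maps**: how much mRNA each factor contributes in each
spot, independent of gene.  σ (spots) is a per-spot scaling variable that
absorbs library-depth and capture-efficiency differences; fixing σ = 1
recovers the core model, in which E[X] = ΦΘ.  Counts are modeled directly
without zero inflation: at ST spot depths the Poisson zeros produced by
small μ account for the observed sparsity.

All three parameter blocks carry independent Gamma(shape, rate) priors,
chosen for conjugacy with the Poisson likelihood.  The defaults,
shape = rate = 0.5 for φ, θ and σ, are weakly informative with prior mean 1
and a mild preference for sparsity (density unbounded at 0); results at
desk scale are insensitive to these values because the likelihood dominates.

## Inference

Parameters are learned by Gibbs sampling built on two exact conditionals:

* **Allocation.**  Given the totals and the current rates, the latent
  contributions of each observed count follow a multinomial with
  probabilities ∝ φ_gt θ_ts (σ cancels).  This is Poisson thinning run
  backwards, and it preserves Σ_t x_gts = x_gs as an integer identity at
  every sweep — a property tested exactly, not approximately.
* **Gamma updates.**  Given an allocation, each block is conditionally
  gamma, e.g. φ_gt | · ~ Gamma(a + Σ_s x_gts, b + Σ_s σ_s θ_ts), and
  symmetrically for θ and σ.

A sweep cycles allocate → profiles → activities → scaling and records the
log posterior.  Defaults: T = 10, 2000 sweeps, 500 burn-in, thinning 10.
A single seeded generator drives the whole chain, so runs are bit-for-bit
reproducible given the seed.  Initial values are prior draws; the chain on
desk-scale problems reaches its plateau well inside the default burn-in
(inspect `trace.tsv` / `log_posterior_trace` if in doubt).

**Spatial smoothing (optional, default off).**  With strength λ > 0 the
activity conditional is multiplied by
exp(−λ Σ_{s'∈N(s)} Σ_t (log θ_ts − log θ_ts')²) over the rook-adjacency
graph of array coordinates (neighbors at L1 distance 1, within a section).
The update becomes Metropolis-within-Gibbs with the conjugate draw as
proposal, so only the penalty difference decides acceptance.  The penalty is
on log activities to make it scale-free.

**Multi-section fits.**  Spots carry a section label; fitting the
concatenated matrix shares one Φ across sections while θ and σ remain
per-spot, which groups regions of similar phenotype across sections.  The
neighbor graph never crosses section boundaries.

**Identifiability.**  Three invariances are inherent: factor labels can be
permuted; Φ and Θ share a global per-factor scale; and θ_·s and σ_s share a
per-spot scale.  `summarize_posterior` averages the thinned draws and then
normalizes each profile column to sum 1, moving the scale into Θ (expected
counts are unchanged, to 1e-12).  Labels are matched to a reference only at
evaluation time (`match_factors`, Hungarian assignment on column cosine
similarities); draws within one conjugate chain are averaged without label
matching, because such chains mix within a single labelling mode — averaging
across label-switched chains would blur factors, so multi-chain summaries
are deliberately not offered.  The θ/σ trade-off cannot be normalized away,
which is why recovery of activity maps is evaluated on the identifiable
product σ_s θ_ts (`FactorModel.scaled_activities`, the expected mRNA a
factor contributes per spot): raw-Θ correlations mix in σ noise and sit
around 0.85 on simulations where the identifiable maps are recovered at
0.97–0.99.

T is user-set, not estimated; `heldout_log_likelihood` is provided as a
manual comparison utility only.

## Synthetic data

The generator produces data under the model's own assumptions, with spatial
structure chosen to resemble glandular/stromal tissue organization:

* profiles: Gamma(0.5, 1) draws; each factor receives a block of marker
  genes whose entry is raised to `marker_boost` × the gene's largest
  background value (boost 1 disables planting and leaves profiles
  exchangeable);
* activities: sums of isotropic Gaussian bumps at distinct grid centers
  (default two bumps of width 3 array units per factor), drawn per section,
  globally rescaled so the mean expected library matches the target;
* scaling: LogNormal(0, 0.15);
* defaults: 20 × 20 grid (one section), T = 3, 200 genes, 20 markers per
  factor boosted 10×, ~2000 counts per spot — sized so a full 2000-sweep
  fit takes well under a minute per seed.

What it deliberately does **not** emulate: gene–gene correlation beyond the
factor structure, overdispersion beyond Poisson, segmentation or imaging
artifacts, spot-boundary mixing, or any histology.  Passing recovery tests
therefore demonstrates correctness of the inference under the model, not
robustness to real-tissue misspecification.

The segment simulator plants cluster-shared deletions (cn 0.5) and
amplifications (cn 3.5) on a 1200-bp-aligned slot grid over a small
synthetic genome (two 1.2-Mb chromosomes by default), with N(0, 0.05)
per-slot noise around the diploid baseline, so planted events always clear
the 1.6/2.3 filter and background never does.

## Downstream statistics — numerical choices

* **Spot QC**: drop spots with natural-log library size strictly below
  median − 3 × MAD, MAD with the normal-consistency constant 1.4826.  A
  strict inequality means an all-equal (MAD = 0) dataset loses nothing.
* **Pooled size factors**: a ring of spots ordered by library size; for
  sliding windows of each pool size (default 21 and 41, capped at the spot
  count), the pooled profile's median ratio to the average profile gives one
  linear equation (sum of member factors = ratio); the stacked system is
  solved by least squares and scaled to mean 1.  This keeps the pooling idea
  — per-spot ratios are unstable at ST depths, pooled ratios are not — while
  staying far simpler than the full deconvolution estimator with cluster
  pre-blocking; non-positive or rank-deficient solutions fall back to
  library-size factors with a warning.
* **Variable genes / PCA**: variance and components are computed on
  log(1 + x) normalized values — a plain variance-stabilizing transform used
  in place of a regularized-log fit; ties in the variance ranking break
  lexicographically by gene id, and PCA signs are fixed by making each
  loading's largest-magnitude entry positive, so outputs are deterministic.
* **Factor trees**: quantitative Jaccard (Ružička) distance
  1 − Σ min / Σ max on profile columns (a true metric on non-negative
  vectors; two all-zero profiles are at distance 0 by convention, with a
  warning).  A binary-Jaccard variant exists behind a flag for
  presence/absence analyses.  Agglomeration is Ward on the distance matrix,
  the same criterion as `hclust(method = "ward.D2")`.  Node support is an
  ordinary bootstrap proportion (resampling features with replacement) —
  simpler and more conservative than multiscale-bootstrap AU values.
* **Outlier (marker) genes**: profiles are column-normalized; for gene g
  and factor t a normal distribution is fitted (mean, sd with ddof 1) to the
  gene's values in the other T−1 factors; g is a marker for t iff
  z = (φ_gt − μ̂)/σ̂ > 2.5 **and** a one-sample KS test of the other-factor
  values against N(μ̂, σ̂) has p ≥ 0.05.  Two caveats are inherent and
  documented rather than patched: the KS test with estimated parameters is
  conservative (the Lilliefors correction is not applied), and the z
  threshold with estimated moments behaves like a t_{T−2} tail, i.e. at
  T = 10 the null flag rate is ≈ 2.3 % rather than the 0.6 % a known-moment
  normal would give.  A unit test pins this t-tail behavior.
* **Center vs periphery**: fold change = center mean / periphery mean on
  normalized values; Welch's two-sample t-test (the unequal-variance choice
  is deliberate: group sizes and dispersions differ).  Degenerate genes are
  flagged: zero variance in both groups gives p = 0 (means differ) or 1
  (means equal); zero periphery mean gives an infinite fold-change sentinel.
* **t-SNE colors**: 3-component embedding (exact method — spot counts are
  small; the Barnes–Hut approximation is unnecessary and less reproducible),
  perplexity 30 auto-capped at (rows − 1)/3, each output dimension min-max
  scaled to [0, 1] as RGB.

## Copy-number post-processing

Coordinates are 0-based half-open throughout (a converter from 1-based
closed input is provided).  The module consumes per-sample segment tables
(chrom, start, end, cn) from an upstream read-depth caller whose minimum
bin is 1200 bp; calling itself is out of scope.  Steps: a fixed recentring
summand (default 0.2, mapping the caller's depressed normal level 1.8 to
2.0); exon assignment with per-segment overlap lengths (exons crossing
segment boundaries keep one entry per segment; allosomes excluded because
their normal copy number is 1); deleted exonic base pairs summed per
copy-number level rounded to 0.1; genome slicing into 1200-bp bins; per-bin
cross-sample CNV vectors kept iff **any** sample shows cn < 1.6 or > 2.3
(an "all samples" mode exists behind a flag; the any-sample reading keeps
cluster-discriminating events), minus allosomes and a user-supplied
exclusion BED (e.g. centromere bins — no centromere table is built in, as it
is assembly-dependent), deduplicated on exact values (optional rounding
flag); Ward/Euclidean sample trees with ordinary-bootstrap support over
vectors; and a gene-level copy-number vs relative-expression join
(length-weighted exon mean; genes with an internal break point — more than
one distinct copy number across their exons — excluded; expression as % of
the overall mean, capped at 2000 %; copy numbers restricted to [0, 6]).

## Problem sizes used by the test suite and acceptance script

Fits run at the default synthetic conditions (400 spots × 200 genes, T = 3,
2000 sweeps) — under a minute per seed; the marker-extraction check uses
T = 6, 300 genes, 1000 sweeps (outlier detection needs T ≥ 4, so the T = 3
default cannot exercise it); conjugate exactness uses 50,000 thinned draws
on a 3-gene toy; null calibrations use 10,000 genes (outlier rule, T = 10)
and 5,000 genes (Welch test); CNV recovery uses 12 samples in 4 clusters on
the two-chromosome synthetic genome with 100 bootstrap resamples.  These
sizes are the package's chosen desk-scale study conditions; all are
reproducible from fixed seeds.

## Known limitations

* Poisson (not negative-binomial) observation noise; real ST data can be
  overdispersed beyond what the factor mixture absorbs.
* Single-chain posterior summaries; no cross-chain label matching.
* The simplified pooled size-factor estimator is not the published
  deconvolution algorithm; on strongly heterogeneous tissues compute
  clusters first and normalize within them.
* The outlier-gene rule's null calibration depends on T (t-tail effect
  above); treat the marker lists as a ranking device, not a
  family-wise-error-controlled test.
* Bootstrap clade proportions underestimate support relative to AU values;
  thresholds tuned for AU supports do not transfer.
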