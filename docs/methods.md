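# Methods

`featherbiome` re-implements, as a tested library, the statistical workflow
used to characterise avian feather microbiota (FM): who lives on the feathers
of different passerine species, how strongly host species identity structures
those communities once geography is controlled for, whether community
divergence tracks host phylogeny, what fraction of each community is made of
bacteriocin-producing (BPB) or keratinolytic feather-damaging (FDB) bacteria,
and how those fractions relate to community diversity.  Everything runs on
synthetic studies with known ground truth, so each stage can be validated as
an estimator rather than merely executed.

## The synthetic study generator

The generator emulates a multi-species, multi-locality 16S amplicon survey:

* **Design.** 7 host species, 72 samples, up to 9 localities.  The default
  species-to-locality design deliberately confounds some species with
  sites — two species share a single site, one species is sampled only at
  sites where no other species occurs, and the rest share localities — so
  that the db-RDA disentangling analysis is genuinely exercised.  Per-species
  sample sizes are the near-equal split of 72 (11, 11, 10, 10, 10, 10, 10);
  the real per-species allocation is not public, so this is a package choice.
* **Host phylogeny.** A pure-birth (Yule) tree scaled to unit height, with
  terminal branches extended by the waiting time to the next unrealised
  speciation event and trees rejected when any terminal branch is shorter
  than 5% of tree height: tips represent distinct species, and near-zero
  terminals make the phylogenetic correlation matrix singular.  Posterior
  uncertainty is emulated by multiplying every branch by independent
  lognormal(0, 0.1) noise and rescaling; topology is preserved.
* **Phylosymbiosis.** Per-OTU species effects on log abundance are Brownian
  motion along the host tree with standard deviation `phylosymbiosis_strength`
  (default 1.0).  Brownian motion is the simplest process that makes related
  hosts carry similar communities, with a single strength knob.
* **Space.** Localities are placed uniformly in a Central-European bounding
  box; per-OTU locality effects are a Gaussian process over great-circle
  distances with a squared-exponential kernel (default sd 0.5, range 100 km),
  giving smooth clinal variation.
* **Counts.** Sample log-intensity = baseline OTU log abundance
  (N(0, 1.5²), giving a realistic rank-abundance curve) + species effect +
  locality effect + N(0, 0.5²) noise, mapped through a softmax to multinomial
  probabilities; depth = 2299 + Poisson(500), so every sample survives
  rarefaction to the study's minimum depth of 2299 reads.
* **Sequences.** OTU representative sequences (250 bp) evolve from a random
  root along a Yule tree under Jukes–Cantor, so sequence divergence increases
  with patristic distance.  Afterwards a minimum pairwise p-distance of 6% is
  enforced by adding substitutions at shared sites of too-close pairs: OTUs
  are 97%-identity clusters by definition, so two distinct OTUs cannot be
  near-identical, and 6% keeps every cross-pair unambiguously below both the
  97% and 95% mapping thresholds so the trait ground truth stays crisp.  The
  enforcement can be disabled (`min_otu_divergence=0`) for studying the raw
  evolutionary model.
* **Trait references.** 24.5% of OTUs are designated BPB (split across
  classes I–III) and 12.2% FDB, with 92% of FDB also BPB — the fractions the
  estimator is later asked to recover.  References are exact copies of the
  designated sequences (optionally mutated) plus random decoys far from every
  OTU.
* **Mixed-model data.** A response is generated as
  `y = a + b_B·mean_s(x) + b_W·(x − mean_s(x)) + u_s + phylo_s + e` with
  defaults b_B = −4.5 (echoing the magnitude of the reported interspecific
  slope), b_W = 1.0, species sd 0.5, phylogenetic sd 0.3, residual sd 0.5.

What the generator does **not** emulate: read-level errors, chimeras,
contamination, compositional biases of extraction/PCR, overdispersion beyond
multinomial + softmax-lognormal, and ecological interactions between OTUs.
Passing tests therefore demonstrate correctness of the estimators under a
clean hierarchical model, not robustness to the full messiness of real
amplicon data.

## Diversity and dissimilarity

Rarefaction is a single multivariate-hypergeometric draw per sample (without
replacement) to a common depth, seeded and logged; the workflow rarefies once
rather than averaging draws.  Shannon diversity uses natural logs.  The
interspecific ANOVA is the classical one-way F with R² = SS_between/SS_total.

Bray–Curtis and binary Jaccard come from scipy's pairwise kernels.  Both
UniFrac variants are computed by classifying every branch of the rooted
bacterial tree by the read mass (weighted) or tip presence (unweighted)
descending from it; they are checked against brute-force per-branch oracles
and against scikit-bio.  Weighted UniFrac is normalised by default so it lies
in [0, 1]; the raw variant is a flag.  The tree is used as rooted (no
midpoint re-rooting); tree tips absent from the table contribute no mass.

## Ordination and matrix tests

PCoA is the Gower double-centred eigendecomposition; axes with eigenvalues
above 1e-8 (relative) are embedded, negative eigenvalues are reported but
never embedded and no Cailliez/Lingoes correction is applied.  NMDS wraps
non-metric SMACOF (Kruskal stress-1) with `n_restarts` random starts plus one
PCoA start, returning the lowest-stress solution; an all-equal dissimilarity
matrix returns a flagged zero-stress configuration.  PERMANOVA uses
Anderson's distance-based partition with free permutation of sample labels
(no strata), p = (1 + #{F* ≥ F})/(1 + B).  The Mantel statistic is the
Pearson correlation of condensed matrices with one-tailed (greater)
simultaneous row/column permutation.  Heatmap data use Ward.D2 linkage on
Euclidean distances of relative abundances; "dominant" OTUs reach a mean
relative abundance of at least 1% (configurable — the threshold used in the
original analyses is not recoverable) in at least one species.

## Spatially controlled analysis

Geographic distances are haversine with Earth radius 6371 km.  PCNM uses the
longest minimum-spanning-tree edge as the default truncation distance,
replaces larger distances by 4× the threshold, and keeps
positive-eigenvalue axes (verified identical to vegan's `pcnm`).  Only the
first three PCNM axes enter the standard species-vs-geography model, to
avoid overfitting; this is configurable.

db-RDA regresses the positive PCoA axes of a dissimilarity matrix on
predictor terms.  Marginal term tests use SS_full − SS_reduced with
Freedman–Lane permutation of reduced-model residuals; term F values agree
with vegan's `capscale`/`anova(by="margin")` to four decimals on shared
fixtures.  Forward selection is greedy on permutation p-values with the
double stopping rule (p > α, or candidate model adjusted R² exceeding the
full model's by more than 1e-3 — the tolerance prevents a numerical sliver
from aborting selection in near-noiseless data).  Variance partitioning
converts R² to adjusted R² (Ezekiel) and reports pure, shared and residual
fractions; rank-based complexity counting makes aliased duplicates free, so
the closure identities hold exactly.

## Cophylogeny

Host cophenetic (patristic) distances are expanded to sample level with
conspecific pairs at distance zero; the tied rows are handled naturally by
PCoA and no jitter is added.  Both configurations are PCoA-scaled and
zero-padded to a common width; the microbiota configuration is superimposed
on the phylogenetic one (phylogeny as the fixed reference) by least-squares
Procrustes with translation, rotation and scaling.  Significance permutes
whole rows (samples) of the microbiota configuration, preserving its
internal geometry; p = (1 + #{m²* ≤ m²})/(1 + B) because small residuals
mean strong co-divergence.  Across a tree posterior the per-tree m² and p
are always retained; the pooled summary (mean m², median p) is a reporting
convention.

## Trait mapping (BPB / FDB)

Every OTU is aligned against every reference (exhaustive best-hit rather
than a heuristic candidate order — at this scale exhaustive comparison is
feasible and strictly more accurate, with the same acceptance rule:
identity ≥ 97% ⇒ mapped).  Alignment is semi-global (free terminal gaps on
both sequences; match +1, mismatch −1, gap open −5, gap extend −2).
Identity is matches / alignment columns excluding terminal-gap columns,
with internal gaps counting as errors, and the denominator floored by the
shorter sequence length: without the floor, the score-optimal alignment of
two *unrelated* sequences is a one-column dovetail overlap whose literal
identity is 1.0, and decoy references would absorb every query.  The floor
changes nothing for genuine alignments.  Ties between equally good
references break to the lexicographically smallest id.  Per-sample
proportions of reads on assigned OTUs are the relative-abundance proxy;
category overlap is reported in both read-weighted and OTU-count
conventions, and cross-threshold (97% vs 95%) concordance is the Pearson r
of per-sample proportions.

## Phylogenetic mixed model

The Gaussian model is `y = Xβ + Z u + Z a + ε` with X containing the
intercept, the between-species predictor mean and the within-species
deviation (plus species × within products for the interaction model),
`u ~ N(0, σ²_s I)`, `a ~ N(0, σ²_p A)` and `ε ~ N(0, σ²_e I)`.  A is the
shared-root-path correlation matrix of the unit-height host tree (non-
ultrametric trees are normalised by per-tip depths, with a warning).

Sampling is a blocked Gibbs sampler: all location effects (β, u, a) are
drawn jointly from their multivariate normal conditional, and variances
from inverse-gamma conditionals (IG(0.001, 0.001) priors for the residual
and the working variances).  The two species-level components use
parameter expansion: the effects enter as α_u·Z ũ and α_a·Z ã, and the
reported variances are α²·σ̃².  Plain inverse-gamma Gibbs has a
well-known absorbing state near zero for weakly identified variance
components — with 7 species the chain gets trapped either near zero or at
inflated values — and the expanded chain mixes across it.  The expansion
multipliers are priors in their own right: α_u ~ N(0, 100) leaves the
species repeatability essentially unshrunk (it is identified by
within-species replication), while α_a ~ N(0, 0.3²) gives the
phylogenetic standard deviation a conservative half-t-like scale.  With
only 7 species a phylogenetic variance is barely identifiable, and the
standard comparative-methods stance is that claiming phylogenetic signal
should require strong evidence; under this prior the null posterior of
H² = σ²_p/(σ²_p + σ²_s + σ²_e) concentrates near zero while a strongly
phylogenetic generating model still lifts it by an order of magnitude.

Zeros are shifted by half the smallest nonzero value before log
transformation.  DIC is 2·mean(deviance) − deviance at the posterior mean
fit; |ΔDIC| < 2 is read as practical equivalence.  Default chains are
60,000 iterations, 10,000 burn-in, thinning 25; the validation suite uses
6,000-iteration chains, which the parameter-expanded sampler mixes well at.
Pooling over a tree posterior concatenates equally weighted draws and
recomputes all summaries.

## Problem sizes used in validation

The test suite and the reproduction script scale the study down where full
size adds nothing: oracle checks run on 8-tip trees and 3–5-point
configurations where enumeration is exact; calibration uses 16-sample nulls
with 199 permutations and 500 simulations; the trait-recovery check uses
200 OTUs (the recovered fractions do not depend on pool size); the
reproduction script runs the full 72-sample, 500-OTU study with 999
permutations, 20 posterior trees for the cophylogeny test and 10 for the
mixed model.

## Known limitations

* The db-RDA response drops negative-eigenvalue PCoA axes; for strongly
  non-Euclidean dissimilarities a correction (Cailliez/Lingoes) would change
  absolute variance fractions slightly (vegan's `varpart` on distance input
  differs in the third decimal for this reason).
* The trait estimator's read-weighted fractions recover the configured
  OTU-count fractions only in expectation; abundance weighting adds spread.
* With 7 species, H² and the separation of σ²_s from σ²_p are prior-driven;
  the package reports full posteriors so this is visible, but single-number
  H² summaries should not be over-read.
* The NMDS wrapper inherits SMACOF's local-minimum behaviour; restarts
  mitigate but do not eliminate it.
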