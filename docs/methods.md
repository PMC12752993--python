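# Methods

This note documents the statistical procedures `polyclust` implements, the
defaults it ships, the design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Association profiles and harmonization

Each SNP's evidence in each study is reduced to an absolute z-score. Studies
reporting an effect and standard error give a signed z = β/se (absolute value
used for clustering, sign retained for score weights); studies reporting only
a p-value give |z| = |Φ⁻¹(p/2)| under the two-sided convention, with no sign
available. The z scale removes the studies' very different sample sizes from
the comparison. Harmonization intersects variant ids across studies (ids are
matched verbatim; allele disagreements are logged, not fatal) and keeps the
top fraction q (default 0.01) of SNPs by row-maximum |z|, with the selection
count `ceil(q·n)` and boundary ties broken by variant-id order so the
selection is reproducible. Degenerate corner: a selection that would be empty
raises; a single-SNP selection is allowed and fails later, in clustering,
with a clearer error.

## Weighted correlation clustering

The clustering substrate is the n×P matrix of |z| profiles (P = number of
phenotypes, three in the motivating design). Pairwise profile similarity is a
soft-threshold adjacency from the product-moment correlation of the two
P-vectors. Two variants are implemented:

* **signed (default)**: a = ((1 + cor)/2)^β with β = 12;
* **unsigned**: a = |cor|^β, conventionally with β = 6.

The signed form is the default for a structural reason. With P = 3 the
centred profiles live in a two-dimensional shape plane, and the centred
single-phenotype shape (high, low, low) is *exactly* anti-proportional to the
complementary pair shape (low, high, high): their correlation is −1
identically, so the unsigned form cannot distinguish a cluster specific to
phenotype A from a cluster shared by B and C. Empirically an unsigned network
on the five-group synthetic scenario always collapses to three clusters (each
single-phenotype group fused with its complementary pair group) regardless of
power or cut height. The signed form maps anti-correlated shapes to adjacency
zero and recovers all five groups. β = 12 is the usual soft-threshold power
for signed networks; it is configurable, as is the network type.

Adjacency is denoised into topological overlap

    t_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

k_i = Σ_{u≠i} a_iu, which rewards shared neighbourhoods and damps incidental
pairwise correlation (important here, where a correlation of 3-vectors is
statistically coarse; no further smoothing is added). Clusters come from an
average-linkage dendrogram on d = 1 − t, cut at `cut_height_frac` × (top
merge height); branches with ≥ `min_size` (default 30) leaves become
clusters, everything else is labelled 0 (unassigned), and labels are numbered
1..K by decreasing size. The cut fraction defaults to 0.65: under the
five-group geometry (adjacent profile shapes 60° apart in the shape plane)
the pair-group branches attach to their neighbouring single-phenotype
branches at heights around 0.75–0.85 of the top merge while their internal
structure completes below ~0.55, so a static cut must land between; 0.65 is
the centre of the window that proved stable across seeds and noise levels. A
fraction near 1 provably lumps pair groups into their parent branches. This
static cut plus minimum-size filter is a deliberate simplification of
adaptive branch-cutting; the adaptive hybrid variant is out of scope.

Clusters closer than `merge_dissim` (default 0.25) are merged iteratively.
Cluster distance is 1 − cor of *eigenprofiles*: each member profile is
standardized across phenotypes (correlation-similar profiles share a centred
shape, so the standardized member×phenotype matrix is near rank one) and the
leading right singular vector — the cluster's shape direction, unit norm,
oriented to correlate non-negatively with the cluster's mean raw profile — is
its summary. Standardizing *phenotype columns across members* instead would
remove the cluster mean and leave isotropic noise, making the merge step
vacuous; the per-member standardization is the module-eigengene construct.
The closest pair is merged first and distances recomputed until no pair is
below threshold.

## Resampling robustness

Stability is measured by re-clustering `n_resamples` (default 100) random
draws of `round(frac·n)` SNPs (default 80%, without replacement) with the
full-sample parameters. Each resample's clusters are matched to the
full-sample clusters by greedy maximum overlap — repeatedly pairing the
unpaired (reference, candidate) clusters sharing the most SNPs; unmatched
candidate clusters get fresh labels beyond K, which is how a resample that
splits a cluster shows up. Greedy matching can diverge from optimal
assignment when clusters are near-equal in overlap; for well-separated
clusters it is exact and deterministic, which is why it was chosen.
Per-cluster consistency pools SNP×resample observations:
100 × (#observations matched to the cluster) / (#observations of its SNPs).
A per-SNP averaging denominator would be the alternative reading; pooling was
chosen and is what the reported percentages mean. One root seed spawns
per-resample generators, so any single resample can be reproduced in
isolation.

## LD pruning

Within each cluster, multiallelic SNPs and SNPs with missingness strictly
greater than `max_missing` (default 0.10; exactly 10% is retained) in the
reference panel are removed, then SNPs are greedily pruned: visiting SNPs by
decreasing row-max |z| (ties by id), a SNP is kept iff its r² with every
already-kept SNP is ≤ `r2_threshold` (default 0.3). r² is the squared
product-moment correlation of dosages over pairwise-complete panel samples
(composite LD — no phasing needed, sensible for imputed dosages); pairs with
fewer than 3 complete samples or a monomorphic member get r² = 0 with a
warning. The kept set is maximal and order-independent given the priorities.
Keeping the higher-|z| member of a correlated pair is a convention — the most
informative SNP survives.

## Polygenic scores

A cluster score is PRS_i = (1/M) Σ_j w_j (g_ij − 2f_j): signed z weights for
the effect allele, dosage centred by twice the reference effect-allele
frequency, averaged over the M weight SNPs. Division by M ("mean scaling")
makes scores comparable across clusters of different sizes, which the
relative score ΔPRS = PRS_a − PRS_b requires; z-standardization across the
cohort is the alternative reading of mean scaling and is available as an
option, but is not the default because it erases between-cluster scale.
Weights require a study with direction of effect — a p-value-only study
cannot define signed weights, and its cluster simply cannot be scored (the
HS-Aging-like phenotype in the synthetic default). Where a study's convention
defines the effect allele as the reference minor allele, the
`minor_allele_rule` reassigns it (flipping the weight's sign if that swaps
the stated alleles; frequency ties at 0.5 pick the alphabetically first
allele). Alignment to the cohort's counted allele flips w and f when the
non-effect allele is counted, and drops SNPs matching neither stated allele.
Missing dosages impute to 2f (exactly zero contribution), and individuals
missing more than `max_missing` of a score's SNPs are excluded from that
score — and hence from any ΔPRS involving it. Dosages are real-valued in
[0, 2] throughout (imputed data, not hard calls).

## Trait association

"One-way ANOVA controlling for covariates" is implemented as the partial
F-test for the group factor in a linear model that always contains the
covariates (age, binary-coded sex, prior-GWAS inclusion as a categorical
dummy-coded factor): F = [(RSS_reduced − RSS_full)/df₁] / [RSS_full/df₂].
Sums-of-squares typing reduces to this covariates-always-included comparison
(type-II style). Complete cases only, with logged counts; singular designs
raise, naming the collinear columns. Pairwise follow-ups are pooled-variance
two-sided t-tests, BH-adjusted within their family. Regional burden scans
treat the 5-level ordinal rating {0, 0.5, 1, 2, 3} as a categorical factor
(matching the per-level pairwise structure; trend tests are a non-goal), BH
across all scanned regions by default (the family is configurable), with
pairwise follow-ups only in regions passing FDR. Mutation-carrier subset
analyses reuse the same partial F-test with sample filters and binary
impairment factors (any-MND vs none; any-cognitive vs none).

## Enrichment

Cluster SNPs map to genes through a user-supplied two-column table; the gene
universe is the union of the GMT file's members (a "reference list"
semantics), query genes outside it are dropped with a warning. Per term:
expected = n_query·n_term/|background|, fold = overlap/expected, p =
P(X ≥ overlap) from the hypergeometric distribution, BH across terms.
Overrepresentation only; depletion is a non-goal. Results on real annotation
snapshots are version-dependent by nature and are not a reproduction target.

## Synthetic data

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes — it defines the study conditions
the tests run under.

* **Summary statistics**: 4,945 SNPs in five planted groups — single-phenotype
  1910/1450/1042 and phenotype-pair 144/121 (pair groups an order of magnitude
  smaller), plus 278 null-background SNPs. Group |z| profiles are Normal
  (truncated at 0) around means like (4.5, 0.8, 0.8) for single-phenotype and
  (3.2, 3.2, 0.8) for pair groups with noise sd 0.3; the null background is
  isotropic around (2.2, 2.2, 2.2) with sd 0.9 — elevated |z| (these SNPs
  passed a top-fraction selection) but incoherent shape. |z| is simulated
  directly rather than via genotype-level GWAS because the clustering consumes
  nothing else. The ALS-like study reports signed β/se (random signs — the
  clustering must ignore them, the scores must use them), the FTLD-like study
  reports β/se and the matching p, and the HS-like study reports p only, so
  the cannot-score-a-directionless-study path is always exercised.
* **Reference panel**: allele frequencies Uniform(0.05, 0.95); haplotypes
  from a latent Gaussian chain with neighbour correlation `ld_rho` (default
  0.8) within blocks of 10 consecutive SNPs, thresholded per-SNP at its
  frequency; diploid dosage = sum of two haplotypes; 2% missingness; 1% of
  variants flagged multiallelic. The frequency table reports realized
  frequencies.
* **Cohort** (n = 260): genotypes at HWE from the reference frequencies;
  *generative-truth* weight tables built from the planted groups (the
  cohort's latent risk must not depend on the analysis run on it); latent
  variable = standardized ΔPRS (FTLD-like − ALS-like). Clinical group comes
  from a multinomial whose baseline matches the cohort margins (125/31/104
  for MND-only / Cog+MND / Cog-only) with logits shifted ±`group_effect`
  (default 1.0) × the latent score. Burden in the four FTLD-characteristic
  regions shifts by `burden_effect` (default 0.8) × the latent score on a
  latent-normal ordinal scale; the two ALS-characteristic regions are
  independent of it; one third of individuals lack burden ratings (no
  neuropathological assessment). Covariates match the sample marginals: age ~
  N(64.5, 9.9), P(male) = 0.57, prior-GWAS inclusion (none/ALS/FTLD) ≈
  (0.62, 0.28, 0.10), mutation categories ≈ (48% none, 44% C9orf72-like, 6%
  GRN-like, rest rare).
* **Annotation fixture**: SNP→gene in position order, random gene-set terms
  plus one term spiked with a designated cluster's genes.

What the generator does *not* emulate: realistic human LD maps and MAF
spectra, population structure and ancestry confounding, genotype-level effect
sizes and winner's-curse in the selection step, correlated noise between
phenotypes, repeat-expansion genetics. Passing tests therefore demonstrate
that the *procedure* behaves as specified under its assumed structure — not
that real data would yield these cluster counts or F statistics.

## Numerical and engineering choices

* Cluster recovery evaluation excludes planted-null SNPs: absorbed null SNPs
  whose realized profile genuinely resembles a cluster's shape are not
  recoverable errors any method could avoid.
* Dendrogram ties are resolved by scipy's deterministic nearest-neighbour
  chain; label numbering ties (equal sizes) break by first member position.
* The problem sizes used by the test suite and acceptance script (full
  ~5,000-SNP scenario for cluster counting; 2,000 SNPs × 100 resamples for
  stability; 20-seed Monte-Carlo at reduced scale for contracts and power)
  were chosen to keep full runs at desk scale while leaving the pair-group
  clusters above the minimum cluster size.
* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  spawning; identical configs give byte-identical artifacts, and every
  written table carries a provenance header (config hash, seed, stage).
* Scores, r² and consistency percentages are plain floats; no tolerance
  tuning is applied anywhere in the pipeline itself.

## Known limitations

* Correlations of three-element profiles are coarse; the TOM step mitigates
  but cannot remove this, and with more phenotypes both forms of adjacency
  would behave better.
* The static dendrogram cut needs a sensible `cut_height_frac` for the data
  at hand; adaptive branch decomposition would remove that knob.
* Greedy label matching and greedy LD pruning are order-deterministic
  heuristics, not global optima.
* The ANCOVA treats ordinal burden as categorical, spending degrees of
  freedom; an ordinal-regression treatment is explicitly out of scope.
* Composite (dosage-correlation) r² differs from phased-haplotype r²,
  especially at low frequencies.
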