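# Methods

This note documents the models, parameter choices and numerical decisions
behind each module, and what the synthetic-data validation does and does not
demonstrate about real data.

## Lea-Coulson rate estimation

A fluctuation assay observes, for each of C parallel cultures, the number of
selectable mutants at plating. Under the Lea-Coulson model (wild type and
mutants grow at equal rates), mutation events per culture are Poisson(m) and
each event founds a clone whose final size K has P(K = k) = 1/(k(k+1)) — the
limit law of a mutation arising uniformly over exponential growth and growing
exponentially thereafter. The pmf of the per-culture count is computed by the
Ma-Sandri-Sarkar recursion, which is the Panjer compound-Poisson recursion
with that jump law.

Numerical choices:

* **Jackpot cap.** Counts above a cap (default 150) contribute the right-tail
  probability P(K ≥ cap) to the likelihood instead of a pmf value. This keeps
  the recursion length bounded while preserving the information jackpot
  cultures carry (essentially "the count is large").
* **Optimizer.** Bounded 1-D maximization of the log-likelihood (Brent,
  tolerance 1e-6 in m) with an expanding upper bracket; m̂ = 0 is returned
  when the likelihood is non-increasing from the origin, as with all-zero
  counts.
* **Confidence intervals.** Profile-likelihood ratio bounds at χ²₁(0.95)/2
  below the maximum, found by bisection. All-zero experiments get a one-sided
  interval from the exact exponential likelihood e^(−Cm).
* **Partial plating.** When a fraction ε < 1 of each culture is plated, each
  clone is thinned Binomial(k, ε). The thinned jump law is computed by a
  truncated sum (accurate for ε ≥ ~0.01) and fed to the same recursion;
  ε = 1 reproduces the plain recursion exactly and is the default, matching
  the assay convention in which dilution before selective plating is not
  corrected for.

The rate is m̂/Nt with Nt = colonies × dilution factor from a permissive
plate count. Replicate assays are reported individually plus their mean;
fold differences between strains are simple rate ratios.

## Pooled-amplicon mutation calling

N independently derived mutants are pooled in equal proportions, so each
mutation is expected at frequency 1/N. The caller consumes a per-position
pileup (allele counts at each amplicon coordinate) and a read-pair
co-occurrence table; it never touches reads.

Rules, all configurable via `PoolConfig` with defaults at the validated
operating point:

* Sites outside the callable interval or with depth < 200 are removed;
  the pool fails QC when < 40% of amplicon positions survive (the coverage
  rule is pool-level because a single site cannot "cover" an amplicon).
* Alleles with frequency in [0.65/N, 0.95] (both ends inclusive) become
  calls; below the window is sequencing error, above it is a fixed
  strain-specific variant routed to the strain-identity check (fraction of
  fixed alleles matching the expected strain's SNP set, PASS at ≥ 0.9).
* Adjacent same-kind indels whose frequencies differ by < 0.10 (absolute)
  merge into one call at the leftmost position with the mean frequency;
  merged spans > 1 bp are excluded from single-bp indel spectra.
* Pairs of calls within 10 bp, with frequencies within ±0.09 (absolute) and
  with ≥ 70% of informative read pairs carrying both alleles, become MNMs;
  MNMs sharing a member merge transitively into complex MNMs. Candidate
  pairs lacking a co-occurrence record are left unresolved rather than
  merged. The ±9% and <10% tolerances are interpreted as absolute frequency
  differences, the natural reading since frequencies are the compared
  quantities.
* Multiplicity: with μ and σ the mean and population SD of all call
  frequencies in the pool, calls with f > μ + 2σ represent round(f/μ)
  pooled mutants; all others count once.
* Substitutions are strand-collapsed to the six A/C-centered classes;
  consequences come from standard-code codon translation on the ORF strand.

## Polymorphism spectra

* **Polarization.** The ancestral allele is accepted when ≥ 4 of 5 outgroup
  genomes are fixed for one allele *and* that allele matches the panel ref
  or alt; outgroup consensus on a third allele leaves the site uncallable
  and excluded.
* **Filters.** Biallelic SNPs, missingness strictly < 0.20, inside the
  mappable-region mask, outside the repeat mask, ancestral callable, derived
  allele frequency strictly < 0.5 (guards against mispolarization).
* **Counting modes.** All-variant spectra weight homozygous derived
  genotypes 2 and heterozygous 1; rare-variant spectra (derived allele count
  2–4, diploid convention) weight both 1, as do singleton spectra, which
  additionally require the variant to be private to the strain and
  homozygous in haploid/homozygous-diploid strains, heterozygous otherwise.
* **Relative exclusion.** Pairs closer than 8,000 differences are broken by
  iteratively dropping the member of the closest pair with more close
  relatives (ties: lexicographically later name), a deterministic rule.
  Allele counts are recomputed after exclusion.
* **PCA.** Populations are subsampled to ≤ 30 strains (seeded) to balance
  representation; strains with < 8 counted variants are excluded; spectra
  are normalized, mean-centered and decomposed with full-rank SVD. Each
  loading's sign is fixed so its largest-magnitude entry is positive, making
  projections reproducible.
* **C>A enrichment.** Strains are ranked by rare-variant C>A fraction and
  the top 5% flagged. The bootstrap null resamples each strain's variant
  count from the panel-pooled rare-variant class distribution with add-one
  smoothing, p = (1 + #{resampled fraction ≥ observed})/(B + 1), B = 10,000.
  Since only the C>A fraction is scored, the resampled C>A count is drawn
  from its exact binomial marginal — identical in distribution to
  multinomial resampling and much cheaper. This exchangeable null is a
  deliberate design choice where several bootstrap schemes would be
  defensible; it treats every strain as drawing from the common pool, so its
  p-values are calibrated against panel-average composition, not against
  phylogenetic structure.

## Spectrum comparison

Two spectra form a 2×K table (K = 6, or 8 with single-bp indels; zero
columns are retained). The point probability of a table conditional on both
margins is multivariate hypergeometric, computed in log space. Significance
is Monte-Carlo exact: B tables are drawn from the margin-conditional null by
multivariate-hypergeometric sampling of row 1, and
p = (1 + #{tables with probability ≤ observed})/(B + 1), with a small
relative tolerance when comparing log-probabilities so equally probable
tables count as ties. The add-one form keeps p > 0. We use the standard
extremity direction (tables *at most* as probable as observed are extreme);
counting *more* probable tables would assign the modal table p ≈ 0, which
cannot be the intended behavior of an exact test. Degenerate margins (an
empty row, or a single non-empty column) force p = 1. Bonferroni correction
multiplies the raw p by the number of comparisons (the cutoff for 35 tests
at α = 0.05 is 0.05/35 ≈ 0.001429); the number of tests is a parameter, not
an inference.

**Target size.** The nonsense target of an ORF is exactly enumerable: each
position of each non-stop codon contributes (number of stop-creating
substitutions)/3 bp-equivalents. The effective target scales this by the
observed ratio of all point mutations to nonsense mutations, reconstructing
the classic missense-to-nonsense approach; it assumes all nonsense changes
inactivate the reporter and that missense hotspots are captured by the
observed ratio.

## Synthetic data: what it emulates, and what it does not

* **Fluctuation experiments** grow cultures by synchronous doubling from n0
  to n0·2^G cells with Poisson-thinned mutations per generation and
  deterministic doubling of mutant clones — the textbook construction whose
  limit is the Lea-Coulson law. Defaults follow the assay design: 96
  cultures, m near 1. Requested final sizes are rounded down to the nearest
  reachable n0·2^G and the realised m recorded in the truth object. Clone
  sizes are powers of two, so the simulated distribution is the discrete
  Luria-Delbrück variant; the estimator recovery results (median |m̂−1| <
  0.1, ~95% CI coverage) show the Lea-Coulson MLE is robust to this
  discretisation, as it must be for real cultures that also divide in
  near-synchronous generations.
* **Pools** plant one mutation per mutant (class from a configurable
  spectrum, position uniform, expected frequency 1/N, binomial read
  sampling), add uniform strand-symmetric substitution errors (no quality
  scores, no indel errors), and convert a configurable fraction of mutants
  into two-site MNMs with ~98% read co-occurrence. Validation at 38 mutants,
  2,000× depth and 0.3%/bp error — a deliberately harsher error rate and
  lower depth than a clean amplicon run — gives ≥ 37/38 recall with zero
  false positives across 20 pools. Real amplicon data add correlated,
  position- and context-dependent errors that this uniform model does not
  capture, so these numbers bound pipeline logic, not platform behavior.
* **Panels** assign each variant an originating clade, a carrier count k
  with P(k) ∝ 1/k (k ≤ 20), and carriers within the home clade first —
  producing clade-clustered spectra without simulating a coalescent. Strains
  are haploid (genotypes homozygous, allele count 2 per carrier). The
  mutator clade draws its rare variants (carrier count ≤ 2, allele count ≤
  4) from the base spectrum with C>A multiplied threefold and renormalized
  (base 0.10 → 0.25), the effect size the analysis is designed to detect.
  One in ten records is emitted with ref/alt swapped to exercise
  polarization. The base spectrum (A>G 0.28, C>T 0.38, transition-heavy) is
  a realistic yeast polymorphism composition. No linkage, no shared
  phylogeny beyond clade labels, and no sequencing error are modelled;
  passing recovery tests therefore demonstrates the statistical pipeline,
  not robustness to ancestral-state error or cryptic relatedness, which the
  real filters (outgroup support, DAF < 0.5, relative exclusion) mitigate
  but the simulation does not stress.

## Validation problem sizes

The statistical validation suite uses: 1e6 Monte-Carlo replicates for the
pmf total-variation check (threshold 0.01 at m ∈ {0.1, 1, 5}); 200
experiments × 96 cultures for MLE recovery; 20 pools for caller
recall/precision; 500 null pairs (n = 300 draws each, B = 2,000) for the
type-I rate and 200 pairs (B = 10,000) for power at the 0.05/35 cutoff; and
100 panel replicates at 8 clades × 20 strains × 2,000 variants/strain for
mutator recovery. These sizes make Monte-Carlo error small relative to each
acceptance band while keeping the suite quick on a laptop.

## Known limitations

* The Lea-Coulson model assumes equal mutant/wild-type fitness; differential
  growth variants are out of scope.
* The plating-efficiency correction truncates an infinite series; for
  ε < 0.01 the truncation error is no longer negligible.
* The caller trusts the provided co-occurrence table; without records it
  will under-call MNMs (by design) rather than guess.
* The bootstrap enrichment null ignores phylogenetic correlation between
  strains; clade-level enrichment signals should be read as descriptive
  ranks plus per-strain calibration against the pooled panel.
* The target-size estimate inherits the single-reporter assumption that
  synonymous changes never inactivate the gene.
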