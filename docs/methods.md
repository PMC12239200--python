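# Methods

This note documents the models behind each analysis stage, the parameters
that matter, the numerical choices, what the synthetic generators do and do
not emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Haplotype classification and signatures

A gene-copy table (CDS FASTA + metadata TSV) lists full-length gene copies
with 1-based, fully closed genomic coordinates (GFF3 convention). CDSs are
stored on the coding strand 5′→3′ regardless of genomic strand; the strand
field only orders and orients copies. Signal-peptide cleavage offsets are an
input column (a whole number of codons removed from the 5′ end before
divergence analyses); prediction of the cleavage point is upstream of this
package.

Copies of one role are grouped by single-linkage clustering on pairwise
ungapped CDS identity, with positions containing N excluded pairwise and
unequal-length pairs compared after codon-level global alignment. The
default identity threshold is 1.0: a haplotype "shares a gene copy" with
another exactly when the CDSs are identical. The threshold is exposed
because small within-class variation is a defensible alternative reading;
single linkage with labels fixed to the lexicographically smallest member id
makes the partition deterministic and input-order invariant.

A haplotype signature is the start-ordered list of (class, role,
orientation, gap_before) elements, where orientation is relative to the
haplotype's majority strand and gap_before marks an inter-copy distance
(start − previous end − 1) above `gap_threshold_bp` (default 1000).
Signatures are canonicalized so that reading the same haplotype from the
opposite genomic strand — reversed order, flipped orientations, gap markers
shifted onto the new downstream element — produces the same key; the
canonical key is the lexicographic minimum of the two renderings. One
signature per genome (homozygous inbred assumption); genomes lacking the
locus contribute nothing to the sample size.

Premature stops are in-frame TAA/TAG/TGA before the terminal codon; inputs
whose length is not a multiple of three are rejected rather than silently
trimmed.

## Ewens sampling formula machinery

For a sample of n haplotypes, the configuration a = (a₁…a_n) follows the
ESF under the neutral infinite-alleles model. All probability computation is
in log space with log-gamma (no explicit factorials; n ≈ 50 overflows naive
ones). Supporting quantities: E[a_j] and E[K] = Σ θ/(θ+i) in closed form,
both verified against exhaustive partition enumeration and against the
Chinese restaurant process sampler.

θ is estimated by grid search over integers 1…200 by default (configurable;
ties break to the smallest value). k is sufficient for θ, so the maximizer
depends on (n, k) only — asserted as a property test.

### The neutrality p-value

The default test is a **partition-likelihood** (exact conditional) test:
p is the total ESF probability, at the fitted θ, of all configurations no
more likely than the observed one — the likelihood-ordering construction of
the exact multinomial goodness-of-fit test applied to whole allele
configurations. It is enumerated exactly for n ≤ 60 (the partition count of
60 is under a million) and Monte-Carlo sampled above that. Because θ̂
depends on the data only through k, refitting does not use up the
configuration shape the test examines, and simulation shows near-nominal
calibration (the rejection rate at the 0.05 level over 200 neutral
replicates at n = 30, θ = 5 sits inside the binomial confidence band; run
in the test suite).

An alternative **ranked-multinomial** construction is provided behind
`test="ranked_multinomial"`: the k observed class counts, ranked by
decreasing frequency, are compared by multinomial goodness-of-fit to the
expected ranked ESF class-frequency vector (mean sorted class sizes over
CRP draws conditioned on ≥ k classes, truncated to k ranks, renormalized).
This reading was considered as the default, but the same calibration
simulation rejects at rate 0.0 with median p ≈ 0.99: ranking the counts
discards the sampling variability of which class lands in which rank, so
observed ranked counts almost always resemble the expected ranked vector.
The construction is kept for comparison, not as the default.

The multinomial goodness-of-fit primitive itself (p = Σ over outcomes x
with P(x) ≤ P(observed)) auto-selects exact enumeration when the
composition count is ≤ 10⁶ and otherwise uses vectorized Monte Carlo with
an explicit seed and an add-one correction so p > 0. Ties with the observed
outcome's probability are included using a relative log-probability
tolerance of 1e−9.

## Synonymous divergence and dating

Site and difference counting follows Nei–Gojobori (1986): per codon
position, the synonymous site fraction is the share of possible changes
that preserve the amino acid (changes to stop codons count as
nonsynonymous), averaged between the two sequences; multi-difference codons
average their synonymous/nonsynonymous step counts over all substitution
orders, excluding pathways through stop codons (falling back to all
pathways when every one is blocked). Codon columns with a gap or N in
either sequence are excluded whole (pairwise deletion); columns that are
stop codons in either sequence are excluded with a warning, or a hard error
on request.

Synonymous differences are split into transitions and transversions;
Ps = syn transitions/S and Qs = syn transversions/S feed the Kimura
two-parameter correction. `ks_k2p` defaults to **modified** Nei–Gojobori
counting with transition changes weighted κ = 2 in the site count (a
typical nuclear ts/tv rate ratio): with unweighted counting, a
transition-biased process makes per-synonymous-site rates exceed μ and
Ks overshoots 2μT by ~20% at κ = 2. `count_syn_sites_diffs` keeps κ = 1 as
its own default so its documented per-codon values (e.g. S = 1/3 for Lys)
hold; a plain all-site K2P distance is also available. Arguments at or
beyond the K2P domain boundary raise a saturation error naming the pair;
saturated pairs are excluded (with a warning) from group means.

Ages are T = Ks/(2μ) × generation time, with μ = 3.3×10⁻⁸ per site per
generation and 1 generation/year (annual species) as defaults. Averaging
ks then converting equals converting then averaging (linearity); the
group-mean routine averages over all |A|×|B| cross pairs and never
within-group pairs.

The pairwise codon aligner (global Needleman–Wunsch on codons, match +1 /
mismatch −1 / gap −2, diagonal-then-up tie break) is a convenience for
unequal-length inputs; production alignments normally arrive precomputed.

**Accuracy.** Parameter-recovery simulations (in the test suite and the
acceptance script) recover 2μT within Monte-Carlo error for Ks up to ~0.1
at 300 codons and up to ~0.8 at 550 codons (a typical cleaved PME CDS
length). In the saturation approach (Ks ≈ 0.8–1.1, i.e. the 12–17 My
contrasts at the maize rate) the estimator carries a reproducible upward
bias of roughly 5–12%: the K2P correction is convex near its domain
boundary, so sampling noise in Ps/Qs inflates the mean, and the correction
treats the synonymous-site process as homogeneous K2P although two-fold
degenerate sites admit only transitions. Age tests therefore assert 3-SE
unbiasedness below 2 My and 15% relative accuracy at 12/17 My.

## siRNA counting and enrichment

A read "targets" a reference gene when the read is exactly 24 nt and its
sequence or reverse complement is an exact substring of the reference
(mismatch tolerance configurable, default 0 — the strictest reading).
Counting is of unique sequences; abundance is ignored (an
abundance-weighted mode exists). Normalization is count × 2×10⁷ /
total_reads, with total_reads the library size across all read lengths.

Welch's t-test (unequal-variance t with Welch–Satterthwaite df, two-sided
Student-t p) compares the ga1-O and active-Ga1 genotype classes, by default
on raw unique counts, optionally on normalized values. The primitive
refuses both-groups-constant input; the pipeline maps that degenerate case
to p = 1 (equal means) or p = 0 (different means with zero within-group
variance). Allele of origin is assigned by exact containment (either
strand) against allele-specific sequence sets: a 24-mer spanning an
allele-private SNP becomes allele-specific.

The phase-register score is deliberately simple and is this package's own
definition, not a published phasing statistic: the fraction of 5′ start
positions in the modal residue class modulo 24. Perfect phasing scores 1.0;
uniform starts score ≈ 1/24.

## Synthetic-data generators

Every generator is a pure function of its seed. They emulate the
*statistical structure* each stage assumes, not the sequence content of
real loci — passing tests demonstrate correct inference under the stated
models, not robustness to alignment error, assembly artifacts, multi-mapping
reads or selection, none of which are simulated.

- **CRP haplotype samples** are exact ESF draws (verified by chi-square
  against the closed form). A vectorized batch sampler serves the
  conditioned-expectation and calibration computations.
- **Codon divergence** evolves two branches of length T from a random
  stop-free ancestor (uniform over the 61 sense codons) using exact K2P
  matrix-exponential site probabilities — no event discretization error at
  any T. Total rate μ per site per generation, κ = 2 by default.
  Nucleotide-level evolution can create stop codons in descendants; the
  dating stage excludes those columns, mirroring real pseudogene handling.
- **Locus tables** render CRP (or planted) haplotype classes as 1–4 copies
  with random roles, globally distinct CDSs, inter-copy gaps drawn on both
  sides of the 1 kb threshold and a per-class strand, at shifted coordinates
  per genome — so exact-identity classification recovers the planted
  spectrum exactly, and planted premature stops are recovered exactly.
- **siRNA libraries** draw unique-match counts from a negative binomial
  (variance m + m²/dispersion). Defaults represent the contrast seen in
  maize anther small-RNA data at these loci: base silk-target mean 2 in
  active-Ga1 lines, effect multiplier 59 (a 2 vs 118 per-20M contrast),
  equal pollen-target means (~5.5), three libraries per genotype class,
  2×10⁷ total reads. Dispersion 10 is the value at which that contrast is
  Welch-detectable at n = 3 per group (within-group sd near 40 at mean
  118). Matching reads are sampled as exact substrings of the generated
  references; non-matching 24-mers and off-length reads form the
  background.

## Numerical and design choices

- Probability sums use log-sum-exp; spectra validate Σ j·a_j = n at
  construction.
- Multinomial and partition Monte Carlo use add-one-corrected frequencies,
  keeping p in (0, 1].
- Welch on small negative-binomial counts (means ~2, n = 3) is inherently
  conservative because of discreteness; the type-I calibration simulation
  therefore runs at a mean (50) where the test's normal approximation is in
  force, while power is measured at the study's own effect size.
- The universal nuclear genetic code is assumed throughout (nuclear PME
  genes).
- Degenerate inputs fail loudly: empty copy lists, mixed roles or loci,
  duplicate genome ids, frame violations, zero synonymous sites and
  saturated distances all raise typed errors rather than returning NaNs.

## Limitations

- The neutrality test conditions on the fitted θ rather than integrating
  over its uncertainty; with k sufficient this leaves the test close to
  nominal, but p-values at very small n are discrete and conservative.
- Ks-based ages inherit the estimator bias described above near
  saturation, and assume rate constancy, no selection on synonymous sites
  and a single μ across lineages.
- Haplotype classification assumes pre-filtered full-length gene copies;
  truncated fragments must be removed upstream.
- siRNA matching is exact and unweighted; multi-mapping weighting and
  mismatch-tolerant alignment are out of scope.
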