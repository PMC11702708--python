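# Methods

## Setting

A dominant-negative disease allele can be inactivated without targeting the
causal mutation itself: two CRISPR cuts at common heterozygous SNPs flanking
the gene excise one haplotype's entire gene body, and allele-specific guides
confine the cuts to the mutant haplotype.  The package implements the
computational layer of this strategy: population-scale reagent design,
per-patient phase inference, guide enumeration, and digital-PCR readout of
editing outcomes.  Coordinates are 0-based half-open internally; VCF
positions are converted at the I/O boundary only.

## Panel model and pair selection

A phased panel is an `(N, M, 2)` array of allele indices over N diploid
individuals and M biallelic SNPs.  Allele frequencies are always recomputed
from the stored haplotypes (never trusted from VCF INFO fields) so that
frequency filters, heterozygote counts and LD are mutually consistent.
Multi-allelic records, indels and records with missing genotypes are
skipped and counted; unphased genotypes are an error in the default strict
mode, because double-heterozygote coverage requires complete diplotypes.

Candidate variants are those with alternate-allele frequency in
[0.1, 0.9] — bounds inclusive; the exclusive variant is a keyword away —
lying in the half-open windows `[gene.start − flank, gene.start)` and
`[gene.end, gene.end + flank)` with `flank = 50 kb` by default.  A left ×
right pair is retained when its excision span (left SNP to right SNP, which
by construction contains the gene) does **not fully contain** any protected
neighbouring interval: a span that merely overlaps a neighbour truncates
rather than excises it, and a stricter overlap-based exclusion is available
as a flag.  Per pair, the covered set is the individuals heterozygous at
both SNPs.  LD between sites is the squared haplotype correlation
`r² = (p₁₁ − p₁q₁)² / (p₁(1−p₁)q₁(1−q₁))` computed from the 2N phased
chromosomes pooled across the panel.

## Greedy portfolio

Reagent selection is classic greedy maximum coverage: at each step, pick
the candidate whose covered set adds the most not-yet-covered individuals;
stop at a target coverage, an item cap, or exhaustion.  Ties are broken
deterministically — smaller excision span first (shorter excisions are
preferred in practice), then lexicographically by span coordinates — so the
result is invariant to input order.  Marginal gains are non-increasing by
submodularity, and greedy coverage is within (1 − 1/e) of the exhaustive
optimum at every prefix; both properties are asserted in tests against a
subset-enumeration oracle.

Three therapy modes share this machinery: SNP pairs (covered =
double heterozygotes), anchored singles (one constant biallelic guide plus
one allele-specific guide; covered = heterozygotes at the single SNP; the
anchor adds one reagent in total), and the mutation-specific baseline,
idealised as n equal-frequency mutations so k reagents cover k/n of
patients.  Reagent counts deduplicate SNPs shared between selections
(`per_snp`, the default, one optimised enzyme/guide per SNP site) or count
each targetable allele separately (`per_allele`, twice the distinct sites).
An alternative greedy objective that maximises coverage per newly
introduced reagent is available behind a flag.

## Phase inference

Given a patient's dosage vector over a SNP subset and the population
haplotype-frequency table for that subset (counted from the 2N phased
chromosomes; optionally restricted to a population), every unordered
haplotype pair consistent with the genotype is scored under Hardy–Weinberg
pairing, `L(h₁,h₂) = 2f(h₁)f(h₂)` (or `f(h)²` when homozygous), and
posteriors normalise over consistent pairs.  Pseudo-count smoothing
(`pseudo = 1` spread over the consistent patterns) is applied **only** when
no pair of observed haplotypes is consistent, and the call is flagged.
Calls with top posterior below 0.95 are flagged low-confidence rather than
refused.  One anchored variant — a SNP whose allele in cis with the
mutation was determined experimentally — identifies which inferred
haplotype carries the mutation; that haplotype's alleles at every subset
variant are the propagated cis-allele map.  The anchor must be heterozygous
in the inferred diplotype, otherwise it is uninformative and an error.

## Guide enumeration

Both strands of both allele-substituted sequences are scanned for the PAM
pattern (default NGG; IUPAC codes accepted).  Every 20-nt protospacer whose
protospacer-or-PAM window covers the SNP is emitted with the SNP's position
counted 1..20 from the PAM-proximal end (0 = inside the PAM) and a
discrimination class: `seed` (position ≤ seed length, default 10 nt — the
conventional seed definition, configurable), `non_seed`, `snp_derived_pam`
(PAM valid on exactly one allele), or `pam_snp` (SNP at the PAM's
unconstrained base; no discrimination).  The predicted blunt cut sits
between protospacer positions 3 and 4 from the PAM, the canonical position
for this enzyme class.  Candidates are exhaustive and annotated, not
ranked: cleavage-efficiency prediction is out of scope, and a seed-region
SNP is no guarantee of discrimination in cells — the classes describe the
mechanism, not a promise.  Guide pairs are allele-specific when at least
one member discriminates: one discriminating guide plus one biallelic guide
already confines the excision to one haplotype.

## Digital-PCR estimators

Partition tables hold joint positive/negative counts over named channels.
The default estimators are the raw positive-partition ratios used in
practice; Poisson occupancy correction (`λ = −ln(1 − k/n)` per channel) is
an explicit option:

* **Excision/inversion frequency** = junction-positive / reference-positive
  partitions.  The reference assay and the gene both contribute two copies
  per genome, so the ratio estimates the excised fraction of all gene
  copies.  The raw ratio is biased upward at higher loading (concavity of
  `1 − e^{−λ}`); the Poisson-corrected ratio `λ_junction/λ_reference` is
  not, and is what the recovery tests and the reproduction script use.
* **4-plex specificity** = among junction-positive partitions positive for
  exactly one allele probe, the fraction carrying the target allele.
  Triple-positive partitions (junction + both alleles, pure co-loading
  ambiguity) are excluded; their share of junction-positive partitions is
  reported and flagged at ≥ 10% (a configurable QC bound).
  Junction-positive partitions with no allele signal carry no information
  and are likewise excluded and reported.
* **Fractional abundance** = `k_A/(k_A+k_B)` (0.5 is the unedited
  heterozygote baseline) and **expression ratio** = target/reference
  positives, each with a Poisson-corrected variant.

Confidence intervals: Wilson for binomial proportions (clamped to include
boundary MLEs, which Wilson's shrunk centre can otherwise exclude); delta
method on the log scale for ratios, ignoring the weak between-channel
co-loading correlation.  Recovery simulations (below) confirm ≥ 90% pooled
coverage of 95% intervals across the tested parameter grid.

## Synthetic data: what it emulates, what it does not

* **Panels**: K founder haplotypes with per-SNP alt frequencies pinned near
  their targets (stochastic rounding of K·f, random placement — a pure
  Bernoulli draw per founder would leave realized frequencies with
  O(1/√K) scatter around the target); each of the 2N panel haplotypes is a
  founder mosaic that switches to a fresh founder between adjacent SNPs
  with a per-interval recombination probability.  Two parameters span
  perfect LD (K = 2, no recombination) to equilibrium, which is the axis
  pair coverage and phase inference care about.  No coalescent or
  demographic realism, no population structure, no mutation: realized LD
  decays with switch probability, not with genetic distance, so absolute
  coverage numbers on synthetic panels are not forecasts for any real
  cohort.
* **Carriers**: a private mutation is planted on one haplotype of one
  panel member; the truth record lists its cis alleles for scoring
  inference.  The panel itself is unchanged (the mutation is private).
* **Digital PCR**: molecule species load into partitions as independent
  Poisson counts (fragmented genomic DNA), each gene allele at rate λ_g
  and the 2-copy reference at 2λ_g per partition.  Per-allele edit
  probabilities derive from the excised fraction e of all gene copies and
  specificity s as `p_target = 2es`, `p_other = 2e(1−s)`.  The excision
  junction stays physically linked to its flanking-SNP allele on the same
  molecule — the premise of the specificity assay — so triple-positives
  arise only from co-loading and grow with λ_g.  No fluorescence rain,
  threshold noise or channel cross-talk: the estimators assume clean
  channel calls, as their real-world counterparts do after gating.

Passing tests therefore demonstrate correctness of the algorithms and
calibration of the estimators under these generative assumptions, not
robustness to instrument noise or demographic history.

## Problem sizes and numerical choices

The test suite and reproduction script use: cohort-scale panels of
N = 2,548 (matching the reference-panel cohort size) with 45 flank SNPs
for design; N = 2,000 panels, 4 founders, 1% recombination and 200 carriers
for phase recovery (accuracy ≥ 95%, degrading monotonically as
recombination rises through {0, 0.01, 0.05, 0.2}); 8,500-partition tables
(a common instrument plate format) with 50–100 replicates per cell of the
(e, s, λ_g) ∈ {0.05, 0.3} × {0.8, 0.99} × {0.05, 0.2} grid for estimator
calibration.  Greedy-vs-optimal checks enumerate all subsets on instances
of ≤ 20 samples and ≤ 8 pairs, where exhaustive enumeration is exact and
cheap.  All simulators are pure functions of (config, seed), and every
stochastic test fixes its seed.

Degenerate inputs are errors, not silent results: empty panels, saturated
digital-PCR channels (λ undefined), monomorphic sites in LD, genotypes
with no consistent haplotype pair (after smoothing), homozygous anchors,
and zero informative double-positives in the specificity ratio each raise
a dedicated exception.

## Known limitations

* Coverage optimisation is unweighted; ancestry- or prevalence-weighted
  selection and exact set-cover solvers are out of scope (brute force
  exists only as a test oracle).
* Guide annotation carries no efficiency or off-target scores.
* The phased panel is taken as ground truth; statistical phasing and
  imputation of the panel are out of scope.
* The digital-PCR model omits rain/cross-talk, and the CI for ratio
  estimators ignores between-channel correlation (conservative in the
  regimes tested).
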