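# haploedit

Design and quantification toolkit for **allele-specific haplotype excision**
— silencing a dominant disease allele by excising one haplotype's entire gene
body with a pair of CRISPR guides anchored at common heterozygous SNPs,
instead of designing one reagent per causal mutation.

It is written for genomics analysts and genome-engineering groups who need
to answer, computationally, the questions this strategy raises:

* **Which SNP pairs?** From a phased population panel (e.g. 1000 Genomes
  Phase 3 VCFs), find common variants (allele frequency 0.1–0.9) in the
  50 kb flanks of the target gene, enumerate left × right excision pairs
  whose span spares neighbouring genes, and count, per pair, the
  individuals heterozygous at both SNPs — the patients that pair can treat.
* **How many reagents for the population?** Greedy maximum-coverage
  selection of SNP pairs (or of single SNPs combined with one constant
  biallelic guide), plotted as patients treatable vs. unique Cas/gRNA
  count, against the one-reagent-per-mutation baseline.
* **Which haplotype carries the patient's mutation?** Diplotype inference
  from population haplotype frequencies under Hardy–Weinberg pairing,
  `P(h₁,h₂) = 2f(h₁)f(h₂)`, with one experimentally anchored variant
  propagating the mutation's phase to every flanking SNP.
* **Which guides discriminate the alleles?** Exhaustive protospacer/PAM
  enumeration at heterozygous SNPs, classifying each candidate as
  seed-region mismatch, SNP-derived PAM, or non-discriminating.
* **Did the edit work, and on the right allele?** Digital-PCR estimators:
  excision/inversion frequency as the junction-positive to
  reference-positive partition ratio (with optional Poisson occupancy
  correction, λ = −ln(1 − k/n)), and 4-plex allele specificity
  `s = n(junction ∧ target ∧ ¬other) / [n(junction ∧ target ∧ ¬other) + n(junction ∧ other ∧ ¬target)]`
  with triple-positive co-loading ambiguity excluded and reported.

A synthetic-data module generates every input — phased panels with
founder-haplotype block LD, mutation carriers with known phase, and
molecule-level digital-PCR partition tables — so the full pipeline runs and
is tested without any download.

## Worked example

```python
import haploedit as he

cfg = he.PanelSimConfig(
    n_individuals=500,
    left_positions=(24_905_000, 24_920_000, 24_940_000),
    right_positions=(24_960_000, 24_980_000, 25_000_000),
    founder_count=8, recombination_prob=0.02, target_alt_freqs=0.4,
    chrom="chr8", seed=0)
panel = he.simulate_panel(cfg)

locus = he.LocusModel(
    gene=he.GenomicInterval("chr8", 24_950_955, 24_956_869),
    protected=(he.GenomicInterval("chr8", 24_913_878, 24_919_064),))
cands = he.filter_common_flanking(panel, locus)
pairs = [he.double_het_coverage(panel, p)
         for p in he.enumerate_excision_pairs(cands, locus, panel)]
pf = he.greedy_pair_portfolio(pairs, panel.n_samples,
                              he.StopRule(target_coverage=0.8))
print(pf.summary_frame(he.CountingConvention("per_snp")).to_string(index=False))
```

```
 step   therapy  marginal_gain  reagents  coverage
    1 pair(2,4)            132         2     0.264
    2 pair(1,3)            105         4     0.474
    3 pair(2,3)             42         4     0.558
    4 pair(1,5)             38         5     0.634
    5 pair(2,5)              1         5     0.636
```

Each row is one greedy step: the pair covering the most not-yet-covered
individuals is added, `reagents` deduplicates SNPs shared between selected
pairs (step 3 reuses both of its SNPs, so the reagent count stays at 4), and
`coverage` is the cumulative fraction of the panel heterozygous at both
members of at least one selected pair.  Here the six simulated flank SNPs
saturate at 63.6% coverage before the 80% target, so selection stops at
exhaustion.

Quantifying an edit from a simulated 4-plex digital-PCR run (8,500
partitions, true excision fraction 0.30, true specificity 0.95):

```python
table = he.simulate_partitions(he.DpcrSimConfig(
    n_partitions=8500, lambda_g=0.1, excision_fraction=0.3,
    specificity=0.95, seed=1))
exc = he.excision_frequency(table, method="poisson_corrected")
spec = he.allele_specificity_4plex(table)
```

```
excision frequency: 0.293 (95% CI 0.265-0.325)
allele specificity: 0.958 (95% CI 0.935-0.973)
triple-positive ambiguity: 0.098
```

Both intervals cover the generative truth; 9.8% of junction-positive
partitions were triple-positive co-loading ambiguities, excluded from the
specificity ratio.

A `haploedit` command-line tool wraps the same functions
(`haploedit select|portfolio|phase|guides|dpcr --help`).

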