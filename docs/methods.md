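# Methods

This note records the statistical model behind each analysis, the default
parameters and why they hold their values, the simulators' realism limits,
and known estimator biases.

## 1. Clonality of somatic mutations

**Model.** A heterozygous somatic SNV/InDel in a diploid region of a clone
with cellular prevalence `c`, observed in a specimen of tumour content
(purity) `tc`, has expected variant allele frequency `f = c · tc / 2`: only
cancer cells of that clone carry the variant, on one of two alleles.
Inverting,

- `f' = min(f / tc, 1)` — purity correction, clipped because sampling
  noise can push `f` above the value a fully clonal mutation can attain;
- `c = 2 f'` when `f' ≤ 0.5`;
- when `f' > 0.5` the single-allele heterozygous model is violated
  (e.g. loss of the wild-type allele); the mutation is treated as clonal
  (`c = 1`) and the two-allele decomposition `(1, 2f' − 1)` is recorded.

**Diploid prescreen.** The doubling step assumes two alleles, so mutations
inside high-confidence copy-number-altered regions are excluded before
estimation (`select_diploid_mutations`).

**Assumptions.** One mutated allele per cancer cell; uniform sequencing
efficiency across alleles; purity known without error. Purity error
propagates multiplicatively into `c`.

## 2. Clonality of copy-number alterations

For amplified/deleted regions the somatic allele frequency is not directly
observable, so the allelic imbalance of inherited heterozygous SNPs is used
instead. Each SNP's B-allele frequency deviates from 0.5 in proportion to
the fraction of cells carrying the event:

- `median_af` — median of the region's het-SNP allele frequencies after
  mirroring about 0.5 (`max(af, 1 − af)`). Mirroring is necessary because
  which inherited allele sits on the affected haplotype is random per SNP:
  the raw frequencies form two clusters symmetric about 0.5, and the plain
  median of a balanced bimodal sample is arbitrary. Folding makes the
  estimator well defined and reflection-invariant.
- `f~' = 0.5 + (median_af − 0.5) / tc`, clipped to [0, 1];
- `c = min(2 |f~' − 0.5|, 1)`.

**Known bias.** The linear map from AF deviation to prevalence is exact
only for a fully clonal single-copy loss (CN = 1, where the folded AF
reaches 1 at `tc = 1`) and for the balanced case `c = 0`. At intermediate
prevalence the relation is curved, and for a single-copy gain (CN = 3) the
maximum attainable folded deviation is 1/6 (AF 2/3), so the estimator
saturates at `c = 1/3`. Estimates for amplifications should therefore be
read as ordinal, not absolute; the test suite asserts recovery only at the
exact points.

## 3. Clone-composition call

Alteration clonalities are binned: low `c < 0.35`, mid `0.35 ≤ c ≤ 0.80`,
high `c > 0.80`. The largest bin gives the label — polyclonal, biclonal or
monoclonal respectively — with ties resolved toward the less clonal label
(a conservative choice: claiming fewer dominant clones requires clearer
evidence). A Gaussian KDE with the nrd0 bandwidth
(`0.9 · min(sd, IQR/1.34) · n^(−1/5)`), evaluated on a 512-point grid and
renormalised over [0, 1], summarises the distribution; expected per-bin
counts are rescaled to sum exactly to the number of alterations.

Sensitivity: the 0.35/0.80 edges matter most for biclonal tumours whose
subclone sits near 50% prevalence at low purity, where binomial noise
spreads mass across an edge. The recovery experiment (300 tumours,
purities uniform in 0.4–0.9, depth 200) measures the induced error rate
directly; at these defaults it is ≈ 0.

## 4. Variant filters

Tumour somatic: ≥ 10 variant reads, VAF ≥ 5%, ≥ 1% of variant reads on
each strand. Normal: ≥ 2 variant reads (subtraction is deliberately more
sensitive than calling). Germline SNPs: ≥ 10 variant reads, strand
balance, VAF in [40%, 60%] or > 90% (heterozygous/homozygous genotypes).
Damaging: stop-gain/loss always; nonsynonymous when at least 4 of the 5
predictors with available calls vote damaging (missing predictors abstain
by default; a strict mode counts them as non-damaging). Rare: all
available population minor allele frequencies < 1%, unobserved counts as
rare. Cohort artifact removal drops variants absent from population panels
yet carried by > 50% of pooled samples — such sites are far likelier to be
recurrent alignment errors than true ultra-rare variants.

## 5. Gene-level copy-number status and drivers

A segment is a high-confidence aberration when CN ≠ 2, segmentation
reliability > 75, it holds ≥ 3 het SNPs, and Shapiro–Wilk rejects
normality of the SNP AFs at α = 0.05 (allelic imbalance makes the AFs
bimodal; a unimodal-normal AF cloud suggests a miscalled segment). A gene
is amplified/deleted when the union of same-direction high-confidence
segments covers ≥ 80% of its span; directions never sum, and a tie goes to
amplified. Putative drivers: any nonsilent mutation, or an oncogene
amplified / tumour suppressor deleted with the gene midpoint inside a
recurrently altered region.

## 6. Statistical policy

All burden comparisons use the one-tailed Wilcoxon rank-sum test (cohort A
stochastically greater), with three branches:

- **exact** (scipy, `method="exact"`) when the pooled sample is tie-free
  and has ≤ 20 observations;
- **normal approximation** with continuity correction for larger tie-free
  samples;
- **seeded Monte Carlo permutation null** (9,999 resamples,
  `(1 + hits) / (1 + R)` estimator) whenever ties are present. Mutation
  burdens are small integers, so ties dominate; the tie-corrected normal
  approximation measured a type-I error of 0.0558 ± 0.0017 (18,000 null
  replicates at the study regime, Poisson(0.3) burdens, n = 33 vs 406),
  while the permutation null holds level ≤ α by construction. The
  permutation stream is seeded from the sorted per-group values, making
  the p-value deterministic and invariant to sample order; the attainable
  p floor is 1e-4.
- degenerate pooled data (every value identical) carry no evidence and
  return p = 1.

Fisher's exact test (scipy) compares pooled class fractions; BH adjustment
(statsmodels) controls FDR across gene sets. Independent oracles —
permutation enumeration, exact-integer hypergeometric sums, the literal
step-up formula, per-base interval counting — live only in the test suite
and the acceptance script.

**MEGA bootstrap.** To control for unequal cohort sizes, the larger cohort
is resampled with replacement down to the smaller cohort's size and the
test re-run; the reported quantity is the fraction of iterations with
p < 0.05. Equal-size cohorts reduce to the indicator of the single test.

## 7. Expression classes

Per sample, over the full gene universe: not expressed (TPM < 0.1, taking
precedence), high (strictly above the 75th percentile), low (strictly
below the 25th), medium otherwise. Scaled-estimate matrices are converted
by × 1e6. Class fractions within a gene set are pooled over (gene, sample)
pairs into a 2×2 table and compared with Fisher's exact test; the
size-matched bootstrap draws |A| samples from the larger cohort without
replacement per iteration.

## 8. Synthetic-data generators and their realism limits

- **Tumours**: `alt ~ Binomial(total, c·tc/2)`, `total ~ Poisson(depth)`.
  No purity mis-estimation, no copy-number contamination of the "diploid"
  mutations, no FFPE artefacts, independent reads. Clone architectures for
  the recovery experiment: monoclonal (1.0 × 150 mutations), biclonal
  (1.0 × 60 + 0.5 × 90), polyclonal (0.25/0.20/0.15 × 50 each). The
  unequal biclonal counts make the generating class the modal bin under
  binomial noise — with equal counts the label would sit on a knife edge,
  testing the tie-break rather than recovery.
- **CNV segments**: per-SNP random affected haplotype; AF mixes normal,
  unaffected-cancer and affected-cancer cells with weights `1 − tc`,
  `tc(1 − c)`, `tc·c`. Subclonal events are uniform across the segment
  (no nested subclones).
- **Burden cohorts**: per-gene Poisson counts, background rate 0.015 per
  gene, so a 20-gene set has mean burden 0.3; the enrichment multiplier
  10/3 raises cohort A to 1.0. Defaults (33 vs 406 samples) match the
  studied regime. Genes are independent — no linkage or gene-length
  effects.
- **Expression**: baseline `LogNormal(μ=1.5, σ=2.0)` puts ≈ 3% of genes
  per sample below 0.1 TPM; suppression forces a random 10% of a target
  set's genes below the cutoff in every cohort-A sample. Defaults 14 vs
  193 samples. No gene–gene correlation, batch effects or count noise.

Randomness: one global seed feeds named substreams
(`SeedSequence(seed, crc32(name))`), so adding a generator never perturbs
another's output, and derived seeds stay below 2³¹.

## 9. Open design decisions

- Clonality bin edges (0.35, 0.80), the 80% overlap threshold, reliability
  75, predictor quorum 4-of-5, and the 1% rarity cutoff are domain
  conventions, exposed as constants/config rather than derived quantities.
- The KDE is descriptive only; the clone label comes from the raw bin
  counts, so bandwidth choice cannot change a call.
- The permutation-null resample count (9,999) trades runtime for a p floor
  of 1e-4; raise `PERMUTATION_RESAMPLES` when scanning very large set
  collections at strict FDR.

## 10. Limitations

Purity is taken as known; clonality error scales as 1/tc. CNV clonality is
biased at intermediate prevalence (section 2). The clone labels describe
the prevalence distribution of alterations, not a phylogeny — a "biclonal"
call does not resolve whether the mid-clonality cluster is one subclone or
several of similar size. MEGA tests burden shifts, not which genes drive
them, and its bootstrap quantifies robustness to cohort-size imbalance,
not a calibrated p-value.
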