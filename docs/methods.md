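# Methods

## De novo expectation model

The null hypothesis throughout is that variants arise in proportion to
mutational opportunity. A `ContextRateTable` holds 192 per-base,
per-generation substitution probabilities (64 trinucleotide contexts × 3
alternate bases). For every base of a transcript's coding sequence that
falls inside the capture region, and for each alternate allele, the rate is
looked up in genomic-strand context and the consequence is classified from
the genetic code on the transcript strand: synonymous, missense, stop-gain,
stop-loss, start-loss (any change in the initiator codon), or canonical
splice (the ±2 intronic bases of each internal exon junction, regardless of
the alternate allele). Class probabilities are the sums of these rates;
frameshift probability is then set to 1.25 × the stop-gain probability, a
fixed empirical scaling, and in-frame indels are not modelled at all.
Classification is exact and exhaustively tested against an independent
translate-and-compare oracle over all 9 substitutions of every codon.

Assumptions worth keeping in mind:

- Mutation rates depend only on the trinucleotide context. CpG methylation
  tiers are not modelled; a methylation-aware table can be supplied as an
  alternative 192-entry table per stratum.
- The splice model is positional only (±2 bp); no splicing-strength score.
- Sequencing depth enters as a per-gene multiplier in [0, 1]. When a
  coverage summary is provided, the multiplier is the fraction of the
  gene's captured bases at which at least 8 independent reads are present
  in at least 90% of samples (both configurable); with no summary it is 1.
- The context model cannot know which missense changes a deleteriousness
  classifier would call damaging. A per-gene `dmis_fraction` (default 0.30,
  an input column in real use) partitions missense probability mass into
  damaging and tolerated parts wherever the damaging-missense class is
  needed.

Cohort expectations are 2 × N_trios × p (two haploid genomes per proband).

## Filter cascades

All thresholds are inclusive exactly as printed and live in one
configuration block (`RunConfig`): de novo candidates need an exonic or
splice-site class, DP ≥ 10 in all three trio members, proband alternate
reads ≥ 5, proband alternate allele ratio ≥ 0.28 below 10 alternate reads
(≥ 0.20 otherwise), parental alternate ratios ≤ 0.035, and reference-
population MAF ≤ 4×10⁻⁴. Transmitted dominant candidates need a VQSR pass,
MAF ≤ 5×10⁻⁵, in-cohort MAF ≤ 5×10⁻³, proband DP ≥ 8, GQ ≥ 20 and a
damaging class (LoF, or missense with MetaSVM "D" or MPC ≥ 2). Recessive
candidates relax frequency to 10⁻³/10⁻², admit in-frame indels, and accept
homozygotes plus parent-phased compound heterozygotes (one passing
heterozygote inherited from each parent); probands without both parents
contribute homozygotes only. Rules are conjunctive; the verdict names the
first failing rule in the documented order and records every rule's metric
either way, which is what makes the planted-violation recall test
(one planted record per rule, attribution must be exact) meaningful.

Design choices where the procedure was underdetermined: the de novo
pre-screen, used when no upstream caller output is supplied, is the naive
Mendelian test (proband heterozygous, parents homozygous reference);
in-cohort allele frequency is computed over founders only (parents plus
parentless probands, duplicates excluded) to avoid proband-enrichment
bias; a missing DP falls back to the AD sum; indel alleles are normalized
by shared-suffix-then-prefix trimming (full left-alignment would need the
reference sequence, which the VCF reader deliberately does not require).

## Kinship and duplicate QC

Duplicate detection uses the Jaccard sharing of rare-variant sites; pairs
sharing ≥ 0.80 are flagged and the deeper-covered sample retained.
Relatedness uses a KING-robust-style within-pair estimate from common
biallelic genotypes, φ = (N_het-both − 2·N_opposite-hom) / (N_het_i +
N_het_j), reported as 2φ so duplicates sit at ~1, parent–offspring pairs
at ~0.5 (flagged outside [0.45, 0.55]) and unrelated pairs at ~0. The
estimator is unbiased in simulation; its standard error scales as
~1/√(number of common sites), so desk-scale cohorts should simulate a few
thousand background sites before reading anything into the flags.

## Enrichment tests

- **Per-class cohort burden**: one-sided Poisson upper tail
  P(X ≥ observed) at the summed class expectation, computed through the
  survival function (regularized incomplete gamma), never a normal
  approximation; agreement with term-by-term pmf summation is tested to
  10⁻¹² for expected ≤ 50, observed ≤ 200. Classes reported: total,
  synonymous, tolerated and damaging missense, LoF, protein-altering,
  protein-damaging, for all genes and for the pLI ≥ 0.9 subset.
- **Per-gene DNV tests**: protein-altering, protein-damaging and LoF per
  gene, Bonferroni threshold 0.05 / (3 × n_genes); with the study's
  19,347-gene universe that is 8.6×10⁻⁷. Genes with zero total mutability
  are excluded from testing and reported separately.
- **Transmitted**: strata at the printed pLI boundaries with boundary
  values assigned upward; the binomial test takes n = L_k and
  p = mutability share, the only self-consistent reading of the expectation
  formula (the expectation then matches it exactly and conservation
  Σ expected = L_k holds to machine precision). Threshold 0.05 / n_genes.
  The damaging mutability feeding the share is LoF classes plus
  dmis_fraction × missense, configurable to LoF-only.
- **Case-control burden**: one-sided (greater) Fisher exact test on the
  2×2 allele-count table; the odds ratio is the sample odds ratio and the
  one-sided 95% interval is (exact conditional lower bound, ∞), the bound
  solving P(X ≥ a | ψ) = 0.05 under Fisher's noncentral hypergeometric
  law (bisection on log ψ over ±50, tolerance 10⁻¹⁰).
- **Gene-set enrichment**: indicator logistic regression in two recorded
  orientations — disease ~ set + covariates for module analyses, set ~
  disease + covariates for cell-type analyses; both are implemented and
  the choice is explicit per run. Covariates are log10-transformed where
  scale-like (length, expression), left raw where already fractions (GC),
  and z-scored, making fits invariant to affine rescaling. Complete or
  quasi-complete separation is detected (non-finite or exploding standard
  errors) and refit with Firth's Jeffreys-penalised likelihood, flagged in
  the result; with the fallback disabled it is a hard error. The
  Bonferroni divisor defaults to the full set count even when an
  unassigned ("gray") set is excluded from testing, matching the
  convention of dividing by the total module count; genes exclusively in
  the unassigned set leave the background.

## Attributable fraction and saturation

The attributable fraction is (observed − expected) damaging DNVs over the
number of probands, floored at zero, with an uncertainty interval from the
exact (Garwood) Poisson interval on the observed count. The risk-gene
Monte Carlo assumes the excess is carried by M mutability-weighted genes:
for each candidate M, the excess is scattered multinomially over a random
M-gene risk set on top of Poisson background hits, and the expected count
of multi-hit genes (≥ 2 damaging DNVs) — which decreases as M grows — is
matched to the observation; the interval collects the M whose simulated
multi-hit distribution covers the observed count centrally (2.5–97.5%).
Saturation at a future cohort size is the expected fraction of the M risk
genes attaining ≥ 1 (configurable ≥ 2) damaging DNV when per-gene rates
combine the background and the per-trio excess share. Everything is seeded
and replicate counts are explicit (≥ 100 enforced). Published saturation
percentages depend on simulation details their source did not fully
specify, so this module is validated by self-consistency (an interval that
covers the planted gene count) rather than by matching those percentages.

## Synthetic data

The generator's defaults mirror the study conditions: 90 trios, 13 duos,
11 singletons; a 2,000-gene desk-scale exome of random single-exon ORFs
(log-normal size, mean 150 codons, σ = 0.4, 40% on the minus strand);
log-normal context rates (σ = 0.5) rescaled once so the cohort-level
expected DNV total is 99.7 — the scale of the real capture; pLI drawn from
a five-component mixture putting mass 0.225 in each printed quartile
stratum and 0.10 missing; dmis_fraction ~ Beta(3, 7) (mean 0.3). Read
support uses Poisson(60) depth, Beta(20, 20) heterozygous allele balance
and a 0.005 error-allele rate in homozygous-reference calls, chosen so
genuine records pass the cascades and only deliberately planted records
fail; planted violations (one per rule, per cascade) and duplicate samples
are recorded in a ground-truth JSON. Transmitted variants are multinomial
over mutability within each pLI stratum with fixed totals per stratum
(defaults 40/50/60/50/20, a plausible rare-damaging yield for a cohort of
this size). Spiked risk genes multiply damaging-class rates by a fold
≥ 1; given a target attributable fraction the fold is derived from
fraction = 2 × Σ_risk p_damaging × (fold − 1), and supplying both an
inconsistent fold and target is an error that names the feasible value.

All randomness flows from one mandatory seed through named substreams
(CRC-keyed `SeedSequence` spawn keys), so adding a stage never perturbs
earlier draws and regeneration is byte-identical.

What passing on synthetic data does **not** show: the generator emits
random ORFs, not human sequence; no linkage disequilibrium, population
structure, batch effects, mosaicism, or caller artifacts; single-exon
transcripts by default (the mutability model itself handles multi-exon
transcripts and splice sites, which unit tests exercise directly). Results
on real cohorts additionally depend on annotation quality (functional
classes, MetaSVM/MPC, population frequencies are consumed, never
computed).

## Problem sizes and numerics

Calibration and recovery checks run at the cohort's own scale — 2,000
genes × 90 trios with 500 null replicates and 200 recovery replicates —
using the count-level generative process (per-gene Poisson/multinomial
draws), which is the exact distribution the full VCF-level simulator
implements; VCF-level paths are exercised on a 3-trio/20-gene fixture and
a 60-trio/400-gene example. Tail probabilities use scipy survival
functions at full precision; conservation identities are asserted to
10⁻⁹ absolute per unit; the Firth solver iterates Newton steps with
step-halving to gradient tolerance 10⁻⁸.

## Known limitations

- Depth adjustment consumes a coverage summary; it does not compute
  coverage from alignments.
- The recessive cascade phases compound heterozygotes only through
  parental genotypes; no read-backed or population phasing.
- The in-silico visualization / manual review step of real pipelines is
  inherently not reproducible in code and is omitted.
- Duo and singleton families pass through the shared genotype-quality
  filters but contribute no DNV candidates and no phased compound
  heterozygotes.
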