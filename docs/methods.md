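# Methods

This note documents the models, defaults and numerical choices behind
`swarmscan`, and what the synthetic study conditions do and do not
establish.

## Synthetic hybrid swarms

**Founders.** Two populations (A, B) of `n_lines_per_pop` inbred lines
(default 34, as in the design being emulated) drawn from `n_collections`
(default 7) geographic collections, balanced across populations. Per-site
alt-allele frequencies come from a configurable frequency model (default
Uniform(0.05, 0.95)); founder alleles are drawn **independently per site**.
Residual heterozygosity: each line x site carries a het flag at rate
`het_rate` (default 0.005); at het sites the line's two haplotypes carry
one ref and one alt allele, and any offspring genotype that draws on such a
site is treated as missing (resolvable only by imputation), mirroring how
heterozygous founder calls are handled in practice.

**Genome and recombination.** Five arms — 2L, 2R, 3L, 3R, X — with physical
lengths 23, 21, 24.5, 28 and 22.4 Mb and female map lengths 0.55, 0.55,
0.55, 0.55 and 0.70 Morgans, uniform within arm. Crossover counts per
female meiosis per arm are Poisson (no interference), positions uniform;
males are achiasmate (off by default, switchable). Arms of one chromosome
are linked: the gamete's phase carries across the centromere. The X is
hemizygous in males: sons receive the maternal X gamete only, daughters the
father's X intact. These map values are the package's own defaults chosen
to give Drosophila-scale segment sizes; they are fully configurable.

**Propagation.** F1 is formed by four independent randomly ordered
round-robin cross sets (each line once as dam and once as sire per set);
later generations are discrete, by random union of gametes (random mating
was chosen where the original mating scheme after F1 is not recorded; it is
a documented assumption, not an asserted fact). Sampled, phenotyped
individuals are virgin females, as in the experiment being emulated.

**Phenotypes.** diapause ~ Bernoulli(logit^-1(eta)) with eta = intercept +
covariate terms (centred temperature and photoperiod, generation,
population, *Wolbachia*) + per-SNP effects x dosage. The stage-10 cutoff
shares the latent uniform draw with stage 8 plus an offset (default +0.7 on
the logit scale), so stage-8 diapause is a subset of stage-10 diapause, the
ordering the two cutoffs imply. Default temperature effect is negative
(incidence falls with warming). *Wolbachia* read ratios are a mixture of
two log-normals centred at 1e-4 (uninfected) and 1e-2 (infected), sigma
0.35 decades; only the 1:1000 classification threshold is anchored
externally.

**Frequency panels.** Ten east-coast locales from Homestead, FL (25.5°N) to
Bowdoin, ME (44°N), spring and fall samples each, plus a Zambia-like
outgroup locale with independent base frequencies. Expected alt frequency
is logit-linear in latitude (slope per degree, base defined at latitude 0)
plus a spring offset; observed frequencies add binomial noise with
Neff = (1/(2n) + 1/depth)^-1 trials — the standard pooled-sequencing
effective allele count, adopted because the source only states that
frequencies were corrected for individuals sampled and read depth.

## Mosaic QC

"Short" means strictly less than `min_len` (default 1 Mb; an exactly-1 Mb
segment is kept). Bridging (a single short segment with identical,
non-short flanking founders is absorbed into the flank, restoring its
genotypes and removing both breakpoints) is applied before grouping
(remaining maximal runs of consecutive short segments collapse into one
UNKNOWN segment, masked for genotypes and counted as one parental segment
for recombination). Order of the two rules is a design choice — bridging is
the more specific rule. UNKNOWN segments are never considered short, which
makes cleanup idempotent; a short segment at a chromosome end is masked,
never bridged. Reconstruction accuracy is the proportion of identical
dosages over comparable sites, excluding founder-het/missing sites and
sites missing in either row.

## Imputation and filters

Step 1 resolves founder-het missingness by an independent uniform allele
draw per genotype per imputation; step 2 recomputes within-population
allele frequencies (after step 1) and sets every remaining missing entry to
the Hardy-Weinberg argmax over {0, 1, 2}. Ties (p = 1/3 or 2/3) break
toward the homozygote of the major allele — a deterministic,
frequency-consistent rule. A site unobserved in an entire population falls
back to the combined frequency with a warning. The 5% sample filter and
10% SNP filter count both het-resolved and HW-imputed entries ("imputed"
is not qualified at the source); provenance flags make the alternative
convention recomputable. SNP filters: imputed fraction > 0.10, Weir-
Cockerham two-population FST > 0.2, HWE exact mid-P < 1e-20 in either
population or combined (minimum of the three), and — for the GRM set only —
fixed in exactly one population. Filter statistics are computed on observed
genotypes so the report is imputation-independent. MAF > 0.05 within the
mapping sample is enforced at testing time.

## Relatedness and LD

GRM entries use 2p(1-p) scaling with frequencies from the analysis sample;
monomorphic SNPs are skipped; LOCO variants drop both arms of a chromosome.
PCA is the GRM eigendecomposition (k = 32 by default, matching the LASSO
covariate set), sign-fixed by making each component's largest-magnitude
loading positive. LD is squared Pearson correlation of unphased dosages;
the decay analysis samples one partner per focal SNP per distance bin
(target +/- 5%).

## GWAS

Penalized quasi-likelihood with average-information REML for tau:
convergence when max(|d beta|, |d tau|) < 1e-6, at most 100 outer
iterations, tau initialized at 0.1 x Var(working residual). The AI step is
relaxed (half step) and capped at half the current scale — full Newton
steps alternate with the beta/mu update in a two-cycle on small, strongly
structured samples. tau = 0 reduces the fit to plain logistic regression
(verified against an independent IRLS/GLM fit), and the score test then
equals the classic Rao score test (verified against statsmodels).
lambda_GC uses the chi-square(1) median as a fixed literal
(0.4549364231195724) for bit-stability. Permutations shuffle sample IDs
within population with a per-population stream derived from (seed,
CRC32(label)), so the same seed gives identical shuffles across phenotypes
and subsets; each permutation draws genotypes from one randomly chosen
imputation. Heritability is single-component linear REML on the observed
0/1 scale (no liability transform, matching the reported procedure), with
the association-model covariates as fixed effects; SE by the delta method
from the expected information; CI = estimate +/- 1.96 SE; Vg pinned at the
zero boundary is reported as such.

## Selection and ROC

Ranking is by ascending P with deterministic (chrom, pos) tie-break. The
LASSO stage standardizes all predictors and penalizes environment, PCs and
SNPs together (the described model does not exempt covariates); an
unpenalized-covariate sensitivity mode is available behind a flag
(implemented by rescaling the shielded columns so their effective penalty
is negligible). Penalty chosen by 10-fold stratified CV at the deviance
minimum. ROC curves are vertically averaged on a 101-point FPR grid;
predictions use the penalized coefficients directly (the refit-then-predict
alternative is the flag's natural companion and was left out of scope).

## Population genetics

Clinal effects: per-locale frequencies averaged over sampling times with
Neff weights, then a binomial GLM (logit link, Neff pseudo-counts) of
frequency on latitude per SNP. Polygenic scores multiply the signed GWAS
effect (score-based U/V for ranked SNPs, the LASSO coefficient for LASSO
SNPs) by the clinal or seasonal effect and sum; SNPs absent from a panel
are excluded and counted. Seasonal per-locale scores use logit(f_spring) -
logit(f_fall) with frequencies clamped to [1/(2 Neff + 1), 1 - 1/(2 Neff +
1)]. iHS: EHH within each allele class (pro-diapause treated as derived),
trapezoidal integration over physical position, stopping after EHH first
drops below 0.05 (that trapezoid included); chromosome-end truncation is
flagged; allele classes need >= 5 haplotypes and MAF >= 0.05;
standardization is a z-score (sample SD) within 20 equal-width
pro-allele-frequency bins. Re-polarizing an alt-polarized table is a sign
flip plus re-binning, so one EHH integration serves every imputation and
permutation. The significance rule: more than 50% of imputations beyond
the 2.5% or 97.5% permutation quantile on one tail; annotation-style
enrichment uses the quantile rank of the observed median (below 0.05
de-enriched, above 0.95 enriched). SNP matching across datasets is by
(chrom, pos, ref, alt) with consistent strand assumed; region exclusion
(e.g. a focal window on the X) is a generic chrom:start-end filter.

## Problem sizes

Tests and the analysis drivers run at desk scale, the package's chosen
study sizes: swarms of a few hundred females, 400-10,000 SNPs, 20
imputations and 60-100 permutations; the null-calibration check uses 2,000
individuals x 10,000 SNPs, and heritability recovery uses n = 1,500 with
5,000 markers over 20 replicates. Replicate counts are configurable up to
the full 100 imputations / 1,000 permutations of the emulated design.

## What the generator does not emulate

- **No founder LD.** Founder alleles are independent across sites, so LD
  decay curves sit at the 1/n sampling floor at every distance and
  haplotype-based statistics carry no background structure; passing tests
  show the machinery is correct, not that real founder haplotype structure
  is reproduced. Consequences anchored in real haplotype structure (e.g.
  LOCO inflation magnitudes on real data) are not asserted.
- **No read-level error.** Reconstruction error is modeled at the segment
  level (short wrong-founder insertions at boundaries), not by simulating
  reads through an external haplotype-inference pipeline.
- **Short-segment fraction.** Under the default map (Poisson female-only
  crossovers at ~0.55-0.70 M/arm), pooled F4+F5 samples have ~7% of true
  ancestry segments below 1 Mb; the count distribution is overdispersed
  (crossovers accumulate through a random number of female meioses), which
  raises this fraction above what a fixed-count intuition suggests. An
  independent pure-Poisson Monte Carlo of breakpoint spacings reproduces
  the simulator's value.

## Known limitations

- PQL score tests can be mildly conservative for strongly unbalanced
  binary traits; no saddlepoint correction is applied.
- The heritability model is linear on the 0/1 scale by design; estimates
  are not transformed to the liability scale.
- iHS integrates over physical distance; genetic-distance integration is
  not implemented.
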