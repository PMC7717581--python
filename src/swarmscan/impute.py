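"""Two-step genotype imputation and sample/SNP quality filters.

Missing dosages arise two ways in the hybrid-swarm design: a contributing
founder was heterozygous at the site (the true transmitted allele is simply
unrecorded), or the ancestry itself is unknown (masked reconstruction or a
missed founder call). Step 1 resolves founder-het missingness by choosing
one allele uniformly at random per offspring genotype — deliberately random,
so repeated imputations span the range of possibilities. Step 2 then sets
every remaining missing genotype to the most likely genotype under
Hardy-Weinberg proportions at the sample's own population allele frequency.
Repeating both steps M times yields M complete genotype sets; all downstream
analyses run on every set so imputation uncertainty is visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .synth import GenotypeMatrix

OBSERVED, HET_RESOLVED, HW_IMPUTED = 0, 1, 2


@dataclass
class ImputationSet:
    """M complete dosage matrices plus per-entry provenance.

    provenance is identical across imputations (which entries were missing
    is a property of the data); the realized values differ. The imputed
    fraction counts both het-resolved and HW-imputed entries; the two are
    distinguishable through provenance so either convention is recomputable.
    """

    genotypes: GenotypeMatrix
    dosages: list[np.ndarray]
    provenance: np.ndarray
    population_labels: np.ndarray
    master_seed: int

    @property
    def m(self) -> int:
        return len(self.dosages)

    @property
    def sample_imputed_fraction(self) -> np.ndarray:
        return (self.provenance > 0).mean(axis=1)

    @property
    def sample_hw_imputed_fraction(self) -> np.ndarray:
        return (self.provenance == HW_IMPUTED).mean(axis=1)

    @property
    def snp_imputed_fraction(self) -> np.ndarray:
        return (self.provenance > 0).mean(axis=0)


def hw_most_likely_genotype(p: np.ndarray) -> np.ndarray:
    """Argmax genotype under HW proportions {(1-p)^2, 2p(1-p), p^2}.

    Ties (p = 1/3 or 2/3, where the het probability equals a homozygote's)
    break toward the homozygote of the major allele.
    """
    p = np.asarray(p, dtype=float)
    hom = np.where(p >= 0.5, 2, 0)
    p_hom = np.where(p >= 0.5, p * p, (1.0 - p) * (1.0 - p))
    p_het = 2.0 * p * (1.0 - p)
    # the >= comparison carries the tie rule; the epsilon keeps float rounding
    # at the exact-tie frequencies (1/3, 2/3) from flipping it
    return np.where(p_hom >= p_het - 1e-12, hom, 1).astype(np.int8)


def impute_genotypes(
    genotypes: GenotypeMatrix,
    population_labels: np.ndarray | None = None,
    m: int = 100,
    seed: int = 0,
) -> ImputationSet:
    """Generate M independently imputed complete genotype sets.

    Within each imputation: founder-het entries are resolved by adding a
    Binomial(het haplotypes, 1/2) alt-allele count to the deterministic part
    of the dosage; population allele frequencies are then recomputed and
    remaining missing entries set to the HW-most-likely genotype. A site
    with no observed genotypes in a population falls back to the combined
    frequency with a warning.
    """
    if population_labels is None:
        population_labels = genotypes.samples["population"].to_numpy()
    population_labels = np.asarray(population_labels)
    if len(population_labels) != genotypes.n_samples:
        raise ValueError("population labels must cover all samples")

    dosage0 = genotypes.dosage
    het_entries = (genotypes.het_count > 0) & ~genotypes.unknown
    unknown_entries = genotypes.unknown
    provenance = np.zeros_like(dosage0, dtype=np.uint8)
    provenance[het_entries] = HET_RESOLVED
    provenance[unknown_entries] = HW_IMPUTED

    pops = np.unique(population_labels)
    dosages: list[np.ndarray] = []
    warned = False
    for k in range(m):
        rng = np.random.default_rng([seed, k])
        d = dosage0.astype(np.int8).copy()
        # step 1: random allele per het haplotype
        hc = genotypes.het_count[het_entries].astype(np.int64)
        d[het_entries] = genotypes.known_part[het_entries] + rng.binomial(hc, 0.5)
        # step 2: HW argmax at recomputed within-population frequencies
        obs = d >= 0
        num_all = np.where(obs, d, 0).sum(axis=0).astype(float)
        den_all = 2.0 * obs.sum(axis=0)
        for pop in pops:
            rows = population_labels == pop
            dp = d[rows]
            obs_p = dp >= 0
            den = 2.0 * obs_p.sum(axis=0)
            num = np.where(obs_p, dp, 0).sum(axis=0).astype(float)
            no_freq = den == 0
            if no_freq.any() and not warned:
                warnings.warn(
                    f"{int(no_freq.sum())} site(s) unobserved in population {pop}; "
                    "falling back to combined-population frequency",
                    stacklevel=2,
                )
                warned = True
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(no_freq, num_all / np.maximum(den_all, 1.0), num / np.maximum(den, 1.0))
            fill = hw_most_likely_genotype(p)
            miss = ~obs_p
            dp[miss] = np.broadcast_to(fill, dp.shape)[miss]
            d[rows] = dp
        dosages.append(d)
    return ImputationSet(
        genotypes=genotypes,
        dosages=dosages,
        provenance=provenance,
        population_labels=population_labels,
        master_seed=seed,
    )


def filter_samples(imputation_set: ImputationSet, max_imputed_fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of retained samples (imputed fraction <= threshold).

    "More than 5% imputed" drops a sample, so exactly 5% is retained. Both
    het-resolved and HW-imputed entries count.
    """
    frac = imputation_set.sample_imputed_fraction
    keep = frac <= max_imputed_fraction
    if not keep.any():
        raise ValueError("all samples dropped by the imputed-fraction filter")
    return keep


# ---------------------------------------------------------------------------
# per-SNP statistics


def genotype_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n0, n1, n2) per site from a dosage matrix, ignoring missing."""
    return (
        (dosage == 0).sum(axis=0),
        (dosage == 1).sum(axis=0),
        (dosage == 2).sum(axis=0),
    )


def weir_cockerham_fst(
    counts_a: tuple[np.ndarray, np.ndarray, np.ndarray],
    counts_b: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    """Two-population Weir-Cockerham theta per SNP from genotype counts.

    Returns NaN where the variance components sum to zero (monomorphic
    across both populations).
    """
    comps = []
    for n0, n1, n2 in (counts_a, counts_b):
        n = np.asarray(n0) + n1 + n2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (n1 + 2.0 * n2) / (2.0 * n)
            h = n1 / n
        comps.append((n.astype(float), p, h))
    (na, pa, ha), (nb, pb, hb) = comps
    r = 2.0
    n_bar = (na + nb) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (na**2 + nb**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (na * pa + nb * pb) / (r * n_bar)
        s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (na * ha + nb * hb) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - s2 * (r - 1.0) / r
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (inner - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar))
        c = h_bar / 2.0
        theta = a / (a + b + c)
    return theta


def hwe_exact_midp(n0: int, n1: int, n2: int) -> float:
    """Mid-P exact Hardy-Weinberg test on genotype counts (two-sided).

    Conditions on the allele counts; sums the probabilities of heterozygote
    counts strictly less probable than the observed one, plus half the
    probability of outcomes exactly as probable (mid-P).
    """
    n = n0 + n1 + n2
    if n == 0:
        return float("nan")
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n1)]
    lower = probs < p_obs * (1 - 1e-12)
    equal = np.abs(probs - p_obs) <= p_obs * 1e-12
    return float(probs[lower].sum() + 0.5 * probs[equal].sum())


def hwe_exact_midp_many(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    return np.array([hwe_exact_midp(int(a), int(b), int(c)) for a, b, c in zip(n0, n1, n2)])


@dataclass
class SnpFilterReport:
    table: pd.DataFrame  # per-SNP statistics and verdicts
    grm_set: np.ndarray  # bool mask
    gwas_set: np.ndarray  # bool mask


def filter_snps(
    imputation_set: ImputationSet,
    population_labels: np.ndarray | None = None,
    max_imputed_fraction: float = 0.10,
    max_fst: float = 0.2,
    min_hwe_p: float = 1e-20,
) -> SnpFilterReport:
    """SNP filters for GRM construction and for mapping.

    Both sets exclude SNPs with > 10% imputed genotypes, between-population
    FST > 0.2, or a Hardy-Weinberg exact mid-P below 1e-20 in either
    population alone or combined. The GRM set additionally drops SNPs fixed
    in exactly one population; the mapping (GWAS) set retains those.
    Statistics are computed on observed (unimputed) genotypes so the report
    is deterministic across imputations.
    """
    gm = imputation_set.genotypes
    if population_labels is None:
        population_labels = imputation_set.population_labels
    pops = np.unique(population_labels)
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    for pop in pops:
        if (population_labels == pop).sum() < 2:
            raise ValueError(f"population {pop} has fewer than 2 samples")

    d = gm.dosage
    rows_a = population_labels == pops[0]
    rows_b = population_labels == pops[1]
    counts_a = genotype_counts(d[rows_a])
    counts_b = genotype_counts(d[rows_b])
    counts_all = genotype_counts(d)

    imp_frac = imputation_set.snp_imputed_fraction
    fst = weir_cockerham_fst(counts_a, counts_b)

    def freq(counts):
        n0, n1, n2 = counts
        n = n0 + n1 + n2
        with np.errstate(invalid="ignore", divide="ignore"):
            return (n1 + 2.0 * n2) / (2.0 * n)

    pa, pb = freq(counts_a), freq(counts_b)
    fixed_a = (pa == 0.0) | (pa == 1.0)
    fixed_b = (pb == 0.0) | (pb == 1.0)
    fixed_in_one = fixed_a ^ fixed_b

    hwe_a = hwe_exact_midp_many(*counts_a)
    hwe_b = hwe_exact_midp_many(*counts_b)
    hwe_all = hwe_exact_midp_many(*counts_all)
    hwe_min = np.fmin(np.fmin(hwe_a, hwe_b), hwe_all)

    p_all = freq(counts_all)
    maf = np.fmin(p_all, 1.0 - p_all)

    base = (
        (imp_frac <= max_imputed_fraction)
        & ~(fst > max_fst)  # NaN FST (monomorphic) does not trigger the FST rule
        & ~(hwe_min < min_hwe_p)
    )
    gwas_set = base.copy()
    grm_set = base & ~fixed_in_one

    table = pd.DataFrame(
        {
            "chrom": gm.sites["chrom"].to_numpy(),
            "pos": gm.sites["pos"].to_numpy(),
            "imputed_fraction": imp_frac,
            "fst": fst,
            "fixed_in_one": fixed_in_one,
            "hwe_p_a": hwe_a,
            "hwe_p_b": hwe_b,
            "hwe_p_combined": hwe_all,
            "maf": maf,
            "grm_set": grm_set,
            "gwas_set": gwas_set,
        }
    )
    return SnpFilterReport(table=table, grm_set=grm_set, gwas_set=gwas_set)
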