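"""Synthetic hybrid-swarm data: founders, mosaic genomes, genotypes, phenotypes, panels.

The generator emulates a two-swarm multiparental mapping design: two
populations (A and B) each founded by inbred lines drawn from several
geographic collections, intercrossed by randomly ordered round-robin crosses
at F1 and then propagated as discrete generations by random union of
gametes. Only females recombine (Drosophila males are achiasmate); the X is
hemizygous in males. Every simulated individual carries its full truth
ancestry mosaic, so downstream reconstruction-cleanup, imputation, GWAS and
selection-scan stages can all be validated against known ground truth.

Founder alleles are drawn independently per site (no founder LD); this is a
documented limitation for LD-decay comparisons, not an accident.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import DEFAULT_GENOME, Genome

UNKNOWN = -1  # founder label for masked/unknown ancestry

# A haplotype is a list of (start, end, founder) with 1-based inclusive
# coordinates tiling the arm; founder is an integer line index or UNKNOWN.
Segment = tuple[int, int, int]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RecombinationModel:
    """Poisson crossovers, uniform placement, no interference.

    Per-arm genetic lengths (Morgans) default to the genome's female map;
    ``genetic_lengths`` overrides individual arms. Male recombination is off
    by default.
    """

    genome: Genome = DEFAULT_GENOME
    male_recombination: bool = False
    genetic_lengths: Mapping[str, float] | None = None

    def arm_morgans(self, arm_name: str) -> float:
        if self.genetic_lengths and arm_name in self.genetic_lengths:
            val = float(self.genetic_lengths[arm_name])
        else:
            val = self.genome.arm(arm_name).genetic_length
        if val < 0:
            raise ValueError(f"negative genetic length for arm {arm_name}")
        return val


@dataclass
class FounderPanel:
    """Phased founder haplotypes with line metadata.

    lines: one row per line (line_id, population, collection).
    sites: one row per site (chrom, pos, ref, alt), sorted by genome arm
        order then position, strictly increasing within arm.
    haplotypes: (n_lines, 2, n_sites) int8 in {0, 1} (alt-allele indicator).
        The two haplotypes of a line are identical except at het_mask sites
        (residual heterozygosity), where genotype calls in offspring are
        treated as missing.
    """

    lines: pd.DataFrame
    sites: pd.DataFrame
    haplotypes: np.ndarray
    het_mask: np.ndarray
    genome: Genome = DEFAULT_GENOME

    def __post_init__(self) -> None:
        n_lines, two, n_sites = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (n_lines, 2, n_sites)")
        if n_sites == 0:
            raise ValueError("founder panel has zero sites")
        if len(self.lines) != n_lines or self.het_mask.shape != (n_lines, n_sites):
            raise ValueError("inconsistent panel dimensions")
        for arm, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {arm}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def arm_site_index(self, arm: str) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == arm).to_numpy())

    def line_indices(self, population: str) -> np.ndarray:
        return np.flatnonzero((self.lines["population"] == population).to_numpy())


@dataclass
class MosaicGenome:
    """A diploid (female) or X-hemizygous (male) individual as ancestry segments.

    haplotypes maps arm name -> list of segment lists (two entries; one for
    the male X). Segments tile the arm without gaps or overlaps, 1-based
    inclusive, and adjacent segments with the same founder are merged.
    """

    individual_id: str
    generation: int
    population: str
    sex: str
    haplotypes: dict[str, list[list[Segment]]]

    def n_haplotypes(self, arm: str) -> int:
        return len(self.haplotypes[arm])


@dataclass
class GenotypeMatrix:
    """Individuals x sites dosage matrix with missingness provenance.

    dosage: int8, 0/1/2 alt-allele dosage, -1 missing.
    het_count: number of contributing haplotypes whose founder was
        heterozygous at the site (these drive missingness resolvable by the
        random-allele imputation step).
    unknown: True where any contributing segment has UNKNOWN ancestry (or
        the founder call itself is treated as missing); resolvable only by
        Hardy-Weinberg imputation.
    known_part: summed alt alleles over the non-het, non-unknown
        contributing haplotypes (the deterministic part of the dosage).
    """

    samples: pd.DataFrame  # individual_id, population, generation, sex
    sites: pd.DataFrame  # chrom, pos, ref, alt
    dosage: np.ndarray
    het_count: np.ndarray
    unknown: np.ndarray
    known_part: np.ndarray
    genome: Genome = DEFAULT_GENOME

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def missing(self) -> np.ndarray:
        return self.dosage < 0

    def allele_freq(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Observed alt-allele frequency per site, ignoring missing entries."""
        d = self.dosage if sample_mask is None else self.dosage[sample_mask]
        obs = d >= 0
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))


@dataclass(frozen=True)
class EnvDesign:
    """Factorial chamber design: temperature x photoperiod, assigned at random."""

    temperatures: tuple[float, ...] = (10.0, 12.0, 14.0, 16.0)
    photoperiods: tuple[float, ...] = (9.0, 11.0, 13.0, 15.0)


@dataclass(frozen=True)
class WolbachiaModel:
    """Bimodal Wolbachia-to-nuclear read-ratio mixture.

    Two log-normal components straddle the 1:1000 classification threshold:
    uninfected individuals centre near 1e-4, infected near 1e-2.
    """

    prevalence: float = 0.5
    uninfected_log10_mu: float = -4.0
    infected_log10_mu: float = -2.0
    log10_sigma: float = 0.35


@dataclass(frozen=True)
class PhenoModel:
    """Logistic diapause model: eta = intercept + covariates + SNP effects.

    Covariate coefficients apply to centred temperature/photoperiod when
    ``center`` is set. snp_effects maps site index -> effect per alt-allele
    dosage. The stage-10 cutoff scores strictly more flies as diapausing
    than the stage-8 cutoff; a shared latent uniform draw plus
    ``stage10_offset`` on the linear predictor makes stage-8 diapause a
    subset of stage-10 diapause.
    """

    intercept: float = -1.0
    beta_temperature: float = -0.45
    beta_photoperiod: float = 0.0
    beta_generation: float = 0.2  # F5 vs F4
    beta_population: float = 0.0  # B vs A
    beta_wolbachia: float = -0.3
    snp_effects: Mapping[int, float] = field(default_factory=dict)
    stage10_offset: float = 0.7
    center: bool = True


@dataclass(frozen=True)
class Locale:
    locale_id: str
    latitude: float
    n_individuals: int = 50
    depth: float = 100.0
    year: int = 2012


# Ten east-coast sampling locales spanning Florida to Maine.
EAST_COAST_LOCALES: tuple[Locale, ...] = (
    Locale("Homestead_FL", 25.5),
    Locale("Hahira_GA", 30.8),
    Locale("Eutawville_SC", 33.4),
    Locale("Athens_GA", 34.0),
    Locale("Charlottesville_VA", 38.0),
    Locale("Media_PA", 39.9),
    Locale("StateCollege_PA", 40.8),
    Locale("Ithaca_NY", 42.4),
    Locale("Lancaster_MA", 42.5),
    Locale("Bowdoin_ME", 44.0),
)


def effective_allele_count(n_individuals: int, depth: float) -> float:
    """Pooled-sequencing effective number of allele counts.

    Combines the number of chromosomes sampled (2n) and the read depth:
    Neff = 1 / (1/(2n) + 1/depth). Always <= min(2n, depth).
    """
    return 1.0 / (1.0 / (2.0 * n_individuals) + 1.0 / depth)


# ---------------------------------------------------------------------------
# founders


def _draw_site_freqs(freq_model, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(freq_model, (int, float)):
        return np.full(n_sites, float(freq_model))
    if isinstance(freq_model, np.ndarray):
        if len(freq_model) != n_sites:
            raise ValueError("freq array length mismatch")
        return freq_model.astype(float)
    kind = freq_model[0]
    if kind == "uniform":
        return rng.uniform(freq_model[1], freq_model[2], n_sites)
    if kind == "beta":
        return rng.beta(freq_model[1], freq_model[2], n_sites)
    if kind == "fixed":
        return np.full(n_sites, float(freq_model[1]))
    raise ValueError(f"unknown freq_model {freq_model!r}")


def make_sites(n_sites: int, genome: Genome = DEFAULT_GENOME, seed: int | None = 0) -> pd.DataFrame:
    """Uniform random site positions, allocated to arms in proportion to length."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    total = genome.total_length
    rows = []
    remaining = n_sites
    for i, arm in enumerate(genome.arms):
        n_arm = remaining if i == len(genome.arms) - 1 else int(round(n_sites * arm.length_bp / total))
        n_arm = min(n_arm, remaining)
        pos = np.sort(rng.choice(arm.length_bp, size=n_arm, replace=False) + 1)
        ref, alt = _random_alleles(n_arm, rng)
        rows.append(pd.DataFrame({"chrom": arm.name, "pos": pos, "ref": ref, "alt": alt}))
        remaining -= n_arm
    return pd.concat(rows, ignore_index=True)


def _random_alleles(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n)]
    shift = rng.integers(1, 4, n)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    return ref, alt


def simulate_founders(
    n_lines_per_pop: int,
    n_collections: int = 7,
    sites: pd.DataFrame | int = 5000,
    freq_model=("uniform", 0.05, 0.95),
    het_rate: float = 0.005,
    seed: int = 0,
    genome: Genome = DEFAULT_GENOME,
) -> FounderPanel:
    """Simulate inbred founder lines for two swarm populations.

    Returns 2 * n_lines_per_pop lines split into populations A and B with
    balanced representation of ``n_collections`` geographic collections.
    Alleles are drawn independently per site from the site's alt frequency;
    each line is homozygous except at het_mask sites (rate ``het_rate``),
    where its two haplotypes carry one ref and one alt allele.
    """
    if n_lines_per_pop < 2:
        raise ValueError("need at least 2 lines per population")
    if not 0.0 <= het_rate <= 1.0:
        raise ValueError("het_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(sites, int):
        sites = make_sites(sites, genome, seed=rng.integers(2**31))
    sites = sites.reset_index(drop=True)
    if len(sites) == 0:
        raise ValueError("founder panel has zero sites")

    n_lines = 2 * n_lines_per_pop
    n_sites = len(sites)
    freqs = np.clip(_draw_site_freqs(freq_model, n_sites, rng), 0.0, 1.0)

    base = (rng.random((n_lines, n_sites)) < freqs).astype(np.int8)
    het = rng.random((n_lines, n_sites)) < het_rate
    hap = np.stack([base.copy(), base.copy()], axis=1)
    # at het sites the two haplotypes disagree: one ref, one alt, random order
    which = rng.integers(0, 2, size=het.sum())
    li, si = np.nonzero(het)
    hap[li, which, si] = 0
    hap[li, 1 - which, si] = 1

    lines = pd.DataFrame(
        {
            "line_id": [f"{p}{i:03d}" for p in "AB" for i in range(n_lines_per_pop)],
            "population": ["A"] * n_lines_per_pop + ["B"] * n_lines_per_pop,
            "collection": [f"coll{i % n_collections}" for i in range(n_lines_per_pop)] * 2,
        }
    )
    return FounderPanel(lines=lines, sites=sites, haplotypes=hap, het_mask=het, genome=genome)


# ---------------------------------------------------------------------------
# swarm propagation


def _merge_segments(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for s in segs:
        if s[0] > s[1]:
            continue
        if out and out[-1][2] == s[2] and out[-1][1] + 1 == s[0]:
            out[-1] = (out[-1][0], s[1], s[2])
        else:
            out.append(s)
    return out


def _extract(segs: list[Segment], a: int, b: int) -> list[Segment]:
    """Segments restricted to [a, b] (1-based inclusive)."""
    return [(max(s, a), min(e, b), f) for s, e, f in segs if e >= a and s <= b]


class _Indiv:
    __slots__ = ("sex", "haps")

    def __init__(self, sex: str, haps: dict[str, list[list[Segment]]]):
        self.sex = sex
        self.haps = haps


def _female_gamete(parent: _Indiv, recomb: RecombinationModel, rng: np.random.Generator) -> dict[str, list[Segment]]:
    """Recombining gamete: one crossover process per arm, phase linked per chromosome."""
    genome = recomb.genome
    out: dict[str, list[Segment]] = {}
    for chrom in genome.chromosomes:
        h = int(rng.integers(0, 2))
        for arm in genome.chromosome_arms(chrom):
            haps = parent.haps[arm.name]
            if len(haps) == 1:  # hemizygous arm: pass intact
                out[arm.name] = list(haps[0])
                continue
            n_cx = rng.poisson(recomb.arm_morgans(arm.name))
            if n_cx == 0 or arm.length_bp < 2:
                out[arm.name] = list(haps[h])
                continue
            breaks = np.unique(rng.integers(1, arm.length_bp, size=n_cx))
            segs: list[Segment] = []
            cur = 1
            for b in breaks:
                segs.extend(_extract(haps[h], cur, int(b)))
                h = 1 - h
                cur = int(b) + 1
            segs.extend(_extract(haps[h], cur, arm.length_bp))
            out[arm.name] = _merge_segments(segs)
    return out


def _male_gamete(
    parent: _Indiv, recomb: RecombinationModel, rng: np.random.Generator
) -> tuple[dict[str, list[Segment]], dict[str, list[Segment]]]:
    """(autosomal gamete, X contribution). X passes intact to daughters only."""
    if recomb.male_recombination:
        auto = _female_gamete(parent, recomb, rng)
        auto.pop("X", None)
    else:
        genome = recomb.genome
        auto = {}
        for chrom in genome.chromosomes:
            if chrom == "X":
                continue
            h = int(rng.integers(0, 2))
            for arm in genome.chromosome_arms(chrom):
                auto[arm.name] = list(parent.haps[arm.name][h])
    x_arms = {a.name: list(parent.haps[a.name][0]) for a in recomb.genome.arms if a.chromosome == "X"}
    return auto, x_arms


def _make_child(
    mother: _Indiv, father: _Indiv, recomb: RecombinationModel, rng: np.random.Generator
) -> _Indiv:
    sex = "F" if rng.random() < 0.5 else "M"
    mat = _female_gamete(mother, recomb, rng)
    pat_auto, pat_x = _male_gamete(father, recomb, rng)
    haps: dict[str, list[list[Segment]]] = {}
    for arm in recomb.genome.arms:
        if arm.chromosome == "X":
            if sex == "F":
                haps[arm.name] = [mat[arm.name], pat_x[arm.name]]
            else:
                haps[arm.name] = [mat[arm.name]]
        else:
            haps[arm.name] = [mat[arm.name], pat_auto[arm.name]]
    return _Indiv(sex, haps)


def _founder_indiv(line: int, sex: str, genome: Genome) -> _Indiv:
    haps = {}
    for arm in genome.arms:
        whole = [(1, arm.length_bp, line)]
        if arm.chromosome == "X" and sex == "M":
            haps[arm.name] = [list(whole)]
        else:
            haps[arm.name] = [list(whole), list(whole)]
    return _Indiv(sex, haps)


def simulate_swarm(
    founders: FounderPanel,
    recomb: RecombinationModel | None = None,
    generations: int = 5,
    census: int = 10_000,
    n_sample: int = 100,
    seed: int = 0,
    population: str | None = None,
    n_round_robin_sets: int = 4,
) -> list[MosaicGenome]:
    """Propagate one hybrid swarm and sample females from the final generation.

    F1 is formed by ``n_round_robin_sets`` independent randomly ordered
    round-robin crosses among the population's founder lines (each line
    appears once as dam and once as sire per set); later generations are
    non-overlapping, formed by random union of gametes. Only females
    recombine unless the model says otherwise. Returned individuals are
    females carrying full truth mosaics.
    """
    if recomb is None:
        recomb = RecombinationModel(genome=founders.genome)
    if generations < 2:
        raise ValueError("generations must be >= 2 (F1 is the first hybrid generation)")
    if census < 2:
        raise ValueError("census must be >= 2")
    if census < n_sample:
        raise ValueError("census must be >= n_sample")

    pops = founders.lines["population"].unique()
    if population is None:
        if len(pops) != 1:
            raise ValueError("founders span multiple populations; pass population=")
        population = pops[0]
    line_idx = founders.line_indices(population)
    if len(line_idx) < 2:
        raise ValueError(f"fewer than 2 founder lines in population {population}")

    rng = np.random.default_rng(seed)
    genome = founders.genome

    # randomly ordered round-robin crosses: (dam line, sire line) pairs
    crosses: list[tuple[int, int]] = []
    for _ in range(n_round_robin_sets):
        order = rng.permutation(line_idx)
        crosses.extend((int(order[i]), int(order[(i + 1) % len(order)])) for i in range(len(order)))

    current: list[_Indiv] = []
    for k in range(census):
        dam, sire = crosses[k % len(crosses)]
        mother = _founder_indiv(dam, "F", genome)
        father = _founder_indiv(sire, "M", genome)
        current.append(_make_child(mother, father, recomb, rng))

    for _gen in range(2, generations + 1):
        females = [i for i in current if i.sex == "F"]
        males = [i for i in current if i.sex == "M"]
        if not females or not males:
            raise RuntimeError("a generation lost one sex entirely; increase census")
        nxt = []
        fi = rng.integers(0, len(females), size=census)
        mi = rng.integers(0, len(males), size=census)
        for k in range(census):
            nxt.append(_make_child(females[fi[k]], males[mi[k]], recomb, rng))
        current = nxt

    females = [i for i in current if i.sex == "F"]
    if len(females) < n_sample:
        raise RuntimeError("not enough females in the final generation to sample")
    pick = rng.choice(len(females), size=n_sample, replace=False)
    out = []
    for j, k in enumerate(sorted(pick)):
        ind = females[k]
        out.append(
            MosaicGenome(
                individual_id=f"{population}_F{generations}_{j:04d}",
                generation=generations,
                population=population,
                sex="F",
                haplotypes={a: [list(h) for h in ind.haps[a]] for a in ind.haps},
            )
        )
    return out


# ---------------------------------------------------------------------------
# genotypes from mosaics


def derive_genotypes(mosaics: Sequence[MosaicGenome], founders: FounderPanel) -> GenotypeMatrix:
    """Dosages by direct lookup of founder alleles under each ancestry segment.

    Sites under UNKNOWN segments are missing (unknown flag); sites where a
    contributing founder is heterozygous are missing with het_count set, so
    the random-allele imputation step can resolve them. Hemizygous male X
    haplotypes count twice (dosage 0/2).
    """
    n_ind = len(mosaics)
    n_sites = founders.n_sites
    if n_ind == 0:
        raise ValueError("no mosaics")
    het_count = np.zeros((n_ind, n_sites), dtype=np.uint8)
    unknown = np.zeros((n_ind, n_sites), dtype=bool)
    known = np.zeros((n_ind, n_sites), dtype=np.uint8)

    arm_index = {a: founders.arm_site_index(a) for a in founders.genome.arm_names}
    arm_pos = {a: founders.sites["pos"].to_numpy()[idx] for a, idx in arm_index.items()}

    for i, mos in enumerate(mosaics):
        for arm, haps in mos.haplotypes.items():
            idx = arm_index[arm]
            if len(idx) == 0:
                continue
            pos = arm_pos[arm]
            weight = 2 if len(haps) == 1 else 1  # hemizygous X counts twice
            for hap in haps:
                for s, e, f in hap:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="right")
                    if lo == hi:
                        continue
                    cols = idx[lo:hi]
                    if f == UNKNOWN:
                        unknown[i, cols] = True
                        continue
                    site_het = founders.het_mask[f, cols]
                    het_count[i, cols] += (weight * site_het).astype(np.uint8)
                    alleles = founders.haplotypes[f, 0, cols]
                    known[i, cols] += weight * np.where(site_het, 0, alleles).astype(np.uint8)

    dosage = known.astype(np.int8)
    dosage[(het_count > 0) | unknown] = -1
    samples = pd.DataFrame(
        {
            "individual_id": [m.individual_id for m in mosaics],
            "population": [m.population for m in mosaics],
            "generation": [f"F{m.generation}" for m in mosaics],
            "sex": [m.sex for m in mosaics],
        }
    )
    return GenotypeMatrix(
        samples=samples,
        sites=founders.sites,
        dosage=dosage,
        het_count=het_count,
        unknown=unknown,
        known_part=known,
        genome=founders.genome,
    )


# ---------------------------------------------------------------------------
# reconstruction-error emulation


def degrade_mosaics(
    mosaics: Sequence[MosaicGenome],
    spurious_rate: float = 0.17,
    spurious_length_dist=("uniform", 10_000, 999_999),
    seed: int = 0,
    n_founders: int | None = None,
) -> list[MosaicGenome]:
    """Inject short wrong-founder segments at segment boundaries.

    Emulates haplotype-reconstruction error, which over-represents short
    (<1 Mb) segments; the default rate makes roughly a fifth of all segments
    short, against a few percent in the truth. spurious_rate=0 is the
    identity.
    """
    if not 0.0 <= spurious_rate <= 1.0:
        raise ValueError("spurious_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_founders is None:
        n_founders = 1 + max(
            (f for m in mosaics for haps in m.haplotypes.values() for h in haps for _, _, f in h),
            default=0,
        )

    def draw_len() -> int:
        kind = spurious_length_dist[0]
        if kind == "uniform":
            return int(rng.integers(spurious_length_dist[1], spurious_length_dist[2] + 1))
        if kind == "exp":
            return max(1, int(rng.exponential(spurious_length_dist[1])))
        raise ValueError(f"unknown length dist {spurious_length_dist!r}")

    out = []
    for m in mosaics:
        new_haps: dict[str, list[list[Segment]]] = {}
        for arm, haps in m.haplotypes.items():
            new_haps[arm] = []
            for hap in haps:
                segs: list[Segment] = [hap[0]]
                for seg in hap[1:]:
                    s, e, f = seg
                    if spurious_rate > 0 and rng.random() < spurious_rate:
                        length = min(draw_len(), e - s)  # keep a remnant of the true segment
                        candidates = [x for x in range(n_founders) if x != f and x != segs[-1][2]]
                        if length >= 1 and candidates:
                            wrong = int(rng.choice(candidates))
                            segs.append((s, s + length - 1, wrong))
                            segs.append((s + length, e, f))
                            continue
                    segs.append(seg)
                new_haps[arm].append(_merge_segments(segs))
        out.append(
            MosaicGenome(
                individual_id=m.individual_id,
                generation=m.generation,
                population=m.population,
                sex=m.sex,
                haplotypes=new_haps,
            )
        )
    return out


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    env_design: EnvDesign | None = None,
    coef: PhenoModel | None = None,
    wolbachia_model: WolbachiaModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary diapause phenotypes under a logistic environment + SNP model.

    Each individual is assigned a chamber (temperature x photoperiod) at
    random; diapause ~ Bernoulli(logit^-1(eta)) with eta = intercept +
    covariate terms + sum of SNP effects x dosage. Wolbachia status is drawn
    from the model's prevalence and its read ratio from the bimodal mixture.
    Missing dosages contribute their population-mean dosage to eta.
    """
    env_design = env_design or EnvDesign()
    coef = coef or PhenoModel()
    wolbachia_model = wolbachia_model or WolbachiaModel()
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples

    temp = rng.choice(env_design.temperatures, size=n)
    photo = rng.choice(env_design.photoperiods, size=n)
    gen_f5 = (genotypes.samples["generation"] == "F5").to_numpy().astype(float)
    pop_b = (genotypes.samples["population"] == "B").to_numpy().astype(float)
    wolb = (rng.random(n) < wolbachia_model.prevalence).astype(int)
    mu = np.where(wolb == 1, wolbachia_model.infected_log10_mu, wolbachia_model.uninfected_log10_mu)
    read_ratio = 10.0 ** rng.normal(mu, wolbachia_model.log10_sigma)

    t = temp - np.mean(env_design.temperatures) if coef.center else temp
    p = photo - np.mean(env_design.photoperiods) if coef.center else photo
    eta = (
        coef.intercept
        + coef.beta_temperature * t
        + coef.beta_photoperiod * p
        + coef.beta_generation * gen_f5
        + coef.beta_population * pop_b
        + coef.beta_wolbachia * wolb
    )
    for site, beta in coef.snp_effects.items():
        if not 0 <= site < genotypes.n_sites:
            raise ValueError(f"SNP effect references absent site {site}")
        d = genotypes.dosage[:, site].astype(float)
        obs = d >= 0
        if obs.any():
            d[~obs] = d[obs].mean()
        else:
            d[:] = 0.0
        eta = eta + beta * d

    u = rng.random(n)
    p8 = 1.0 / (1.0 + np.exp(-eta))
    p10 = 1.0 / (1.0 + np.exp(-(eta + coef.stage10_offset)))
    return pd.DataFrame(
        {
            "individual_id": genotypes.samples["individual_id"],
            "diapause8": (u < p8).astype(int),
            "diapause10": (u < p10).astype(int),
            "temperature": temp,
            "photoperiod": photo,
            "generation": genotypes.samples["generation"],
            "population": genotypes.samples["population"],
            "wolbachia": wolb,
            "read_ratio": read_ratio,
        }
    )


# ---------------------------------------------------------------------------
# allele-frequency panels


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_frequency_panels(
    snps: pd.DataFrame,
    clinal_slope: np.ndarray | float = 0.0,
    seasonal_delta: np.ndarray | float = 0.0,
    locales: Sequence[Locale] = EAST_COAST_LOCALES,
    base_freq=("uniform", 0.2, 0.8),
    outgroup_freq=("uniform", 0.05, 0.95),
    noise: bool = True,
    seasons: Sequence[str] = ("spring", "fall"),
    outgroup_id: str = "ZI",
    seed: int = 0,
) -> pd.DataFrame:
    """Clinal/seasonal allele-frequency panel plus an outgroup locale.

    Expected alt frequency at a locale is logit^-1(logit(base) +
    clinal_slope * latitude + seasonal_delta * [season == spring]); with
    noise on, the observed frequency is binomial with Neff trials, where
    Neff combines individuals sampled and read depth. The outgroup locale
    has its own base frequencies (no cline, no season).
    """
    if len(locales) == 0:
        raise ValueError("locales must be nonempty")
    rng = np.random.default_rng(seed)
    n_snps = len(snps)
    slope = np.broadcast_to(np.asarray(clinal_slope, dtype=float), (n_snps,))
    delta = np.broadcast_to(np.asarray(seasonal_delta, dtype=float), (n_snps,))
    base = np.clip(_draw_site_freqs(base_freq, n_snps, rng), 1e-12, 1 - 1e-12)
    if noise and (np.any(base <= 0) or np.any(base >= 1)):
        raise ValueError("base frequency at 0 or 1 with noise requested")
    base_logit = _logit(base)

    snp_id = snps["chrom"].astype(str) + ":" + snps["pos"].astype(str)
    rows = []
    for loc in locales:
        for season in seasons:
            expected = _invlogit(base_logit + slope * loc.latitude + delta * (season == "spring"))
            neff = effective_allele_count(loc.n_individuals, loc.depth)
            if noise:
                freq = rng.binomial(int(round(neff)), expected) / round(neff)
            else:
                freq = expected
            rows.append(
                pd.DataFrame(
                    {
                        "snp_id": snp_id,
                        "chrom": snps["chrom"].to_numpy(),
                        "pos": snps["pos"].to_numpy(),
                        "locale_id": loc.locale_id,
                        "latitude": loc.latitude,
                        "season": season,
                        "year": loc.year,
                        "n_individuals": loc.n_individuals,
                        "depth": loc.depth,
                        "neff": neff,
                        "alt_freq": freq,
                    }
                )
            )
    # outgroup: independent base frequencies unless explicitly coupled
    og = np.clip(_draw_site_freqs(outgroup_freq, n_snps, rng), 0.0, 1.0)
    og_loc = Locale(outgroup_id, float("nan"), n_individuals=100, depth=30.0)
    neff = effective_allele_count(og_loc.n_individuals, og_loc.depth)
    freq = rng.binomial(int(round(neff)), np.clip(og, 0, 1)) / round(neff) if noise else og
    rows.append(
        pd.DataFrame(
            {
                "snp_id": snp_id,
                "chrom": snps["chrom"].to_numpy(),
                "pos": snps["pos"].to_numpy(),
                "locale_id": og_loc.locale_id,
                "latitude": np.nan,
                "season": pd.NA,
                "year": og_loc.year,
                "n_individuals": og_loc.n_individuals,
                "depth": og_loc.depth,
                "neff": neff,
                "alt_freq": freq,
            }
        )
    )
    return pd.concat(rows, ignore_index=True)
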