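"""Genetic relatedness matrices, principal components, IBS and LD summaries.

The GRM uses the standard allele-frequency-scaled cross-product,
G_ij = (1/L) sum_l (g_il - 2 p_l)(g_jl - 2 p_l) / (2 p_l (1 - p_l)),
with frequencies computed on the analysis sample and monomorphic sites
skipped. LOCO variants exclude every SNP on a chromosome (both arms), the
standard remedy for proximal contamination of single-SNP tests. PCA is the
eigendecomposition of the GRM. LD is the squared Pearson correlation of
unphased dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DEFAULT_GENOME, Genome
from .synth import GenotypeMatrix


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: list[str]
    n_snps: int
    excluded_chrom: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite GRM")


def _complete_dosage(genotypes: GenotypeMatrix | np.ndarray) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosage, genotypes.sites
    return np.asarray(genotypes), None


def compute_grm(
    genotypes: GenotypeMatrix,
    dosage: np.ndarray | None = None,
    snp_set: np.ndarray | None = None,
    loco_chrom: str | None = None,
    genome: Genome | None = None,
) -> GRM:
    """GRM from complete (post-imputation) dosages.

    ``dosage`` overrides the matrix stored in ``genotypes`` (so one
    GenotypeMatrix can carry site metadata for many imputed dosage sets).
    ``snp_set`` is a boolean mask (e.g. the GRM filter); ``loco_chrom``
    drops every SNP whose arm belongs to that chromosome.
    """
    genome = genome or genotypes.genome
    d = genotypes.dosage if dosage is None else dosage
    if (d < 0).any():
        raise ValueError("GRM requires complete genotypes; impute first")
    mask = np.ones(d.shape[1], dtype=bool) if snp_set is None else snp_set.copy()
    if loco_chrom is not None:
        arms = genotypes.sites["chrom"].to_numpy()
        chrom_of = {a.name: a.chromosome for a in genome.arms}
        on_chrom = np.array([chrom_of.get(a, a) == loco_chrom for a in arms])
        mask &= ~on_chrom
    g = d[:, mask].astype(float)
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    g = g[:, poly]
    p = p[poly]
    if g.shape[1] == 0:
        raise ValueError("zero usable SNPs for GRM")
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    mat = (z @ z.T) / g.shape[1]
    return GRM(
        matrix=mat,
        sample_ids=list(genotypes.samples["individual_id"]),
        n_snps=g.shape[1],
        excluded_chrom=loco_chrom,
    )


def loco_grms(
    genotypes: GenotypeMatrix,
    dosage: np.ndarray | None = None,
    snp_set: np.ndarray | None = None,
    genome: Genome | None = None,
) -> dict[str, GRM]:
    """One GRM per chromosome, each excluding that chromosome's SNPs."""
    genome = genome or genotypes.genome
    return {
        chrom: compute_grm(genotypes, dosage=dosage, snp_set=snp_set, loco_chrom=chrom, genome=genome)
        for chrom in genome.chromosomes
    }


def pca(grm: GRM, k: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal components from the GRM eigendecomposition.

    Returns (coordinates n x k, eigenvalues length k), components ordered by
    decreasing eigenvalue; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    n = grm.matrix.shape[0]
    if k > n - 1:
        raise ValueError("k must be <= n - 1")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))
    return coords, vals


def ibs_matrix(dosage: np.ndarray) -> np.ndarray:
    """Mean identity-by-state: 1 - |g_i - g_j| / 2 averaged over sites."""
    d = dosage.astype(float)
    n = d.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        out[i] = 1.0 - np.abs(d - d[i]).mean(axis=1) / 2.0
    return out


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


DEFAULT_LD_DISTANCES_KB = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)


def ld_decay(
    genotypes: GenotypeMatrix,
    dosage: np.ndarray | None = None,
    distances_kb=DEFAULT_LD_DISTANCES_KB,
    tolerance: float = 0.05,
    n_focal: int = 10_000,
    maf: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Dosage R^2 between random focal SNPs and one partner per distance bin.

    A partner qualifies if its distance to the focal SNP is within
    +/- tolerance of the target distance; one qualifying partner is chosen
    at random. Reports median and the 2.5/97.5% interval of R^2 per
    distance, plus the number of focal SNPs with no partner in the bin.
    """
    rng = np.random.default_rng(seed)
    d = genotypes.dosage if dosage is None else dosage
    p = d.mean(axis=0) / 2.0
    keep = np.fmin(p, 1 - p) > maf
    arms = genotypes.sites["chrom"].to_numpy()
    pos = genotypes.sites["pos"].to_numpy()
    idx_all = np.flatnonzero(keep)
    if len(idx_all) < 2:
        raise ValueError("not enough SNPs after MAF filter")
    focal = rng.choice(idx_all, size=min(n_focal, len(idx_all)), replace=False)

    rows = []
    for dist_kb in distances_kb:
        target = dist_kb * 1000.0
        lo, hi = target * (1 - tolerance), target * (1 + tolerance)
        r2s = []
        n_skipped = 0
        for f in focal:
            same_arm = idx_all[arms[idx_all] == arms[f]]
            gap = np.abs(pos[same_arm] - pos[f])
            cand = same_arm[(gap >= lo) & (gap <= hi)]
            if len(cand) == 0:
                n_skipped += 1
                continue
            partner = int(rng.choice(cand))
            r2s.append(_r2(d[:, f].astype(float), d[:, partner].astype(float)))
        r2s = np.array(r2s, dtype=float)
        r2s = r2s[np.isfinite(r2s)]
        rows.append(
            {
                "distance_kb": dist_kb,
                "n_pairs": len(r2s),
                "n_skipped": n_skipped,
                "median_r2": np.median(r2s) if len(r2s) else np.nan,
                "q025": np.quantile(r2s, 0.025) if len(r2s) else np.nan,
                "q975": np.quantile(r2s, 0.975) if len(r2s) else np.nan,
                "mean_r2": r2s.mean() if len(r2s) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def long_range_ld(
    genotypes: GenotypeMatrix,
    dosage: np.ndarray | None = None,
    n_within: int = 10_000,
    n_between: int = 30_000,
    maf: float = 0.05,
    seed: int = 0,
    genome: Genome | None = None,
) -> dict[str, np.ndarray]:
    """R^2 for opposite-arm pairs (2L-2R, 3L-3R) and cross-chromosome pairs."""
    genome = genome or genotypes.genome
    rng = np.random.default_rng(seed)
    d = genotypes.dosage if dosage is None else dosage
    p = d.mean(axis=0) / 2.0
    keep = np.fmin(p, 1 - p) > maf
    arms = genotypes.sites["chrom"].to_numpy()
    chrom_of = {a.name: a.chromosome for a in genome.arms}

    def sample_pairs(idx_x: np.ndarray, idx_y: np.ndarray, n: int) -> np.ndarray:
        if len(idx_x) == 0 or len(idx_y) == 0:
            raise ValueError("missing arm for long-range LD")
        xs = rng.choice(idx_x, size=n, replace=True)
        ys = rng.choice(idx_y, size=n, replace=True)
        out = np.array([_r2(d[:, a].astype(float), d[:, b].astype(float)) for a, b in zip(xs, ys)])
        return out[np.isfinite(out)]

    result: dict[str, np.ndarray] = {}
    for left, right, label in (("2L", "2R", "2L-2R"), ("3L", "3R", "3L-3R")):
        ix = np.flatnonzero(keep & (arms == left))
        iy = np.flatnonzero(keep & (arms == right))
        result[label] = sample_pairs(ix, iy, n_within)
    chroms = np.array([chrom_of.get(a, a) for a in arms])
    uniq = [c for c in dict.fromkeys(chroms)]
    xs, ys = [], []
    n_draw = 0
    while n_draw < n_between:
        c1, c2 = rng.choice(len(uniq), size=2, replace=False)
        i1 = np.flatnonzero(keep & (chroms == uniq[c1]))
        i2 = np.flatnonzero(keep & (chroms == uniq[c2]))
        xs.append(int(rng.choice(i1)))
        ys.append(int(rng.choice(i2)))
        n_draw += 1
    out = np.array([_r2(d[:, a].astype(float), d[:, b].astype(float)) for a, b in zip(xs, ys)])
    result["cross-chromosome"] = out[np.isfinite(out)]
    return result
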