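"""Shared study conditions for the numbered analysis drivers.

One synthetic two-swarm world is built once (and cached under scratch/) so
every driver operates on the same data: two populations of 34 founder lines
each, F5 hybrid females, a polygenic diapause phenotype with twelve planted
causal SNPs of alternating sign on 3R, and 20 imputations of the missing
genotypes. Sizes are desk-scale so the full analysis sequence runs in
minutes.
"""

from __future__ import annotations

import pickle
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

sys.path.insert(0, str(ROOT / "src"))

import swarmscan as sw  # noqa: E402

SEED = 2026
N_LINES = 34
N_SITES = 3000
N_SAMPLE = 200  # females per population
CENSUS = 450
M_IMPUTATIONS = 20
N_PERMUTATIONS = 60
N_CAUSAL = 12
CAUSAL_EFFECT = 0.8


def build_world():
    panel = sw.synth.simulate_founders(
        N_LINES, n_collections=7, sites=N_SITES, het_rate=0.005, seed=SEED
    )
    mosaics = []
    for pop, seed in (("A", SEED + 1), ("B", SEED + 2)):
        mosaics += sw.synth.simulate_swarm(
            panel, generations=5, census=CENSUS, n_sample=N_SAMPLE, seed=seed, population=pop
        )
    gm = sw.synth.derive_genotypes(mosaics, panel)

    freq = gm.allele_freq()
    on_3r = np.flatnonzero(
        (gm.sites["chrom"].to_numpy() == "3R") & (np.fmin(freq, 1 - freq) > 0.25)
    )
    causal_sites = on_3r[np.linspace(10, len(on_3r) - 10, N_CAUSAL).astype(int)]
    causal = {
        int(c): (CAUSAL_EFFECT if i % 2 == 0 else -CAUSAL_EFFECT)
        for i, c in enumerate(causal_sites)
    }
    pheno = sw.synth.simulate_phenotypes(
        gm, coef=sw.synth.PhenoModel(snp_effects=causal), seed=SEED + 3
    )
    imp = sw.impute.impute_genotypes(gm, m=M_IMPUTATIONS, seed=SEED + 4)
    report = sw.impute.filter_snps(imp)
    return {
        "panel": panel,
        "mosaics": mosaics,
        "genotypes": gm,
        "phenotypes": pheno,
        "imputations": imp,
        "snp_report": report,
        "causal": causal,
    }


def _cached(name: str, builder):
    SCRATCH.mkdir(exist_ok=True)
    path = SCRATCH / name
    if path.exists():
        with open(path, "rb") as fh:
            return pickle.load(fh)
    obj = builder()
    with open(path, "wb") as fh:
        pickle.dump(obj, fh)
    return obj


def load_world():
    return _cached("world.pkl", build_world)


def run_all_gwas(world):
    """Per-imputation GWAS plus the within-population permutation null."""

    def builder():
        gm = world["genotypes"]
        imp = world["imputations"]
        rng = np.random.default_rng(SEED + 5)
        common = dict(
            sites=gm.sites,
            sample_ids=gm.samples["individual_id"],
            grm_snp_set=world["snp_report"].grm_set,
            test_snp_set=world["snp_report"].gwas_set,
            mapping_population="both",
            grm_mode="nonloco",
        )
        observed = [
            sw.gwas.run_gwas(dosage=imp.dosages[k], phenotypes=world["phenotypes"], **common)
            for k in range(imp.m)
        ]
        permuted = []
        for j in range(N_PERMUTATIONS):
            k = int(rng.integers(0, imp.m))
            perm = sw.gwas.permute_phenotypes(world["phenotypes"], seed=SEED + 1000 + j)
            permuted.append(sw.gwas.run_gwas(dosage=imp.dosages[k], phenotypes=perm, **common))
        return observed, permuted

    return _cached("gwas_tables.pkl", builder)


def complete_matrix(gm, dosage):
    """A GenotypeMatrix carrying an imputed (complete) dosage set."""
    return sw.synth.GenotypeMatrix(
        samples=gm.samples,
        sites=gm.sites,
        dosage=dosage,
        het_count=np.zeros_like(dosage, dtype=np.uint8),
        unknown=np.zeros_like(dosage, dtype=bool),
        known_part=dosage.astype(np.uint8),
        genome=gm.genome,
    )


def snp_id(sites: pd.DataFrame) -> pd.Series:
    return sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)


def effect_series(table: pd.DataFrame) -> pd.Series:
    key = table["chrom"].astype(str) + ":" + table["pos"].astype(str)
    return pd.Series(table["effect"].to_numpy(), index=key).dropna()


def write(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
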