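"""Spatiotemporal and selection signals of diapause-associated alleles.

Scores the GWAS results against synthetic clinal/seasonal frequency panels
with planted concordant signal at the causal SNPs, an outgroup panel with
independent frequencies (null), and a haplotype panel carrying partial
sweeps on the anti-diapause alleles. Significance uses the
imputation-vs-permutation quantile rule throughout.
"""

import numpy as np
import pandas as pd

from _common import SEED, load_world, run_all_gwas, write, effect_series
import swarmscan as sw

world = load_world()
gm, causal = world["genotypes"], world["causal"]
observed, permuted = run_all_gwas(world)
rng = np.random.default_rng(SEED + 77)

slope_vec = np.zeros(gm.n_sites)
delta_vec = np.zeros(gm.n_sites)
for site, beta in causal.items():
    slope_vec[site] = 0.1 * np.sign(beta)  # pro-diapause more common north
    delta_vec[site] = 0.6 * np.sign(beta)  # and in spring

panel = sw.synth.simulate_frequency_panels(
    gm.sites, clinal_slope=slope_vec, seasonal_delta=delta_vec, noise=True, seed=SEED + 6
)
clinal = sw.popgen.clinal_effects(panel).set_index("snp_id")["slope"]
outgroup = panel[panel["locale_id"] == "ZI"].set_index("snp_id")["alt_freq"]

rows = []


def score_all(tables, fn):
    return np.array([fn(effect_series(t)) for t in tables])


checks = {
    "clinal_polygenic_score": lambda eff: sw.popgen.polygenic_score(eff, clinal)[0],
    "seasonal_score_Media_PA": lambda eff: sw.popgen.population_seasonal_score(
        panel, eff, "Media_PA"
    )[0],
    "outgroup_median_freq": lambda eff: sw.popgen.outgroup_median_frequency(eff, outgroup),
}
for name, fn in checks.items():
    obs = score_all(observed, fn)
    null = score_all(permuted, fn)
    res = sw.popgen.quantile_significance(obs, null)
    rows.append(
        {
            "statistic": name,
            "obs_median": float(np.median(obs)),
            "null_q025": res.null_q_low,
            "null_q975": res.null_q_high,
            "pct_above": res.pct_above,
            "pct_below": res.pct_below,
            "significant": res.significant,
            "tail": res.tail or "",
        }
    )

# iHS: haplotype panel with partial sweeps favoring the anti-diapause allele
on_3r = np.flatnonzero(gm.sites["chrom"].to_numpy() == "3R")
pos = gm.sites["pos"].to_numpy()[on_3r].astype(float)
n_hap, n_sites = 60, len(on_3r)
hap = (rng.random((n_hap, n_sites)) < rng.uniform(0.3, 0.7, n_sites)).astype(np.int8)
key_3r = (gm.sites["chrom"].astype(str) + ":" + gm.sites["pos"].astype(str)).to_numpy()[on_3r]
key_to_local = {k: i for i, k in enumerate(key_3r)}
for site, beta in causal.items():
    j = int(np.searchsorted(on_3r, site))
    anti = 0 if beta > 0 else 1
    hap[:, j] = (rng.random(n_hap) < 0.6) == (anti == 1)
    carriers = np.flatnonzero(hap[:, j] == anti)
    for t in range(max(0, j - 12), min(n_sites, j + 13)):
        dist = abs(t - j)
        p_copy = 1.0 if dist <= 6 else max(0.0, 1.0 - (dist - 6) / 6.0)
        hap[carriers[rng.random(len(carriers)) < p_copy], t] = hap[carriers[0], t]

base = sw.popgen.compute_ihs(hap, pos, pro_is_alt=np.ones(n_sites, bool), maf=0.05)


def median_top_ihs(table):
    top = table[table["chrom"] == "3R"].dropna(subset=["p"]).nsmallest(30, "p")
    keys = (top["chrom"].astype(str) + ":" + top["pos"].astype(str)).to_numpy()
    eff = pd.Series(top["effect"].to_numpy(), index=keys)
    pro_is_alt = np.ones(n_sites, dtype=bool)
    sel = []
    for k in keys:
        if k in key_to_local:
            pro_is_alt[key_to_local[k]] = eff[k] > 0
            sel.append(key_to_local[k])
    pol = sw.popgen.repolarize_ihs(base.table, pro_is_alt)
    vals = pol[pol["snp"].isin(sel)]["ihs"].dropna()
    return float(np.median(vals)) if len(vals) else np.nan


obs = np.array([median_top_ihs(t) for t in observed])
null = np.array([median_top_ihs(t) for t in permuted])
res = sw.popgen.quantile_significance(obs[np.isfinite(obs)], null[np.isfinite(null)])
rows.append(
    {
        "statistic": "median_ihs_top_snps",
        "obs_median": float(np.nanmedian(obs)),
        "null_q025": res.null_q_low,
        "null_q975": res.null_q_high,
        "pct_above": res.pct_above,
        "pct_below": res.pct_below,
        "significant": res.significant,
        "tail": res.tail or "",
    }
)

out = pd.DataFrame(rows)
write(out, "07_popgen_scores.tsv")
print(out.round(4).to_string(index=False))
print("\nplanted concordant clinal/seasonal signal is detected (upper tail); the")
print("outgroup median sits inside the permutation band (null); the planted")
print("anti-diapause sweeps pull the median iHS below the permutation 2.5% quantile.")
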