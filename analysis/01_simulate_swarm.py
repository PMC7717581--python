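"""Simulate the hybrid swarms and summarize their genetic makeup.

Builds the shared synthetic world (two 34-line swarms, F5 females,
polygenic diapause) and reports founder-ancestry balance, true ancestry
segment sizes, genotype missingness, and diapause incidence by chamber.
"""

import numpy as np
import pandas as pd

from _common import load_world, write
import swarmscan as sw

world = load_world()
panel, mosaics, gm, pheno = (
    world["panel"], world["mosaics"], world["genotypes"], world["phenotypes"],
)

# contributions are per swarm: each population draws on its own 34 lines
summaries = []
for pop in ("A", "B"):
    pop_mosaics = [m for m in mosaics if m.population == pop]
    contrib = sw.mosaic_qc.founder_contributions(pop_mosaics, n_founders=panel.n_lines)
    lines = list(panel.line_indices(pop))
    s = sw.mosaic_qc.contribution_summary(contrib).loc[lines].reset_index(names="line")
    s["line_id"] = panel.lines["line_id"].to_numpy()[s["line"].astype(int)]
    s.insert(0, "population", pop)
    summaries.append(s)
summary = pd.concat(summaries, ignore_index=True)
write(summary, "01_founder_contributions.tsv")

lens = sw.mosaic_qc.segment_lengths(mosaics)
seg = pd.DataFrame(
    {
        "n_segments": [len(lens)],
        "median_mb": [np.median(lens) / 1e6],
        "pct_below_1mb": [100 * np.mean(lens < 1_000_000)],
    }
)
write(seg, "01_segment_sizes.tsv")

incidence = (
    pheno.groupby(["temperature", "photoperiod"], as_index=False)
    .agg(n=("diapause8", "size"), stage8=("diapause8", "mean"), stage10=("diapause10", "mean"))
)
write(incidence, "01_diapause_incidence.tsv")

print(f"simulated {len(mosaics)} F5 females from {panel.n_lines} founder lines")
print(f"mean per-line ancestry: {100 * summary['mean'].mean():.2f}% (expected {100 / 34:.2f}%)")
print(f"true segments < 1 Mb: {seg['pct_below_1mb'][0]:.2f}% of {seg['n_segments'][0]}")
print(f"genotype missingness before imputation: {100 * gm.missing.mean():.2f}%")
print("diapause incidence falls with temperature:")
print(incidence.groupby("temperature")[["stage8", "stage10"]].mean().round(3).to_string())
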