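"""LASSO SNP selection and ROC evaluation of nested prediction models.

For a handful of imputations, the top-ranked SNPs enter an L1-penalized
logistic model alongside the environmental covariates and genetic PCs; the
retained ("LASSO") SNPs are counted and their predictive value compared
through ROC/AUC for env, env+PC and env+PC+SNP models, against permuted
scans as the null.
"""

import numpy as np
import pandas as pd

from _common import complete_matrix, load_world, run_all_gwas, write
import swarmscan as sw

world = load_world()
gm, imp, report = world["genotypes"], world["imputations"], world["snp_report"]
pheno = world["phenotypes"]
observed, permuted = run_all_gwas(world)

y = pheno["diapause8"].to_numpy().astype(float)
env_cols = ["temperature", "photoperiod", "wolbachia"]
env = pheno[env_cols].to_numpy().astype(float)
TOP_N = 300
N_ITER = 5  # imputations / permutations entering the LASSO stage

gmc = complete_matrix(gm, imp.dosages[0])
grm = sw.relatedness.compute_grm(gmc, snp_set=report.grm_set)
pcs, _ = sw.relatedness.pca(grm, k=32)

key_all = (gm.sites["chrom"].astype(str) + ":" + gm.sites["pos"].astype(str)).to_numpy()
col_of = {k: i for i, k in enumerate(key_all)}


def lasso_for(table, dosage, seed):
    top = sw.select.rank_snps(table, top_n=min(TOP_N, table["p"].notna().sum()))
    keys = (top["chrom"].astype(str) + ":" + top["pos"].astype(str)).to_numpy()
    cols = [col_of[k] for k in keys]
    model = sw.select.lasso_select(
        y, env, pcs, dosage[:, cols].astype(float), list(keys),
        covariate_names=env_cols, folds=5, seed=seed, c_grid=np.logspace(-2.5, 0.5, 8),
    )
    X_full = np.column_stack([env, pcs, dosage[:, cols].astype(float)])
    return model, model.predict_proba(X_full)


counts, preds_full, preds_perm = [], [], []
retained_sets = []
for k in range(N_ITER):
    model, prob = lasso_for(observed[k], imp.dosages[k], seed=k)
    counts.append(len(model.retained_snps))
    retained_sets.append(set(model.retained_snps))
    preds_full.append(prob)
perm_counts = []
for k in range(N_ITER):
    model, prob = lasso_for(permuted[k], imp.dosages[k], seed=100 + k)
    perm_counts.append(len(model.retained_snps))
    preds_perm.append(prob)

# nested baseline models (refit per imputation is unnecessary: env and PCs fixed)
from sklearn.linear_model import LogisticRegression

env_model = LogisticRegression(max_iter=1000).fit(env, y)
envpc_model = LogisticRegression(max_iter=1000).fit(np.column_stack([env, pcs]), y)
roc = sw.select.roc_models(
    y,
    {
        "env": [env_model.predict_proba(env)[:, 1]] * N_ITER,
        "env+PC": [envpc_model.predict_proba(np.column_stack([env, pcs]))[:, 1]] * N_ITER,
        "env+PC+GWAS": preds_full,
        "permuted": preds_perm,
    },
)
auc = roc.auc.groupby("model", as_index=False)["auc"].mean()
write(auc, "06_auc.tsv")

overlap = sw.select.overlap_count(
    {"imp_even": retained_sets[::2], "imp_odd": retained_sets[1::2]}
)
write(overlap, "06_lasso_overlap.tsv")
write(
    pd.DataFrame({"set": ["observed"] * N_ITER + ["permuted"] * N_ITER,
                  "n_lasso_snps": counts + perm_counts}),
    "06_lasso_counts.tsv",
)

print(f"LASSO retained {counts} SNPs per imputation (permuted: {perm_counts})")
print("mean AUC by model:")
print(auc.round(3).to_string(index=False))
print(f"LASSO-SNP overlap between imputations: {overlap['overlap'].tolist()}")
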