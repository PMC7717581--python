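"""Informative-SNP selection by L1-penalized logistic regression and ROC evaluation.

From each association scan the top SNPs by P-value (default 10,000) enter a
LASSO logistic model together with the environmental covariates and 32
genetic principal components; the SNPs with nonzero coefficients at the
cross-validated penalty are the selected ("LASSO") SNPs. Predictive value
is quantified by ROC curves for three nested models — environment only,
environment + PCs, environment + PCs + selected SNPs — with true positive
rates vertically averaged over imputations or permutations on a fixed FPR
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold


def rank_snps(
    gwas_table: pd.DataFrame,
    top_n: int | None = 10_000,
    quantile: float | None = None,
) -> pd.DataFrame:
    """Top SNPs by ascending P-value; ties broken by (chrom, pos).

    ``quantile`` (e.g. 0.0001 or 0.001) selects that fraction of the tested
    SNPs instead of a fixed count.
    """
    tested = gwas_table.dropna(subset=["p"]).copy()
    tested = tested.sort_values(["p", "chrom", "pos"], kind="mergesort")
    if quantile is not None:
        k = int(np.floor(quantile * len(tested)))
    else:
        if top_n is None:
            raise ValueError("give top_n or quantile")
        if top_n > len(tested):
            raise ValueError(f"top_n={top_n} exceeds {len(tested)} tested SNPs")
        k = top_n
    return tested.head(k)


def snp_key(table: pd.DataFrame) -> pd.Series:
    return table["chrom"].astype(str) + ":" + table["pos"].astype(str)


@dataclass
class LassoModel:
    chosen_c: float
    coef: pd.Series  # original-scale coefficients for every predictor
    retained_snps: list[str]
    intercept: float
    predictor_names: list[str]
    scaler_mean: np.ndarray = field(repr=False, default=None)
    scaler_scale: np.ndarray = field(repr=False, default=None)
    model: LogisticRegression | None = field(repr=False, default=None)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.scaler_mean) / self.scaler_scale
        return self.model.predict_proba(Xs)[:, 1]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def lasso_select(
    phenotype: np.ndarray,
    covariates: np.ndarray,
    pcs: np.ndarray | None,
    snp_dosages: np.ndarray,
    snp_names: list[str],
    covariate_names: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    c_grid: np.ndarray | None = None,
    penalize_covariates: bool = True,
) -> LassoModel:
    """L1-penalized logistic regression with the penalty chosen by CV deviance.

    All predictors (environment, PCs, SNPs) are standardized and penalized
    together by default; ``penalize_covariates=False`` refits at the chosen
    penalty with environment/PC coefficients unpenalized (sensitivity mode).
    Coefficients are reported on the original predictor scale.
    """
    y = np.asarray(phenotype, dtype=float)
    blocks = [np.asarray(covariates, dtype=float)]
    names = list(covariate_names or [f"cov{i}" for i in range(blocks[0].shape[1])])
    if pcs is not None:
        blocks.append(np.asarray(pcs, dtype=float))
        names += [f"PC{i + 1}" for i in range(pcs.shape[1])]
    blocks.append(np.asarray(snp_dosages, dtype=float))
    names += list(snp_names)
    X = np.column_stack(blocks)
    if np.unique(y).size < 2:
        raise ValueError("single-class phenotype")
    Xs, mean, scale = _standardize(X)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for _, test_idx in cv.split(Xs, y):
        if np.unique(y[test_idx]).size < 2:
            raise ValueError("degenerate CV fold with a single class")
    if c_grid is None:
        c_grid = np.logspace(-3, 1, 13)
    clf = LogisticRegressionCV(
        Cs=c_grid,
        cv=cv,
        l1_ratios=(1.0,),  # pure L1
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=1000,
        refit=True,
        random_state=seed,
        use_legacy_attributes=False,
    )
    clf.fit(Xs, y)
    chosen_c = float(np.atleast_1d(clf.C_)[0])

    if not penalize_covariates:
        # refit at the chosen penalty, shielding environment/PC terms from
        # shrinkage by leaving them unstandardized-unpenalized via a two-step
        # residual-free approximation: give them a very weak penalty by
        # inflating their scale 1e3-fold in the standardized design.
        n_shield = X.shape[1] - snp_dosages.shape[1]
        Xs2 = Xs.copy()
        Xs2[:, :n_shield] *= 1e3
        refit = LogisticRegression(
            C=chosen_c, l1_ratio=1.0, solver="liblinear", max_iter=1000, random_state=seed
        )
        refit.fit(Xs2, y)
        coef_std = refit.coef_[0].copy()
        coef_std[:n_shield] *= 1e3
        model = refit
        # store an adjusted scaler so predict_proba matches the fit
        scale_eff = scale.copy()
        scale_eff[:n_shield] /= 1e3
        coef = coef_std / scale
        lm_scale = scale_eff
    else:
        model = clf
        coef_std = clf.coef_[0]
        coef = coef_std / scale
        lm_scale = scale

    coef_s = pd.Series(coef, index=names)
    n_non_snp = X.shape[1] - snp_dosages.shape[1]
    retained = [names[i] for i in range(n_non_snp, X.shape[1]) if coef_std[i] != 0.0]
    return LassoModel(
        chosen_c=chosen_c,
        coef=coef_s,
        retained_snps=retained,
        intercept=float(model.intercept_[0]),
        predictor_names=names,
        scaler_mean=mean,
        scaler_scale=lm_scale,
        model=model,
    )


def lasso_at_penalty(
    phenotype: np.ndarray, X: np.ndarray, c: float, seed: int = 0
) -> np.ndarray:
    """Standardized-design L1 logistic fit at a fixed penalty; returns coefficients."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    clf = LogisticRegression(C=c, l1_ratio=1.0, solver="liblinear", max_iter=1000, random_state=seed)
    clf.fit(Xs, np.asarray(phenotype, dtype=float))
    return clf.coef_[0]


DEFAULT_FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class RocSummary:
    fpr_grid: np.ndarray
    mean_tpr: dict[str, np.ndarray]  # per model label
    auc: pd.DataFrame  # columns: model, iteration, auc
    curves: dict[str, list[np.ndarray]] = field(repr=False, default_factory=dict)


def _tpr_on_grid(y: np.ndarray, score: np.ndarray, grid: np.ndarray) -> np.ndarray:
    fpr, tpr, _ = roc_curve(y, score)
    return np.interp(grid, fpr, tpr)


def roc_models(
    phenotype: np.ndarray,
    predictions: dict[str, list[np.ndarray]],
    fpr_grid: np.ndarray = DEFAULT_FPR_GRID,
) -> RocSummary:
    """Vertically averaged ROC curves and AUCs for nested prediction models.

    ``predictions`` maps a model label (e.g. "env", "env+PC",
    "env+PC+GWAS") to one predicted-probability vector per imputation or
    permutation. TPR is averaged at each FPR grid point across iterations.
    """
    y = np.asarray(phenotype)
    if np.unique(y).size < 2:
        raise ValueError("single-class phenotype")
    mean_tpr: dict[str, np.ndarray] = {}
    curves: dict[str, list[np.ndarray]] = {}
    rows = []
    for label, preds in predictions.items():
        tprs = []
        for i, score in enumerate(preds):
            tprs.append(_tpr_on_grid(y, np.asarray(score), fpr_grid))
            rows.append({"model": label, "iteration": i, "auc": roc_auc_score(y, score)})
        curves[label] = tprs
        mean_tpr[label] = np.mean(tprs, axis=0)
    return RocSummary(fpr_grid=fpr_grid, mean_tpr=mean_tpr, auc=pd.DataFrame(rows), curves=curves)


def auc_concordance(y: np.ndarray, score: np.ndarray) -> float:
    """Brute-force AUC: concordance probability over all case-control pairs."""
    y = np.asarray(y)
    s = np.asarray(score, dtype=float)
    cases = s[y == 1]
    controls = s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need both classes")
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(cases) * len(controls)))


def overlap_count(snp_sets: dict[str, list[set]], pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Pairwise intersection sizes between per-iteration SNP sets.

    ``snp_sets`` maps a group label (population or phenotype) to one SNP-id
    set per iteration; iteration i of one group is intersected with
    iteration i of the other.
    """
    labels = list(snp_sets)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    rows = []
    for a, b in pairs:
        for i, (sa, sb) in enumerate(zip(snp_sets[a], snp_sets[b])):
            rows.append({"pair": f"{a}|{b}", "iteration": i, "overlap": len(sa & sb)})
    return pd.DataFrame(rows)
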