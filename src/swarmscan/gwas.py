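"""Binomial mixed-model association testing, inflation diagnostics, heritability.

The association model is a logistic mixed model,

    logit P(diapause_i = 1) = x_i' beta + u_i,   u ~ N(0, tau * GRM),

fitted by penalized quasi-likelihood: iterate a working linear mixed model
on the adjusted response z = eta + (y - mu)/(mu(1-mu)) with covariance
tau*K + diag(1/(mu(1-mu))), updating tau by average-information REML. Each
SNP is then evaluated by the score test under the fitted null: U = g'(y -
mu), V = g'Pg with P the REML projection, U^2/V ~ chi^2_1. The signed
effect U/V and its sign define the pro-diapause allele.

Heritability is estimated on the observed 0/1 scale by single-component
linear REML (Fisher scoring / average information), with the same fixed
effects as the association model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genome import DEFAULT_GENOME
from .relatedness import GRM, compute_grm, loco_grms
from .synth import GenotypeMatrix

# median of the chi-square(1) distribution, fixed as a literal so lambda_GC is
# bit-stable across library versions (0.4549364 to the precision usually printed)
CHI2_1_MEDIAN = 0.4549364231195724

DEFAULT_COVARIATES = ("temperature", "photoperiod", "generation", "population", "wolbachia")


def build_design(
    phenotypes: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept + covariates.

    Categorical covariates (generation, population) are dummy-coded with the
    first level as reference; a covariate with a single observed level is
    dropped automatically (e.g. the population term in single-population
    fits).
    """
    cols: list[np.ndarray] = [np.ones(len(phenotypes))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in phenotypes.columns:
            continue
        series = phenotypes[cov]
        if series.dtype == object or str(series.dtype) == "category":
            levels = sorted(series.unique())
            for lev in levels[1:]:
                cols.append((series == lev).to_numpy().astype(float))
                names.append(f"{cov}[{lev}]")
        else:
            vals = series.to_numpy().astype(float)
            if np.ptp(vals) == 0:
                continue
            cols.append(vals)
            names.append(cov)
    return np.column_stack(cols), names


@dataclass
class NullModel:
    beta: np.ndarray
    beta_names: list[str]
    tau: float
    mu: np.ndarray
    eta: np.ndarray
    y: np.ndarray
    projection: np.ndarray  # P matrix of the working model at convergence
    converged: bool
    n_iter: int
    iterations: list[dict] = field(default_factory=list, repr=False)

    @property
    def residual(self) -> np.ndarray:
        return self.y - self.mu


def _logistic_irls(y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Plain logistic regression by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        new = linalg.solve(X.T @ wx, wx.T @ z, assume_a="pos")
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def fit_null_model(
    phenotypes: pd.DataFrame,
    grm: GRM,
    response: str = "diapause8",
    covariates=DEFAULT_COVARIATES,
    fix_tau: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> NullModel:
    """Fit the logistic mixed null model by PQL with AI-REML for tau.

    ``fix_tau`` pins the variance component (fix_tau=0 reduces the fit to
    plain logistic regression, a useful oracle). Raises on separation or
    non-convergence of the inner solves.
    """
    y = phenotypes[response].to_numpy().astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    X, names = build_design(phenotypes, covariates)
    n = len(y)
    K = grm.matrix
    if K.shape != (n, n):
        raise ValueError("GRM dimension does not match phenotype rows")

    beta = _logistic_irls(y, X)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.min(mu) < 1e-10 or np.max(mu) > 1 - 1e-10:
        raise ValueError("separation detected: fitted probabilities at 0/1")
    w = mu * (1.0 - mu)
    z = eta + (y - mu) / w
    tau = 0.1 * np.var(z - X @ beta) if fix_tau is None else float(fix_tau)

    converged = False
    iterations = []
    P = None
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        sigma = tau * K + np.diag(1.0 / w)
        try:
            cho = linalg.cho_factor(sigma)
        except linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError("working covariance not positive definite") from exc
        sigma_inv = linalg.cho_solve(cho, np.eye(n))
        xt_si = X.T @ sigma_inv
        bmat = xt_si @ X
        beta_new = linalg.solve(bmat, xt_si @ z, assume_a="pos")
        P = sigma_inv - xt_si.T @ linalg.solve(bmat, xt_si, assume_a="pos")
        pz = P @ z
        tau_new = tau
        if fix_tau is None:
            kpz = K @ pz
            score = -0.5 * (np.sum(P * K) - pz @ kpz)
            ai = 0.5 * (kpz @ (P @ kpz))
            if ai > 0:
                # relax and cap the AI step: full Newton steps alternate with
                # the beta/mu update in a two-cycle on small structured samples
                step = 0.5 * score / ai
                cap = 0.5 * (tau + 0.1)
                tau_new = max(tau + np.clip(step, -cap, cap), 0.0)
        delta = max(np.max(np.abs(beta_new - beta)), abs(tau_new - tau))
        beta, tau = beta_new, tau_new
        u = tau * (K @ (sigma_inv @ (z - X @ beta)))
        eta = X @ beta + u
        mu = 1.0 / (1.0 + np.exp(-eta))
        iterations.append({"iter": it, "tau": tau, "delta": delta})
        if delta < tol:
            converged = True
            break

    # refresh the projection at the converged parameter values
    w = mu * (1.0 - mu)
    sigma = tau * K + np.diag(1.0 / w)
    sigma_inv = linalg.cho_solve(linalg.cho_factor(sigma), np.eye(n))
    xt_si = X.T @ sigma_inv
    P = sigma_inv - xt_si.T @ linalg.solve(xt_si @ X, xt_si, assume_a="pos")

    return NullModel(
        beta=beta,
        beta_names=names,
        tau=tau,
        mu=mu,
        eta=eta,
        y=y,
        projection=P,
        converged=converged,
        n_iter=len(iterations),
        iterations=iterations,
    )


def score_test(null: NullModel, dosages: np.ndarray) -> dict:
    """Score test of one SNP under the fitted null; NA for monomorphic SNPs."""
    if not null.converged:
        raise ValueError("null model did not converge")
    g = np.asarray(dosages, dtype=float)
    if np.ptp(g) == 0:
        return {"score_u": np.nan, "score_v": np.nan, "effect": np.nan, "p": np.nan}
    u = float(g @ null.residual)
    v = float(g @ (null.projection @ g))
    if v <= 0:
        raise ValueError("non-positive score variance")
    p = float(stats.chi2.sf(u * u / v, df=1))
    return {"score_u": u, "score_v": v, "effect": u / v, "p": p}


def score_test_many(null: NullModel, dosage_matrix: np.ndarray, sites: pd.DataFrame) -> pd.DataFrame:
    """Vectorized score tests for a samples x SNPs dosage matrix.

    Returns a table with U, V, the signed effect U/V, the chi^2_1 P-value,
    the pro-diapause allele (alt iff U > 0), and the within-sample MAF.
    Monomorphic SNPs get NA rows.
    """
    if not null.converged:
        raise ValueError("null model did not converge")
    G = dosage_matrix.astype(float)
    freq = G.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    U = G.T @ null.residual
    PG = null.projection @ G
    V = np.einsum("ij,ij->j", G, PG)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(poly & (V > 0), U * U / np.maximum(V, 1e-300), np.nan)
        p = stats.chi2.sf(chi2, df=1)
        effect = np.where(poly, U / np.maximum(V, 1e-300), np.nan)
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "score_u": np.where(poly, U, np.nan),
            "score_v": np.where(poly, V, np.nan),
            "effect": effect,
            "p": p,
            "pro_diapause_allele": np.where(poly, np.where(U > 0, "alt", "ref"), "NA"),
            "maf": np.fmin(freq, 1 - freq),
        }
    )
    return out


def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda_GC: median observed chi^2_1 quantile over the null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no finite P-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P-values must lie in (0, 1]")
    return float(np.median(stats.chi2.isf(p, df=1)) / CHI2_1_MEDIAN)


def permute_phenotypes(
    phenotypes: pd.DataFrame,
    population_labels: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Shuffle sample IDs within each population, keeping rows intact.

    Phenotype and environmental covariates stay paired (rows are not
    touched); only the individual_id assignment is permuted, dissociating
    genotype from phenotype. The permutation for a population depends only
    on the seed, the population label and the number of its rows, so the
    same seed yields the identical shuffle for either diapause cutoff and
    for any subset that preserves row order.
    """
    out = phenotypes.copy()
    labels = (
        phenotypes["population"].to_numpy() if population_labels is None else np.asarray(population_labels)
    )
    ids = phenotypes["individual_id"].to_numpy().copy()
    for pop in np.unique(labels):
        rows = np.flatnonzero(labels == pop)
        rng = np.random.default_rng([seed, zlib.crc32(str(pop).encode())])
        ids[rows] = ids[rows][rng.permutation(len(rows))]
    out["individual_id"] = ids
    return out


def run_gwas(
    dosage: np.ndarray,
    sites: pd.DataFrame,
    phenotypes: pd.DataFrame,
    sample_ids: pd.Series | np.ndarray,
    grm_snp_set: np.ndarray | None = None,
    test_snp_set: np.ndarray | None = None,
    mapping_population: str = "both",
    grm_mode: str = "nonloco",
    response: str = "diapause8",
    maf_min: float = 0.05,
    genome=None,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """One complete GWAS on one imputed dosage set.

    Aligns phenotype rows to genotype samples by individual_id, restricts to
    the mapping population ("A", "B" or "both"), builds the GRM from
    ``grm_snp_set`` SNPs (non-LOCO, or one GRM per chromosome in LOCO mode),
    fits the null and score-tests every ``test_snp_set`` SNP with MAF >
    ``maf_min`` in the mapping sample.
    """
    sample_ids = pd.Series(np.asarray(sample_ids), name="individual_id")
    pheno = phenotypes.set_index("individual_id").loc[sample_ids].reset_index()
    if mapping_population != "both":
        keep = (pheno["population"] == mapping_population).to_numpy()
    else:
        keep = np.ones(len(pheno), dtype=bool)
    pheno = pheno.loc[keep].reset_index(drop=True)
    d = dosage[keep]

    freq = d.mean(axis=0) / 2.0
    maf_ok = np.fmin(freq, 1 - freq) > maf_min
    test_mask = maf_ok if test_snp_set is None else (test_snp_set & maf_ok)

    gm_meta = GenotypeMatrix(
        samples=pd.DataFrame({"individual_id": pheno["individual_id"], "population": pheno["population"],
                              "generation": pheno.get("generation", "F5"), "sex": "F"}),
        sites=sites,
        dosage=d,
        het_count=np.zeros_like(d, dtype=np.uint8),
        unknown=np.zeros_like(d, dtype=bool),
        known_part=np.zeros_like(d, dtype=np.uint8),
        genome=genome if genome is not None else DEFAULT_GENOME,
    )

    if grm_mode == "nonloco":
        grm = compute_grm(gm_meta, snp_set=grm_snp_set)
        null = fit_null_model(pheno, grm, response=response, covariates=covariates)
        table = score_test_many(null, d[:, test_mask], sites.loc[test_mask])
    elif grm_mode == "loco":
        grms = loco_grms(gm_meta, snp_set=grm_snp_set)
        chrom_of = {a.name: a.chromosome for a in gm_meta.genome.arms}
        parts = []
        arms = sites["chrom"].to_numpy()
        for chrom, grm in grms.items():
            on = np.array([chrom_of.get(a, a) == chrom for a in arms]) & test_mask
            if not on.any():
                continue
            null = fit_null_model(pheno, grm, response=response, covariates=covariates)
            parts.append(score_test_many(null, d[:, on], sites.loc[on]))
        table = pd.concat(parts, ignore_index=True)
    else:
        raise ValueError("grm_mode must be 'loco' or 'nonloco'")
    table["population_set"] = mapping_population
    table["grm_mode"] = grm_mode
    return table


# ---------------------------------------------------------------------------
# heritability


@dataclass
class HeritabilityEstimate:
    vg: float
    ve: float
    h2: float
    se: float
    ci: tuple[float, float]
    converged: bool
    boundary: bool
    n_iter: int


def estimate_heritability(
    phenotype: np.ndarray,
    covariates: np.ndarray,
    grm: GRM,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> HeritabilityEstimate:
    """Single-component REML on the observed 0/1 scale by Fisher scoring.

    Model: y = X beta + g + e, g ~ N(0, Vg K), e ~ N(0, Ve I). h^2 =
    Vg/(Vg+Ve); the standard error comes from the inverse expected
    information via the delta method, and the confidence interval is the
    estimate +/- 1.96 SE. Vg pinned at the zero boundary is reported.
    """
    y = np.asarray(phenotype, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    vals, U = np.linalg.eigh(grm.matrix)
    vals = np.maximum(vals, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    vy = np.var(y)
    vg, ve = 0.5 * vy, 0.5 * vy
    floor = 1e-8 * vy
    converged = False
    info = np.eye(2)
    for it in range(1, max_iter + 1):
        w = vg * vals + ve
        w = np.maximum(w, 1e-12)
        wi = 1.0 / w
        XtWi = Xt * wi[:, None]
        B = Xt.T @ XtWi
        Binv = np.linalg.inv(B)
        # P y and diag-weighted traces without forming P when possible
        Py = wi * yt - XtWi @ (Binv @ (XtWi.T @ yt))
        # P = diag(wi) - XtWi Binv XtWi^T (dense, n x n)
        P = np.diag(wi) - XtWi @ Binv @ XtWi.T
        Vj = (vals, np.ones(n))
        score = np.empty(2)
        for j in range(2):
            score[j] = -0.5 * (np.sum(np.diag(P) * Vj[j]) - (Py * Vj[j]) @ Py)
        info = np.empty((2, 2))
        P2 = P * P
        for j in range(2):
            for k in range(j, 2):
                info[j, k] = info[k, j] = 0.5 * float(Vj[j] @ P2 @ Vj[k])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        new_vg, new_ve = vg + step[0], ve + step[1]
        # step halving into the feasible region
        halvings = 0
        while (new_vg < 0 or new_ve <= 0) and halvings < 30:
            step *= 0.5
            new_vg, new_ve = vg + step[0], ve + step[1]
            halvings += 1
        new_vg = max(new_vg, 0.0)
        new_ve = max(new_ve, floor)
        delta = max(abs(new_vg - vg), abs(new_ve - ve))
        vg, ve = new_vg, new_ve
        if delta < tol * max(vy, 1e-12):
            converged = True
            break
    if not converged and it >= max_iter:
        raise RuntimeError("heritability REML did not converge")

    h2 = vg / (vg + ve)
    cov = np.linalg.inv(info)
    grad = np.array([ve, -vg]) / (vg + ve) ** 2
    se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return HeritabilityEstimate(
        vg=float(vg),
        ve=float(ve),
        h2=float(h2),
        se=se,
        ci=(h2 - 1.96 * se, h2 + 1.96 * se),
        converged=converged,
        boundary=bool(vg <= floor),
        n_iter=it,
    )
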