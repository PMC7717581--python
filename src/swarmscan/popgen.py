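"""Spatiotemporal and selection-history scoring of association-mapped alleles.

Pro-diapause alleles (positive signed GWAS effect) are predicted to be more
common in the north and in spring. Four summaries test that prediction:

- clinal polygenic score: sum over SNPs of (GWAS effect x clinal slope of
  alt-allele frequency on latitude, logit scale);
- per-population seasonal score: sum of (logit f_spring - logit f_fall) x
  GWAS effect;
- outgroup median frequency of pro-diapause alleles in an ancestral-range
  panel;
- iHS with the pro-diapause allele treated as "derived", standardized
  within pro-allele frequency bins.

Observed (per-imputation) statistics are compared to permutation nulls by
the quantile rule: significant iff more than 50% of imputations fall beyond
the 2.5% or 97.5% permutation quantile on one tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def _logit(p):
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# clinal effects


def clinal_effects(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP logit-scale slope of alt-allele frequency on latitude.

    Frequencies are first averaged over sampling times within each locale,
    weighted by the effective allele count Neff; the per-locale means are
    then regressed on latitude in a binomial GLM (logit link) with the
    summed Neff as pseudo-counts. Returns slope, SE and locale count per
    SNP; monomorphic-across-locales SNPs get NA slopes.
    """
    clinal = panel.dropna(subset=["latitude"])
    by_locale = (
        clinal.assign(wfreq=clinal["alt_freq"] * clinal["neff"])
        .groupby(["snp_id", "locale_id", "latitude"], as_index=False)
        .agg(wfreq=("wfreq", "sum"), neff=("neff", "sum"))
    )
    by_locale["freq"] = by_locale["wfreq"] / by_locale["neff"]

    rows = []
    for snp, grp in by_locale.groupby("snp_id", sort=False):
        lats = grp["latitude"].to_numpy()
        if len(np.unique(lats)) < 3:
            raise ValueError("need >= 3 locales with distinct latitudes")
        freqs = grp["freq"].to_numpy()
        if np.all(freqs == freqs[0]) and freqs[0] in (0.0, 1.0):
            rows.append({"snp_id": snp, "slope": np.nan, "se": np.nan, "n_locales": len(grp)})
            continue
        X = sm.add_constant(lats)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(freqs, X, family=sm.families.Binomial(), var_weights=grp["neff"].to_numpy()).fit()
        rows.append(
            {"snp_id": snp, "slope": fit.params[1], "se": fit.bse[1], "n_locales": len(grp)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# polygenic scores


def polygenic_score(
    gwas_effects: pd.Series,
    external_effects: pd.Series,
    snp_set: pd.Index | list | None = None,
) -> tuple[float, int, int]:
    """Sum over SNPs of (GWAS effect x clinal/seasonal effect).

    Both series are keyed by SNP id with effects on the alt allele; SNPs
    missing from either side are excluded and counted. Positive scores mean
    pro-diapause alleles are more common north / in spring. Returns (score,
    n_used, n_excluded).
    """
    keys = gwas_effects.index if snp_set is None else pd.Index(snp_set)
    shared = keys.intersection(gwas_effects.index).intersection(external_effects.index)
    n_excluded = len(keys) - len(shared)
    if len(shared) == 0:
        raise ValueError("zero overlapping SNPs")
    score = float((gwas_effects.loc[shared] * external_effects.loc[shared]).sum())
    return score, len(shared), n_excluded


def seasonal_logit_differences(
    panel: pd.DataFrame, locale_id: str, clamp: bool = True
) -> pd.Series:
    """Per-SNP logit(f_spring) - logit(f_fall) for one locale.

    Frequencies at 0 or 1 are clamped to [1/(2 Neff + 1), 1 - 1/(2 Neff +
    1)] before the logit (continuity correction).
    """
    loc = panel[panel["locale_id"] == locale_id]
    spring = loc[loc["season"] == "spring"].set_index("snp_id")
    fall = loc[loc["season"] == "fall"].set_index("snp_id")
    shared = spring.index.intersection(fall.index)
    if len(shared) == 0:
        raise ValueError(f"locale {locale_id} lacks both seasons")
    out = {}
    for season_df in (spring, fall):
        f = season_df.loc[shared, "alt_freq"].to_numpy(dtype=float)
        if clamp:
            eps = 1.0 / (2.0 * season_df.loc[shared, "neff"].to_numpy(dtype=float) + 1.0)
            f = np.clip(f, eps, 1.0 - eps)
        elif np.any((f <= 0) | (f >= 1)):
            raise ValueError("frequency at 0 or 1; enable the continuity correction")
        out[id(season_df)] = f
    delta = _logit(out[id(spring)]) - _logit(out[id(fall)])
    return pd.Series(delta, index=shared)


def population_seasonal_score(
    panel: pd.DataFrame,
    gwas_effects: pd.Series,
    locale_id: str,
    snp_set: pd.Index | list | None = None,
) -> tuple[float, int, int]:
    """Seasonal polygenic score for one locale: sum of delta-logit x GWAS effect."""
    delta = seasonal_logit_differences(panel, locale_id)
    return polygenic_score(gwas_effects, delta, snp_set=snp_set)


def outgroup_median_frequency(
    gwas_effects: pd.Series,
    outgroup_freqs: pd.Series,
    snp_set: pd.Index | list | None = None,
) -> float:
    """Median pro-diapause-allele frequency in the outgroup panel.

    The pro-diapause allele is alt when the signed effect is positive, so
    its frequency is the alt frequency, else 1 - alt frequency.
    """
    keys = gwas_effects.index if snp_set is None else pd.Index(snp_set)
    shared = keys.intersection(gwas_effects.index).intersection(outgroup_freqs.index)
    if len(shared) == 0:
        raise ValueError("empty overlap with the outgroup panel")
    eff = gwas_effects.loc[shared].to_numpy(dtype=float)
    freq = outgroup_freqs.loc[shared].to_numpy(dtype=float)
    pro = np.where(eff > 0, freq, 1.0 - freq)
    return float(np.median(pro))


def exclude_region(keys: pd.Index | pd.Series, region: str) -> np.ndarray:
    """Boolean keep-mask excluding SNP ids inside 'chrom:start-end'."""
    chrom, span = region.split(":")
    start, end = (int(x.replace(",", "")) for x in span.split("-"))
    keep = []
    for key in keys:
        c, p = str(key).split(":")
        keep.append(not (c == chrom and start <= int(p) <= end))
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# iHS


@dataclass
class IhsResult:
    table: pd.DataFrame  # snp index, freq_pro, ihh_pro, ihh_anti, uns_ihs, ihs, bin, edge
    n_skipped: int


def _ehh_curve(hap: np.ndarray, pos: np.ndarray, focal: int, carriers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EHH within one allele class at every site, walking outward from focal.

    Returns (ehh values over all sites, evaluated flags). EHH at the focal
    site is 1 by definition; at site t it is the probability that two
    randomly drawn carrier haplotypes are identical at every site between
    focal and t inclusive.
    """
    n = len(carriers)
    ehh = np.zeros(len(pos))
    ehh[focal] = 1.0
    denom = n * (n - 1) / 2.0
    for direction in (-1, 1):
        groups = {(): list(carriers)}
        t = focal
        while True:
            t += direction
            if t < 0 or t >= len(pos):
                break
            new_groups: dict[tuple, list[int]] = {}
            for key, members in groups.items():
                for h in members:
                    nk = key + (int(hap[h, t]),)
                    new_groups.setdefault(nk, []).append(h)
            groups = new_groups
            ehh[t] = sum(len(g) * (len(g) - 1) / 2.0 for g in groups.values()) / denom
            if ehh[t] == 0.0:
                break
    return ehh, None


def _integrate_ihh(
    ehh: np.ndarray, pos: np.ndarray, focal: int, cutoff: float
) -> tuple[float, bool]:
    """Trapezoidal integral of EHH outward from the focal SNP.

    Integration stops after the first site where EHH drops below the cutoff
    (that trapezoid is included); hitting the chromosome end before decay
    flags the value as edge-truncated.
    """
    total = 0.0
    edge = False
    for direction in (-1, 1):
        t = focal
        while True:
            nxt = t + direction
            if nxt < 0 or nxt >= len(pos):
                if ehh[t] >= cutoff:
                    edge = True
                break
            total += 0.5 * (ehh[t] + ehh[nxt]) * abs(pos[nxt] - pos[t])
            if ehh[nxt] < cutoff:
                break
            t = nxt
    return total, edge


def compute_ihs(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    pro_is_alt: np.ndarray,
    chrom: np.ndarray | None = None,
    maf: float = 0.05,
    min_haplotypes: int = 5,
    ehh_cutoff: float = 0.05,
    n_bins: int = 20,
) -> IhsResult:
    """Integrated haplotype score polarized by the pro-diapause allele.

    ``haplotypes`` is a binary (n_haplotypes x n_sites) matrix (one
    haplotype per effectively-haploid line; impute missing genotypes
    beforehand); ``pro_is_alt`` marks SNPs whose alt allele is
    pro-diapause. Per focal SNP, EHH is integrated over physical position
    within each allele class until it decays below ``ehh_cutoff``; the
    unstandardized score is ln(iHH_pro / iHH_anti) and the standardized iHS
    is its z-score within equal-width pro-allele-frequency bins.
    """
    hap = np.asarray(haplotypes, dtype=np.int8)
    pos = np.asarray(positions, dtype=float)
    n_hap, n_sites = hap.shape
    if chrom is None:
        chrom = np.zeros(n_sites, dtype=int)
    chrom = np.asarray(chrom)

    rows = []
    n_skipped = 0
    for s in range(n_sites):
        on_chrom = np.flatnonzero(chrom == chrom[s])
        local = np.searchsorted(on_chrom, s)
        sub_hap = hap[:, on_chrom]
        sub_pos = pos[on_chrom]
        alt = hap[:, s] == 1
        pro = alt if pro_is_alt[s] else ~alt
        freq_pro = pro.mean()
        f_alt = alt.mean()
        if min(f_alt, 1 - f_alt) < maf or pro.sum() < min_haplotypes or (~pro).sum() < min_haplotypes:
            n_skipped += 1
            continue
        ihh = {}
        edge_any = False
        for label, cls in (("pro", np.flatnonzero(pro)), ("anti", np.flatnonzero(~pro))):
            ehh, _ = _ehh_curve(sub_hap, sub_pos, local, cls)
            ihh[label], edge = _integrate_ihh(ehh, sub_pos, local, ehh_cutoff)
            edge_any |= edge
        if ihh["pro"] <= 0 or ihh["anti"] <= 0:
            n_skipped += 1
            continue
        rows.append(
            {
                "snp": s,
                "freq_pro": freq_pro,
                "ihh_pro": ihh["pro"],
                "ihh_anti": ihh["anti"],
                "uns_ihs": np.log(ihh["pro"] / ihh["anti"]),
                "edge": edge_any,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        bins = np.minimum((table["freq_pro"] * n_bins).astype(int), n_bins - 1)
        table["bin"] = bins
        z = np.full(len(table), np.nan)
        for b, grp in table.groupby("bin"):
            vals = grp["uns_ihs"].to_numpy()
            sd = vals.std(ddof=1) if len(vals) >= 2 else 0.0
            if len(vals) >= 2 and sd > 0:
                z[grp.index.to_numpy()] = (vals - vals.mean()) / sd
            elif len(vals) >= 1:
                z[grp.index.to_numpy()] = 0.0
        table["ihs"] = z
    return IhsResult(table=table, n_skipped=n_skipped)


def repolarize_ihs(base_table: pd.DataFrame, pro_is_alt: np.ndarray, n_bins: int = 20) -> pd.DataFrame:
    """Re-polarize an alt-polarized iHS table for a new pro-diapause assignment.

    compute_ihs with pro_is_alt=all-True yields ln(iHH_alt/iHH_anti) per SNP;
    the polarized unstandardized score for any GWAS sign vector is just a
    sign flip (swapping allele labels negates the score), after which the
    frequency-bin standardization is redone. This lets one EHH integration
    serve every imputation and permutation.
    """
    out = base_table.reset_index(drop=True)
    flip = ~np.asarray(pro_is_alt, dtype=bool)[out["snp"].to_numpy()]
    out["uns_ihs"] = np.where(flip, -out["uns_ihs"], out["uns_ihs"])
    out["freq_pro"] = np.where(flip, 1.0 - out["freq_pro"], out["freq_pro"])
    out["bin"] = np.minimum((out["freq_pro"] * n_bins).astype(int), n_bins - 1)
    z = np.full(len(out), np.nan)
    for _, grp in out.groupby("bin"):
        vals = grp["uns_ihs"].to_numpy()
        sd = vals.std(ddof=1) if len(vals) >= 2 else 0.0
        if len(vals) >= 2 and sd > 0:
            z[grp.index.to_numpy()] = (vals - vals.mean()) / sd
        elif len(vals) >= 1:
            z[grp.index.to_numpy()] = 0.0
    out["ihs"] = z
    return out


# ---------------------------------------------------------------------------
# imputation-vs-permutation significance


@dataclass
class ScoreSummary:
    observed: np.ndarray
    null_q_low: float
    null_q_high: float
    pct_above: float
    pct_below: float
    significant: bool
    tail: str | None


def quantile_significance(
    observed: np.ndarray,
    null: np.ndarray,
    tails: tuple[float, float] = (0.025, 0.975),
) -> ScoreSummary:
    """The >50%-of-imputations-beyond-the-permutation-quantiles rule.

    Significant iff more than half the observed (per-imputation) statistics
    are above the upper null quantile, or more than half are below the
    lower one.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if len(observed) == 0:
        raise ValueError("no observed statistics")
    if len(null) < 20:
        raise ValueError("need >= 20 permutation values")
    q_low, q_high = np.quantile(null, tails)
    pct_above = 100.0 * np.mean(observed > q_high)
    pct_below = 100.0 * np.mean(observed < q_low)
    if pct_above > 50.0:
        sig, tail = True, "upper"
    elif pct_below > 50.0:
        sig, tail = True, "lower"
    else:
        sig, tail = False, None
    return ScoreSummary(
        observed=observed,
        null_q_low=float(q_low),
        null_q_high=float(q_high),
        pct_above=float(pct_above),
        pct_below=float(pct_below),
        significant=sig,
        tail=tail,
    )


def quantile_rank(observed_median: float, null: np.ndarray) -> float:
    """Quantile rank of an observed median within the permutation values.

    Ranks below 0.05 indicate de-enrichment, above 0.95 enrichment (the
    annotation-category convention).
    """
    null = np.asarray(null, dtype=float)
    return float(np.mean(null < observed_median) + 0.5 * np.mean(null == observed_median))
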