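"""Clinal/seasonal polygenic scores, outgroup frequencies, iHS, quantile rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

import swarmscan as sw
from swarmscan.popgen import (
    clinal_effects,
    compute_ihs,
    exclude_region,
    outgroup_median_frequency,
    polygenic_score,
    population_seasonal_score,
    quantile_rank,
    quantile_significance,
    repolarize_ihs,
    seasonal_logit_differences,
)


def make_panel(**kwargs):
    snps = pd.DataFrame({"chrom": ["2L"] * 6, "pos": np.arange(1, 7) * 1000})
    return sw.synth.simulate_frequency_panels(snps, **kwargs)


class TestClinal:
    def test_flat_frequencies_give_zero_slope(self):
        panel = make_panel(clinal_slope=0.0, base_freq=("fixed", 0.35), noise=False, seed=0)
        out = clinal_effects(panel)
        assert np.allclose(out["slope"], 0.0, atol=1e-8)

    def test_generating_slope_recovered_exactly_without_noise(self):
        panel = make_panel(clinal_slope=0.1, base_freq=("fixed", 0.5), noise=False, seed=0)
        out = clinal_effects(panel)
        assert np.allclose(out["slope"], 0.1, atol=1e-6)

    def test_lower_depth_increases_standard_error(self):
        locs_hi = [sw.synth.Locale(f"L{i}", 30.0 + i, depth=200.0) for i in range(5)]
        locs_lo = [sw.synth.Locale(f"L{i}", 30.0 + i, depth=10.0) for i in range(5)]
        hi = clinal_effects(make_panel(clinal_slope=0.05, locales=locs_hi, noise=False, seed=1))
        lo = clinal_effects(make_panel(clinal_slope=0.05, locales=locs_lo, noise=False, seed=1))
        assert (lo["se"].to_numpy() > hi["se"].to_numpy()).all()

    def test_too_few_locales_rejected(self):
        locs = [sw.synth.Locale("L1", 30.0), sw.synth.Locale("L2", 40.0)]
        with pytest.raises(ValueError):
            clinal_effects(make_panel(locales=locs, noise=False, seed=0))


class TestPolygenicScore:
    def test_zero_external_effects_give_zero(self):
        g = pd.Series([1.0, -2.0], index=["a", "b"])
        e = pd.Series([0.0, 0.0], index=["a", "b"])
        assert polygenic_score(g, e)[0] == 0.0

    def test_hand_arithmetic(self):
        g = pd.Series([2.0, -1.0, 0.5], index=["s1", "s2", "s3"])
        c = pd.Series([0.1, 0.2, -0.4], index=["s1", "s2", "s3"])
        score, n_used, n_excl = polygenic_score(g, c)
        assert score == pytest.approx(0.2 - 0.2 - 0.2)
        assert n_used == 3 and n_excl == 0

    def test_allele_flip_leaves_score_unchanged(self):
        g = pd.Series([2.0, -1.0], index=["s1", "s2"])
        c = pd.Series([0.1, 0.2], index=["s1", "s2"])
        g2, c2 = g.copy(), c.copy()
        g2["s1"], c2["s1"] = -g2["s1"], -c2["s1"]  # recode s1 to the other allele
        assert polygenic_score(g, c)[0] == pytest.approx(polygenic_score(g2, c2)[0])

    def test_bilinearity_over_disjoint_sets(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(20)]
        g = pd.Series(rng.normal(size=20), index=idx)
        c = pd.Series(rng.normal(size=20), index=idx)
        total = polygenic_score(g, c, snp_set=idx)[0]
        part = polygenic_score(g, c, snp_set=idx[:7])[0] + polygenic_score(g, c, snp_set=idx[7:])[0]
        assert total == pytest.approx(part)

    def test_missing_snps_excluded_and_counted(self):
        g = pd.Series([1.0, 1.0], index=["s1", "s2"])
        c = pd.Series([0.5], index=["s1"])
        score, n_used, n_excl = polygenic_score(g, c)
        assert (score, n_used, n_excl) == (0.5, 1, 1)
        with pytest.raises(ValueError):
            polygenic_score(g, pd.Series([1.0], index=["zzz"]))


class TestSeasonal:
    def _panel(self, f_spring, f_fall):
        rows = []
        for i, (fs, ff) in enumerate(zip(f_spring, f_fall)):
            for season, f in (("spring", fs), ("fall", ff)):
                rows.append(
                    {"snp_id": f"s{i}", "locale_id": "L", "season": season,
                     "alt_freq": f, "neff": 100.0}
                )
        return pd.DataFrame(rows)

    def test_equal_seasons_give_zero(self):
        panel = self._panel([0.3, 0.6], [0.3, 0.6])
        g = pd.Series([1.0, 2.0], index=["s0", "s1"])
        assert population_seasonal_score(panel, g, "L")[0] == pytest.approx(0.0)

    def test_closed_form_logit_difference(self):
        panel = self._panel([0.6], [0.5])
        delta = seasonal_logit_differences(panel, "L")
        assert delta["s0"] == pytest.approx(np.log(0.6 / 0.4) - 0.0, abs=1e-12)
        assert delta["s0"] == pytest.approx(0.4055, abs=1e-4)
        g = pd.Series([1.0], index=["s0"])
        assert population_seasonal_score(panel, g, "L")[0] == pytest.approx(0.4055, abs=1e-4)

    def test_boundary_frequencies_clamped(self):
        panel = self._panel([1.0], [0.5])
        delta = seasonal_logit_differences(panel, "L")
        clamped = 1.0 - 1.0 / 201.0
        assert delta["s0"] == pytest.approx(np.log(clamped / (1 - clamped)))

    def test_missing_season_rejected(self):
        panel = self._panel([0.5], [0.5])
        panel = panel[panel["season"] == "spring"]
        with pytest.raises(ValueError):
            population_seasonal_score(panel, pd.Series([1.0], index=["s0"]), "L")


class TestOutgroup:
    def test_all_half_median_is_half_regardless_of_polarity(self):
        g = pd.Series([1.0, -1.0, 2.0], index=["a", "b", "c"])
        f = pd.Series([0.5, 0.5, 0.5], index=["a", "b", "c"])
        assert outgroup_median_frequency(g, f) == 0.5

    def test_negative_effect_contributes_complement(self):
        g = pd.Series([-1.0], index=["a"])
        f = pd.Series([0.9], index=["a"])
        assert outgroup_median_frequency(g, f) == pytest.approx(0.1)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            outgroup_median_frequency(pd.Series([1.0], index=["a"]), pd.Series([0.5], index=["b"]))


class TestExcludeRegion:
    def test_tlk_style_window_filter(self):
        keys = pd.Index(["X:3650000", "X:3670000", "X:3685000", "2L:3670000"])
        keep = exclude_region(keys, "X:3660000-3685000")
        assert list(keep) == [True, False, False, True]


def brute_force_ihh(hap, pos, focal, carriers, cutoff=0.05):
    """EHH by pairwise enumeration + hand trapezoids, both directions."""
    n = len(carriers)
    total = 0.0
    for direction in (-1, 1):
        prev_ehh = 1.0
        t = focal
        while True:
            nxt = t + direction
            if nxt < 0 or nxt >= len(pos):
                break
            lo, hi = min(focal, nxt), max(focal, nxt)
            pairs = list(itertools.combinations(carriers, 2))
            same = sum(1 for a, b in pairs if (hap[a, lo : hi + 1] == hap[b, lo : hi + 1]).all())
            ehh = same / len(pairs)
            total += 0.5 * (prev_ehh + ehh) * abs(pos[nxt] - pos[t])
            if ehh < cutoff:
                break
            prev_ehh = ehh
            t = nxt
    return total


class TestIhs:
    def test_mirror_symmetric_classes_score_zero(self):
        # two allele classes with identical flanking haplotype structure
        block = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1], [0, 1, 1]])
        hap = np.column_stack([np.vstack([block, block]), np.array([1] * 5 + [0] * 5), np.vstack([block, block])])
        pos = np.array([10, 20, 30, 55, 80, 90, 100.0])
        res = compute_ihs(hap, pos, pro_is_alt=np.ones(7, bool), maf=0.0, min_haplotypes=2)
        focal_row = res.table[res.table["snp"] == 3]
        assert focal_row["uns_ihs"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        hap = rng.integers(0, 2, size=(8, 7))
        hap[:, 3] = [0, 0, 0, 0, 1, 1, 1, 1]  # focal SNP with 4/4 split
        pos = np.sort(rng.choice(1000, 7, replace=False)).astype(float)
        res = compute_ihs(
            hap, pos, pro_is_alt=np.ones(7, bool), maf=0.0, min_haplotypes=2, ehh_cutoff=0.05
        )
        row = res.table[res.table["snp"] == 3].iloc[0]
        carriers_pro = [i for i in range(8) if hap[i, 3] == 1]
        carriers_anti = [i for i in range(8) if hap[i, 3] == 0]
        assert row["ihh_pro"] == pytest.approx(brute_force_ihh(hap, pos, 3, carriers_pro), rel=1e-12)
        assert row["ihh_anti"] == pytest.approx(brute_force_ihh(hap, pos, 3, carriers_anti), rel=1e-12)
        assert row["uns_ihs"] == pytest.approx(np.log(row["ihh_pro"] / row["ihh_anti"]))

    def test_allele_relabel_negates_unstandardized_score(self):
        rng = np.random.default_rng(8)
        hap = rng.integers(0, 2, size=(12, 9))
        pos = np.sort(rng.choice(5000, 9, replace=False)).astype(float)
        a = compute_ihs(hap, pos, pro_is_alt=np.ones(9, bool), maf=0.0, min_haplotypes=2)
        b = compute_ihs(hap, pos, pro_is_alt=np.zeros(9, bool), maf=0.0, min_haplotypes=2)
        merged = a.table.merge(b.table, on="snp", suffixes=("_a", "_b"))
        assert np.allclose(merged["uns_ihs_a"], -merged["uns_ihs_b"], atol=1e-12)

    def test_standardized_scores_centered_within_bins(self):
        rng = np.random.default_rng(9)
        hap = rng.integers(0, 2, size=(40, 60))
        pos = np.sort(rng.choice(10**6, 60, replace=False)).astype(float)
        res = compute_ihs(hap, pos, pro_is_alt=rng.integers(0, 2, 60).astype(bool))
        for _, grp in res.table.dropna(subset=["ihs"]).groupby("bin"):
            if len(grp) >= 2 and grp["uns_ihs"].std() > 0:
                assert abs(grp["ihs"].mean()) < 1e-6
                assert grp["ihs"].std() == pytest.approx(1.0, abs=1e-6)

    def test_repolarize_matches_direct_computation(self):
        rng = np.random.default_rng(10)
        hap = rng.integers(0, 2, size=(20, 30))
        pos = np.sort(rng.choice(10**5, 30, replace=False)).astype(float)
        base = compute_ihs(hap, pos, pro_is_alt=np.ones(30, bool), maf=0.0, min_haplotypes=3)
        polarity = rng.integers(0, 2, 30).astype(bool)
        direct = compute_ihs(hap, pos, pro_is_alt=polarity, maf=0.0, min_haplotypes=3)
        fast = repolarize_ihs(base.table, polarity)
        merged = direct.table.merge(fast, on="snp", suffixes=("_d", "_f"))
        assert np.allclose(merged["uns_ihs_d"], merged["uns_ihs_f"], atol=1e-12)
        assert np.allclose(merged["ihs_d"], merged["ihs_f"], atol=1e-9, equal_nan=True)

    def test_rare_allele_class_skipped(self):
        hap = np.zeros((10, 3), dtype=np.int8)
        hap[0, 1] = 1  # singleton
        res = compute_ihs(hap, np.array([1.0, 2.0, 3.0]), np.ones(3, bool), maf=0.0)
        assert 1 not in set(res.table.get("snp", []))


class TestQuantileRule:
    def test_all_observed_above_null_max(self):
        out = quantile_significance(np.array([10.0] * 30), np.random.default_rng(0).normal(size=100))
        assert out.significant and out.tail == "upper" and out.pct_above == 100.0

    def test_iid_null_observed_rarely_flags(self):
        rng = np.random.default_rng(1)
        flags = 0
        trials = 400
        for _ in range(trials):
            null = rng.normal(size=100)
            obs = rng.normal(size=20)
            if quantile_significance(obs, null).significant:
                flags += 1
        assert flags / trials <= 0.05

    def test_minimum_null_size_enforced(self):
        with pytest.raises(ValueError):
            quantile_significance(np.ones(5), np.ones(10))

    def test_quantile_rank_enrichment_convention(self):
        null = np.arange(100.0)
        assert quantile_rank(99.5, null) == pytest.approx(1.0)
        assert quantile_rank(-5.0, null) == 0.0
        assert 0.45 < quantile_rank(49.5, null) < 0.55
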