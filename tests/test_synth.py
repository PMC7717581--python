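"""Synthetic-data generator: founders, swarm propagation, genotypes, phenotypes, panels."""

import numpy as np
import pandas as pd
import pytest

import swarmscan as sw
from swarmscan.genome import DEFAULT_GENOME
from swarmscan.synth import (
    EnvDesign,
    PhenoModel,
    RecombinationModel,
    UNKNOWN,
    derive_genotypes,
    simulate_founders,
    simulate_frequency_panels,
    simulate_phenotypes,
    simulate_swarm,
)


class TestFounders:
    def test_line_counts_and_balanced_collections(self):
        fp = simulate_founders(34, n_collections=7, sites=50, seed=0)
        assert fp.n_lines == 68
        counts = fp.lines.groupby("population").size()
        assert counts["A"] == counts["B"] == 34
        # collections represented equally in both populations
        tab = fp.lines.groupby(["population", "collection"]).size().unstack()
        assert (tab.loc["A"] == tab.loc["B"]).all()

    def test_monomorphic_panel_when_alt_frequency_fixed_at_one(self):
        fp = simulate_founders(4, sites=30, freq_model=("fixed", 1.0), het_rate=0.0, seed=0)
        assert (fp.haplotypes == 1).all()

    def test_haplotypes_identical_except_at_het_sites(self):
        fp = simulate_founders(6, sites=300, het_rate=0.1, seed=3)
        same = fp.haplotypes[:, 0, :] == fp.haplotypes[:, 1, :]
        assert (same == ~fp.het_mask).all()
        # at het sites the two haplotypes carry one ref and one alt
        li, si = np.nonzero(fp.het_mask)
        assert (fp.haplotypes[li, 0, si] + fp.haplotypes[li, 1, si] == 1).all()

    def test_seed_reproducibility(self):
        a = simulate_founders(5, sites=100, seed=9)
        b = simulate_founders(5, sites=100, seed=9)
        c = simulate_founders(5, sites=100, seed=10)
        assert (a.haplotypes == b.haplotypes).all() and (a.het_mask == b.het_mask).all()
        assert (a.haplotypes != c.haplotypes).any()

    @pytest.mark.parametrize(
        "kwargs", [{"sites": 0}, {"het_rate": -0.1}, {"het_rate": 1.5}]
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_founders(4, **{"sites": 20, **kwargs})


def _assert_tiling(mosaic):
    for arm_name, haps in mosaic.haplotypes.items():
        arm = DEFAULT_GENOME.arm(arm_name)
        for hap in haps:
            assert hap[0][0] == 1 and hap[-1][1] == arm.length_bp
            for (s1, e1, f1), (s2, e2, f2) in zip(hap, hap[1:]):
                assert e1 + 1 == s2, "gap or overlap"
                assert f1 != f2, "unmerged adjacent same-founder segments"
            assert all(s <= e for s, e, _ in hap)


class TestSwarm:
    def test_segments_tile_every_arm(self, small_swarm):
        for mos in small_swarm:
            _assert_tiling(mos)

    def test_zero_map_gives_intact_founder_chromosomes(self, small_panel):
        recomb = RecombinationModel(
            genome=small_panel.genome,
            genetic_lengths={a: 0.0 for a in small_panel.genome.arm_names},
        )
        mos = simulate_swarm(
            small_panel, recomb=recomb, generations=5, census=80, n_sample=20, seed=1, population="A"
        )
        for m in mos:
            for haps in m.haplotypes.values():
                for hap in haps:
                    assert len(hap) == 1

    def test_breakpoint_count_matches_female_only_poisson_expectation(self, small_panel):
        # F4, 0.5 M arms: E[breaks per haploid arm] = 3 meioses * 0.5 M * 1/2
        recomb = RecombinationModel(
            genome=small_panel.genome,
            genetic_lengths={a: 0.5 for a in small_panel.genome.arm_names},
        )
        mos = simulate_swarm(
            small_panel, recomb=recomb, generations=4, census=1400, n_sample=550, seed=5, population="B"
        )
        counts = [len(h) - 1 for m in mos for arm in ("2L", "2R", "3L", "3R") for h in m.haplotypes[arm]]
        expected = 3 * 0.5 * 0.5
        se = np.std(counts) / np.sqrt(len(counts))
        assert len(counts) >= 2000
        # founder coalescence hides a small fraction of junctions, so allow a
        # one-sided margin below the analytic mean as well as 3 SE noise
        assert expected - 3 * se - 0.05 < np.mean(counts) < expected + 3 * se

    def test_mean_founder_contribution_near_reciprocal_of_line_count(self, small_swarm, small_panel):
        contrib = sw.mosaic_qc.founder_contributions(small_swarm, n_founders=small_panel.n_lines)
        line_idx = small_panel.line_indices("A")
        means = contrib[list(line_idx)].mean(axis=0)
        assert abs(means.sum() + contrib["UNKNOWN"].mean() - 1) < 1e-9
        assert np.allclose(means.mean(), 1 / len(line_idx), atol=1e-9)

    def test_mixed_population_panel_requires_explicit_population(self, small_panel):
        with pytest.raises(ValueError, match="population"):
            simulate_swarm(small_panel, generations=4, census=50, n_sample=10, seed=0)

    @pytest.mark.parametrize("kwargs", [{"generations": 1}, {"census": 1}, {"census": 5, "n_sample": 10}])
    def test_invalid_swarm_parameters(self, small_panel, kwargs):
        with pytest.raises(ValueError):
            simulate_swarm(
                small_panel,
                population="A",
                **{"generations": 4, "census": 50, "n_sample": 10, **kwargs},
            )


class TestDeriveGenotypes:
    def test_homogeneous_mosaic_doubles_founder_haplotype(self, small_panel):
        line = 2
        mos = sw.synth.MosaicGenome(
            individual_id="hom",
            generation=5,
            population="A",
            sex="F",
            haplotypes={
                a.name: [[(1, a.length_bp, line)], [(1, a.length_bp, line)]]
                for a in small_panel.genome.arms
            },
        )
        gm = derive_genotypes([mos], small_panel)
        het = small_panel.het_mask[line]
        expected = 2 * small_panel.haplotypes[line, 0, :]
        assert (gm.dosage[0, ~het] == expected[~het]).all()
        assert (gm.dosage[0, het] == -1).all()

    def test_dosages_match_brute_force_segment_scan(self, small_panel, small_swarm, swarm_genotypes):
        sites = small_panel.sites
        for i in [0, 7, 23]:
            mos = small_swarm[i]
            for j in range(0, small_panel.n_sites, 17):
                arm, pos = sites["chrom"].iloc[j], sites["pos"].iloc[j]
                alleles = []
                het = False
                unknown = False
                for hap in mos.haplotypes[arm]:
                    for s, e, f in hap:
                        if s <= pos <= e:
                            if f == UNKNOWN:
                                unknown = True
                            elif small_panel.het_mask[f, j]:
                                het = True
                            else:
                                alleles.append(small_panel.haplotypes[f, 0, j])
                            break
                expected = -1 if (het or unknown) else sum(alleles)
                assert swarm_genotypes.dosage[i, j] == expected

    def test_het_masked_founder_site_is_missing(self, small_panel):
        li, si = np.nonzero(small_panel.het_mask)
        line, site = int(li[0]), int(si[0])
        arm = small_panel.sites["chrom"].iloc[site]
        other = (line + 1) % small_panel.n_lines
        haps = {
            a.name: [[(1, a.length_bp, line)], [(1, a.length_bp, other)]]
            for a in small_panel.genome.arms
        }
        mos = sw.synth.MosaicGenome("x", 5, "A", "F", haps)
        gm = derive_genotypes([mos], small_panel)
        assert gm.dosage[0, site] == -1
        assert gm.het_count[0, site] >= 1


class TestDegrade:
    def test_zero_rate_is_identity(self, small_swarm):
        out = sw.synth.degrade_mosaics(small_swarm, spurious_rate=0.0, seed=1)
        assert all(a.haplotypes == b.haplotypes for a, b in zip(out, small_swarm))

    def test_seeded_reproducibility_and_short_excess(self, small_swarm):
        a = sw.synth.degrade_mosaics(small_swarm, spurious_rate=0.17, seed=5, n_founders=8)
        b = sw.synth.degrade_mosaics(small_swarm, spurious_rate=0.17, seed=5, n_founders=8)
        assert all(x.haplotypes == y.haplotypes for x, y in zip(a, b))
        truth_frac = sw.mosaic_qc.short_segment_fraction(small_swarm)
        degraded_frac = sw.mosaic_qc.short_segment_fraction(a)
        assert degraded_frac > truth_frac

    def test_degraded_mosaics_still_tile(self, small_swarm):
        for m in sw.synth.degrade_mosaics(small_swarm, spurious_rate=0.3, seed=2, n_founders=8):
            _assert_tiling(m)


class TestPhenotypes:
    def test_null_model_gives_half_incidence(self, two_pop_dataset):
        _, _, gm, _ = two_pop_dataset
        coef = PhenoModel(
            intercept=0.0, beta_temperature=0.0, beta_photoperiod=0.0,
            beta_generation=0.0, beta_population=0.0, beta_wolbachia=0.0, stage10_offset=0.0,
        )
        ph = simulate_phenotypes(gm, coef=coef, seed=123)
        n = len(ph)
        assert abs(ph["diapause8"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_closed_form_logistic_probability(self):
        # intercept 0, centred-temperature coefficient -1, +1 degree above the mean
        assert abs(1 / (1 + np.exp(1)) - 0.2689) < 5e-4
        design = EnvDesign(temperatures=(13.0, 15.0), photoperiods=(12.0,))
        coef = PhenoModel(
            intercept=0.0, beta_temperature=-1.0, beta_photoperiod=0.0,
            beta_generation=0.0, beta_population=0.0, beta_wolbachia=0.0,
        )
        from conftest import make_genotype_matrix

        gmat = make_genotype_matrix(np.zeros((6000, 3), dtype=np.int8))
        ph = simulate_phenotypes(gmat, env_design=design, coef=coef, seed=5)
        hot = ph[ph["temperature"] == 15.0]  # centred value +1
        p_emp = hot["diapause8"].mean()
        assert abs(p_emp - 0.2689) < 3 * np.sqrt(0.2689 * 0.7311 / len(hot))

    def test_incidence_decreases_with_temperature(self, two_pop_dataset):
        _, _, gm, pheno = two_pop_dataset
        by_temp = pheno.groupby("temperature")["diapause8"].mean()
        assert by_temp.iloc[0] > by_temp.iloc[-1]

    def test_stage8_diapause_subset_of_stage10(self, two_pop_dataset):
        _, _, _, pheno = two_pop_dataset
        assert (pheno["diapause8"] <= pheno["diapause10"]).all()

    def test_snp_effect_referencing_absent_site_rejected(self, two_pop_dataset):
        _, _, gm, _ = two_pop_dataset
        with pytest.raises(ValueError, match="absent site"):
            simulate_phenotypes(gm, coef=PhenoModel(snp_effects={10**6: 1.0}), seed=0)


class TestFrequencyPanels:
    snps = pd.DataFrame({"chrom": ["2L"] * 4, "pos": [100, 200, 300, 400]})

    def test_flat_panel_without_signal_or_noise(self):
        panel = simulate_frequency_panels(
            self.snps, clinal_slope=0.0, seasonal_delta=0.0,
            base_freq=("fixed", 0.4), noise=False, seed=0,
        )
        non_og = panel.dropna(subset=["latitude"])
        assert np.allclose(non_og["alt_freq"], 0.4)

    def test_closed_form_logistic_frequency(self):
        loc = [sw.synth.Locale("L40", 40.0)]
        panel = simulate_frequency_panels(
            self.snps, clinal_slope=0.1, base_freq=("fixed", 0.5), locales=loc, noise=False, seed=0
        )
        clinal = panel.dropna(subset=["latitude"])
        assert np.allclose(clinal["alt_freq"], 1 / (1 + np.exp(-4.0)), atol=1e-12)
        assert abs(clinal["alt_freq"].iloc[0] - 0.982) < 5e-4

    def test_default_geometry_spans_florida_to_maine(self):
        panel = simulate_frequency_panels(self.snps, seed=0)
        lats = panel.dropna(subset=["latitude"])["latitude"]
        assert panel.dropna(subset=["latitude"])["locale_id"].nunique() == 10
        assert lats.min() < 26 and lats.max() > 43
        assert set(panel.dropna(subset=["latitude"])["season"]) == {"spring", "fall"}
        assert (panel["locale_id"] == "ZI").any()

    def test_neff_bounded_by_chromosomes_sampled(self):
        neff = sw.synth.effective_allele_count(50, 100.0)
        assert neff <= 2 * 50 and neff <= 100
        assert abs(1 / neff - (1 / 100 + 1 / 100)) < 1e-12

    def test_noise_free_panel_inverts_to_generating_slope(self):
        slopes = np.array([0.05, -0.08, 0.0, 0.12])
        panel = simulate_frequency_panels(
            self.snps, clinal_slope=slopes, base_freq=("fixed", 0.45), noise=False, seed=0
        )
        est = sw.popgen.clinal_effects(panel).set_index("snp_id")
        key = self.snps["chrom"] + ":" + self.snps["pos"].astype(str)
        assert np.allclose(est.loc[key, "slope"].to_numpy(), slopes, atol=1e-6)
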