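import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovistep import (
    SimConfig,
    corrupt_pedigree,
    count_opposing_homozygotes,
    drop_genotypes,
    simulate_pedigree,
    simulate_scores,
    simulate_traits,
)
from ovistep.simulate import ConfigError
from ovistep.varcomp import VarianceComponents

SW = VarianceComponents(8.97, 18.58)


class TestConfig:
    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(missing_rate=1.5)

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(founder_maf_range=(0.0, 0.6))


class TestSimulatePedigree:
    def test_zero_generations_founders_only(self):
        ped = simulate_pedigree(SimConfig(n_founders=10, n_generations=0, n_flocks=1))
        assert ped.n == 10
        assert (ped.sire == -1).all() and (ped.dam == -1).all()

    def test_seed_determinism(self):
        cfg = SimConfig(n_founders=20, n_generations=3, n_flocks=2, seed=42)
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert p1.ids == p2.ids
        assert (p1.sire == p2.sire).all() and (p1.dam == p2.dam).all()

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_topological_order_and_sex_consistency(self, seed):
        cfg = SimConfig(n_founders=60, n_generations=3, n_flocks=3, seed=seed)
        ped = simulate_pedigree(cfg)
        for i in range(ped.n):
            for p, want in ((ped.sire[i], "M"), (ped.dam[i], "F")):
                if p >= 0:
                    assert p < i
                    assert ped.sex[p] == want
        assert len(set(ped.flock)) == 3
        assert ped.birth_year.max() == cfg.base_year + 3


class TestDropGenotypes:
    def test_forced_transmission(self):
        # both parents homozygous 0 at every SNP -> offspring must be 0
        cfg = SimConfig(n_founders=2, n_generations=1, n_flocks=1, dams_per_sire=1,
                        progeny_per_dam=1, n_snps=50, seed=3,
                        genotyping_error_rate=0.0, missing_rate=0.0,
                        founder_maf_range=(1e-9, 1e-9))
        with pytest.raises(ConfigError):
            SimConfig(founder_maf_range=(0.0, 0.0))
        ped = simulate_pedigree(cfg)
        panel = drop_genotypes(ped, cfg, all_animals=True)
        # founder freq ~0 => everyone homozygous 0
        assert (panel.calls == 0).all()

    def test_mendelian_consistency_zero_oh(self):
        cfg = SimConfig(n_founders=40, n_generations=2, n_flocks=2, seed=8, n_snps=300,
                        genotyping_error_rate=0.0, missing_rate=0.0)
        ped = simulate_pedigree(cfg)
        panel = drop_genotypes(ped, cfg, all_animals=True)
        for i in range(ped.n):
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    n_opp, _, rate = count_opposing_homozygotes(
                        panel.calls[i], panel.calls[p]
                    )
                    assert n_opp == 0

    def test_founder_frequency_recovered(self):
        cfg = SimConfig(n_founders=4000, n_generations=0, n_flocks=1, seed=10,
                        n_snps=5, genotyping_error_rate=0.0, missing_rate=0.0,
                        founder_maf_range=(0.3, 0.3))
        ped = simulate_pedigree(cfg)
        panel = drop_genotypes(ped, cfg, all_animals=True)
        p_hat = panel.calls.mean(axis=0) / 2.0
        se = math.sqrt(0.3 * 0.7 / (2 * 4000))
        assert np.all(np.abs(p_hat - 0.3) < 3 * se)

    def test_noise_rates_applied(self):
        cfg = SimConfig(n_founders=300, n_generations=0, n_flocks=1, seed=10,
                        n_snps=400, genotyping_error_rate=0.0, missing_rate=0.1)
        ped = simulate_pedigree(cfg)
        panel = drop_genotypes(ped, cfg, all_animals=True)
        miss = (panel.calls == -1).mean()
        assert abs(miss - 0.1) < 0.01


class TestSimulateTraits:
    def test_degenerate_components_residual_only(self):
        cfg = SimConfig(n_founders=800, n_generations=0, n_flocks=1, seed=2,
                        prop_phenotyped=1.0, young_phenotyped_factor=1.0,
                        fixed_effect_sd=0.0,
                        trait_components={"t": VarianceComponents(0.0, 4.0)})
        ped = simulate_pedigree(cfg)
        phen, truth = simulate_traits(ped, cfg, traits=["t"])
        v = phen["value"].var()
        assert abs(v - 4.0) < 0.6  # sampling error at n=800
        assert (truth.breeding["t"] == 0).all()

    def test_founder_bv_variance_matches_sigma2a(self):
        cfg = SimConfig(n_founders=600, n_generations=0, n_flocks=1, seed=6,
                        n_snps=400, trait_components={"swt": SW})
        ped = simulate_pedigree(cfg)
        _, truth = simulate_traits(ped, cfg)
        v = truth.breeding["swt"].var()
        n = ped.n
        lo = SW.sigma2_a * stats.chi2.ppf(0.025, n - 1) / (n - 1)
        hi = SW.sigma2_a * stats.chi2.ppf(0.975, n - 1) / (n - 1)
        assert lo < v < hi

    def test_h2_structure_at_scan_weight_truth(self):
        cfg = SimConfig(n_founders=2500, n_generations=1, n_flocks=2, seed=12,
                        prop_phenotyped=1.0, young_phenotyped_factor=1.0,
                        fixed_effect_sd=0.0, trait_components={"swt": SW})
        ped = simulate_pedigree(cfg)
        phen, truth = simulate_traits(ped, cfg)
        assert len(phen) >= 3000
        a = truth.breeding["swt"].reindex(phen["animal"]).to_numpy()
        resid = phen["value"].to_numpy() - phen["value"].mean()
        h2_hat = np.cov(a, resid)[0, 1] / np.var(resid)
        assert abs(h2_hat - 0.33) < 0.04

    def test_midparent_regression_near_one(self):
        cfg = SimConfig(n_founders=400, n_generations=2, n_flocks=2, seed=14,
                        n_snps=600, trait_components={"swt": SW})
        ped = simulate_pedigree(cfg)
        _, truth = simulate_traits(ped, cfg)
        bv = truth.breeding["swt"].to_numpy()
        both = (ped.sire >= 0) & (ped.dam >= 0)
        mid = 0.5 * (bv[ped.sire[both]] + bv[ped.dam[both]])
        slope = np.cov(bv[both], mid)[0, 1] / np.var(mid)
        assert abs(slope - 1.0) < 0.15

    def test_missing_components_raise(self):
        cfg = SimConfig(n_founders=10, n_generations=0, n_flocks=1)
        ped = simulate_pedigree(cfg)
        with pytest.raises(ConfigError):
            simulate_traits(ped, cfg, traits=["mystery"])

    def test_determinism(self):
        cfg = SimConfig(n_founders=50, n_generations=2, n_flocks=2, seed=4,
                        trait_components={"swt": SW})
        ped = simulate_pedigree(cfg)
        p1, _ = simulate_traits(ped, cfg)
        p2, _ = simulate_traits(ped, cfg)
        pd.testing.assert_frame_equal(p1, p2)


@pytest.fixture(scope="module")
def score_data():
    cfg = SimConfig(n_founders=120, n_generations=2, n_flocks=2, seed=9,
                    trait_components={"footrot": VarianceComponents(0.04, 0.28)})
    ped = simulate_pedigree(cfg)
    return simulate_scores(ped, "footrot", cfg)


class TestSimulateScores:
    def test_transform_is_invertible(self, score_data):
        scores, _ = score_data
        sites = scores[["site1", "site2", "site3", "site4"]]
        assert sites.min().min() >= 0 and sites.max().max() <= 4
        np.testing.assert_allclose(np.log1p(sites.sum(axis=1)), scores["value"])

    def test_visit_counts_in_range(self, score_data):
        scores, _ = score_data
        visits = scores.groupby("animal")["visit"].max()
        assert visits.between(1, 5).all()

    def test_repeat_records_share_animal_effects(self, score_data):
        scores, truth = score_data
        # all visits of one ewe reference the same true breeding value
        assert truth.breeding["footrot"].index.is_unique

    def test_non_health_trait_rejected(self):
        cfg = SimConfig(trait_components={"swt": SW})
        ped = simulate_pedigree(SimConfig(n_founders=10, n_generations=0, n_flocks=1))
        with pytest.raises(ConfigError):
            simulate_scores(ped, "swt", cfg)


@pytest.fixture(scope="module")
def flock():
    cfg = SimConfig(n_founders=150, n_generations=3, n_flocks=3, seed=13,
                    n_snps=600, prop_genotyped=0.6,
                    genotyping_error_rate=0.0, missing_rate=0.0,
                    trait_components={"swt": SW})
    ped = simulate_pedigree(cfg)
    return ped, drop_genotypes(ped, cfg)


class TestCorruptPedigree:
    def test_rate_zero_no_change(self, flock):
        ped, panel = flock
        new_ped, planted = corrupt_pedigree(ped, panel, 0.0, seed=1)
        assert planted == []
        assert (new_ped.sire == ped.sire).all() and (new_ped.dam == ped.dam).all()

    def test_planted_count_binomial(self, flock):
        ped, panel = flock
        _, planted = corrupt_pedigree(ped, panel, 0.05, seed=2)
        n = panel.n_samples
        sd = math.sqrt(n * 0.05 * 0.95)
        assert abs(len(planted) - 0.05 * n) < 4 * sd

    def test_planted_errors_show_high_oh_rates(self, flock):
        ped, panel = flock
        bad, planted = corrupt_pedigree(ped, panel, 0.08, seed=3)
        idx = {a: i for i, a in enumerate(panel.animal_ids)}
        checked = 0
        for rec in planted:
            if rec["wrong_parent"] in idx:
                _, _, rate = count_opposing_homozygotes(
                    panel.calls[idx[rec["animal"]]], panel.calls[idx[rec["wrong_parent"]]]
                )
                assert rate > 0.01
                checked += 1
        assert checked >= 3
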