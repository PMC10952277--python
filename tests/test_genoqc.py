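import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ovistep import SimConfig, corrupt_pedigree, drop_genotypes, simulate_pedigree
from ovistep.genoqc import (
    DuplicateConflictError,
    DuplicateSample,
    GenotypePanel,
    PanelError,
    count_opposing_homozygotes,
    filter_samples_by_call_rate,
    filter_snps,
    hwe_chi2_pvalues,
    intersect_snps,
    resolve_duplicate_samples,
    verify_and_discover_parentage,
)


def make_panel(calls, labels=None, snp_meta=None, prefix="S"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypePanel(
        [f"{prefix}{i}" for i in range(n)],
        [f"snp{j}" for j in range(m)],
        calls,
        labels or ["50K"] * n,
        snp_meta,
    )


class TestSampleCallRate:
    def test_complete_sample_retained(self):
        panel = make_panel(np.ones((1, 100)))
        out, rep = filter_samples_by_call_rate(panel, 0.894)
        assert out.n_samples == 1 and not rep.samples_removed

    def test_11pct_missing_removed_at_default(self):
        calls = np.ones((1, 100), dtype=np.int8)
        calls[0, :11] = -1  # call rate 0.89 < 0.894
        out, rep = filter_samples_by_call_rate(make_panel(calls))
        assert out.n_samples == 0
        assert rep.samples_removed[0][0] == "S0"

    def test_survivors_match_direct_count(self):
        rng = np.random.default_rng(5)
        calls = np.ones((10, 200), dtype=np.int8)
        miss_frac = np.linspace(0, 0.3, 10)
        for i, f in enumerate(miss_frac):
            k = int(f * 200)
            calls[i, rng.choice(200, k, replace=False)] = -1
        panel = make_panel(calls)
        out, rep = filter_samples_by_call_rate(panel, 0.894)
        expected = {f"S{i}" for i in range(10) if (calls[i] >= 0).mean() >= 0.894}
        assert set(out.animal_ids) == expected
        assert len(rep.samples_removed) == 10 - len(expected)

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(8, 50)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.2] = -1
        once, _ = filter_samples_by_call_rate(make_panel(calls))
        twice, rep = filter_samples_by_call_rate(once)
        assert twice.animal_ids == once.animal_ids and not rep.samples_removed


class TestSnpFilters:
    def test_exact_hwe_retained(self):
        calls = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)])
        panel = make_panel(calls.reshape(-1, 1))
        out, rep = filter_snps(panel)
        assert out.n_snps == 1 and not rep.snps_removed

    def test_low_maf_removed(self):
        # 100 samples, 8 heterozygotes -> maf 0.04
        calls = np.zeros(100)
        calls[:8] = 1
        out, rep = filter_snps(make_panel(calls.reshape(-1, 1)))
        assert out.n_snps == 0
        assert rep.snps_removed[0][1] == "maf"

    def test_hwe_chi2_matches_textbook_formula(self):
        n0, n1, n2 = 40, 20, 40
        calls = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2)])
        pv = hwe_chi2_pvalues(calls.reshape(-1, 1).astype(np.int8))[0]
        n = n0 + n1 + n2
        p = (2 * n2 + n1) / (2 * n)
        e = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        chi2 = ((np.array([n0, n1, n2]) - e) ** 2 / e).sum()
        assert pv == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
        out, rep = filter_snps(make_panel(calls.reshape(-1, 1)))
        assert out.n_snps == 0 and rep.snps_removed[0][1] == "hwe"

    def test_removal_counts_reconcile(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.01, 0.5, 60)
        calls = rng.binomial(2, p, size=(150, 60)).astype(np.int8)
        panel = make_panel(calls)
        out, rep = filter_snps(panel)
        assert panel.n_snps - out.n_snps == len(rep.snps_removed)


class TestIntersectSnps:
    def test_identical_sets(self):
        a = make_panel(np.ones((2, 3)), prefix="A")
        b = make_panel(np.zeros((2, 3)), prefix="B")
        out = intersect_snps([a, b])
        assert out.snp_ids == a.snp_ids and out.n_samples == 4

    def test_partial_overlap(self):
        a = GenotypePanel(["x"], ["a", "b", "c"], np.ones((1, 3), dtype=np.int8), ["HD"])
        b = GenotypePanel(["y"], ["b", "c", "d"], np.ones((1, 3), dtype=np.int8), ["50K"])
        out = intersect_snps([a, b])
        assert out.snp_ids == ["b", "c"]

    def test_allele_flip_reconciled(self):
        from ovistep.genoqc import default_snp_meta

        meta_a = default_snp_meta(["s1"])
        meta_b = default_snp_meta(["s1"])
        meta_b.loc["s1", ["allele_a", "allele_b"]] = ["B", "A"]  # swapped
        a = GenotypePanel(["x"], ["s1"], np.array([[2]], dtype=np.int8), ["HD"], meta_a)
        b = GenotypePanel(["y"], ["s1"], np.array([[0]], dtype=np.int8), ["50K"], meta_b)
        out = intersect_snps([a, b])
        assert out.calls[0, 0] == 2 and out.calls[1, 0] == 2

    def test_random_masks_match_set_intersection(self):
        rng = np.random.default_rng(8)
        all_snps = [f"snp{j}" for j in range(300)]
        panels = []
        kept_sets = []
        for k in range(4):
            keep = sorted(rng.choice(300, 200, replace=False))
            snps = [all_snps[j] for j in keep]
            kept_sets.append(set(snps))
            panels.append(GenotypePanel(
                [f"P{k}_{i}" for i in range(3)], snps,
                rng.integers(0, 3, size=(3, 200)).astype(np.int8),
                ["LDv1"] * 3,
            ))
        out = intersect_snps(panels)
        assert set(out.snp_ids) == set.intersection(*kept_sets)


class TestOpposingHomozygotes:
    def test_identical_vectors_zero(self):
        g = np.array([0, 1, 2, 2, 0], dtype=np.int8)
        n_opp, n_comp, rate = count_opposing_homozygotes(g, g)
        assert n_opp == 0 and n_comp == 5 and rate == 0.0

    def test_fully_opposing(self):
        g1 = np.zeros(50, dtype=np.int8)
        g2 = np.full(50, 2, dtype=np.int8)
        n_opp, n_comp, rate = count_opposing_homozygotes(g1, g2)
        assert (n_opp, n_comp, rate) == (50, 50, 1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(PanelError):
            count_opposing_homozygotes(np.zeros(3, dtype=np.int8), np.zeros(4, dtype=np.int8))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.choice([-1, 0, 1, 2], 200).astype(np.int8)
        g2 = rng.choice([-1, 0, 1, 2], 200).astype(np.int8)
        n_opp = n_comp = 0
        for a, b in zip(g1, g2):
            if a >= 0 and b >= 0:
                n_comp += 1
                if {a, b} == {0, 2}:
                    n_opp += 1
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = count_opposing_homozygotes(g1, g2)
        assert got[0] == n_opp and got[1] == n_comp


@pytest.fixture(scope="module")
def qc_flock():
    cfg = SimConfig(n_founders=150, n_generations=3, n_flocks=3, seed=13,
                    n_snps=600, prop_genotyped=0.6,
                    genotyping_error_rate=0.0, missing_rate=0.0)
    ped = simulate_pedigree(cfg)
    return ped, drop_genotypes(ped, cfg)


class TestParentageVerification:
    def test_clean_pedigree_unchanged(self, qc_flock):
        ped, panel = qc_flock
        new_ped, rep = verify_and_discover_parentage(panel, ped)
        assert not rep.parentage_changes
        assert (new_ped.sire == ped.sire).all() and (new_ped.dam == ped.dam).all()

    def test_planted_errors_detected_and_recovered(self, qc_flock):
        ped, panel = qc_flock
        bad, planted = corrupt_pedigree(ped, panel, 0.06, seed=44)
        fixed, rep = verify_and_discover_parentage(panel, bad)
        planted_keys = {(p["animal"], p["slot"]): p for p in planted}
        detected = {(c[0], c[1]): c for c in rep.parentage_changes}
        recall = len(planted_keys.keys() & detected.keys()) / len(planted_keys)
        assert recall >= 0.95
        # no correct parents rejected
        assert not (detected.keys() - planted_keys.keys())
        # genotyped true parents recovered by discovery
        for key, p in planted_keys.items():
            if key in detected and p["true_parent_genotyped"]:
                assert detected[key][3] == p["true_parent"]

    def test_ungenotyped_animals_untouched(self, qc_flock):
        ped, panel = qc_flock
        genotyped = set(panel.animal_ids)
        bad, _ = corrupt_pedigree(ped, panel, 0.1, seed=45)
        fixed, rep = verify_and_discover_parentage(panel, bad)
        for a in ped.ids:
            if a not in genotyped:
                i = ped.index[a]
                assert fixed.sire[i] == bad.sire[i] and fixed.dam[i] == bad.dam[i]

    def test_unrecoverable_wrong_parent_set_unknown(self):
        # animal + wrong recorded sire genotyped, true sire not genotyped
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.5, 400)
        sire_t = rng.binomial(2, p).astype(np.int8)
        dam_t = rng.binomial(2, p).astype(np.int8)
        child = ((rng.random(400) < sire_t / 2) + (rng.random(400) < dam_t / 2)).astype(np.int8)
        stranger = rng.binomial(2, p).astype(np.int8)
        from ovistep.pedigree import sort_and_validate

        ped = sort_and_validate([
            ("true_sire", "0", "0", "M", "F1", 2000),
            ("stranger", "0", "0", "M", "F1", 2000),
            ("dam", "0", "0", "F", "F1", 2000),
            ("kid", "stranger", "dam", "F", "F1", 2002),
        ])
        panel = GenotypePanel(
            ["stranger", "dam", "kid"], [f"s{j}" for j in range(400)],
            np.vstack([stranger, dam_t, child]), ["50K"] * 3,
        )
        fixed, rep = verify_and_discover_parentage(panel, ped)
        assert fixed.sire[fixed.index["kid"]] == -1
        (animal, slot, old, new, rate) = rep.parentage_changes[0]
        assert (animal, slot, old, new) == ("kid", "sire", "stranger", "0")
        assert rate > 0.01


class TestDuplicateResolution:
    def _sample(self, label, ok=True, calls=None, key=""):
        if calls is None:
            calls = np.array([0, 1, 2, 1], dtype=np.int8)
        return DuplicateSample(calls=calls, array_label=label, parentage_ok=ok, key=key)

    def test_single_sample_returned(self):
        s = self._sample("LDv1")
        assert resolve_duplicate_samples([s]) is s

    def test_concordant_pair_prefers_50k(self):
        hd, fifty = self._sample("HD"), self._sample("50K")
        assert resolve_duplicate_samples([hd, fifty]) is fifty

    def test_priority_order_over_all_arrays(self):
        samples = [self._sample(lbl) for lbl in ("LDv1", "LDv2", "HD", "50K")]
        assert resolve_duplicate_samples(samples).array_label == "50K"

    def test_only_parentage_passing_sample_kept(self):
        ldv1 = self._sample("LDv1", ok=True)
        ldv2 = self._sample("LDv2", ok=False)
        assert resolve_duplicate_samples([ldv1, ldv2]) is ldv1

    def test_discordant_passing_pair_raises(self):
        a = self._sample("HD", calls=np.array([0, 1, 2, 1], dtype=np.int8), key="a")
        b = self._sample("50K", calls=np.array([2, 1, 2, 1], dtype=np.int8), key="b")
        with pytest.raises(DuplicateConflictError):
            resolve_duplicate_samples([a, b])

    def test_missing_calls_do_not_count_as_discordance(self):
        a = self._sample("HD", calls=np.array([-1, 1, 2, 1], dtype=np.int8))
        b = self._sample("50K", calls=np.array([0, 1, -1, 1], dtype=np.int8))
        assert resolve_duplicate_samples([a, b]).array_label == "50K"
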