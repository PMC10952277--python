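import numpy as np
import pandas as pd
import pytest

from ovistep import SimConfig, drop_genotypes, simulate_pedigree
from ovistep.genoqc import GenotypePanel
from ovistep.grm import (
    GenomicRelationship,
    GrmError,
    allele_frequencies,
    blend_with_pedigree,
    build_h_inverse,
    genomic_relationship_vanraden1,
    h_inverse_terms,
    principal_components,
    tune_to_pedigree,
)
from ovistep.pedigree import a_inverse, relationship_submatrix, sort_and_validate


def make_panel(calls, prefix="S"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypePanel([f"{prefix}{i}" for i in range(n)],
                         [f"snp{j}" for j in range(m)], calls, ["50K"] * n)


class TestAlleleFrequencies:
    def test_simple_tally(self):
        panel = make_panel([[0], [1], [2]])
        assert allele_frequencies(panel)["snp0"] == pytest.approx(0.5)

    def test_monomorphic_zero(self):
        panel = make_panel([[0], [0], [0]])
        assert allele_frequencies(panel)["snp0"] == 0.0

    def test_matches_bruteforce_with_missing(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([-1, 0, 1, 2], size=(30, 40)).astype(np.int8)
        freqs = allele_frequencies(make_panel(calls))
        for j in range(40):
            col = calls[:, j]
            obs = col[col >= 0]
            assert freqs.iloc[j] == pytest.approx(obs.sum() / (2 * len(obs)))


class TestVanRaden1:
    def test_identical_animals_equal_entries(self):
        rng = np.random.default_rng(4)
        row = rng.integers(0, 3, 50).astype(np.int8)
        panel = make_panel(np.vstack([row, row]))
        G = genomic_relationship_vanraden1(panel)
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])
        assert G.values[0, 0] == pytest.approx(G.values[1, 1])

    def test_matches_explicit_matrix_arithmetic(self):
        # 5 animals x 10 SNPs with small integer calls; independent brute force
        calls = np.array([
            [0, 1, 2, 0, 1, 2, 1, 0, 2, 1],
            [1, 1, 0, 0, 2, 2, 0, 0, 1, 1],
            [2, 0, 1, 1, 1, 0, 2, 1, 0, 0],
            [0, 0, 0, 2, 2, 1, 1, 2, 2, 0],
            [1, 2, 1, 1, 0, 0, 0, 1, 1, 2],
        ], dtype=np.int8)
        panel = make_panel(calls)
        p = calls.mean(axis=0) / 2.0
        Z = calls - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        G = genomic_relationship_vanraden1(panel)
        np.testing.assert_allclose(G.values, expected, atol=1e-12)

    def test_founder_panel_mean_diag_near_one(self):
        cfg = SimConfig(n_founders=1000, n_generations=0, n_flocks=1, seed=17,
                        n_snps=800, genotyping_error_rate=0.0, missing_rate=0.0)
        ped = simulate_pedigree(cfg)
        panel = drop_genotypes(ped, cfg, all_animals=True)
        G = genomic_relationship_vanraden1(panel)
        assert abs(np.diag(G.values).mean() - 1.0) < 0.05

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(GrmError):
            genomic_relationship_vanraden1(make_panel(np.zeros((3, 5))))

    def test_invariant_to_row_and_column_permutation(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        G = genomic_relationship_vanraden1(make_panel(calls))
        rp = rng.permutation(8)
        cp = rng.permutation(60)
        G2 = genomic_relationship_vanraden1(make_panel(calls[np.ix_(rp, cp)]))
        np.testing.assert_allclose(G2.values, G.values[np.ix_(rp, rp)], atol=1e-12)

    def test_parent_offspring_near_half(self):
        cfg = SimConfig(n_founders=300, n_generations=1, n_flocks=1, dams_per_sire=5,
                        seed=19, n_snps=2000, genotyping_error_rate=0.0,
                        missing_rate=0.0)
        ped = simulate_pedigree(cfg)
        panel = drop_genotypes(ped, cfg, all_animals=True)
        G = tune_to_pedigree(
            genomic_relationship_vanraden1(panel),
            relationship_submatrix(ped, panel.animal_ids),
        )
        vals = [G.values[i, ped.sire[i]] for i in range(ped.n) if ped.sire[i] >= 0]
        assert len(vals) >= 100
        assert abs(np.mean(vals) - 0.5) < 0.05


class TestBlend:
    def test_weight_one_unchanged(self):
        G = GenomicRelationship(["a", "b"], np.eye(2), pd.Series(dtype=float))
        out = blend_with_pedigree(G, np.full((2, 2), 0.5), 1.0)
        np.testing.assert_allclose(out.values, np.eye(2))

    def test_convex_combination_elementwise(self):
        G = GenomicRelationship(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.1]]),
                                pd.Series(dtype=float))
        A22 = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = blend_with_pedigree(G, A22, 0.95)
        np.testing.assert_allclose(out.values, 0.95 * G.values + 0.05 * A22)

    def test_monotone_in_weight(self):
        G = GenomicRelationship(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]),
                                pd.Series(dtype=float))
        A22 = np.array([[1.2, 0.6], [0.6, 1.2]])
        prev = blend_with_pedigree(G, A22, 0.2).values
        for w in (0.5, 0.8):
            cur = blend_with_pedigree(G, A22, w).values
            assert ((cur - prev) * (G.values - A22) >= -1e-12).all()
            prev = cur

    def test_singular_g_becomes_positive_definite(self):
        row = np.ones(30, dtype=np.int8)
        rng = np.random.default_rng(2)
        calls = np.vstack([rng.integers(0, 3, 30), row, row]).astype(np.int8)
        G = genomic_relationship_vanraden1(make_panel(calls))
        assert np.linalg.eigvalsh(G.values).min() < 1e-10
        A22 = np.eye(3)
        out = blend_with_pedigree(G, A22, 0.95)
        assert np.linalg.eigvalsh(out.values).min() > 0


class TestHInverse:
    def _trio(self):
        return sort_and_validate([("s", "0", "0"), ("d", "0", "0"), ("x", "s", "d")])

    def test_degenerate_equality_gives_zero_correction(self):
        ped = self._trio()
        A22 = relationship_submatrix(ped, ["s", "x"])
        G = GenomicRelationship(["s", "x"], A22.copy(), pd.Series(dtype=float))
        delta = h_inverse_terms(G, A22)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)
        H = build_h_inverse(a_inverse(ped), delta, np.array([0, 2]))
        np.testing.assert_allclose(H.toarray(), a_inverse(ped).toarray(), atol=1e-12)

    def test_three_animal_direct_inversion_oracle(self):
        A22 = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        Gv = np.array([[1.05, 0.45, 0.30], [0.45, 0.98, 0.52], [0.30, 0.52, 1.02]])
        G = GenomicRelationship(["a", "b", "c"], Gv, pd.Series(dtype=float))
        delta = h_inverse_terms(G, A22)
        np.testing.assert_allclose(delta, np.linalg.inv(Gv) - np.linalg.inv(A22))

    def test_h_from_h_inverse_is_spd(self, small_sim):
        cfg, ped, panel, phen, truth = small_sim
        ids = panel.animal_ids[:50]
        sub = panel.subset(sample_idx=np.arange(50))
        A22 = relationship_submatrix(ped, ids)
        G = tune_to_pedigree(genomic_relationship_vanraden1(sub), A22)
        Gb = blend_with_pedigree(G, A22, 0.95)
        delta = h_inverse_terms(Gb, A22)
        closure_ped_ids = ids
        # H^-1 over the genotyped subset's ancestor-closed pedigree
        from ovistep.pedigree import ancestor_closure, subset_pedigree

        closure = ancestor_closure(ped, [ped.index[a] for a in ids])
        sped = subset_pedigree(ped, closure)
        Hinv = build_h_inverse(
            a_inverse(sped), delta, np.array([sped.index[a] for a in ids])
        ).toarray()
        H = np.linalg.inv(Hinv)
        np.testing.assert_allclose(H, H.T, atol=1e-8)
        assert np.linalg.eigvalsh(H).min() > 0


class TestPCA:
    def test_identical_animals_flagged(self):
        panel = make_panel(np.ones((4, 20)))
        with pytest.warns(UserWarning):
            scores, fr = principal_components(panel, 2)
        assert (fr == 0).all()

    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(11)
        a = rng.binomial(2, 0.1, size=(40, 300)).astype(np.int8)
        b = rng.binomial(2, 0.9, size=(40, 300)).astype(np.int8)
        panel = make_panel(np.vstack([a, b]))
        scores, fr = principal_components(panel, 2)
        group = np.array([0] * 40 + [1] * 40)
        r = np.corrcoef(scores[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_variance_fractions_monotone_and_bounded(self):
        rng = np.random.default_rng(12)
        panel = make_panel(rng.integers(0, 3, size=(30, 100)).astype(np.int8))
        _, fr = principal_components(panel, 5)
        assert (np.diff(fr) <= 1e-12).all()
        assert fr.sum() <= 1.0 + 1e-12

    def test_k_beyond_rank_truncated(self):
        rng = np.random.default_rng(13)
        panel = make_panel(rng.integers(0, 3, size=(3, 50)).astype(np.int8))
        with pytest.warns(UserWarning):
            scores, fr = principal_components(panel, 10)
        assert scores.shape[1] <= 3
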