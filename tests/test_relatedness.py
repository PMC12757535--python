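"""KING kinship, IBS distances, neighbor joining and PCA."""

import io

import numpy as np
import pandas as pd
import pytest

from smallpop.relatedness import (
    ibs_distance,
    king_kinship,
    kinship_category,
    nj_tree,
    pca,
)
from smallpop.simulate import (
    SimulationScenario,
    plant_relative_pair,
    random_hwe_cohort,
    simulate_cohort,
)

from .conftest import make_matrix


class TestKingKinship:
    def test_duplicated_sample_is_monozygotic(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 2, size=(500, 1, 2)).astype(np.int8)
        gt = np.concatenate([gt, gt], axis=1)
        g = make_matrix(gt)
        k = king_kinship(g)
        assert k.phi.iloc[0] == pytest.approx(0.5)
        assert k.category.iloc[0] == "monozygotic"

    def test_unrelated_pair_near_zero(self):
        # 20 replicates of an HWE-independent pair at 10k SNPs: the
        # mean phi is within 0.02 of zero and no replicate strays far
        phis = []
        for rep in range(20):
            g = random_hwe_cohort(2, 5000, seed=rep)
            phis.append(king_kinship(g).phi.iloc[0])
        assert abs(np.mean(phis)) < 0.02
        assert np.max(np.abs(phis)) < 0.05

    def test_no_informative_sites_flagged(self):
        gt = np.zeros((50, 2, 2), dtype=np.int8)  # all hom-ref
        g = make_matrix(gt)
        k = king_kinship(g)
        assert np.isnan(k.phi.iloc[0])
        assert k.category.iloc[0] == "undefined"

    @pytest.mark.parametrize(
        "degree,expected_cat,min_ok",
        [
            ("parent-offspring", "first", 19),
            ("second", "second", 19),
            ("unrelated", "unrelated", 19),
            ("monozygotic", "monozygotic", 19),
        ],
    )
    def test_planted_pedigree_band_classification(self, degree,
                                                  expected_cat, min_ok):
        base = random_hwe_cohort(20, 5000, seed=3)
        ok = 0
        for rep in range(20):
            gp, _ = plant_relative_pair(base, degree, seed=rep,
                                        recomb_rate=3e-6)
            sub = gp.take_samples([gp.n_samples - 2, gp.n_samples - 1])
            k = king_kinship(sub)
            ok += k.category.iloc[0] == expected_cat
        assert ok >= min_ok

    def test_third_degree_mean_recovers_expectation(self):
        base = random_hwe_cohort(20, 5000, seed=3)
        phis = []
        for rep in range(20):
            gp, tt = plant_relative_pair(base, "third", seed=rep,
                                         recomb_rate=3e-6)
            sub = gp.take_samples([gp.n_samples - 2, gp.n_samples - 1])
            phis.append(king_kinship(sub).phi.iloc[0])
        assert np.mean(phis) == pytest.approx(0.0625, abs=0.02)

    def test_band_edges(self):
        assert kinship_category(0.40) == "monozygotic"
        assert kinship_category(0.25) == "first"
        assert kinship_category(0.125) == "second"
        assert kinship_category(0.0625) == "third"
        assert kinship_category(0.01) == "unrelated"


class TestIbsDistance:
    def test_identical_and_opposite(self):
        gt = np.zeros((10, 3, 2), dtype=np.int8)
        gt[:, 1] = 0  # identical to s0
        gt[:, 2] = 1  # opposite homozygote at every site
        g = make_matrix(gt)
        d = ibs_distance(g)
        assert d.loc["s0", "s1"] == 0.0
        assert d.loc["s0", "s2"] == 1.0

    def test_hand_computed_half_shares(self):
        # site 0: het vs hom (share 1/2); site 1: identical (share 1)
        gt = np.array(
            [[[0, 1], [0, 0]], [[1, 1], [1, 1]]], dtype=np.int8
        )
        g = make_matrix(gt)
        d = ibs_distance(g)
        assert d.loc["s0", "s1"] == pytest.approx(0.25)

    def test_symmetry_bounds_diagonal(self, small_cohort):
        g = small_cohort[0].take_samples(np.arange(12))
        d = ibs_distance(g).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


def _parse_newick_lengths(nwk):
    skbio = pytest.importorskip("skbio")
    return skbio.TreeNode.read(io.StringIO(nwk))


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree: (a:2, b:3)-5-(c:4, d:1) => additive distances
        d = {
            ("a", "b"): 5, ("a", "c"): 11, ("a", "d"): 8,
            ("b", "c"): 12, ("b", "d"): 9, ("c", "d"): 5,
        }
        labels = ["a", "b", "c", "d"]
        m = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    m[i, j] = m[j, i] = d[(x, y)]
        nwk = nj_tree(pd.DataFrame(m, index=labels, columns=labels))
        tree = _parse_newick_lengths(nwk)
        # patristic distances must reproduce the input exactly
        for (x, y), v in d.items():
            tx = tree.find(x)
            assert tx.distance(tree.find(y)) == pytest.approx(v)

    def test_three_taxa_point_formulas(self):
        m = pd.DataFrame(
            [[0, 4, 6], [4, 0, 8], [6, 8, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        nwk = nj_tree(m)
        tree = _parse_newick_lengths(nwk)
        la = tree.find("a").length
        lb = tree.find("b").length
        lc = tree.find("c").length
        assert la == pytest.approx((4 + 6 - 8) / 2)
        assert lb == pytest.approx((4 + 8 - 6) / 2)
        assert lc == pytest.approx((6 + 8 - 4) / 2)

    def test_topology_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        x = rng.random((8, 5))
        m = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(8)]
        ours = _parse_newick_lengths(
            nj_tree(pd.DataFrame(m, index=labels, columns=labels))
        )
        ref = skbio_nj(DistanceMatrix(m, ids=labels))
        rf = ours.compare_rfd(ref)
        assert rf == 0

    def test_missing_entries_rejected(self):
        m = pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                         columns=list("abc"))
        m.loc["a", "b"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            nj_tree(m)


class TestPca:
    def test_two_pure_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        h1 = rng.integers(0, 2, size=(100, 1, 2)).astype(np.int8)
        h2 = rng.integers(0, 2, size=(100, 1, 2)).astype(np.int8)
        gt = np.concatenate([np.repeat(h1, 5, axis=1),
                             np.repeat(h2, 5, axis=1)], axis=1)
        g = make_matrix(gt)
        pc = pca(g, 2)
        c = pc.coords["PC1"].to_numpy()
        assert np.allclose(c[:5], c[0]) and np.allclose(c[5:], c[5])
        assert (c[:5] > 0).all() != (c[5:] > 0).all()

    def test_spectral_identities(self, small_cohort):
        g = small_cohort[0]
        pc = pca(g, 4)
        assert pc.explained_variance_ratio.sum() <= 1 + 1e-9
        coords = pc.coords.to_numpy()
        gram = coords.T @ coords
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_too_many_components_rejected(self, small_cohort):
        g = small_cohort[0]
        with pytest.raises(ValueError):
            pca(g, g.n_samples + 1)

    def test_separates_demes_at_modest_fst(self):
        hits = 0
        for rep in range(6):
            scn = SimulationScenario(
                deme_sizes=(50, 50), n_chromosomes=2,
                chrom_length_bp=2_000_000, sites_per_chromosome=800,
                ancestral_size=100, burn_in_generations=1000,
                split_generations=8, migration_rate=0.0,
                selfing_or_consanguinity=0.0, recombination_rate=5e-7,
                balancing_block=None, sweep_block=None,
                mhc_region=(0, 0, 100_000), seed=2100 + rep,
            )
            g, _, _ = simulate_cohort(scn)
            pc = pca(g, 2)
            a = pc.coords.loc[[s for s in g.sample_ids
                               if s.startswith("A")], "PC1"]
            b = pc.coords.loc[[s for s in g.sample_ids
                               if s.startswith("B")], "PC1"]
            acc = max(
                (np.mean(a > 0) + np.mean(b <= 0)) / 2,
                (np.mean(a <= 0) + np.mean(b > 0)) / 2,
            )
            hits += acc > 0.9
        assert hits >= 5
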