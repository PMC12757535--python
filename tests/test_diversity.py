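"""Heterozygosity, allelic richness, windowed pi and F_ST."""

import itertools
import math

import numpy as np
import pytest

from smallpop.diversity import (
    allelic_richness,
    hudson_fst_components,
    per_site_pi,
    site_heterozygosity,
    wc_fst_components,
    windowed_fst,
    windowed_pi,
)

from .conftest import make_matrix


class TestSiteHeterozygosity:
    def test_textbook_values(self):
        # site 0: all het; site 1: monomorphic; site 2: AA=6 Aa=2 aa=2
        gt = np.zeros((3, 10, 2), dtype=np.int8)
        gt[0, :, 1] = 1
        gt[2, :2] = [0, 1]
        gt[2, 2:4] = [1, 1]
        g = make_matrix(gt)
        out = site_heterozygosity(g)["all"].values
        assert out.loc[0, "Ho"] == 1.0
        assert out.loc[0, "He"] == pytest.approx(0.5)
        assert out.loc[1, "Ho"] == 0.0 and out.loc[1, "He"] == 0.0
        assert out.loc[2, "Ho"] == pytest.approx(0.2)
        assert out.loc[2, "He"] == pytest.approx(2 * 0.7 * 0.3)

    def test_he_exceeds_ho_under_consanguinity(self, small_cohort):
        g = small_cohort[0]
        res = site_heterozygosity(g)["all"]
        assert res.medians["He"] > res.medians["Ho"]


class TestAllelicRichness:
    def test_fixed_site_is_one(self):
        gt = np.zeros((1, 10, 2), dtype=np.int8)
        g = make_matrix(gt)
        out = allelic_richness(g, rarefaction_size=4)["all"].values
        assert out["AR"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_at_half_frequency(self):
        # 10 diploids, p = 0.5, grab 2: AR = 2 - 2*C(10,2)/C(20,2)
        gt = np.zeros((1, 10, 2), dtype=np.int8)
        gt[0, :5] = 1
        g = make_matrix(gt)
        out = allelic_richness(g, rarefaction_size=2)["all"].values
        expect = 2 - 2 * math.comb(10, 2) / math.comb(20, 2)
        assert out["AR"].iloc[0] == pytest.approx(expect)

    def test_monotone_in_rarefaction_size(self, small_cohort):
        g = small_cohort[0]
        prev = None
        for grab in (2, 6, 12):
            med = allelic_richness(g, rarefaction_size=grab)["all"]
            cur = med.values.set_index(["chrom", "pos"])["AR"]
            if prev is not None:
                joined = prev.to_frame("lo").join(cur.to_frame("hi"),
                                                  how="inner")
                assert (joined["hi"] >= joined["lo"] - 1e-12).all()
            prev = cur


def brute_force_window_pi(hap_block: np.ndarray) -> float:
    """Mean over sites of mean pairwise haplotype difference."""
    n = hap_block.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    per_site = []
    for row in hap_block:
        diffs = [row[i] != row[j] for i, j in pairs]
        per_site.append(np.mean(diffs))
    return float(np.mean(per_site))


class TestWindowedPi:
    def test_monomorphic_window_is_zero(self):
        gt = np.zeros((25, 6, 2), dtype=np.int8)
        g = make_matrix(gt)
        out = windowed_pi(g, window_sites=20, step_sites=5)
        assert (out["pi"] == 0).all()

    def test_two_haplotypes_all_different(self):
        gt = np.zeros((20, 1, 2), dtype=np.int8)
        gt[:, 0, 1] = 1  # one het individual: its 2 haplotypes differ
        g = make_matrix(gt)
        out = windowed_pi(g, window_sites=20, step_sites=5)
        assert out["pi"].iloc[0] == pytest.approx(1.0)

    def test_equals_brute_force_pairwise(self, small_cohort):
        g = small_cohort[0]
        hap = g.haplotypes()
        out = windowed_pi(g, window_sites=20, step_sites=5)
        chrom0 = out[out["chrom"] == g.chrom[0]]
        # exact check on every window of the first chromosome
        on = np.nonzero(g.chrom == g.chrom[0])[0]
        for w, (_, row) in enumerate(chrom0.iterrows()):
            start = w * 5
            win = on[start : start + 20]
            expect = brute_force_window_pi(hap[win])
            assert row["pi"] == pytest.approx(expect, abs=1e-12)


def wc_theta_general(counts1: np.ndarray, counts2: np.ndarray,
                     het1: int, het2: int) -> tuple[float, float]:
    """Independent Weir-Cockerham components via the general
    multi-allele formulation (loop over alleles, r = 2 populations)."""
    n1, n2 = counts1.sum() / 2, counts2.sum() / 2  # diploid counts
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    num = den = 0.0
    for a in range(len(counts1)):
        p1 = counts1[a] / (2 * n1)
        p2 = counts2[a] / (2 * n2)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (
            (r - 1) * n_bar
        )
        # frequency of heterozygotes carrying allele a (for biallelic
        # sites every heterozygote carries both alleles)
        h_bar = (het1 + het2) / (n1 + n2)
        a_comp = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
            / (n_bar - 1)
        )
        b_comp = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c_comp = h_bar / 2
        num += a_comp
        den += a_comp + b_comp + c_comp
    return num / 2, den / 2  # each biallelic allele counted twice


class TestWcFst:
    def test_identical_frequencies_near_zero(self):
        gt = np.zeros((30, 20, 2), dtype=np.int8)
        gt[:, :, 1] = 1  # every individual het at every site
        g = make_matrix(gt)
        pops = {"A": g.sample_ids[:10], "B": g.sample_ids[10:]}
        out = windowed_fst(g, pops, window_sites=30)
        assert abs(out["fst"].iloc[0]) < 1e-9

    def test_fixed_difference_is_one(self):
        gt = np.zeros((25, 20, 2), dtype=np.int8)
        gt[:, 10:] = 1
        g = make_matrix(gt)
        pops = {"A": g.sample_ids[:10], "B": g.sample_ids[10:]}
        out = windowed_fst(g, pops, window_sites=25)
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_matches_independent_general_form(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1 = int(rng.integers(5, 40))
            n2 = int(rng.integers(5, 40))
            gt = np.zeros((1, n1 + n2, 2), dtype=np.int8)
            gt[0] = rng.integers(0, 2, size=(n1 + n2, 2))
            g = make_matrix(gt)
            if len(np.unique(gt)) < 2:
                continue
            i1, i2 = np.arange(n1), np.arange(n1, n1 + n2)
            num, den = wc_fst_components(g, i1, i2)
            c1 = g.allele_counts(sample_idx=i1)[0]
            c2 = g.allele_counts(sample_idx=i2)[0]
            het1 = int(g.is_het[0, i1].sum())
            het2 = int(g.is_het[0, i2].sum())
            ref_num, ref_den = wc_theta_general(c1, c2, het1, het2)
            assert num[0] == pytest.approx(ref_num, abs=1e-6)
            assert den[0] == pytest.approx(ref_den, abs=1e-6)

    def test_ratio_of_sums_invariant_to_site_order(self, small_cohort,
                                                   small_pops):
        g = small_cohort[0]
        idx = np.nonzero(g.chrom == g.chrom[0])[0][:20]
        i1 = g.sample_index(small_pops["A"])
        i2 = g.sample_index(small_pops["B"])
        num, den = wc_fst_components(g, i1, i2)
        theta = num[idx].sum() / den[idx].sum()
        rng = np.random.default_rng(0)
        perm = rng.permutation(idx)
        assert num[perm].sum() / den[perm].sum() == pytest.approx(theta)

    def test_hudson_agrees_in_sign_and_scale(self, small_cohort,
                                             small_pops):
        g = small_cohort[0]
        wc = windowed_fst(g, small_pops, estimator="wc")
        hu = windowed_fst(g, small_pops, estimator="hudson")
        ok = wc["fst"].notna() & hu["fst"].notna()
        assert np.corrcoef(wc.loc[ok, "fst"], hu.loc[ok, "fst"])[0, 1] > 0.9


class TestPerSitePi:
    def test_equals_mean_pairwise_difference(self):
        rng = np.random.default_rng(4)
        gt = rng.integers(0, 2, size=(30, 8, 2)).astype(np.int8)
        g = make_matrix(gt)
        pi = per_site_pi(g)
        hap = g.haplotypes()
        pairs = list(itertools.combinations(range(16), 2))
        for s in range(30):
            expect = np.mean([hap[s, i] != hap[s, j] for i, j in pairs])
            assert pi[s] == pytest.approx(expect, abs=1e-12)
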