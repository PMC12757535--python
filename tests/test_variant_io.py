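"""VCF round trips, the filtering protocol, LD pruning, stratification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smallpop.matrix import GenotypeMatrix
from smallpop.variant_io import (
    FilterConfig,
    RegionAnnotation,
    apply_filters,
    filter_individuals,
    filter_sites,
    hwe_exact_test,
    ld_prune,
    read_vcf,
    stratify,
    write_vcf,
)

from .conftest import make_matrix


# ----------------------------------------------------------------------
# VCF IO
# ----------------------------------------------------------------------
class TestVcfRoundTrip:
    def test_shapes_and_content(self, tmp_path):
        gt = np.array(
            [
                [[0, 0], [0, 1], [1, 1]],
                [[0, 1], [-1, -1], [0, 0]],
                [[1, 1], [0, 0], [0, 1]],
                [[0, 0], [0, 0], [0, 0]],
                [[0, 1], [1, 0], [1, 1]],
            ],
            dtype=np.int8,
        )
        g = make_matrix(gt)
        path = tmp_path / "t.vcf"
        write_vcf(g, str(path))
        g2 = read_vcf(str(path))
        assert g2.n_samples == 3 and g2.n_variants == 5
        assert np.array_equal(g2.gt, g.gt)
        assert np.array_equal(g2.phased, g.phased)
        assert g2.sample_ids == g.sample_ids

    def test_missing_call_excluded_from_counts(self, tmp_path):
        gt = np.array([[[0, 1], [-1, -1]]], dtype=np.int8)
        g = make_matrix(gt)
        path = tmp_path / "m.vcf"
        write_vcf(g, str(path))
        g2 = read_vcf(str(path))
        assert g2.is_missing[0, 1]
        counts = g2.allele_counts()
        assert counts[0].sum() == 2  # only the called diploid

    def test_rewrite_is_byte_identical(self, tmp_path, small_cohort):
        g = small_cohort[0]
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(g, str(p1))
        write_vcf(read_vcf(str(p1)), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_unsorted_records_rejected(self):
        gt = np.zeros((2, 1, 2), dtype=np.int8)
        with pytest.raises(ValueError, match="strictly increasing"):
            make_matrix(gt, pos=[100, 100])


# ----------------------------------------------------------------------
# site/individual filters
# ----------------------------------------------------------------------
class TestFilters:
    def test_triallelic_sites_removed(self):
        g = make_matrix(np.zeros((10, 4, 2), dtype=np.int8))
        for i in (1, 3, 5, 7):
            g.alt[i] = ("T", "G")
        g.gt[:, 0, 1] = 1  # keep sites polymorphic
        out, log = filter_sites(g, FilterConfig(hwe_p_floor=0.0))
        assert out.n_variants == 6
        assert log.set_index("criterion").loc["biallelic",
                                              "sites_remaining"] == 6

    def test_maf_threshold_strict(self):
        # 25 diploids: 2 alt copies -> MAF 0.04; 6 copies -> 0.12
        gt = np.zeros((2, 25, 2), dtype=np.int8)
        gt[0, 0] = [0, 1]
        gt[0, 1] = [0, 1]
        gt[1, :3] = [0, 1]
        gt[1, 3:6] = [1, 0]
        g = make_matrix(gt)
        out, _ = filter_sites(g, FilterConfig(maf_min=0.05, hwe_p_floor=0.0))
        assert out.n_variants == 1
        assert out.pos[0] == g.pos[1]

    def test_site_missingness_fraction(self):
        # 3/20 missing = 0.15 > 0.10 -> removed
        gt = np.zeros((2, 20, 2), dtype=np.int8)
        gt[:, 0, 1] = 1
        gt[0, 1:4] = -1
        g = make_matrix(gt)
        out, _ = filter_sites(g, FilterConfig(hwe_p_floor=0.0, maf_min=0.0))
        assert out.n_variants == 1

    def test_individual_missingness_boundary(self):
        # 10 sites; individual 1 misses 3 (30%, kept), individual 2
        # misses 4 (40%, removed): "over 30%" is strict
        gt = np.zeros((10, 3, 2), dtype=np.int8)
        gt[:, 0, 1] = 1
        gt[:3, 1] = -1
        gt[:4, 2] = -1
        g = make_matrix(gt)
        out, log = filter_individuals(g, FilterConfig())
        assert out.sample_ids == ["s0", "s1"]

    def test_all_individuals_removed_raises(self):
        gt = np.full((10, 2, 2), -1, dtype=np.int8)
        g = make_matrix(gt)
        with pytest.raises(ValueError, match="all individuals"):
            filter_individuals(g, FilterConfig())

    def test_gq_masking_feeds_missingness(self):
        # low-GQ calls become missing and then trip the missingness cap
        gt = np.zeros((1, 10, 2), dtype=np.int8)
        gt[0, 0, 1] = 1
        gq = np.full((1, 10), 99, dtype=np.int32)
        gq[0, :3] = 10  # 3/10 masked -> 0.3 > 0.1
        g = make_matrix(gt, gq=gq)
        out, _ = filter_sites(g, FilterConfig(hwe_p_floor=0.0, maf_min=0.0))
        assert out.n_variants == 0

    def test_filtering_is_idempotent(self, small_cohort):
        g = small_cohort[0]
        cfg = FilterConfig(maf_min=0.05)
        once, _ = apply_filters(g, cfg)
        twice, _ = apply_filters(once, cfg)
        assert np.array_equal(once.gt, twice.gt)
        assert once.sample_ids == twice.sample_ids


def _hwe_oracle(n_het, n_hom1, n_hom2):
    """Exact HWE p by direct factorial enumeration (Levene's formula)."""
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het

    def prob(h):
        # multinomial genotype-count probability conditional on allele
        # counts, up to a constant normalized away below
        if (rare - h) % 2:
            return 0.0
        hr = (rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            return 0.0
        return (
            math.factorial(n)
            / (math.factorial(hr) * math.factorial(hc) * math.factorial(h))
            * 2**h
        )

    probs = {h: prob(h) for h in range(rare + 1)}
    tot = sum(probs.values())
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12)) / tot


class TestHweExact:
    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, het, hom1, hom2):
        if het + hom1 + hom2 == 0:
            return
        p = hwe_exact_test(het, hom1, hom2)
        q = _hwe_oracle(het, hom1, hom2)
        assert p == pytest.approx(q, rel=1e-8)

    def test_extreme_het_excess_is_deep_tail(self):
        assert hwe_exact_test(100, 0, 0) < 1e-20
        assert hwe_exact_test(10, 5, 5) == pytest.approx(1.0)


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------
class TestLdPrune:
    def test_duplicated_site_one_survives(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(1, 30, 2)).astype(np.int8)
        gt = np.concatenate([base, base], axis=0)
        g = make_matrix(gt)
        out = ld_prune(g, seed=1)
        assert out.n_variants == 1

    def test_independent_sites_untouched(self):
        rng = np.random.default_rng(1)
        # many samples -> sample r2 of independent sites stays low
        gt = rng.integers(0, 2, size=(30, 500, 2)).astype(np.int8)
        g = make_matrix(gt)
        out = ld_prune(g, r2_max=0.2, seed=1)
        assert out.n_variants >= 25

    def test_planted_blocks_reduced_to_one_and_oracle_clean(self):
        rng = np.random.default_rng(2)
        blocks = []
        for _ in range(6):
            h = rng.integers(0, 2, size=(1, 40, 2)).astype(np.int8)
            blocks.append(np.repeat(h, 5, axis=0))  # 5 identical SNPs
        gt = np.concatenate(blocks, axis=0)
        g = make_matrix(gt)
        out = ld_prune(g, seed=3)
        assert out.n_variants == 6
        # exhaustive all-pairs oracle on the pruned set
        d = out.dosage()
        for i in range(out.n_variants):
            for j in range(i + 1, out.n_variants):
                r = np.corrcoef(d[i], d[j])[0, 1]
                assert r * r <= 0.2 + 1e-9

    def test_deterministic_under_seed(self, small_cohort):
        g = small_cohort[0]
        a = ld_prune(g, seed=7)
        b = ld_prune(g, seed=7)
        assert np.array_equal(a.pos, b.pos)


# ----------------------------------------------------------------------
# stratification
# ----------------------------------------------------------------------
class TestStratify:
    def _ann(self):
        iv = pd.DataFrame(
            [
                ("chr1", 10_000, 20_000, "CDS"),
                ("chr1", 14_000, 16_000, "MHC_CDS"),
            ],
            columns=["chrom", "start", "end", "cls"],
        )
        return RegionAnnotation(iv, {"chr1": 100_000})

    def test_flank_boundaries(self):
        # CDS is [10000, 20000) 0-based -> 1-based [10001, 20000];
        # the 1 kb flank covers 1-based (9001..10000] and [20001..21000]
        pos = [20_999, 21_001, 15_000, 5_000]
        order = np.argsort(pos)
        gt = np.zeros((4, 2, 2), dtype=np.int8)
        g = make_matrix(gt, pos=sorted(pos))
        sets = stratify(g, self._ann(), flank_bp=1000)
        by_pos = {int(g.pos[i]): i for i in range(4)}
        assert by_pos[20_999] not in sets["non_CDS"]  # inside flank
        assert by_pos[21_001] in sets["non_CDS"]  # past the flank
        assert by_pos[15_000] in sets["CDS"]
        assert by_pos[15_000] in sets["MHC_CDS"]
        assert by_pos[5_000] in sets["non_CDS"]

    def test_mhc_subset_of_cds(self, small_cohort):
        g, ann = small_cohort[0], small_cohort[1]
        sets = stratify(g, ann)
        assert set(sets["MHC_CDS"]).issubset(set(sets["CDS"]))
        assert not set(sets["non_CDS"]) & set(sets["CDS"])

    def test_chromosome_mismatch_raises(self):
        gt = np.zeros((2, 2, 2), dtype=np.int8)
        g = make_matrix(gt, chrom=["scaffold9", "scaffold9"])
        with pytest.raises(ValueError, match="scaffold9"):
            stratify(g, self._ann())
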