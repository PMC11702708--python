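import numpy as np
import pytest

from haploedit.panel import GenomicInterval, LocusModel
from haploedit.pairs import (CandidateVariants, MonomorphicVariantError,
                             SnpPair, double_het_coverage,
                             enumerate_excision_pairs, filter_common_flanking,
                             het_pair_matrix, ld_r2)

from conftest import make_panel, panel_from_haplotype_counts


def random_panel(rng, n=20, m=8):
    return make_panel(rng.integers(0, 2, size=(n, m, 2)),
                      positions=sorted(rng.choice(10_000, size=m, replace=False) + 1))


class TestFilterCommonFlanking:
    locus = LocusModel(gene=GenomicInterval("chr8", 4000, 6000), flank_bp=2000)

    def test_rare_variants_are_excluded(self, rng):
        haps = np.zeros((20, 4, 2), dtype=np.int8)
        haps[0, :, 0] = 1  # alt_freq 1/40 = 0.025 everywhere
        panel = make_panel(haps, positions=[2500, 3000, 6500, 7000])
        cands = filter_common_flanking(panel, self.locus)
        assert cands.left == () and cands.right == ()

    def test_matches_exhaustive_position_and_af_scan(self, rng):
        for _ in range(20):
            panel = random_panel(rng)
            cands = filter_common_flanking(panel, self.locus)
            left, right = [], []
            for j, v in enumerate(panel.variants):
                if not 0.1 <= v.alt_freq <= 0.9:
                    continue
                pos0 = v.pos - 1
                if 2000 <= pos0 < 4000:
                    left.append(j)
                elif 6000 <= pos0 < 8000:
                    right.append(j)
            assert cands.left == tuple(left) and cands.right == tuple(right)

    def test_af_bounds_inclusive_by_default_exclusive_on_request(self):
        # 2 alt alleles of 20 = 0.10 exactly
        haps = np.zeros((10, 1, 2), dtype=np.int8)
        haps[0, 0, :] = 1
        panel = make_panel(haps, positions=[3000])
        assert filter_common_flanking(panel, self.locus).left == (0,)
        assert filter_common_flanking(panel, self.locus, inclusive=False).left == ()

    def test_flank_windows_are_half_open_at_gene_boundaries(self):
        haps = np.tile(np.array([[0, 1]], dtype=np.int8), (10, 1)).reshape(10, 1, 2)
        for pos0, expected_side in [(1999, None), (2000, "left"), (3999, "left"),
                                    (4000, None), (5999, None), (6000, "right"),
                                    (7999, "right"), (8000, None)]:
            panel = make_panel(haps, positions=[pos0 + 1])
            cands = filter_common_flanking(panel, self.locus)
            side = "left" if cands.left else "right" if cands.right else None
            assert side == expected_side, f"pos0={pos0}"

    def test_candidate_sides_must_be_disjoint(self):
        with pytest.raises(ValueError):
            CandidateVariants(left=(1, 2), right=(2, 3))


class TestEnumerateExcisionPairs:
    def _setup(self, protected):
        locus = LocusModel(gene=GenomicInterval("chr8", 4000, 6000),
                           protected=protected, flank_bp=2000)
        haps = np.tile(np.array([0, 1], dtype=np.int8), (10, 4, 1))
        panel = make_panel(haps, positions=[2500, 3500, 6500, 7500])
        cands = filter_common_flanking(panel, locus)
        return locus, panel, cands

    def test_distant_protected_gene_keeps_all_pairs(self):
        locus, panel, cands = self._setup((GenomicInterval("chr8", 20_000, 21_000),))
        pairs = enumerate_excision_pairs(cands, locus, panel)
        assert len(pairs) == len(cands.left) * len(cands.right)
        for p in pairs:
            assert p.span.contains(locus.gene)

    def test_protected_gene_inside_every_span_excludes_all(self):
        locus, panel, cands = self._setup((GenomicInterval("chr8", 6100, 6300),))
        assert enumerate_excision_pairs(cands, locus, panel) == []

    def test_matches_interval_containment_oracle(self, rng):
        protected = (GenomicInterval("chr8", 6600, 7000),
                     GenomicInterval("chr8", 2000, 2800))
        locus, panel, cands = self._setup(protected)
        pairs = enumerate_excision_pairs(cands, locus, panel)
        got = {(p.left, p.right) for p in pairs}
        expected = set()
        for li in cands.left:
            for ri in cands.right:
                lo = panel.variants[li].pos - 1
                hi = panel.variants[ri].pos  # span end is exclusive
                if not any(lo <= pr.start and pr.end <= hi for pr in protected):
                    expected.add((li, ri))
        assert got == expected

    def test_overlap_mode_is_stricter(self):
        # protected interval overlapping (not contained in) some spans
        locus, panel, cands = self._setup((GenomicInterval("chr8", 7000, 9000),))
        lenient = enumerate_excision_pairs(cands, locus, panel)
        strict = enumerate_excision_pairs(cands, locus, panel,
                                          exclude_on_overlap=True)
        assert len(strict) < len(lenient)


class TestDoubleHetCoverage:
    def test_all_homozygous_panel_has_zero_coverage(self):
        panel = make_panel(np.ones((5, 2, 2)), positions=[100, 200])
        pair = SnpPair(0, 1, GenomicInterval("chr8", 99, 200))
        assert double_het_coverage(panel, pair).coverage_count == 0

    def test_counts_only_double_heterozygotes(self):
        # genotype classes per sample: (het,het),(het,hom),(hom,het),(het,het)
        haps = np.array([
            [[0, 1], [0, 1]],
            [[0, 1], [1, 1]],
            [[0, 0], [0, 1]],
            [[1, 0], [1, 0]],
        ])
        panel = make_panel(haps, positions=[100, 200])
        pair = double_het_coverage(panel, SnpPair(0, 1, GenomicInterval("chr8", 99, 200)))
        assert pair.covered == frozenset({0, 3})

    def test_matches_per_sample_loop_oracle(self, rng):
        for _ in range(20):
            panel = random_panel(rng, n=15, m=4)
            pair = double_het_coverage(
                panel, SnpPair(0, 3, GenomicInterval("chr8", 1, 20_000)))
            expected = {
                i for i in range(15)
                if panel.haplotypes[i, 0, 0] != panel.haplotypes[i, 0, 1]
                and panel.haplotypes[i, 3, 0] != panel.haplotypes[i, 3, 1]
            }
            assert pair.covered == frozenset(expected)

    def test_coverage_bounded_by_single_site_het_counts(self, rng):
        panel = random_panel(rng, n=40, m=5)
        het = panel.het_mask()
        for left in range(2):
            for right in range(3, 5):
                pair = double_het_coverage(
                    panel, SnpPair(left, right, GenomicInterval("chr8", 1, 20_000)))
                assert pair.coverage_count <= min(het[:, left].sum(), het[:, right].sum())


class TestHetPairMatrix:
    def test_universal_pair_scores_hundred(self):
        haps = np.tile(np.array([0, 1], dtype=np.int8), (6, 2, 1))
        panel = make_panel(haps, positions=[100, 200])
        mat = het_pair_matrix(panel, [0], [1])
        assert mat.iloc[0, 0] == pytest.approx(100.0)

    def test_entries_match_double_het_coverage(self, rng):
        panel = random_panel(rng, n=25, m=6)
        mat = het_pair_matrix(panel, [0, 1, 2], [3, 4, 5])
        for a, left in enumerate([0, 1, 2]):
            for b, right in enumerate([3, 4, 5]):
                pair = double_het_coverage(
                    panel, SnpPair(left, right, GenomicInterval("chr8", 1, 20_000)))
                assert mat.iloc[a, b] == pytest.approx(100 * pair.coverage_count / 25)

    def test_invariant_under_sample_permutation(self, rng):
        panel = random_panel(rng, n=25, m=6)
        perm = rng.permutation(25)
        shuffled = make_panel(panel.haplotypes[perm],
                              positions=[v.pos for v in panel.variants])
        a = het_pair_matrix(panel, [0, 1], [4, 5])
        b = het_pair_matrix(shuffled, [0, 1], [4, 5])
        assert np.allclose(a.values, b.values)
        assert ((a.values >= 0) & (a.values <= 100)).all()


class TestLdR2:
    def test_identical_columns_give_one(self):
        panel = panel_from_haplotype_counts({(0, 0): 5, (1, 1): 5})
        assert ld_r2(panel, 0, 1) == pytest.approx(1.0)

    def test_independent_counts_give_zero(self):
        panel = panel_from_haplotype_counts({(1, 1): 1, (1, 0): 1, (0, 1): 1, (0, 0): 1})
        assert ld_r2(panel, 0, 1) == pytest.approx(0.0)

    def test_known_haplotype_counts(self):
        # AB=40, Ab=10, aB=10, ab=40: (0.4 - 0.25)^2 / (0.25 * 0.25) = 0.36
        panel = panel_from_haplotype_counts({(1, 1): 40, (1, 0): 10,
                                             (0, 1): 10, (0, 0): 40})
        assert ld_r2(panel, 0, 1) == pytest.approx(0.36)

    def test_symmetric_and_label_swap_invariant(self, rng):
        for _ in range(10):
            haps = rng.integers(0, 2, size=(20, 2, 2))
            if haps[:, 0, :].min() == haps[:, 0, :].max():
                continue
            if haps[:, 1, :].min() == haps[:, 1, :].max():
                continue
            panel = make_panel(haps)
            r2 = ld_r2(panel, 0, 1)
            assert r2 == pytest.approx(ld_r2(panel, 1, 0))
            flipped = make_panel(np.stack([1 - haps[:, 0, :], haps[:, 1, :]], axis=1))
            assert r2 == pytest.approx(ld_r2(flipped, 0, 1))
            assert 0.0 <= r2 <= 1.0 + 1e-12

    def test_monomorphic_variant_is_an_error(self):
        panel = panel_from_haplotype_counts({(0, 0): 5, (0, 1): 5})
        with pytest.raises(MonomorphicVariantError):
            ld_r2(panel, 0, 1)
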