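import numpy as np
import pytest

from haploedit.guides import (GuideCandidate, enumerate_biallelic_guides,
                              enumerate_guides, pair_guides, revcomp,
                              PROTOSPACER_LEN)
from haploedit.simulate import make_guide_test_sequence


def brute_force_guides(sequence, snp_offset, alleles, pam_pattern="NGG",
                       seed_len=10):
    """Independent oracle: test every 23-nt window on both strands of both
    allele-substituted sequences with direct string comparisons."""
    from haploedit.guides import _IUPAC

    plen = len(pam_pattern)
    out = set()
    subs = {}
    ref, alt = alleles
    subs["ref"] = sequence[:snp_offset] + ref + sequence[snp_offset + 1:]
    subs["alt"] = sequence[:snp_offset] + alt + sequence[snp_offset + 1:]

    def pam_ok(s):
        return all(b in _IUPAC[p] for b, p in zip(s, pam_pattern))

    for strand in "+-":
        for p in range(len(sequence) - plen + 1):
            if strand == "+":
                if p < PROTOSPACER_LEN:
                    continue
                window = (p - PROTOSPACER_LEN, p + plen)
            else:
                if p + plen + PROTOSPACER_LEN > len(sequence):
                    continue
                window = (p, p + plen + PROTOSPACER_LEN)
            if not window[0] <= snp_offset < window[1]:
                continue
            valid = {}
            for allele in ("ref", "alt"):
                pam_seq = subs[allele][p:p + plen]
                valid[allele] = pam_ok(pam_seq if strand == "+" else revcomp(pam_seq))
            if not any(valid.values()):
                continue
            if strand == "+":
                snp_pos = p - snp_offset if snp_offset < p else 0
            else:
                snp_pos = (snp_offset - (p + plen) + 1
                           if snp_offset >= p + plen else 0)
            if valid["ref"] != valid["alt"]:
                allele = "ref" if valid["ref"] else "alt"
                out.add((p, strand, allele, "snp_derived_pam"))
            elif snp_pos == 0:
                out.add((p, strand, "both", "pam_snp"))
            else:
                klass = "seed" if snp_pos <= seed_len else "non_seed"
                out.add((p, strand, "ref", klass))
                out.add((p, strand, "alt", klass))
    return out


class TestEnumerateGuides:
    def test_pam_free_sequence_yields_nothing(self):
        assert enumerate_guides("A" * 60, 30, ("A", "G")) == []

    def test_planted_seed_snp_yields_one_candidate_per_allele(self):
        seq, _ = make_guide_test_sequence(
            60, planted_pams=[(30, "+")], snp_offset=27, alleles=("A", "G"),
            seed=3)
        cands = enumerate_guides(seq, 27, ("A", "G"))
        assert len(cands) == 2
        by_allele = {c.targeted_allele: c for c in cands}
        assert set(by_allele) == {"ref", "alt"}
        for c in cands:
            assert c.klass == "seed" and c.snp_protospacer_pos == 3
        # otherwise identical guides differing at a single nucleotide
        diffs = [i for i, (a, b) in enumerate(zip(by_allele["ref"].protospacer,
                                                  by_allele["alt"].protospacer))
                 if a != b]
        assert len(diffs) == 1

    def test_snp_in_gg_creates_snp_derived_pam(self):
        # ref allele breaks the PAM, alt allele (G) completes it
        seq = "T" + "CATCATCATCATCATCATCA" + "AG" + "T" * 10
        snp_offset = 23  # the second G of NGG under the alt allele
        cands = enumerate_guides(seq + "A", snp_offset, ("A", "G"))
        derived = [c for c in cands if c.klass == "snp_derived_pam"]
        assert derived and all(c.targeted_allele == "alt" for c in derived)
        assert all(c.snp_protospacer_pos == 0 for c in derived)

    def test_matches_brute_force_window_scan(self, rng):
        bases = np.array(list("ACGT"))
        for trial in range(30):
            seq = "".join(rng.choice(bases, size=120))
            snp_offset = int(rng.integers(0, 120))
            ref = seq[snp_offset]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            got = {(c.pam_start, c.strand, c.targeted_allele, c.klass)
                   for c in enumerate_guides(seq, snp_offset, (ref, alt))}
            assert got == brute_force_guides(seq, snp_offset, (ref, alt))

    def test_reverse_complement_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(10):
            seq = "".join(rng.choice(bases, size=100))
            snp_offset = int(rng.integers(0, 100))
            ref = seq[snp_offset]
            alt = "A" if ref != "A" else "C"
            fwd = enumerate_guides(seq, snp_offset, (ref, alt))
            rc_seq = revcomp(seq)
            rc_ref, rc_alt = revcomp(ref), revcomp(alt)
            rev = enumerate_guides(rc_seq, len(seq) - 1 - snp_offset,
                                   (rc_ref, rc_alt))
            fwd_set = {(c.protospacer, c.pam, c.targeted_allele, c.klass)
                       for c in fwd}
            rev_set = {(c.protospacer, c.pam, c.targeted_allele, c.klass)
                       for c in rev}
            assert fwd_set == rev_set

    def test_seed_class_pair_differs_at_one_seed_position(self, rng):
        bases = np.array(list("ACGT"))
        checked = 0
        for _ in range(40):
            seq = "".join(rng.choice(bases, size=120))
            snp_offset = int(rng.integers(0, 120))
            ref = seq[snp_offset]
            alt = "T" if ref != "T" else "G"
            cands = enumerate_guides(seq, snp_offset, (ref, alt))
            by_site = {}
            for c in cands:
                if c.klass == "seed":
                    by_site.setdefault((c.pam_start, c.strand), {})[
                        c.targeted_allele] = c
            for pair in by_site.values():
                assert set(pair) == {"ref", "alt"}
                diffs = [i + 1 for i, (a, b) in enumerate(
                    zip(pair["ref"].protospacer[::-1],
                        pair["alt"].protospacer[::-1])) if a != b]
                assert diffs == [pair["ref"].snp_protospacer_pos]
                assert diffs[0] <= 10
                checked += 1
        assert checked > 5

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            enumerate_guides("ACGTN" * 10, 3, ("G", "T"))
        with pytest.raises(ValueError):
            enumerate_guides("ACGT" * 10, 100, ("A", "G"))


class TestBiallelicGuides:
    def test_window_without_pam_is_empty(self):
        assert enumerate_biallelic_guides("A" * 80, (0, 80)) == []

    def test_single_planted_pam_gives_one_forward_candidate(self):
        seq, truth = make_guide_test_sequence(
            60, planted_pams=[(40, "+")], snp_offset=2, seed=9)
        cands = enumerate_biallelic_guides(seq, (0, 60))
        assert len(cands) == 1
        c = cands[0]
        assert (c.strand, c.pam_start, c.klass) == ("+", 40, "biallelic")
        assert c.protospacer == truth[0]["protospacer"]
        assert c.predicted_cut == 37  # blunt cut 3 bp 5' of the PAM

    def test_heterozygous_site_excludes_overlapping_candidates(self):
        seq, _ = make_guide_test_sequence(60, planted_pams=[(40, "+")],
                                          snp_offset=2, seed=9)
        assert enumerate_biallelic_guides(seq, (0, 60), het_positions=[30]) == []
        assert enumerate_biallelic_guides(seq, (0, 60), het_positions=[5]) != []

    def test_matches_window_scan_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seq = "".join(rng.choice(bases, size=100))
            got = {(c.pam_start, c.strand)
                   for c in enumerate_biallelic_guides(seq, (0, 100))}
            expected = set()
            for p in range(98):
                if seq[p + 1:p + 3] == "GG" and p >= 20:
                    expected.add((p, "+"))
                if seq[p:p + 2] == "CC" and p + 23 <= 100:
                    expected.add((p, "-"))
            assert got == expected

    def test_candidate_count_monotone_in_window_size(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=150))
        counts = [len(enumerate_biallelic_guides(seq, (0, end)))
                  for end in (50, 100, 150)]
        assert counts == sorted(counts)


class TestPairGuides:
    def _candidates(self):
        seq, _ = make_guide_test_sequence(
            120, planted_pams=[(30, "+"), (80, "+")], snp_offset=27,
            alleles=("A", "G"), seed=4)
        lefts = enumerate_guides(seq, 27, ("A", "G"))
        rights = enumerate_biallelic_guides(seq, (40, 120))
        return lefts, rights

    def test_single_combination_has_cut_distance_excision(self):
        lefts, rights = self._candidates()
        pairs = pair_guides([lefts[0]], [rights[0]])
        assert len(pairs) == 1
        p = pairs[0]
        assert p.excision_length == rights[0].predicted_cut - lefts[0].predicted_cut
        assert p.allele_specific  # seed-class left member discriminates

    def test_two_biallelic_members_filtered_when_specificity_required(self):
        _, rights = self._candidates()
        assert pair_guides(rights, rights, require_allele_specific=True) == []

    def test_allele_specific_plus_biallelic_is_retained(self):
        lefts, rights = self._candidates()
        pairs = pair_guides(lefts, rights, require_allele_specific=True)
        assert pairs and all(p.allele_specific for p in pairs)

    def test_left_cut_must_precede_right_cut(self):
        lefts, rights = self._candidates()
        assert pair_guides(rights, lefts) == []
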