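"""Allele-specific protospacer enumeration at heterozygous SNPs.

A Cas9 guide discriminates between a patient's two haplotypes in one of two
ways: the SNP sits in the PAM-proximal seed region of the protospacer, where
a single mismatch abolishes cleavage of the non-target allele (two guides,
one per allele, differing at a single nucleotide), or the SNP creates a PAM
on one allele only (a SNP-derived PAM, which can target just that allele).
This module scans both strands of both allele-substituted sequences for PAM
sites, emits every candidate whose protospacer-or-PAM window covers the SNP,
and classifies the discrimination mechanism.  Guides in windows identical on
both haplotypes (biallelic guides) are enumerated separately — one such
constant guide anchors the single-SNP therapy mode.

Conventions: protospacers are reported 5'->3' on the targeting strand;
``pam_start`` is the 0-based offset of the PAM's first base in input-sequence
coordinates on either strand; ``snp_protospacer_pos`` counts 1..20 from the
PAM-proximal end (0 = SNP inside the PAM); the predicted blunt cut falls
between protospacer positions 3 and 4 from the PAM and is reported as the
0-based input coordinate of the first base 3' of the cut on the forward
strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GuideCandidate",
    "GuidePair",
    "enumerate_guides",
    "enumerate_biallelic_guides",
    "pair_guides",
]

PROTOSPACER_LEN = 20
DEFAULT_SEED_LEN = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DISCRIMINATING_CLASSES = frozenset({"seed", "snp_derived_pam"})


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _matches_pam(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC[p] for b, p in zip(seq, pattern)
    )


@dataclass(frozen=True)
class GuideCandidate:
    protospacer: str
    pam: str
    strand: str  # '+' or '-'
    pam_start: int
    snp_protospacer_pos: int | None  # 1..20 from PAM, 0 = in PAM, None = no SNP
    targeted_allele: str  # 'ref' | 'alt' | 'both'
    klass: str  # 'seed' | 'non_seed' | 'pam_snp' | 'snp_derived_pam' | 'biallelic'
    predicted_cut: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def discriminates(self) -> bool:
        return self.klass in DISCRIMINATING_CLASSES


@dataclass(frozen=True)
class GuidePair:
    """A left/right guide combination and its predicted excision."""

    left: GuideCandidate
    right: GuideCandidate
    allele_specific: bool

    def __post_init__(self) -> None:
        if self.left.predicted_cut >= self.right.predicted_cut:
            raise ValueError("left cut must precede right cut")

    @property
    def excision_length(self) -> int:
        return self.right.predicted_cut - self.left.predicted_cut


def _pam_sites(seq: str, pattern: str) -> Iterable[tuple[int, str]]:
    """(pam_start, strand) for every PAM with protospacer room; '-' sites are
    the reverse-complement pattern read on the forward strand."""
    plen = len(pattern)
    rc_pattern = revcomp(pattern)
    for p in range(len(seq) - plen + 1):
        window = seq[p:p + plen]
        if p >= PROTOSPACER_LEN and _matches_pam(window, pattern):
            yield p, "+"
        if p + plen + PROTOSPACER_LEN <= len(seq) and _matches_pam(window, rc_pattern):
            yield p, "-"


def _window_bounds(pam_start: int, strand: str, plen: int) -> tuple[int, int]:
    """Forward-strand footprint [start, end) of protospacer + PAM."""
    if strand == "+":
        return pam_start - PROTOSPACER_LEN, pam_start + plen
    return pam_start, pam_start + plen + PROTOSPACER_LEN


def _extract(seq: str, pam_start: int, strand: str, plen: int) -> tuple[str, str, int]:
    """(protospacer, pam, predicted_cut) at a site, on the targeting strand."""
    if strand == "+":
        proto = seq[pam_start - PROTOSPACER_LEN:pam_start]
        pam = seq[pam_start:pam_start + plen]
        cut = pam_start - 3
    else:
        proto = revcomp(seq[pam_start + plen:pam_start + plen + PROTOSPACER_LEN])
        pam = revcomp(seq[pam_start:pam_start + plen])
        cut = pam_start + plen + 3
    return proto, pam, cut


def _snp_pos_from_pam(snp_offset: int, pam_start: int, strand: str,
                      plen: int) -> int:
    """1..20 from the PAM-proximal protospacer end; 0 when inside the PAM."""
    if strand == "+":
        return pam_start - snp_offset if snp_offset < pam_start else 0
    proto_start = pam_start + plen
    return snp_offset - proto_start + 1 if snp_offset >= proto_start else 0


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence must contain only A/C/G/T")
    return sequence


def enumerate_guides(sequence: str, snp_offset: int, alleles: tuple[str, str],
                     pam_pattern: str = "NGG",
                     seed_len: int = DEFAULT_SEED_LEN) -> list[GuideCandidate]:
    """Every protospacer whose protospacer-or-PAM window covers the SNP, on
    both strands of both allele-substituted sequences, with its
    allele-discrimination class.

    Classes: ``seed`` / ``non_seed`` — SNP at protospacer position <=
    ``seed_len`` / beyond it (one candidate per allele, protospacers
    differing at exactly one nucleotide); ``snp_derived_pam`` — the PAM
    exists on exactly one allele; ``pam_snp`` — the SNP sits in the PAM but
    both alleles keep a valid PAM (no discrimination; targeted_allele
    'both').
    """
    sequence = _validate_sequence(sequence)
    ref, alt = alleles
    if not 0 <= snp_offset < len(sequence):
        raise ValueError("snp_offset outside sequence")
    if ref == alt or {ref, alt} - set("ACGT"):
        raise ValueError(f"bad allele pair {alleles}")
    plen = len(pam_pattern)
    subs = {
        "ref": sequence[:snp_offset] + ref + sequence[snp_offset + 1:],
        "alt": sequence[:snp_offset] + alt + sequence[snp_offset + 1:],
    }
    sites = set(_pam_sites(subs["ref"], pam_pattern)) | set(
        _pam_sites(subs["alt"], pam_pattern))

    out: list[GuideCandidate] = []
    for pam_start, strand in sorted(sites):
        w_lo, w_hi = _window_bounds(pam_start, strand, plen)
        if not w_lo <= snp_offset < w_hi:
            continue
        valid = {
            allele: _matches_pam(
                subs[allele][pam_start:pam_start + plen] if strand == "+"
                else revcomp(subs[allele][pam_start:pam_start + plen]),
                pam_pattern)
            for allele in ("ref", "alt")
        }
        snp_pos = _snp_pos_from_pam(snp_offset, pam_start, strand, plen)
        if valid["ref"] != valid["alt"]:
            allele = "ref" if valid["ref"] else "alt"
            proto, pam, cut = _extract(subs[allele], pam_start, strand, plen)
            out.append(GuideCandidate(proto, pam, strand, pam_start, snp_pos,
                                      allele, "snp_derived_pam", cut))
        elif snp_pos == 0:
            # SNP in the PAM's unconstrained position: PAM valid either way,
            # protospacer identical -> no discrimination
            proto, pam, cut = _extract(subs["ref"], pam_start, strand, plen)
            out.append(GuideCandidate(proto, pam, strand, pam_start, 0,
                                      "both", "pam_snp", cut))
        else:
            klass = "seed" if snp_pos <= seed_len else "non_seed"
            for allele in ("ref", "alt"):
                proto, pam, cut = _extract(subs[allele], pam_start, strand, plen)
                out.append(GuideCandidate(proto, pam, strand, pam_start,
                                          snp_pos, allele, klass, cut))
    return out


def enumerate_biallelic_guides(sequence: str, window: tuple[int, int],
                               pam_pattern: str = "NGG",
                               het_positions: Sequence[int] = ()
                               ) -> list[GuideCandidate]:
    """Guides whose full protospacer+PAM footprint lies inside ``window``
    (0-based half-open sequence offsets) and covers no heterozygous site —
    candidates identical on both haplotypes."""
    sequence = _validate_sequence(sequence)
    w_start, w_end = int(window[0]), int(window[1])
    if not 0 <= w_start < w_end <= len(sequence):
        raise ValueError(f"window [{w_start}, {w_end}) outside sequence")
    plen = len(pam_pattern)
    het = set(het_positions)
    out = []
    for pam_start, strand in sorted(_pam_sites(sequence, pam_pattern)):
        lo, hi = _window_bounds(pam_start, strand, plen)
        if lo < w_start or hi > w_end:
            continue
        if any(lo <= h < hi for h in het):
            continue
        proto, pam, cut = _extract(sequence, pam_start, strand, plen)
        out.append(GuideCandidate(proto, pam, strand, pam_start, None,
                                  "both", "biallelic", cut))
    return out


def pair_guides(lefts: Sequence[GuideCandidate],
                rights: Sequence[GuideCandidate],
                require_allele_specific: bool = False) -> list[GuidePair]:
    """All left x right combinations with left cut strictly before right cut.

    A pair is allele-specific when at least one member discriminates alleles
    (seed-region SNP or SNP-derived PAM): one discriminating guide plus one
    biallelic guide already confines the excision to one haplotype.
    """
    if not lefts or not rights:
        raise ValueError("need candidates on both sides")
    pairs = []
    for lg in lefts:
        for rg in rights:
            if lg.predicted_cut >= rg.predicted_cut:
                continue
            specific = lg.discriminates or rg.discriminates
            if require_allele_specific and not specific:
                continue
            pairs.append(GuidePair(lg, rg, allele_specific=specific))
    return pairs
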