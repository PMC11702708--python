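"""Candidate SNP filtering, excision-pair enumeration and LD.

The excision strategy needs one common SNP on each side of the target gene:
an individual heterozygous at both SNPs (a double heterozygote) carries a
distinguishable pair of cut sites on each haplotype, so a dual-guide excision
can remove one allele's entire gene body.  This module filters flank variants
by allele frequency, enumerates left x right pairs whose excision span keeps
neighbouring genes intact, counts double heterozygotes per pair, and computes
LD r-squared between sites from the phased haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenomicInterval, LocusModel, PhasedPanel

__all__ = [
    "CandidateVariants",
    "SnpPair",
    "filter_common_flanking",
    "enumerate_excision_pairs",
    "double_het_coverage",
    "het_pair_matrix",
    "ld_r2",
    "MonomorphicVariantError",
]


class MonomorphicVariantError(ValueError):
    """LD is undefined when a site carries only one allele."""


@dataclass(frozen=True)
class CandidateVariants:
    """AF-filtered flank variants: indices left (upstream) and right
    (downstream) of the gene body."""

    left: tuple[int, ...]
    right: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.left) & set(self.right):
            raise ValueError("a variant cannot flank the gene on both sides")

    @property
    def n_total(self) -> int:
        return len(self.left) + len(self.right)


@dataclass
class SnpPair:
    """A left-flank / right-flank SNP pair with its double-heterozygote set."""

    left: int
    right: int
    span: GenomicInterval
    covered: frozenset[int] = frozenset()

    @property
    def coverage_count(self) -> int:
        return len(self.covered)

    def coverage_fraction(self, n_samples: int) -> float:
        return self.coverage_count / n_samples


def filter_common_flanking(panel: PhasedPanel, locus: LocusModel,
                           af_lo: float = 0.1, af_hi: float = 0.9,
                           inclusive: bool = True) -> CandidateVariants:
    """Common variants in the flanking windows on either side of the gene.

    Variants with recomputed alt frequency in [af_lo, af_hi] (inclusive by
    default; ``inclusive=False`` uses open bounds) and position inside
    [gene.start - flank_bp, gene.start) or [gene.end, gene.end + flank_bp)
    are retained.  Positions are compared 0-based.
    """
    if panel.n_variants == 0:
        raise ValueError("empty panel")
    up = locus.upstream_flank
    down = locus.downstream_flank
    left, right = [], []
    for j, v in enumerate(panel.variants):
        if v.chrom != locus.gene.chrom:
            continue
        if inclusive:
            if not af_lo <= v.alt_freq <= af_hi:
                continue
        elif not af_lo < v.alt_freq < af_hi:
            continue
        pos0 = v.pos - 1
        if up.contains_point(pos0):
            left.append(j)
        elif down.contains_point(pos0):
            right.append(j)
    return CandidateVariants(left=tuple(left), right=tuple(right))


def enumerate_excision_pairs(cands: CandidateVariants, locus: LocusModel,
                             panel: PhasedPanel,
                             exclude_on_overlap: bool = False) -> list[SnpPair]:
    """All left x right pairs whose excision span spares protected genes.

    The excision span runs from the left SNP to the right SNP.  By
    construction it contains the whole gene body; a pair is excluded when the
    span fully contains a protected interval (with ``exclude_on_overlap``,
    any overlap disqualifies — the stricter rule for when truncation is also
    unacceptable).  Coverage sets are not yet filled.
    """
    pairs = []
    for li in cands.left:
        for ri in cands.right:
            lpos0 = panel.variants[li].pos - 1
            rpos0 = panel.variants[ri].pos - 1
            span = GenomicInterval(locus.gene.chrom, lpos0, rpos0 + 1)
            bad = False
            for prot in locus.protected:
                if prot.chrom != span.chrom:
                    continue
                if span.contains(prot) or (exclude_on_overlap and span.overlaps(prot)):
                    bad = True
                    break
            if not bad:
                pairs.append(SnpPair(left=li, right=ri, span=span))
    return pairs


def double_het_coverage(panel: PhasedPanel, pair: SnpPair) -> SnpPair:
    """Fill the pair's covered set with samples heterozygous at both SNPs."""
    het = panel.het_mask()
    mask = het[:, pair.left] & het[:, pair.right]
    return SnpPair(left=pair.left, right=pair.right, span=pair.span,
                   covered=frozenset(np.flatnonzero(mask).tolist()))


def het_pair_matrix(panel: PhasedPanel, left: tuple[int, ...] | list[int],
                    right: tuple[int, ...] | list[int]) -> pd.DataFrame:
    """Double-heterozygote percentages for every left x right combination.

    Entry (i, j) = 100 * |double hets for (left_i, right_j)| / N, labelled by
    variant id — the population-coverage heatmap for a guide panel.
    """
    if not len(left) or not len(right):
        raise ValueError("need at least one variant on each side")
    het = panel.het_mask()
    lmat = het[:, list(left)].astype(np.int64)  # (N, L)
    rmat = het[:, list(right)].astype(np.int64)  # (N, R)
    counts = lmat.T @ rmat  # (L, R) double-het counts
    pct = 100.0 * counts / panel.n_samples
    return pd.DataFrame(
        pct,
        index=[panel.variants[i].id for i in left],
        columns=[panel.variants[j].id for j in right],
    )


def ld_r2(panel: PhasedPanel, v1: int, v2: int) -> float:
    """Squared haplotype correlation r^2 between two sites.

    r^2 = (p11 - p1*q1)^2 / (p1(1-p1) q1(1-q1)) over the 2N phased
    haplotypes, where p11 is the frequency of haplotypes carrying the alt
    allele at both sites.  Symmetric and invariant to ref/alt relabelling.
    """
    a = panel.haplotypes[:, v1, :].ravel().astype(float)
    b = panel.haplotypes[:, v2, :].ravel().astype(float)
    p1, q1 = a.mean(), b.mean()
    if p1 in (0.0, 1.0):
        raise MonomorphicVariantError(f"variant {v1} is monomorphic; LD undefined")
    if q1 in (0.0, 1.0):
        raise MonomorphicVariantError(f"variant {v2} is monomorphic; LD undefined")
    p11 = (a * b).mean()
    d = p11 - p1 * q1
    return float(d * d / (p1 * (1 - p1) * q1 * (1 - q1)))
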