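"""Population-haplotype phase inference for private mutations.

A patient carries a private disease mutation plus genotypes at a handful of
common SNPs around the gene.  Which common haplotype the mutation sits on
cannot be read from the genotypes alone, but population haplotype
frequencies resolve it in strong LD: the patient's genotype vector is
decomposed into the most probable pair of known haplotypes, and one
experimentally anchored variant (a SNP whose allele in cis with the mutation
was measured directly, e.g. by allele-specific expression after an
allele-specific edit) picks out which of the two inferred haplotypes carries
the mutation.  The alleles of that haplotype at every other SNP follow.

The diplotype likelihood assumes Hardy–Weinberg pairing of population
haplotypes: P(h1, h2) = 2 f(h1) f(h2) for h1 != h2 and f(h)^2 otherwise.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import PhasedPanel

__all__ = [
    "HaplotypeFrequencyTable",
    "DiplotypeCall",
    "InferenceError",
    "UninformativeAnchorError",
    "haplotype_frequencies",
    "infer_diplotype",
    "propagate_mutation_phase",
]

LOW_CONFIDENCE_THRESHOLD = 0.95


class InferenceError(Exception):
    """No haplotype pair consistent with the genotype has positive weight."""


class UninformativeAnchorError(InferenceError):
    """The anchor allele appears on both inferred haplotypes."""


@dataclass(frozen=True)
class HaplotypeFrequencyTable:
    """Frequencies of haplotype patterns over an ordered variant subset.

    Keys are strings over {0,1} of length ``len(variant_ids)``;
    ``n_haplotypes`` is the number of phased chromosomes counted (2N).
    """

    variant_ids: tuple[str, ...]
    entries: Mapping[str, float]
    n_haplotypes: int

    def __post_init__(self) -> None:
        if not self.variant_ids:
            raise ValueError("empty variant subset")
        width = len(self.variant_ids)
        for key in self.entries:
            if len(key) != width or set(key) - {"0", "1"}:
                raise ValueError(f"bad haplotype key {key!r} for width {width}")
        total = sum(self.entries.values())
        if self.entries and abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    def frequency(self, hap: str) -> float:
        return self.entries.get(hap, 0.0)


@dataclass(frozen=True)
class DiplotypeCall:
    """Ranked genotype-consistent haplotype pairs with posteriors.

    ``ranked`` lists (hap1, hap2, likelihood, posterior) sorted by decreasing
    posterior with a deterministic lexicographic tie-break; ``confidence`` is
    the posterior of the top pair.  ``smoothed`` records whether pseudo-count
    smoothing was needed (no consistent pair of observed haplotypes).
    """

    variant_ids: tuple[str, ...]
    ranked: tuple[tuple[str, str, float, float], ...]
    smoothed: bool = False

    @property
    def best_pair(self) -> tuple[str, str]:
        return self.ranked[0][0], self.ranked[0][1]

    @property
    def confidence(self) -> float:
        return self.ranked[0][3]

    @property
    def low_confidence(self) -> bool:
        return self.confidence < LOW_CONFIDENCE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "variant_ids": list(self.variant_ids),
            "confidence": self.confidence,
            "low_confidence": self.low_confidence,
            "smoothed": self.smoothed,
            "ranked": [
                {"hap1": h1, "hap2": h2, "likelihood": lik, "posterior": post}
                for h1, h2, lik, post in self.ranked
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def haplotype_frequencies(panel: PhasedPanel,
                          subset: Sequence[int]) -> HaplotypeFrequencyTable:
    """Count the 2N phased haplotypes restricted to the given variants."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty variant subset")
    haps = panel.haplotypes[:, subset, :]  # (N, m, 2)
    flat = haps.transpose(0, 2, 1).reshape(-1, len(subset))  # (2N, m)
    counts: dict[str, int] = {}
    for row in flat:
        key = "".join("1" if a else "0" for a in row)
        counts[key] = counts.get(key, 0) + 1
    total = flat.shape[0]
    return HaplotypeFrequencyTable(
        variant_ids=tuple(panel.variants[j].id for j in subset),
        entries={k: c / total for k, c in counts.items()},
        n_haplotypes=total,
    )


def _consistent_pairs(genotype: Sequence[int]) -> list[tuple[str, str]]:
    """All unordered haplotype pairs whose element-wise sum is the genotype."""
    het_sites = [i for i, g in enumerate(genotype) if g == 1]
    base = ["1" if g == 2 else "0" for g in genotype]
    pairs = []
    seen = set()
    for bits in itertools.product("01", repeat=len(het_sites)):
        h1 = list(base)
        h2 = list(base)
        for site, bit in zip(het_sites, bits):
            h1[site] = bit
            h2[site] = "1" if bit == "0" else "0"
        key = tuple(sorted(("".join(h1), "".join(h2))))
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    return pairs


def infer_diplotype(genotype: Sequence[int], table: HaplotypeFrequencyTable,
                    pseudo: float = 1.0) -> DiplotypeCall:
    """Most probable haplotype pair for a genotype, from population
    frequencies.

    Enumerates every unordered pair (h1, h2) with h1 + h2 = genotype;
    likelihood = 2 f(h1) f(h2) (f(h)^2 for homozygous pairing); posteriors
    normalise over consistent pairs.  When no pair of observed haplotypes is
    consistent, frequencies are re-smoothed with pseudo-count ``pseudo``
    spread over the consistent patterns, and the call is flagged.
    """
    genotype = [int(g) for g in genotype]
    if len(genotype) != len(table.variant_ids):
        raise ValueError("genotype length does not match table subset")
    if any(g not in (0, 1, 2) for g in genotype):
        raise ValueError("genotype dosages must be 0, 1 or 2")

    pairs = _consistent_pairs(genotype)

    def score(freq) -> list[tuple[str, str, float]]:
        out = []
        for h1, h2 in pairs:
            f1, f2 = freq(h1), freq(h2)
            lik = f1 * f2 if h1 == h2 else 2.0 * f1 * f2
            out.append((h1, h2, lik))
        return out

    scored = score(table.frequency)
    smoothed = False
    if all(lik == 0.0 for _, _, lik in scored):
        if pseudo <= 0:
            raise InferenceError(
                "no genotype-consistent pair of observed haplotypes and "
                "smoothing disabled")
        smoothed = True
        consistent_haps = sorted({h for pair in pairs for h in pair})
        denom = table.n_haplotypes + pseudo * len(consistent_haps)

        def smooth_freq(h: str) -> float:
            return (table.frequency(h) * table.n_haplotypes + pseudo) / denom

        scored = score(smooth_freq)
        if all(lik == 0.0 for _, _, lik in scored):
            raise InferenceError("smoothing failed to produce a consistent pair")

    total = sum(lik for _, _, lik in scored)
    ranked = sorted(
        ((h1, h2, lik, lik / total) for h1, h2, lik in scored),
        key=lambda t: (-t[3], t[0], t[1]),
    )
    return DiplotypeCall(variant_ids=table.variant_ids, ranked=tuple(ranked),
                         smoothed=smoothed)


def propagate_mutation_phase(call: DiplotypeCall,
                             anchor: tuple[str, int]) -> dict[str, int]:
    """Cis-allele map for the mutation, given one anchored variant.

    ``anchor`` names a variant in the call's subset and the allele known to
    be in cis with the mutation.  The inferred haplotype carrying that allele
    is the mutation's haplotype; its alleles at every subset variant are
    returned.  The anchor must be heterozygous in the top call, otherwise it
    cannot distinguish the two haplotypes.
    """
    anchor_id, anchor_allele = anchor
    if anchor_allele not in (0, 1):
        raise ValueError("anchor allele must be 0 or 1")
    try:
        idx = call.variant_ids.index(anchor_id)
    except ValueError:
        raise KeyError(f"anchor variant {anchor_id!r} not in call subset") from None
    h1, h2 = call.best_pair
    bit = str(anchor_allele)
    if h1[idx] == h2[idx]:
        raise UninformativeAnchorError(
            f"anchor {anchor_id!r} is homozygous in the inferred diplotype; "
            "it cannot identify the mutant haplotype")
    mutant = h1 if h1[idx] == bit else h2
    return {vid: int(mutant[i]) for i, vid in enumerate(call.variant_ids)}
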