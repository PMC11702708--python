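"""Synthetic inputs for every pipeline stage.

Three generators cover the data the toolkit consumes:

* :func:`simulate_panel` — phased population panels with block-structured
  linkage disequilibrium, built from K founder haplotypes copied with
  crossovers.  Two knobs (founder count, per-interval recombination
  probability) span the axis from perfect LD (K=2, no recombination) to
  linkage equilibrium, which is exactly what pair selection and phase
  inference need to be exercised against.
* :func:`simulate_partitions` — multi-channel digital-PCR partition tables
  from Poisson co-loading of molecule species.  Fragmented genomic DNA is
  modelled as independent Poisson counts per molecule species; the excision
  junction is physically linked to the flanking-SNP allele on the same
  molecule, so triple-positive (junction + both alleles) partitions arise
  only through co-loading — the ambiguity the 4-plex estimator excludes.
* :func:`make_guide_test_sequence` — DNA strings with PAM sites planted at
  known offsets on a PAM-free background, for oracle-testing guide
  enumeration.

All generators are pure functions of their configuration (including the
seed): identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import PhasedPanel, Variant
from .dpcr import PartitionTable

__all__ = [
    "PanelSimConfig",
    "CarrierTruth",
    "DpcrSimConfig",
    "simulate_panel",
    "plant_mutation",
    "simulate_partitions",
    "simulate_expression_counts",
    "make_guide_test_sequence",
]


@dataclass(frozen=True)
class PanelSimConfig:
    """Configuration for the founder-mosaic panel simulator.

    ``recombination_prob`` is the probability, per adjacent-SNP interval and
    per transmitted haplotype, that the copying process switches to an
    independently chosen founder.
    """

    n_individuals: int
    left_positions: tuple[int, ...]
    right_positions: tuple[int, ...]
    intragenic_positions: tuple[int, ...] = ()
    founder_count: int = 8
    recombination_prob: float = 0.01
    target_alt_freqs: tuple[float, ...] | float = 0.5
    chrom: str = "chr8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.founder_count < 1:
            raise ValueError("founder_count must be >= 1")
        if not 0.0 <= self.recombination_prob <= 1.0:
            raise ValueError("recombination_prob must lie in [0, 1]")
        positions = self.all_positions
        if len(positions) == 0:
            raise ValueError("no SNP positions configured")
        if not np.all(np.diff(positions) > 0):
            raise ValueError("SNP positions must be strictly increasing within each group "
                             "and groups ordered left < intragenic < right")
        freqs = np.atleast_1d(np.asarray(self.target_alt_freqs, dtype=float))
        if freqs.size not in (1, len(positions)):
            raise ValueError("target_alt_freqs must be scalar or one per SNP")
        if np.any((freqs <= 0.0) | (freqs >= 1.0)):
            raise ValueError("target_alt_freqs must lie strictly inside (0, 1)")

    @property
    def all_positions(self) -> np.ndarray:
        return np.array(
            list(self.left_positions) + list(self.intragenic_positions)
            + list(self.right_positions),
            dtype=np.int64,
        )

    @property
    def freqs(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.target_alt_freqs, dtype=float))
        m = len(self.all_positions)
        return np.full(m, float(f[0])) if f.size == 1 else f


@dataclass(frozen=True)
class CarrierTruth:
    """Ground truth for a simulated mutation carrier: which haplotype bears
    the private mutation and which panel alleles are in cis with it."""

    sample_id: str
    sample_index: int
    position: int
    carrier_haplotype: int
    cis_alleles: dict[str, int]


def _founder_alleles(rng: np.random.Generator, k: int, freq: float) -> np.ndarray:
    """Founder alleles at one SNP with the alt count pinned near k*freq.

    Drawing each founder Bernoulli(freq) independently leaves the panel
    frequency with O(1/sqrt(K)) scatter around the target even for large
    panels; fixing the count (with stochastic rounding of the fractional
    part) keeps realized frequencies close to the target while each founder's
    marginal distribution stays Bernoulli(freq).
    """
    expected = k * freq
    count = int(np.floor(expected))
    if rng.random() < expected - count:
        count += 1
    count = min(max(count, 1), k - 1) if 0 < freq < 1 else count
    alleles = np.zeros(k, dtype=np.int8)
    alleles[rng.choice(k, size=count, replace=False)] = 1
    return alleles


def simulate_panel(config: PanelSimConfig) -> PhasedPanel:
    """Simulate a phased panel from founder haplotypes with crossovers.

    K founder haplotypes are drawn with per-SNP alt frequencies near the
    targets; each of the 2N panel haplotypes is a founder mosaic, switching
    to a freshly chosen founder between adjacent SNPs with probability
    ``recombination_prob``.
    """
    rng = np.random.default_rng(config.seed)
    positions = config.all_positions
    m = len(positions)
    k = config.founder_count
    founders = np.stack(
        [_founder_alleles(rng, k, f) for f in config.freqs], axis=1
    )  # (K, M)

    n_haps = 2 * config.n_individuals
    choice = np.empty((n_haps, m), dtype=np.int64)
    choice[:, 0] = rng.integers(0, k, size=n_haps)
    for j in range(1, m):
        switch = rng.random(n_haps) < config.recombination_prob
        choice[:, j] = np.where(switch, rng.integers(0, k, size=n_haps), choice[:, j - 1])
    haps = founders[choice, np.arange(m)]  # (2N, M)
    haps = haps.reshape(config.n_individuals, 2, m).transpose(0, 2, 1)  # (N, M, 2)

    variants = []
    for j, pos in enumerate(positions):
        ref, alt = ("A", "G") if j % 2 == 0 else ("C", "T")
        variants.append(
            Variant(config.chrom, int(pos), f"snp{j}", ref, alt,
                    float(haps[:, j, :].mean()))
        )
    samples = [f"sim{i:04d}" for i in range(config.n_individuals)]
    return PhasedPanel(variants=variants, samples=samples, haplotypes=haps)


def plant_mutation(panel: PhasedPanel, sample: int, position: int,
                   haplotype: int) -> CarrierTruth:
    """Declare a private mutation on one haplotype of one individual.

    The panel is left untouched — the mutation is private to the carrier and
    never enters population frequencies.  The returned truth record lists the
    panel allele in cis with the mutation at every panel variant, read
    directly off the chosen haplotype.
    """
    if not 0 <= sample < panel.n_samples:
        raise IndexError(f"sample index {sample} out of range")
    if haplotype not in (0, 1):
        raise ValueError("haplotype must be 0 or 1")
    cis = {
        v.id: int(panel.haplotypes[sample, j, haplotype])
        for j, v in enumerate(panel.variants)
    }
    return CarrierTruth(
        sample_id=panel.samples[sample],
        sample_index=sample,
        position=position,
        carrier_haplotype=haplotype,
        cis_alleles=cis,
    )


@dataclass(frozen=True)
class DpcrSimConfig:
    """Configuration for the digital-PCR partition simulator.

    ``lambda_g`` is the mean number of diploid genome-equivalents loaded per
    partition.  ``excision_fraction`` is the fraction of ALL copies of the
    edited gene (both alleles pooled) that carry the excision junction;
    ``specificity`` is the fraction of those excision events that occurred on
    the target allele.  Per-allele event probabilities follow as
    ``p_target = 2*e*s`` and ``p_other = 2*e*(1-s)``.
    """

    n_partitions: int = 8500
    lambda_g: float = 0.1
    excision_fraction: float = 0.0
    inversion_fraction: float = 0.0
    specificity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        if self.lambda_g <= 0:
            raise ValueError("lambda_g must be positive")
        for name in ("excision_fraction", "inversion_fraction", "specificity"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for s_allele in (self.specificity, 1.0 - self.specificity):
            if 2 * (self.excision_fraction + self.inversion_fraction) * s_allele > 1.0:
                raise ValueError(
                    "per-allele excision + inversion probability exceeds 1; "
                    "reduce fractions or move specificity toward 0.5"
                )


CHANNEL_TARGET = "target_allele"
CHANNEL_OTHER = "other_allele"
CHANNEL_EXCISION = "excision"
CHANNEL_INVERSION = "inversion"
CHANNEL_REFERENCE = "reference"

FOURPLEX_CHANNELS = (CHANNEL_TARGET, CHANNEL_OTHER, CHANNEL_EXCISION, CHANNEL_REFERENCE)


def simulate_partitions(config: DpcrSimConfig,
                        include_inversion: bool = False) -> PartitionTable:
    """Simulate a multi-channel digital-PCR partition table.

    Molecule species load independently as Poisson counts (fragmented gDNA):
    each allele of the edited gene at rate ``lambda_g`` per partition, split
    by edit state, and the 2-copy reference assay at ``2*lambda_g``.  Channel
    calls: allele channels fire on any intact or excised molecule bearing
    that allele (the junction stays linked to its flanking SNP); the excision
    channel fires on any excised molecule of either allele; the reference
    channel on any reference molecule.  With ``include_inversion`` a fifth
    channel fires on inversion-junction molecules.
    """
    rng = np.random.default_rng(config.seed)
    e, inv, s = config.excision_fraction, config.inversion_fraction, config.specificity
    lam = config.lambda_g
    n = config.n_partitions

    # per-allele edit-state probabilities (see DpcrSimConfig docstring)
    p_exc = {"t": 2 * e * s, "o": 2 * e * (1 - s)}
    p_inv = {"t": 2 * inv * s, "o": 2 * inv * (1 - s)}

    counts: dict[str, np.ndarray] = {}
    for allele in ("t", "o"):
        p_int = 1.0 - p_exc[allele] - p_inv[allele]
        counts[f"{allele}_intact"] = rng.poisson(lam * p_int, size=n)
        counts[f"{allele}_excised"] = rng.poisson(lam * p_exc[allele], size=n)
        counts[f"{allele}_inverted"] = rng.poisson(lam * p_inv[allele], size=n)
    counts["reference"] = rng.poisson(2 * lam, size=n)

    channel_pos = {
        CHANNEL_TARGET: (counts["t_intact"] + counts["t_excised"]) > 0,
        CHANNEL_OTHER: (counts["o_intact"] + counts["o_excised"]) > 0,
        CHANNEL_EXCISION: (counts["t_excised"] + counts["o_excised"]) > 0,
        CHANNEL_REFERENCE: counts["reference"] > 0,
    }
    channels = list(FOURPLEX_CHANNELS)
    if include_inversion:
        channel_pos[CHANNEL_INVERSION] = (counts["t_inverted"] + counts["o_inverted"]) > 0
        channels.append(CHANNEL_INVERSION)

    matrix = np.stack([channel_pos[c] for c in channels], axis=1)
    return PartitionTable.from_boolean_matrix(channels, matrix)


def simulate_expression_counts(
    n_partitions: int,
    lambda_target: float,
    lambda_reference: float,
    seed: int = 0,
) -> tuple[int, int, int]:
    """Two-channel expression assay: (target positives, reference positives, n).

    Target transcripts and reference-gene transcripts load as independent
    Poisson counts; a heterozygote with one silenced allele halves
    ``lambda_target`` relative to its unedited control.
    """
    rng = np.random.default_rng(seed)
    t = int((rng.poisson(lambda_target, size=n_partitions) > 0).sum())
    r = int((rng.poisson(lambda_reference, size=n_partitions) > 0).sum())
    return t, r, n_partitions


# --- guide-design test sequences ------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def make_guide_test_sequence(
    length: int,
    planted_pams: Sequence[tuple[int, str]],
    snp_offset: int,
    alleles: tuple[str, str] = ("A", "G"),
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """A DNA string whose only NGG/CCN PAM sites are the planted ones.

    ``planted_pams`` lists ``(pam_start, strand)`` with 0-based ``pam_start``
    at the first PAM base in genome coordinates ('+': NGG forward; '-': CCN,
    i.e. an NGG on the reverse strand).  The sequence carries the ref allele
    at ``snp_offset``.  Returns the sequence and a ground-truth list of
    planted protospacer records for oracle tests.

    Raises ValueError for placements that collide, leave no room for a 20-nt
    protospacer, or force an unintended PAM.
    """
    rng = np.random.default_rng(seed)
    ref, alt = alleles
    bases = "ACGT"

    # background free of GG and CC dinucleotides => no NGG on either strand
    seq = []
    for i in range(length):
        forbidden = set()
        if seq:
            if seq[-1] == "G":
                forbidden.add("G")
            if seq[-1] == "C":
                forbidden.add("C")
        choices = [b for b in bases if b not in forbidden]
        seq.append(choices[rng.integers(0, len(choices))])

    def set_base(i: int, b: str) -> None:
        if not 0 <= i < length:
            raise ValueError(f"planted site runs outside sequence (index {i})")
        seq[i] = b

    truth: list[dict] = []
    for pam_start, strand in planted_pams:
        if strand == "+":
            if pam_start < 20 or pam_start + 3 > length:
                raise ValueError("forward PAM needs 20 nt upstream and 3 nt of PAM room")
            set_base(pam_start + 1, "G")
            set_base(pam_start + 2, "G")
            if seq[pam_start] == "G":  # would shift the GG window left
                set_base(pam_start, "A")
            if pam_start + 3 < length and seq[pam_start + 3] == "G":
                set_base(pam_start + 3, "A")
        elif strand == "-":
            if pam_start + 3 + 20 > length or pam_start < 0:
                raise ValueError("reverse PAM needs 20 nt downstream and 3 nt of PAM room")
            set_base(pam_start, "C")
            set_base(pam_start + 1, "C")
            if seq[pam_start + 2] == "C":
                set_base(pam_start + 2, "T")
            if pam_start - 1 >= 0 and seq[pam_start - 1] == "C":
                set_base(pam_start - 1, "T")
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    if not 0 <= snp_offset < length:
        raise ValueError("snp_offset outside sequence")
    set_base(snp_offset, ref)
    # the ref allele must not create a stray GG/CC outside planted PAMs
    sequence = "".join(seq)
    planted_windows = {(p, s) for p, s in planted_pams}
    for i in range(length - 1):
        pair = sequence[i:i + 2]
        if pair == "GG" and (i - 1, "+") not in planted_windows:
            raise ValueError("placement forces an unintended forward PAM; "
                             "move snp_offset or planted sites")
        if pair == "CC" and (i, "-") not in planted_windows:
            raise ValueError("placement forces an unintended reverse PAM")

    for pam_start, strand in planted_pams:
        if strand == "+":
            proto = sequence[pam_start - 20:pam_start]
            pam = sequence[pam_start:pam_start + 3]
        else:
            proto = _revcomp(sequence[pam_start + 3:pam_start + 23])
            pam = _revcomp(sequence[pam_start:pam_start + 3])
        truth.append({"pam_start": pam_start, "strand": strand,
                      "protospacer": proto, "pam": pam})
    return sequence, truth
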