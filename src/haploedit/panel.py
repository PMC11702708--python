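"""Phased population panels, genomic loci, and VCF input/output.

The central container is :class:`PhasedPanel`: N diploid individuals typed at
M biallelic SNPs, stored as an ``(N, M, 2)`` array of allele indices (0 = ref,
1 = alt) with phase preserved — haplotype 0 and haplotype 1 of each individual
are the two slices along the last axis.  Everything downstream (double-
heterozygote coverage, LD, haplotype frequency tables) is computed from this
array; allele frequencies are always recomputed from it rather than trusted
from VCF INFO fields, so the coverage arithmetic is internally consistent.

Coordinate conventions: VCF positions are 1-based; every internal interval is
0-based half-open.  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


class PanelError(Exception):
    """Base class for panel construction problems."""


class EmptyPanelError(PanelError):
    """The VCF yielded no usable biallelic phased SNP records."""


class PhasingError(PanelError):
    """An unphased genotype was encountered in strict mode."""


class GenotypeClass(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with its panel-derived alternate-allele frequency."""

    chrom: str
    pos: int  # 1-based, as printed in VCF
    id: str
    ref: str
    alt: str
    alt_freq: float

    def __post_init__(self) -> None:
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValueError(f"alleles must be single nucleotides, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"alt_freq out of range: {self.alt_freq}")
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies fully inside this interval (same chromosome)."""
        self._check_chrom(other)
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        self._check_chrom(other)
        return self.start < other.end and other.start < self.end

    def _check_chrom(self, other: "GenomicInterval") -> None:
        if self.chrom != other.chrom:
            raise ValueError(
                f"interval comparison across chromosomes: {self.chrom} vs {other.chrom}"
            )


@dataclass(frozen=True)
class LocusModel:
    """A target gene, the neighbouring intervals that must not be excised,
    and the flank width searched for excision SNPs on each side."""

    gene: GenomicInterval
    protected: tuple[GenomicInterval, ...] = ()
    flank_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")
        object.__setattr__(self, "protected", tuple(self.protected))

    @property
    def upstream_flank(self) -> GenomicInterval:
        """[gene.start - flank_bp, gene.start), clipped at 0."""
        return GenomicInterval(
            self.gene.chrom, max(0, self.gene.start - self.flank_bp), self.gene.start
        )

    @property
    def downstream_flank(self) -> GenomicInterval:
        return GenomicInterval(self.gene.chrom, self.gene.end, self.gene.end + self.flank_bp)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LocusModel":
        """Load a locus configuration.

        Expected keys: ``gene: {chrom, start, end}``, optional
        ``protected: [{chrom, start, end}, ...]``, optional ``flank_bp``.
        Coordinates in the file are 0-based half-open.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        gene = GenomicInterval(str(cfg["gene"]["chrom"]), int(cfg["gene"]["start"]),
                               int(cfg["gene"]["end"]))
        protected = tuple(
            GenomicInterval(str(p["chrom"]), int(p["start"]), int(p["end"]))
            for p in cfg.get("protected", [])
        )
        return cls(gene=gene, protected=protected, flank_bp=int(cfg.get("flank_bp", 50_000)))


@dataclass
class PhasedPanel:
    """N individuals x M biallelic SNPs x 2 phased haplotypes.

    ``haplotypes[i, j, k]`` is the allele index (0 ref / 1 alt) carried by
    haplotype ``k`` of sample ``i`` at variant ``j``.
    """

    variants: list[Variant]
    samples: list[str]
    haplotypes: np.ndarray
    skipped_records: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n, m = len(self.samples), len(self.variants)
        if self.haplotypes.shape != (n, m, 2):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"{n} samples x {m} variants x 2"
            )
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        """1-based positions of all variants."""
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def dosages(self, sample: int) -> np.ndarray:
        """Per-variant alt-allele dosage (0/1/2) for one sample."""
        return self.haplotypes[sample].sum(axis=1).astype(np.int8)

    def het_mask(self) -> np.ndarray:
        """Boolean (N, M) matrix: True where the sample is heterozygous."""
        return self.haplotypes[:, :, 0] != self.haplotypes[:, :, 1]

    def summary_frame(self):
        """Per-variant summary table: id, pos, alt_freq, het count."""
        import pandas as pd

        het = self.het_mask().sum(axis=0) if self.n_samples else np.zeros(self.n_variants, int)
        return pd.DataFrame(
            {
                "id": [v.id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "alt_freq": [v.alt_freq for v in self.variants],
                "n_het": het,
            }
        )

    def write_summary_tsv(self, path: str | Path) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False)


def alt_allele_frequency(panel: PhasedPanel, index: int) -> float:
    """Alternate-allele frequency at one variant: mean over the 2N phased alleles."""
    if not 0 <= index < panel.n_variants:
        raise IndexError(f"variant index {index} out of range [0, {panel.n_variants})")
    return float(panel.haplotypes[:, index, :].mean())


def genotype_class(panel: PhasedPanel, sample: int, variant: int) -> GenotypeClass:
    """Classify one genotype as hom_ref / het / hom_alt."""
    if not 0 <= sample < panel.n_samples:
        raise IndexError(f"sample index {sample} out of range")
    if not 0 <= variant < panel.n_variants:
        raise IndexError(f"variant index {variant} out of range")
    a, b = panel.haplotypes[sample, variant]
    if a != b:
        return GenotypeClass.HET
    return GenotypeClass.HOM_ALT if a == 1 else GenotypeClass.HOM_REF


def _recompute_variants(variants: list[Variant], haplotypes: np.ndarray) -> list[Variant]:
    out = []
    for j, v in enumerate(variants):
        freq = float(haplotypes[:, j, :].mean()) if haplotypes.size else 0.0
        out.append(Variant(v.chrom, v.pos, v.id, v.ref, v.alt, freq))
    return out


def read_phased_vcf(
    path: str | Path,
    region: GenomicInterval | None = None,
    strict: bool = True,
) -> PhasedPanel:
    """Read fully phased biallelic SNPs from a VCF into a :class:`PhasedPanel`.

    Multi-allelic records, indels/MNPs, and records with missing genotypes are
    skipped and counted.  Unphased genotypes raise :class:`PhasingError` in
    strict mode (the default); with ``strict=False`` the record is skipped
    instead.  Alt-allele frequencies are recomputed from the returned
    haplotypes, never read from INFO.

    ``region`` uses the package's 0-based half-open convention; a tabix index
    is used when available, otherwise the file is scanned and filtered.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad paths
        raise OSError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    record_iter: Iterable = vcf
    manual_filter = False
    if region is not None:
        has_index = Path(path + ".tbi").exists() or Path(path + ".csi").exists()
        if has_index:
            record_iter = vcf(f"{region.chrom}:{region.start + 1}-{region.end}")
        else:
            manual_filter = True  # no index; scan the whole file

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for rec in record_iter:
        if manual_filter and region is not None:
            if rec.CHROM != region.chrom or not region.contains_point(rec.POS - 1):
                continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        if rec.REF not in _NUCLEOTIDES or rec.ALT[0] not in _NUCLEOTIDES:
            skipped += 1
            continue
        gts = rec.genotypes  # per sample: [allele0, allele1, phased]
        col = np.empty((len(samples), 2), dtype=np.int8)
        ok = True
        for i, gt in enumerate(gts):
            if len(gt) < 3 or gt[0] < 0 or gt[1] < 0:
                ok = False  # missing or haploid
                break
            if not gt[2]:
                if strict:
                    raise PhasingError(
                        f"unphased genotype for sample {samples[i]!r} at "
                        f"{rec.CHROM}:{rec.POS} ({rec.ID or '.'})"
                    )
                ok = False
                break
            col[i, 0], col[i, 1] = gt[0], gt[1]
        if not ok:
            skipped += 1
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        variants.append(Variant(rec.CHROM, rec.POS, vid, rec.REF, rec.ALT[0], 0.0))
        columns.append(col)

    if not variants:
        raise EmptyPanelError(f"no usable phased biallelic SNP records in {path!r}")
    haps = np.stack(columns, axis=1)  # (N, M, 2)
    variants = _recompute_variants(variants, haps)
    if skipped:
        logger.info("read_phased_vcf: skipped %d record(s) in %s", skipped, path)
    return PhasedPanel(variants=variants, samples=samples, haplotypes=haps,
                       skipped_records=skipped)


def write_phased_vcf(panel: PhasedPanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF with phased GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({v.chrom for v in panel.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j, v in enumerate(panel.variants):
            gts = "\t".join(
                f"{panel.haplotypes[i, j, 0]}|{panel.haplotypes[i, j, 1]}"
                for i in range(panel.n_samples)
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def subset_panel(panel: PhasedPanel, *, samples: Sequence[int] | None = None,
                 variants: Sequence[int] | None = None) -> PhasedPanel:
    """Panel restricted to the given sample and/or variant indices, with
    allele frequencies recomputed on the subset."""
    s_idx = np.arange(panel.n_samples) if samples is None else np.asarray(samples)
    v_idx = np.arange(panel.n_variants) if variants is None else np.asarray(variants)
    haps = panel.haplotypes[np.ix_(s_idx, v_idx)]
    new_variants = _recompute_variants([panel.variants[j] for j in v_idx], haps)
    return PhasedPanel(
        variants=new_variants,
        samples=[panel.samples[i] for i in s_idx],
        haplotypes=haps,
    )
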