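import numpy as np
import pytest

from haploedit.panel import PhasedPanel, Variant


def make_panel(haps, chrom="chr8", positions=None, ids=None):
    """Build a PhasedPanel directly from an (N, M, 2) allele array."""
    haps = np.asarray(haps, dtype=np.int8)
    n, m, _ = haps.shape
    positions = positions if positions is not None else [100 * (j + 1) for j in range(m)]
    ids = ids if ids is not None else [f"v{j}" for j in range(m)]
    variants = [
        Variant(chrom, int(positions[j]), ids[j], "A", "G",
                float(haps[:, j, :].mean()))
        for j in range(m)
    ]
    return PhasedPanel(variants=variants,
                       samples=[f"s{i}" for i in range(n)],
                       haplotypes=haps)


def panel_from_haplotype_counts(counts):
    """Panel whose 2N haplotypes realise exact two-locus counts.

    ``counts`` maps (allele1, allele2) -> number of haplotypes; haplotypes
    are paired into individuals in order.
    """
    haps = []
    for (a, b), k in counts.items():
        haps.extend([(a, b)] * k)
    haps = np.array(haps, dtype=np.int8)
    assert len(haps) % 2 == 0, "need an even number of haplotypes"
    arr = haps.reshape(-1, 2, 2).transpose(0, 2, 1)  # (N, M=2, 2)
    return make_panel(arr)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def write_vcf(path, lines, samples=("s0", "s1", "s2")):
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr8>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header + list(lines)) + "\n")
    return path
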