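import numpy as np
import pytest

from hetdissect.ld_panel import HaplotypePanel
from hetdissect.simulate import demo_config, simulate_study


@pytest.fixture
def tiny_panel() -> HaplotypePanel:
    """Six haplotypes, four SNPs, hand-written columns (f = 0.5 each)."""
    haps = np.array(
        [
            # m1 m2 m3 m4
            [1, 1, 1, 1],
            [1, 0, 1, 0],
            [0, 0, 1, 1],
            [0, 0, 0, 0],
            [1, 1, 0, 1],
            [0, 1, 0, 0],
        ],
        dtype=np.uint8,
    )
    return HaplotypePanel(
        marker_ids=["m1", "m2", "m3", "m4"],
        chroms=["1", "1", "1", "2"],
        positions=np.array([100, 200, 300, 100]),
        alleles=[("G", "A"), ("T", "C"), ("T", "A"), ("G", "A")],
        haplotypes=haps,
    )


@pytest.fixture(scope="session")
def demo_study():
    """Small six-locus study (two loci carry a planted secondary effect)."""
    return simulate_study(demo_config(seed=7))


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1|1\t0|0
1\t300\trs3\tA\tC\t.\tPASS\t.\tGT\t0|0\t1|0
"""

LEGEND_TEXT = """\
rs position 0 1
rs1 100 G A
rs2 200 C T
rs3 300 A C
"""

# haplotype order matches the VCF: S1|a, S1|b, S2|a, S2|b
PHASED_TEXT = """\
1 1 0
0 1 0
0 0 1
1 0 0
"""

SAMPLE_TEXT = "S1\nS2\n"


@pytest.fixture
def vcf_panel_path(tmp_path):
    path = tmp_path / "panel.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture
def hapmap_panel_prefix(tmp_path):
    prefix = tmp_path / "ceu_chr1"
    (tmp_path / "ceu_chr1_legend.txt").write_text(LEGEND_TEXT)
    (tmp_path / "ceu_chr1_phased").write_text(PHASED_TEXT)
    (tmp_path / "ceu_chr1_sample.txt").write_text(SAMPLE_TEXT)
    return prefix
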