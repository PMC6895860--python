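from __future__ import annotations

import numpy as np
import pytest

from finemap_array.panels import GenotypePanel
from finemap_array.records import VariantKey


def write_text(path, text: str) -> str:
    path.write_text(text)
    return str(path)


PHASED_VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
"""

UNPHASED_VCF = PHASED_VCF.replace("|", "/")

MULTIALLELIC_VCF = """##fileformat=VCFv4.2
##contig=<ID=2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
2\t500\t.\tG\tA,T\t.\tPASS\t.\tGT\t0|1\t2|0
2\t900\t.\tA\tC\t.\tPASS\t.\tGT\t1|0\t0|0
"""


@pytest.fixture
def phased_vcf(tmp_path):
    return write_text(tmp_path / "phased.vcf", PHASED_VCF)


@pytest.fixture
def unphased_vcf(tmp_path):
    return write_text(tmp_path / "unphased.vcf", UNPHASED_VCF)


@pytest.fixture
def multiallelic_vcf(tmp_path):
    return write_text(tmp_path / "multi.vcf", MULTIALLELIC_VCF)


def make_panel(
    population: str,
    planted: dict[VariantKey, np.ndarray],
    phased: bool = True,
) -> GenotypePanel:
    """Panel from explicit haplotype columns (all equal length, even)."""
    keys = list(planted)
    haps = np.column_stack([planted[k] for k in keys]).astype(np.int8)
    panel = GenotypePanel.from_haplotypes(population, keys, haps)
    return panel if phased else panel.to_unphased()


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """One full synthetic study shared by pipeline-level tests."""
    from finemap_array.synthetic import FixtureSpec, generate_study

    root = tmp_path_factory.mktemp("study")
    return generate_study(FixtureSpec(seed=0), root)


@pytest.fixture(scope="session")
def default_result(default_study):
    from finemap_array.pipeline import PipelineConfig, run_design

    config = PipelineConfig.from_yaml(default_study.config)
    return run_design(config)
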