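import numpy as np
import pandas as pd
import pytest

from popgenkit import SampleFrame, SimParams, VariantTable, simulate_dataset


def make_table(genotypes, contigs=None, positions=None, depths=None, sample_ids=None):
    """Small hand-rolled VariantTable from a nested list of dosages."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_loci, n_samples = g.shape
    if contigs is None:
        contigs = ["c1"] * n_loci
    if positions is None:
        positions = list(range(1, n_loci + 1))
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    loci = pd.DataFrame(
        {
            "contig": contigs,
            "pos": positions,
            "ref": ["A"] * n_loci,
            "alt": ["G"] * n_loci,
        }
    )
    return VariantTable(
        loci=loci,
        genotypes=g,
        sample_ids=sample_ids,
        depths=None if depths is None else np.asarray(depths),
    )


@pytest.fixture(scope="session")
def study_dataset():
    """A study-shaped simulated dataset: 3 clusters, 17 sites, 89 samples."""
    params = SimParams(n_loci=600, seed=42)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def spiked_dataset():
    """Dataset with all artifact classes spiked, for cascade tests."""
    params = SimParams(
        n_loci=400,
        n_outlier_loci=15,
        n_paralog_loci=15,
        n_ld_copies=10,
        seed=7,
    )
    return simulate_dataset(params)


@pytest.fixture()
def tiny_vcf(tmp_path):
    """A 3-record VCF with one triallelic site and one missing genotype."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
ctg1\t10\t.\tA\tG\t.\t.\t.\tGT:DP\t0/0:12\t0/1:15\t1/1:9
ctg1\t50\t.\tC\tT,G\t.\t.\t.\tGT:DP\t0/1:20\t0/2:20\t1/2:20
ctg2\t5\t.\tG\tA\t.\t.\t.\tGT:DP\t./.:0\t0/1:30\t0/0:22
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
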