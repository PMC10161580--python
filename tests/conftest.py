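import numpy as np
import pandas as pd
import pytest

from countqtl.expression import CountMatrix
from countqtl.genotypes import GenotypeMatrix

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Site read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


@pytest.fixture
def make_vcf(tmp_path):
    """Factory writing a small plain-text VCF and returning its path."""

    def _make(records, samples=("s1", "s2", "s3"), name="test.vcf"):
        path = tmp_path / name
        lines = [VCF_HEADER.format(samples="\t".join(samples))]
        for rec in records:
            lines.append("\t".join(str(x) for x in rec) + "\n")
        path.write_text("".join(lines))
        return str(path)

    return _make


def toy_genotype_matrix(codes, depth=100, samples=None):
    """GenotypeMatrix straight from a codes array (no VCF round trip)."""
    codes = np.asarray(codes, dtype=np.int8)
    n_var, n_samp = codes.shape
    samples = samples or [f"s{j}" for j in range(n_samp)]
    sites = pd.DataFrame({
        "chrom": "1",
        "pos": np.arange(1, n_var + 1) * 1000,
        "id": [f"v{i}" for i in range(n_var)],
        "ref": "A",
        "alt": "G",
        "depth": depth,
    })
    return GenotypeMatrix(sites=sites, samples=list(samples), codes=codes)


def toy_count_matrix(counts, lengths=None, biotype="protein_coding", samples=None):
    counts = np.asarray(counts)
    n_genes, n_samp = counts.shape
    genes = pd.DataFrame({
        "id": [f"g{i}" for i in range(n_genes)],
        "chrom": "1",
        "start": np.arange(n_genes) * 10_000 + 1,
        "end": np.arange(n_genes) * 10_000 + 5_000,
        "exonic_length": lengths if lengths is not None else 1_000,
        "biotype": biotype,
    })
    samples = samples or [f"s{j}" for j in range(n_samp)]
    return CountMatrix(genes=genes, samples=list(samples), counts=counts)
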