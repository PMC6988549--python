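import numpy as np
import pytest

from popstruct import (GenotypeMatrix, SimConfig, simulate_dataset)

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
scf1\t101\tsnpA\tA\tG\t99\tPASS\t.\tGT:DP:GQ\t0/1:20:80\t0/0:15:60\t1/1:30:90
scf1\t202\tsnpB\tC\tT\t87\tPASS\t.\tGT:DP:GQ\t./.:2:10\t0|1:25:70\t1/1:18:55
"""

# extra records: multi-allelic, indel, half-call
TOY_VCF_EXTENDED = TOY_VCF + """\
scf2\t300\tsnpC\tG\tA,T\t50\tPASS\t.\tGT:DP:GQ\t0/1:20:80\t0/2:20:80\t0/0:20:80
scf2\t400\tindelD\tGT\tG\t70\tPASS\t.\tGT:DP:GQ\t0/0:20:80\t0/1:20:80\t1/1:20:80
scf2\t500\tsnpE\tT\tC\t95\tPASS\t.\tGT:DP:GQ\t./1:20:80\t0/0:20:80\t0/1:20:80
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_vcf_extended(tmp_path):
    p = tmp_path / "toy_ext.vcf"
    p.write_text(TOY_VCF_EXTENDED)
    return p


def make_gm(codes, ref=None, alt=None):
    """Build a GenotypeMatrix from a plain code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=[f"l{j}" for j in range(m)],
        codes=codes,
        ref_allele=np.array(ref if ref is not None else ["A"] * m, dtype=object),
        alt_allele=np.array(alt if alt is not None else ["G"] * m, dtype=object),
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with clear structure, shared across tests."""
    cfg = SimConfig(n_loci=300, individuals_per_locality=12, fst_target=0.05,
                    seed=7)
    return cfg, simulate_dataset(cfg)
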