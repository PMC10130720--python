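"""Shared fixtures: a default synthetic study and its GRM, plus toy inputs."""

from __future__ import annotations

import numpy as np
import pytest

from wildqg.genotypes import impute_missing
from wildqg.relatedness import vanraden_grm
from wildqg.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default-design synthetic study (6 x 40 plants, 5 flowers, 2000 SNPs)."""
    return simulate_study(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def grm(study):
    return vanraden_grm(impute_missing(study.genotypes))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tindA\tindB\tindC
1\t100\tsnp1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\tsnp2\tA\tC,G\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t300\tsnp3\tG\tT\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    """3 samples, 2 biallelic sites and 1 triallelic site (to be skipped)."""
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture()
def toy_dosage_tsv(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(
        "individual_id\tsite\tsnp1\tsnp2\tsnp3\n"
        "indA\tsite1\t0\t2\tNA\n"
        "indB\tsite1\t1\t1\t0\n"
        "indC\tsite2\t2\t0\t1\n"
    )
    return path
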