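"""Shared fixtures: tiny on-disk inputs and small simulated cohorts."""

from __future__ import annotations

import textwrap

import pandas as pd
import pytest

from xciase.io import GeneAnnotation, annotate_par
from xciase.simulate import SimConfig, simulate_dataset


@pytest.fixture
def tiny_vcf(tmp_path):
    """Four sites: chrX het PASS, chrX hom, chr7 het, chrX multi-allelic."""
    text = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=chrX>
        ##contig=<ID=chr7>
        ##FILTER=<ID=PASS,Description="pass">
        ##FILTER=<ID=lowqual,Description="fail">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tdonor1\tdonor2
        chrX\t1000\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:12,15\t0/0:30,0
        chrX\t2000\t.\tC\tT\t.\tlowqual\t.\tGT:AD\t0/1:9,11\t0/1:8,8
        chrX\t3000\t.\tG\tA,C\t.\tPASS\t.\tGT:AD\t0/1:5,6,0\t0/1:4,4,1
        chr7\t4000\t.\tT\tC\t.\tPASS\t.\tGT:AD\t0/1:20,22\t0/1:10,12
        """)
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def count_table(tmp_path):
    path = tmp_path / "counts.tsv"
    pd.DataFrame({
        "contig": ["chrX", "chrX"],
        "position": [1000, 2000],
        "refAllele": ["A", "C"],
        "altAllele": ["G", "T"],
        "refCount": [90, 40],
        "altCount": [10, 50],
        "totalCount": [100, 92],
    }).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def genes():
    """Three annotated genes: one PAR1, two nonPAR (one prior-variable)."""
    return [
        annotate_par(GeneAnnotation("PARG1", "PARG1", "chrX", 200_000, 210_000)),
        annotate_par(GeneAnnotation("GENE1", "GENE1", "chrX", 49_990_000, 50_010_000)),
        annotate_par(GeneAnnotation("VARG1", "VARG1", "chrX", 60_000_000, 60_020_000,
                                    prior_status="variable")),
    ]


@pytest.fixture(scope="session")
def small_detailed_sim():
    """One nmXCI donor, 5 tissues, 80 genes; shared across read-only tests."""
    cfg = SimConfig(n_donors=1, n_nmxci=1, tissues=5, screen_tissue_mix=False,
                    n_genes=80, seed=11)
    return simulate_dataset(cfg)
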