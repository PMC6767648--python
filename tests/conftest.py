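"""Shared fixtures: a hand-written toy panel and a small synthetic cohort."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from avadx import CohortConfig, GeneScoreMatrix, generate_cohort

DATA_DIR = Path(__file__).parent / "data"

# A hand-written multi-sample VCF exercising: multi-allelic split, chrX,
# non-PASS filters, missing genotype calls, and a "chr" prefix.
TOY_VCF = """\
##fileformat=VCFv4.2
##FILTER=<ID=q10,Description="Low quality">
##contig=<ID=1>
##contig=<ID=2>
##contig=<ID=X>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tB1\tB2
1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t0/0
1\t200\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\t1/2
1\t300\t.\tTA\tT\t.\tq10\t.\tGT\t0/1\t0/0\t0/0\t0/1
2\t400\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0
X\t500\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\t0/0
2\t600\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\t0/1
"""

TOY_PHENO = """\
individual_id\tstatus\tfamily_id\tbatch_id
A1\tCD\tA1\tB1
A2\tCD\tA2\tB1
B1\tHC\tB1\tB1
B2\tHC\tB2\tB1
"""

# annotation covers every toy locus except 2:400 (left unannotated on
# purpose) and includes a multi-gene variant and a score-less nonsynonymous
TOY_ANNO = """\
chrom\tpos\tref\talt\tgene\tconsequence\teffect_score
1\t100\tA\tG\tGENE1\tnonsynonymous\t50
1\t200\tC\tT\tGENE1\tsynonymous\t
1\t200\tC\tG\tGENE2\tnonsynonymous\t-30
1\t300\tTA\tT\tGENE2\tindel\t
X\t500\tT\tC\tGENE3\tsynonymous\t
2\t600\tA\tC\tGENE3\tnonsynonymous\t
2\t600\tA\tC\tGENE4\tnonsynonymous\t
"""


@pytest.fixture()
def toy_files(tmp_path):
    vcf = tmp_path / "toy.vcf"
    pheno = tmp_path / "pheno.tsv"
    anno = tmp_path / "anno.tsv"
    vcf.write_text(TOY_VCF)
    pheno.write_text(TOY_PHENO)
    anno.write_text(TOY_ANNO)
    return vcf, pheno, anno


@pytest.fixture(scope="session")
def small_cohort():
    """A small strong-signal synthetic cohort shared by fast tests."""
    return generate_cohort(
        CohortConfig(seed=13, n_cases=20, n_controls=20, n_genes=200,
                     n_causal=4, n_families=1)
    )


@pytest.fixture(scope="session")
def study_cohort():
    """Default-size cohort (60/60, 2000 genes, 10 causal)."""
    return generate_cohort(CohortConfig(seed=7))


def matrix_from_array(x, prefix="g"):
    """Helper: wrap a 2-D array into a GeneScoreMatrix with generic names."""
    x = np.asarray(x, dtype=float)
    return GeneScoreMatrix(
        scores=pd.DataFrame(
            x,
            index=[f"ind{i}" for i in range(x.shape[0])],
            columns=[f"{prefix}{j}" for j in range(x.shape[1])],
        )
    )
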