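import numpy as np
import pytest

import sebpanel as sp
from sebpanel.model import GenotypeMatrix, GroupLabels, LocusInfo


@pytest.fixture(scope="session")
def clean_cohort():
    """Default 4-group cohort, no missing calls, no genotyping error."""
    config = sp.SimulationConfig(seed=11)
    return sp.simulate_cohort(config)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Same structure with missing calls and rare genotyping errors."""
    config = sp.SimulationConfig(missing_rate=0.05, error_rate=0.01, seed=12)
    return sp.simulate_cohort(config)


TOY_VCF = "\n".join(
    [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=30000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
        "chr1\t100\tsnp1\tC\tT\t900\t.\t.\tGT:DP\t0/0:30\t0/1:25\t./.:0",
        "chr1\t200\tsnp2\tA\tG\t300\t.\t.\tGT:DP\t1|1:12\t0/0:18\t./1:22",
    ]
) + "\n"


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


def matrix_from_rows(rows, group_of=None, locus_prefix="L", quals=None,
                     contigs=None, positions=None):
    """Small-matrix builder for hand-written cases.

    *rows*: dict individual -> list of genotype tokens ("CT", "NN", ...).
    """
    individuals = list(rows)
    n_loci = len(next(iter(rows.values())))
    tokens = [rows[ind] for ind in individuals]
    loci = []
    for j in range(n_loci):
        observed = sorted(
            {a for row in tokens for a in row[j] if a in "ACGT"}
        ) or ["A"]
        loci.append(
            LocusInfo(
                id=f"{locus_prefix}{j + 1}",
                contig=contigs[j] if contigs else f"c{j + 1}",
                position=positions[j] if positions else j + 1,
                ref=observed[0],
                alts=tuple(observed[1:]),
                qual=quals[j] if quals else 1000.0,
            )
        )
    matrix = GenotypeMatrix.from_calls(individuals, loci, tokens)
    if group_of is None:
        return matrix
    return matrix, GroupLabels({ind: group_of(ind) for ind in individuals})
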