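import numpy as np
import pytest

from allofound.io_core import MISSING, GenotypeTable


def make_table(
    positions,
    calls,
    alleles=None,
    het_flags=None,
    contig="chr1",
    accessions=None,
    aligned_length=None,
    population="test",
):
    """Small helper: build a GenotypeTable from plain lists."""
    calls = np.asarray(calls, dtype=np.int16)
    n_sites, n_acc = calls.shape
    if alleles is None:
        alleles = [("A", "T") for _ in range(n_sites)]
    if accessions is None:
        accessions = [f"acc{j}" for j in range(n_acc)]
    return GenotypeTable(
        contig=contig,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=list(alleles),
        calls=calls,
        het_flags=het_flags,
        accessions=list(accessions),
        population=population,
        aligned_length=aligned_length,
    )


@pytest.fixture
def toy_table():
    """3 sites x 3 accessions with one missing and one het call."""
    het = np.zeros((3, 3), dtype=bool)
    het[1, 0] = True
    return make_table(
        positions=[10, 20, 30],
        calls=[[0, 0, 1], [1, 0, 0], [0, MISSING, 1]],
        het_flags=het,
    )
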