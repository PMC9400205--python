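import numpy as np
import pytest

from invasweep import GenotypeMatrix, SampleMetadata


def make_gm(dosage, pos=None, chrom="chr1", samples=None, alt=None, gq=None):
    """GenotypeMatrix from a (sites x samples) dosage array; -1 is missing."""
    dosage = np.asarray(dosage, dtype=np.int8)
    m, n = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1, dtype=np.int64)
    if samples is None:
        samples = [f"S{j + 1}" for j in range(n)]
    if alt is None:
        alt = [("T",)] * m
    gm = GenotypeMatrix(
        chrom=np.full(m, chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(m, "A", dtype=object),
        alt=list(alt),
        dosage=dosage,
        samples=list(samples),
        gq=None if gq is None else np.asarray(gq, dtype=np.int16),
    )
    gm.validate()
    return gm


@pytest.fixture
def two_pop_meta():
    return [
        SampleMetadata("A_1", "POPA", "F"), SampleMetadata("A_2", "POPA", "M"),
        SampleMetadata("B_1", "POPB", "F"), SampleMetadata("B_2", "POPB", "M"),
    ]
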