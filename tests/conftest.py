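import numpy as np
import pytest

from mistrans import ProteinRecord, Proteome, build_peptide_index


@pytest.fixture
def toy_proteome() -> Proteome:
    """Two tiny proteins with hand-checkable digests and codons.

    p1 = MKAPKLPK: LysC peptides (no length filter, <=2 missed) include APK
    (single P encoded by CCA) and LPK (single P encoded by CCG).
    p2 shares the AAK peptide with p1's MKAAK region? No - p2 provides a
    duplicated AAK so uniqueness flags can be exercised.
    """
    proteome = Proteome()
    proteome.add(
        ProteinRecord(
            "p1",
            "MKAPKLPK",
            # M  K  A  P  K  L  P  K
            "ATGAAAGCTCCAAAACTGCCGAAA",
        )
    )
    proteome.add(
        ProteinRecord(
            "p2",
            "AAKGGK",
            "GCTGCTAAAGGTGGTAAA",
        )
    )
    proteome.add(
        ProteinRecord(
            "p3",
            "AAKWWK",
            "GCAGCAAAATGGTGGAAA",
        )
    )
    return proteome


@pytest.fixture
def toy_index(toy_proteome):
    return build_peptide_index(toy_proteome, max_missed=2, min_len=1, max_len=None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
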