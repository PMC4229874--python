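import numpy as np
import pytest

from mrnscreen.gvgd import ProteinAlignment
from mrnscreen.variants import DomainAnnotation


@pytest.fixture
def toy_alignment() -> ProteinAlignment:
    """6-species toy alignment, 5 columns, human first.

    Column contents (1-based human positions):
      1: invariant G
      2: {I, L}
      3: invariant T in mammals, M in one deep species
      4: diverse {A, S, T, V}
      5: human-gapped column exercised via position 5 = column 6
    """
    seqs = {
        "human": "GITAW",
        "chimp": "GITSW",
        "mouse": "GLTSW",
        "cow":   "GITTW",
        "frog":  "GLTVW",
        "fish":  "GIMVW",
    }
    mammals = {"human": True, "chimp": True, "mouse": True, "cow": True, "frog": False, "fish": False}
    return ProteinAlignment(gene="TOY", sequences=seqs, mammal_flags=mammals)


@pytest.fixture
def toy_domains() -> list[DomainAnnotation]:
    return [
        DomainAnnotation("MRE11A", "nuclease", 1, 300, True),
        DomainAnnotation("MRE11A", "dna_binding_II", 501, 700, False),
        DomainAnnotation("RAD50", "atpase_c", 1200, 1312, True),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140603)
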