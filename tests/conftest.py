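from itertools import product

import pytest

from antisense.genetic_code import (GeneticCode, ReadingDirection,
                                    build_pairing_table)
from antisense.workflows import DEMO_ANTIBODY_SEGMENTS

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def brute_force_antisense(sense: str, direction: str, code: GeneticCode) -> set:
    """Independent oracle: enumerate every codon spelling of the sense
    peptide, complement (with reversal for 5'→3'), translate, drop spellings
    that hit a STOP, and collect the distinct antisense peptides."""
    per_residue = [code.codons_of(r) for r in sense]
    out = set()
    for spelling in product(*per_residue):
        anti = []
        for codon in spelling:
            comp = "".join(_RNA_COMPLEMENT[b] for b in codon)
            if direction == "5to3":
                comp = comp[::-1]
            aa = code.translate_codon(comp)
            if aa == "*":
                break
            anti.append(aa)
        else:
            out.add("".join(anti))
    return out


@pytest.fixture(scope="session")
def standard_code():
    return GeneticCode.standard()


@pytest.fixture(scope="session")
def table_3to5():
    return build_pairing_table(direction=ReadingDirection.ANTIPARALLEL_3TO5)


@pytest.fixture(scope="session")
def table_5to3():
    return build_pairing_table(direction=ReadingDirection.ANTIPARALLEL_5TO3)


@pytest.fixture(scope="session")
def demo_references():
    return dict(DEMO_ANTIBODY_SEGMENTS)
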