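"""Antisense peptide derivation from the standard genetic code.

The antisense (complementary-peptide) hypothesis: a peptide translated from
the strand complementary to the nucleotide sequence encoding a target
("sense") peptide tends to bind that target.  Because the genetic code is
degenerate, a sense peptide has many codon spellings and hence an *ensemble*
of possible antisense peptides.  This module derives, from the codon table
alone, the per-residue complementary pairing sets for the two reading
conventions of the antisense strand and enumerates the candidate ensembles.

Reading conventions
-------------------
ANTIPARALLEL_3TO5
    The antisense strand is read 3'→5', i.e. each sense codon is base-wise
    complemented *in the same positional order* (no reversal).  This is the
    convention that yields the smallest candidate ensembles.
ANTIPARALLEL_5TO3
    The antisense strand is read conventionally 5'→3': each sense codon is
    reverse-complemented.

In both conventions the antisense candidate is aligned N→C with the sense
peptide, position by position; complementary codons that are STOPs are
dropped from the pair sets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

from Bio.Data.CodonTable import unambiguous_rna_by_id

__all__ = [
    "ReadingDirection",
    "GeneticCode",
    "AntisensePairingTable",
    "AntisenseEnsemble",
    "DirectionReport",
    "validate_peptide",
    "build_pairing_table",
    "enumerate_antisense",
    "direction_comparison",
]

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = frozenset("BJOUXZ")
_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

STOP = "*"


class ReadingDirection(enum.Enum):
    """Reading convention for the antisense strand."""

    ANTIPARALLEL_3TO5 = "3to5"
    ANTIPARALLEL_5TO3 = "5to3"

    @classmethod
    def parse(cls, text: "str | ReadingDirection") -> "ReadingDirection":
        if isinstance(text, ReadingDirection):
            return text
        key = str(text).lower().replace("'", "").replace("′", "")
        for member in cls:
            if key in (member.value, member.name.lower()):
                return member
        raise ValueError(f"unknown reading direction: {text!r}")


def validate_peptide(seq: str) -> str:
    """Validate and normalise a one-letter peptide string.

    Upper-cases the input and rejects empty sequences, ambiguity codes
    (B, J, O, U, X, Z) and anything outside the 20 standard residues.
    """
    if not isinstance(seq, str):
        raise TypeError(f"peptide must be a string, got {type(seq).__name__}")
    s = seq.strip().upper()
    if not s:
        raise ValueError("peptide sequence is empty")
    bad = sorted(set(s) - STANDARD_AMINO_ACIDS)
    if bad:
        kind = "ambiguity code" if set(bad) & _AMBIGUOUS else "residue"
        raise ValueError(f"invalid {kind}(s) {''.join(bad)!r} in peptide {seq!r}")
    return s


def _normalize_codon(codon: str) -> str:
    c = codon.strip().upper().replace("T", "U")
    if len(c) != 3 or set(c) - set("ACGU"):
        raise ValueError(f"invalid codon {codon!r}")
    return c


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon→amino-acid table over RNA triplets.

    ``codon_to_aa`` maps all 64 codons to a one-letter amino acid or ``"*"``
    for STOP.  DNA input (T) is normalised to RNA (U) on construction.
    """

    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        table = {_normalize_codon(c): a.upper() for c, a in self.codon_to_aa.items()}
        if len(table) != 64:
            raise ValueError(f"genetic code must define 64 codons, got {len(table)}")
        n_stop = sum(1 for a in table.values() if a == STOP)
        coding = {a for a in table.values() if a != STOP}
        if n_stop != 3 or coding != STANDARD_AMINO_ACIDS:
            raise ValueError(
                "genetic code must map 61 codons to the 20 standard amino acids "
                f"and 3 to STOP (got {n_stop} stops, {len(coding)} amino acids)"
            )
        object.__setattr__(self, "codon_to_aa", table)

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard genetic code (translation table 1)."""
        t = unambiguous_rna_by_id[1]
        mapping = dict(t.forward_table)
        for stop in t.stop_codons:
            mapping[stop] = STOP
        return cls(mapping)

    def codons_of(self, aa: str) -> Tuple[str, ...]:
        """All codons of one amino acid, in lexicographic order."""
        return tuple(sorted(c for c, a in self.codon_to_aa.items() if a == aa))

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[_normalize_codon(codon)]


def complement_read(codon: str, direction: ReadingDirection) -> str:
    """Complementary codon under a reading convention.

    3'→5': base-wise complement in the same positional order.
    5'→3': reverse complement.
    """
    c = _normalize_codon(codon)
    comp = "".join(_RNA_COMPLEMENT[b] for b in c)
    if direction is ReadingDirection.ANTIPARALLEL_5TO3:
        comp = comp[::-1]
    return comp


@dataclass(frozen=True)
class AntisensePairingTable:
    """Per-amino-acid complementary pairing sets for one reading direction.

    ``pairs[a]`` is the set of residues encoded by the (non-STOP)
    complementary codons of ``a``'s codons.  ``dropped_stops`` counts sense
    codons whose complementary codon is a STOP.  Base complementation is an
    involution at codon level, so the relation is symmetric:
    ``b in pairs[a]  <=>  a in pairs[b]``.
    """

    direction: ReadingDirection
    pairs: Mapping[str, FrozenSet[str]]
    dropped_stops: int = 0

    def __getitem__(self, aa: str) -> FrozenSet[str]:
        return self.pairs[aa]


def build_pairing_table(
    code: Optional[GeneticCode] = None,
    direction: "str | ReadingDirection" = ReadingDirection.ANTIPARALLEL_3TO5,
) -> AntisensePairingTable:
    """Derive the amino-acid complementary pairing table from a genetic code.

    For each amino acid, every one of its codons is complement-read under
    ``direction`` and translated; STOP outcomes are dropped.  A residue whose
    complementary codons are all STOPs would yield an empty set and raises
    (cannot occur on the standard table).
    """
    code = code or GeneticCode.standard()
    direction = ReadingDirection.parse(direction)
    pairs: Dict[str, FrozenSet[str]] = {}
    dropped = 0
    for aa in sorted(STANDARD_AMINO_ACIDS):
        partners = set()
        for codon in code.codons_of(aa):
            partner = code.translate_codon(complement_read(codon, direction))
            if partner == STOP:
                dropped += 1
            else:
                partners.add(partner)
        if not partners:
            raise ValueError(
                f"all complementary codons of {aa} are STOPs in {direction.value}"
            )
        pairs[aa] = frozenset(partners)
    return AntisensePairingTable(direction=direction, pairs=pairs, dropped_stops=dropped)


@dataclass(frozen=True)
class AntisenseEnsemble:
    """The enumerated antisense candidates for one sense peptide."""

    sense: str
    direction: ReadingDirection
    candidates: Tuple[str, ...]
    count: int = field(default=0)

    def __post_init__(self) -> None:
        if self.count == 0:
            object.__setattr__(self, "count", len(self.candidates))

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.candidates

    def __len__(self) -> int:
        return self.count


def enumerate_antisense(
    sense: str,
    direction: "str | ReadingDirection" = ReadingDirection.ANTIPARALLEL_3TO5,
    table: Optional[AntisensePairingTable] = None,
) -> AntisenseEnsemble:
    """Enumerate all antisense peptide candidates for a sense peptide.

    Position *i* of each candidate is drawn from ``pairs[sense[i]]`` (direct
    N→C positional alignment, no reversal in either direction mode).  The
    candidate list is the full Cartesian product, in lexicographic order.

    Examples
    --------
    >>> ens = enumerate_antisense("RHSLFHP", "3to5")
    >>> ens.count
    12
    >>> "AVRDKVG" in ens
    True
    """
    sense = validate_peptide(sense)
    direction = ReadingDirection.parse(direction)
    if table is None:
        table = build_pairing_table(direction=direction)
    if table.direction is not direction:
        raise ValueError(
            f"pairing table direction {table.direction.value} != requested {direction.value}"
        )
    try:
        per_position: List[Tuple[str, ...]] = [tuple(sorted(table[r])) for r in sense]
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} absent from pairing table") from exc
    candidates = tuple("".join(p) for p in product(*per_position))
    return AntisenseEnsemble(sense=sense, direction=direction, candidates=candidates)


@dataclass(frozen=True)
class DirectionReport:
    """Ensemble sizes of the two reading conventions for one sense peptide."""

    sense: str
    count_3to5: int
    count_5to3: int


def direction_comparison(
    sense: str,
    table_3to5: Optional[AntisensePairingTable] = None,
    table_5to3: Optional[AntisensePairingTable] = None,
) -> DirectionReport:
    """Compare ensemble sizes of the two reading directions.

    Counts are computed as products of per-position pair-set sizes, so no
    ensemble is materialised however large the 5'→3' product grows.
    """
    sense = validate_peptide(sense)
    table_3to5 = table_3to5 or build_pairing_table(direction=ReadingDirection.ANTIPARALLEL_3TO5)
    table_5to3 = table_5to3 or build_pairing_table(direction=ReadingDirection.ANTIPARALLEL_5TO3)

    def _count(table: AntisensePairingTable) -> int:
        n = 1
        for r in sense:
            n *= len(table[r])
        return n

    return DirectionReport(sense=sense, count_3to5=_count(table_3to5), count_5to3=_count(table_5to3))
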