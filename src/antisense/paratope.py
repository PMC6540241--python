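"""Consensus paratope selection by k-mer homology against antibody sequences.

Each antisense candidate is decomposed into overlapping k-mers (linear
paratope motifs, quadripeptides by convention) and every motif is scored,
ungapped, against every width-k window of a user-supplied antibody reference
set with a substitution matrix (BLOSUM62 by default).  Candidates are ranked
by how many of their motifs find a hit and by the summed best-hit scores;
the top-ranked candidate is the consensus antisense peptide.

The search is a deterministic exhaustive scan: with at most a few dozen
short motifs against a FASTA of reference sequences there is nothing for a
heuristic seeded search to save, and exact scanning makes the selection
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

from Bio.Align import substitution_matrices

from .genetic_code import AntisenseEnsemble, validate_peptide

__all__ = [
    "Motif",
    "MotifSet",
    "MotifHit",
    "CandidateRanking",
    "kmer_decompose",
    "motif_search",
    "rank_candidates",
    "default_matrix",
]

DEFAULT_MIN_SCORE = 11.0  # half-bits; BLOSUM62 4-mer identity scores run ~16-44


def default_matrix():
    """BLOSUM62, the standard protein substitution matrix."""
    return substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class Motif:
    """One k-mer of a source peptide with its 1-based start offset."""

    kmer: str
    offset: int


@dataclass(frozen=True)
class MotifSet:
    source: str
    k: int
    motifs: Tuple[Motif, ...]

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def kmers(self) -> Tuple[str, ...]:
        return tuple(m.kmer for m in self.motifs)


def kmer_decompose(peptide: str, k: int = 4) -> MotifSet:
    """All overlapping k-mers of a peptide, left to right.

    >>> kmer_decompose("AVRDKVG", 4).kmers
    ('AVRD', 'VRDK', 'RDKV', 'DKVG')
    """
    peptide = validate_peptide(peptide)
    if not 1 <= k <= len(peptide):
        raise ValueError(f"k must lie in [1, {len(peptide)}], got {k}")
    motifs = tuple(
        Motif(kmer=peptide[i : i + k], offset=i + 1)
        for i in range(len(peptide) - k + 1)
    )
    return MotifSet(source=peptide, k=k, motifs=motifs)


@dataclass(frozen=True)
class MotifHit:
    """An ungapped motif-to-window match in a reference sequence."""

    motif: str
    reference_id: str
    reference_pos: int  # 1-based start of the window
    score: float
    exact: bool


def _window_score(motif: str, window: str, matrix) -> float:
    return float(sum(matrix[a, b] for a, b in zip(motif, window)))


def motif_search(
    motifs: MotifSet,
    references: Mapping[str, str],
    matrix=None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> List[MotifHit]:
    """Exhaustive ungapped scan of motifs against reference sequences.

    Every width-k window of every reference is scored against every motif;
    hits reaching ``min_score`` are returned sorted by score (descending),
    then reference id, then position.
    """
    if not references:
        raise ValueError("reference sequence set is empty")
    matrix = matrix if matrix is not None else default_matrix()
    k = motifs.k
    hits: List[MotifHit] = []
    for motif in motifs.kmers:
        for ref_id in sorted(references):
            seq = references[ref_id].upper()
            for pos in range(len(seq) - k + 1):
                window = seq[pos : pos + k]
                try:
                    score = _window_score(motif, window, matrix)
                except (KeyError, IndexError):
                    continue  # windows with non-standard letters are skipped
                if score >= min_score:
                    hits.append(MotifHit(
                        motif=motif, reference_id=ref_id,
                        reference_pos=pos + 1, score=score,
                        exact=(motif == window),
                    ))
    hits.sort(key=lambda h: (-h.score, h.reference_id, h.reference_pos))
    return hits


@dataclass(frozen=True)
class CandidateRanking:
    """Per-candidate motif coverage and summed best-hit scores."""

    candidate: str
    per_motif_best: Tuple[float, ...]
    total_score: float
    covered_motifs: int


def rank_candidates(
    ensemble: AntisenseEnsemble,
    references: Mapping[str, str],
    matrix=None,
    k: int = 4,
    min_score: float = DEFAULT_MIN_SCORE,
) -> List[CandidateRanking]:
    """Rank antisense candidates by antibody motif homology.

    Each candidate is decomposed into k-mers; each motif keeps its single
    best hit score (0 when no window reaches ``min_score``).  Candidates are
    ordered by covered motifs (descending), total score (descending), then
    lexicographically; the first entry is the consensus antisense peptide.
    """
    if ensemble.count == 0:
        raise ValueError("ensemble has no candidates")
    matrix = matrix if matrix is not None else default_matrix()
    rankings: List[CandidateRanking] = []
    for cand in ensemble.candidates:
        motifs = kmer_decompose(cand, k)
        best = []
        for m in motifs.motifs:
            single = MotifSet(source=cand, k=k, motifs=(m,))
            hits = motif_search(single, references, matrix, min_score)
            best.append(hits[0].score if hits else 0.0)
        covered = sum(1 for b in best if b > 0)
        rankings.append(CandidateRanking(
            candidate=cand, per_motif_best=tuple(best),
            total_score=float(sum(best)), covered_motifs=covered,
        ))
    rankings.sort(key=lambda r: (-r.covered_motifs, -r.total_score, r.candidate))
    return rankings
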