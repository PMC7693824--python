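"""Pairwise alignment, positional conservation, motif scan, fragment lookup.

Identity and similarity follow the conventions that reproduce the published
family comparisons: Needleman-Wunsch global alignment under BLOSUM62 with
gap open 10 / extend 0.5 (terminal gaps penalized), percentages over the
total alignment length with gap columns in the denominator, and a
"conservative substitution" defined as a strictly positive BLOSUM62 score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .constants import validate_sequence
from .datasets import PeptideRecord


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-10.0,
        extend_gap_score=-0.5,
    )
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    length: int
    n_identical: int
    n_similar: int

    @property
    def identity_pct(self) -> float:
        return round(100.0 * self.n_identical / self.length, 1)

    @property
    def similarity_pct(self) -> float:
        return round(100.0 * self.n_similar / self.length, 1)


def global_align(a: str, b: str) -> AlignmentResult:
    """Global alignment with identity/similarity over total columns."""
    a = validate_sequence(a, "first sequence")
    b = validate_sequence(b, "second sequence")
    alignment = _aligner().align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matrix = _aligner().substitution_matrix
    n_identical = 0
    n_similar = 0
    for x, y in zip(row_a, row_b):
        if x == y:
            n_identical += 1
            n_similar += 1
        elif x != "-" and y != "-" and matrix[x, y] > 0:
            n_similar += 1
    return AlignmentResult(
        aligned_a=row_a,
        aligned_b=row_b,
        length=len(row_a),
        n_identical=n_identical,
        n_similar=n_similar,
    )


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column residue frequencies over a set of sequences."""

    n_sequences: int
    columns: tuple[dict[str, float], ...]

    @property
    def invariant_positions(self) -> list[int]:
        """1-based positions occupied by a single residue in all sequences."""
        return [
            i + 1
            for i, col in enumerate(self.columns)
            if len(col) == 1 and abs(next(iter(col.values())) - 1.0) < 1e-12
        ]

    @property
    def consensus(self) -> str:
        return "".join(
            max(col, key=lambda a: (col[a], a)) for col in self.columns
        )


def conservation_profile(
    sequences: Sequence[str], mode: str = "left_flush"
) -> ConservationProfile:
    """Column-wise residue frequencies.

    ``left_flush`` stacks the sequences without gaps (the family alignment
    has no internal gaps) and profiles columns up to the shortest length.
    ``msa`` expects pre-aligned equal-length strings and profiles every
    column, ignoring gap characters in the frequency count.
    """
    if len(sequences) < 2:
        raise ValueError("conservation profile needs at least 2 sequences")
    seqs = [s.upper() for s in sequences]
    if mode == "left_flush":
        width = min(len(s) for s in seqs)
    elif mode == "msa":
        width = {len(s) for s in seqs}
        if len(width) != 1:
            raise ValueError("msa mode requires equal-length aligned strings")
        width = width.pop()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    columns = []
    for i in range(width):
        observed = [s[i] for s in seqs if i < len(s) and s[i] != "-"]
        total = len(observed)
        col: dict[str, float] = {}
        for a in observed:
            col[a] = col.get(a, 0.0) + 1.0 / total
        columns.append(col)
    return ConservationProfile(n_sequences=len(seqs), columns=tuple(columns))


_PHI = "VLIFAM"
#: Relaxed N-terminal motif: [GA]-X-X-D-X-X-[KT] with hydrophobic X.
MOTIF_RELAXED = re.compile(f"^[GA][{_PHI}][{_PHI}]D[{_PHI}][{_PHI}][KT]")
#: Strict GXXDXXK form.
MOTIF_STRICT = re.compile(f"^G[{_PHI}][{_PHI}]D[{_PHI}][{_PHI}]K")


def motif_scan(
    sequence: str, strict: bool = False
) -> tuple[bool, Optional[tuple[int, int]]]:
    """Scan positions 1-7 for the family GXXDXXK-type motif.

    Returns (matched, 1-based inclusive span or None).
    """
    seq = validate_sequence(sequence)
    if len(seq) < 7:
        raise ValueError("motif scan needs at least 7 residues")
    pattern = MOTIF_STRICT if strict else MOTIF_RELAXED
    if pattern.match(seq):
        return True, (1, 7)
    return False, None


def fragment_classify(
    query: str, catalogue: Sequence[PeptideRecord]
) -> Optional[tuple[str, tuple[int, int]]]:
    """Find the first catalogue peptide containing ``query`` as a substring.

    Returns (parent name, 1-based inclusive span), or None if the query is
    original with respect to the catalogue.
    """
    if not catalogue:
        raise ValueError("empty catalogue")
    query = validate_sequence(query, "query")
    for rec in catalogue:
        start = rec.sequence.find(query)
        if start >= 0:
            return rec.name, (start + 1, start + len(query))
    return None
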