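"""Global pairwise protein alignment and percent sequence identity.

Protein divergence between orthologs is measured inversely by percent
sequence identity

    psi = 100 * 2 * n_id / (len_a + len_b)

where ``n_id`` is the number of identical aligned residue pairs in an
optimal global (Needleman-Wunsch) alignment and the denominator is the
sum of the *unaligned* sequence lengths (i.e. n_id over the average
length).  The alignment itself is delegated to Biopython's
``PairwiseAligner`` in global mode with affine gap penalties; defaults
are BLOSUM62, gap open 10, gap extend 0.5.  A gap of length L costs
``gap_open + (L - 1) * gap_extend``.

Co-optimal alignments can in principle differ in n_id; the aligner's
first traceback is used, which is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from ._errors import ValidationError
from .sequence_io import ProteinSequence

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (as magnitudes)."""

    matrix: str | Path = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties are magnitudes and must be >= 0")

    def load_matrix(self):
        return _load_matrix(str(self.matrix))


@lru_cache(maxsize=8)
def _load_matrix(name_or_path: str):
    p = Path(name_or_path)
    if p.suffix or p.exists():
        return substitution_matrices.read(str(p))
    return substitution_matrices.load(name_or_path)


@dataclass(frozen=True)
class AlignmentResult:
    n_id: int
    len_a: int
    len_b: int
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned strings must have equal length")
        if not 0 <= self.n_id <= min(self.len_a, self.len_b):
            raise ValidationError("n_id out of range")


def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scoring.load_matrix()
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def global_align(
    a: ProteinSequence, b: ProteinSequence, scoring: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Raises :class:`ValidationError` for residues absent from the scoring
    matrix alphabet.
    """
    scoring = scoring or ScoringScheme()
    matrix = scoring.load_matrix()
    alphabet = set(str(matrix.alphabet))
    for seq in (a, b):
        bad = set(seq.residues) - alphabet
        if bad:
            raise ValidationError(
                f"sequence {seq.seq_id!r} contains residues outside the "
                f"matrix alphabet: {''.join(sorted(bad))}"
            )
    aligner = _make_aligner(scoring)
    alignment = aligner.align(a.residues, b.residues)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    n_id = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    return AlignmentResult(
        n_id=n_id,
        len_a=len(a.residues),
        len_b=len(b.residues),
        aligned_a=ga,
        aligned_b=gb,
        score=float(alignment.score),
    )


def percent_identity(r: AlignmentResult) -> float:
    """psi = 100 * 2 * n_id / (len_a + len_b), in [0, 100]."""
    return 100.0 * 2.0 * r.n_id / (r.len_a + r.len_b)
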