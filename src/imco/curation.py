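"""Record curation: Poisson sequence-conflict filter, predicted-record
exclusion, and longest-isoform selection.

Curated protein databases annotate *sequence conflicts* — discrepancies
between independently reported sequences of the same protein.  Genes
whose conflict count is significantly larger than expected under a
genome-wide per-residue conflict rate are treated as unreliable and
excluded.  The test models the count for a protein of length L as
Poisson with mean ``rate * L`` and excludes a gene when the upper-tail
probability P(X >= k) falls below ``alpha`` (default 0.05): genes with
significantly *more* conflicts than expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from ._errors import ValidationError
from .sequence_io import GeneAnnotation

#: RefSeq accession prefixes of purely computational (predicted) records.
PREDICTED_PREFIXES = ("XP_", "ZP_")


@dataclass(frozen=True)
class ConflictRecord:
    gene_id: str
    length: int  # protein length, residues
    n_conflicts: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.gene_id}: length must be >= 1")
        if self.n_conflicts < 0:
            raise ValidationError(f"{self.gene_id}: negative conflict count")


def estimate_conflict_rate(records: Sequence[ConflictRecord]) -> float:
    """Pooled per-residue conflict rate: total conflicts / total residues."""
    if not records:
        raise ValidationError("cannot estimate a conflict rate from no records")
    total_len = sum(r.length for r in records)
    return sum(r.n_conflicts for r in records) / total_len


def poisson_upper_tail(k: int, mu: float) -> float:
    """P(X >= k) for X ~ Poisson(mu).  P(X >= 0) is 1 by convention."""
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, mu))


def poisson_conflict_filter(
    records: Sequence[ConflictRecord], rate: float, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Partition gene ids into (retained, excluded) by the conflict test.

    A gene with observed count k and expected mean ``mu = rate * length``
    is excluded iff P(X >= k) < alpha under Poisson(mu).
    """
    if rate < 0:
        raise ValidationError("conflict rate must be non-negative")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    retained, excluded = [], []
    for r in records:
        tail = poisson_upper_tail(r.n_conflicts, rate * r.length)
        (excluded if tail < alpha else retained).append(r.gene_id)
    return retained, excluded


def filter_predicted_refseq(ids: Iterable[str]) -> list[str]:
    """Drop isoform ids of predicted RefSeq records (XP_/ZP_ prefixes)."""
    return [i for i in ids if not i.startswith(PREDICTED_PREFIXES)]


def select_longest_isoform(gene: GeneAnnotation) -> str:
    """Transcript id with the longest CDS; ties -> smallest transcript_id."""
    coding = [t for t in gene.transcripts if t.cds_length > 0]
    if not coding:
        raise ValidationError(f"gene {gene.gene_id!r} has no coding transcript")
    max_len = max(t.cds_length for t in coding)
    return min(t.transcript_id for t in coding if t.cds_length == max_len)
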