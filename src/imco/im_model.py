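"""Per-gene isoform multiplicity (IM) and its RNA-seq collapsing rules.

A gene *has IM* when it carries more than one annotated isoform.  For
annotation-based inputs this is read straight off the transcript list;
for RNA-seq-derived tables, per-(gene, individual, tissue) boolean calls
are collapsed in two steps: across tissues of one individual (IM in at
least one tissue), then across individuals (mode ``"any"``: at least one
individual; mode ``"each"``: every individual).

``exons_longest`` is the exon count of the transcript with the longest
CDS — the same transcript whose protein is used for alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._errors import ValidationError
from .curation import select_longest_isoform
from .sequence_io import GeneAnnotation

logger = logging.getLogger(__name__)

COLLAPSE_MODES = ("any", "each")


@dataclass(frozen=True)
class GeneIM:
    """IM status, isoform count and longest-isoform exon count of a gene."""

    gene_id: str
    has_im: bool
    n_isoforms: int
    exons_longest: int
    species: str = ""

    def __post_init__(self) -> None:
        if self.n_isoforms < 1 or self.exons_longest < 1:
            raise ValidationError(f"{self.gene_id}: counts must be positive")
        if self.has_im != (self.n_isoforms > 1):
            raise ValidationError(
                f"{self.gene_id}: has_im must equal (n_isoforms > 1)"
            )


def annotate_im(gene: GeneAnnotation) -> GeneIM:
    """Derive a gene's IM flag and longest-isoform exon count."""
    longest = select_longest_isoform(gene)
    exons = next(t.exon_count for t in gene.transcripts if t.transcript_id == longest)
    n = len(gene.transcripts)
    return GeneIM(
        gene_id=gene.gene_id,
        has_im=n > 1,
        n_isoforms=n,
        exons_longest=exons,
        species=gene.species,
    )


@dataclass
class SampleIMTable:
    """Per-sample IM calls indexed by (gene_id, individual, tissue)."""

    entries: dict[tuple[str, str, str], bool] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, str, bool]]
    ) -> "SampleIMTable":
        entries: dict[tuple[str, str, str], bool] = {}
        for gene, individual, tissue, has_im in records:
            key = (gene, individual, tissue)
            if key in entries:
                raise ValidationError(f"duplicate sample entry {key}")
            entries[key] = bool(has_im)
        return cls(entries=entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleIMTable":
        df = pd.read_csv(path, sep="\t")
        truthy = {"1", "true", "yes", "y"}
        return cls.from_records(
            [
                (str(r.gene_id), str(r.individual), str(r.tissue),
                 str(r.has_im).strip().lower() in truthy)
                for r in df.itertuples(index=False)
            ]
        )

    @property
    def genes(self) -> list[str]:
        return sorted({g for g, _, _ in self.entries})

    @property
    def individuals(self) -> list[str]:
        return sorted({i for _, i, _ in self.entries})


def collapse_tissues(table: SampleIMTable, individual: str) -> dict[str, bool]:
    """IM per gene for one individual: IM in at least one tissue.

    Genes present in the table but without any entry for this individual
    are annotated no-IM (absence-of-evidence convention) with a warning.
    """
    if individual not in table.individuals:
        raise ValidationError(f"unknown individual {individual!r}")
    result: dict[str, bool] = {g: False for g in table.genes}
    covered: set[str] = set()
    for (gene, ind, _tissue), has_im in table.entries.items():
        if ind != individual:
            continue
        covered.add(gene)
        result[gene] = result[gene] or has_im
    missing = set(result) - covered
    if missing:
        logger.warning(
            "%d gene(s) have no sample for individual %s; annotated no-IM",
            len(missing), individual,
        )
    return result


def collapse_individuals(
    per_individual: Mapping[str, Mapping[str, bool]], mode: str = "any"
) -> dict[str, bool]:
    """Collapse per-individual IM calls across individuals.

    mode "any": IM in at least one individual (logical OR);
    mode "each": IM in every individual (logical AND; a gene missing for
    an individual counts as no-IM there).
    """
    if mode not in COLLAPSE_MODES:
        raise ValidationError(f"mode must be one of {COLLAPSE_MODES}, got {mode!r}")
    if not per_individual:
        raise ValidationError("need at least one individual")
    genes = sorted({g for calls in per_individual.values() for g in calls})
    out: dict[str, bool] = {}
    for g in genes:
        calls = [bool(c.get(g, False)) for c in per_individual.values()]
        out[g] = any(calls) if mode == "any" else all(calls)
    return out


def im_by_exon_count(genes: Sequence[GeneIM]) -> pd.DataFrame:
    """Fraction of genes with IM at each longest-isoform exon count.

    Returns a DataFrame with columns ``exons``, ``n_genes``,
    ``im_fraction``, sorted by exon count; counts with no genes are
    simply absent.
    """
    if not genes:
        raise ValidationError("im_by_exon_count needs at least one gene")
    df = pd.DataFrame(
        {"exons": [g.exons_longest for g in genes], "im": [g.has_im for g in genes]}
    )
    grouped = (
        df.groupby("exons")["im"]
        .agg(n_genes="size", im_fraction="mean")
        .reset_index()
        .sort_values("exons", ignore_index=True)
    )
    grouped["im_fraction"] = grouped["im_fraction"].astype(float)
    return grouped
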