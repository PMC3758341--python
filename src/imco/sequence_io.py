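"""Readers and writers for the formats the pipeline touches.

Inputs are protein FASTA files (one sequence per gene, the longest
isoform), Ensembl-dialect GTF annotations (exon and CDS features keyed by
``gene_id``/``transcript_id`` attributes), and a two-column TSV of
one-to-one ortholog pairs.  Outputs are the pipeline's own TSV tables,
with ``NA`` as the missing-value token.

Coordinates in GTF are 1-based inclusive and are only ever used to sum
CDS lengths; they are never exposed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import pandas as pd
from Bio import SeqIO

from ._errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .cooccurrence import IdentityPoint

logger = logging.getLogger(__name__)

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class ProteinSequence:
    """A single protein sequence: 20 amino-acid letters plus X."""

    seq_id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"empty sequence for {self.seq_id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exon_count: int
    cds_length: int  # residues

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise ValidationError(
                f"transcript {self.transcript_id!r}: exon_count must be >= 1"
            )
        if self.cds_length < 0:
            raise ValidationError(
                f"transcript {self.transcript_id!r}: negative cds_length"
            )


@dataclass
class GeneAnnotation:
    """Per-gene transcript structure: isoform count and exon counts."""

    gene_id: str
    transcripts: list[Transcript]
    species: str = ""

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id!r} has no transcripts")


@dataclass
class OrthologTable:
    """One-to-one ortholog pairs (human_gene_id, other_gene_id).

    The one-to-one invariant mirrors the upstream orthology curation:
    genes without a unique orthology relationship are not accepted.
    """

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        offenders = []
        for h, m in self.rows:
            for g in (h, m):
                seen[g] = seen.get(g, 0) + 1
                if seen[g] == 2:
                    offenders.append(g)
        if offenders:
            raise ValidationError(
                "ortholog table is not one-to-one; repeated gene ids: "
                + ", ".join(sorted(offenders))
            )

    def __len__(self) -> int:
        return len(self.rows)


def read_fasta(path: str | Path, species: str = "") -> list[ProteinSequence]:
    """Read a protein FASTA file.

    The header token before the first whitespace becomes ``seq_id``;
    residues are uppercased.  Raises :class:`ParseError` when the first
    non-blank line is not a header, :class:`ValidationError` on duplicate
    ids.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinSequence(seq_id=rec.id, residues=str(rec.seq).upper(), species=species)
        )
    return records


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path, species: str = "") -> list[GeneAnnotation]:
    """Read gene annotations from a GTF file.

    Per transcript, ``exon_count`` is the number of exon-feature lines
    and ``cds_length`` the summed CDS length in nucleotides floor-divided
    by 3 (residues; the stop codon is not subtracted — only relative
    lengths matter for longest-isoform selection).  Genes that carry no
    transcript (e.g. a bare gene feature line) are dropped with a warning.
    """
    path = Path(path)
    exon_counts: dict[tuple[str, str], int] = {}
    cds_nt: dict[tuple[str, str], int] = {}
    gene_of_transcript: dict[tuple[str, str], str] = {}
    gene_order: list[str] = []
    genes_seen: set[str] = set()
    bare_genes: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            feature = fields[2]
            attrs = _parse_gtf_attributes(fields[8])
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            if gene_id not in genes_seen:
                genes_seen.add(gene_id)
                gene_order.append(gene_id)
            if feature == "gene":
                bare_genes.add(gene_id)
                continue
            if feature not in ("exon", "CDS"):
                continue
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise ParseError(
                    f"{path}: line {lineno}: {feature} feature missing "
                    "transcript_id attribute"
                )
            key = (gene_id, tx_id)
            gene_of_transcript[key] = gene_id
            if feature == "exon":
                exon_counts[key] = exon_counts.get(key, 0) + 1
            else:
                start, end = int(fields[3]), int(fields[4])
                cds_nt[key] = cds_nt.get(key, 0) + (end - start + 1)

    by_gene: dict[str, list[Transcript]] = {}
    for key in gene_of_transcript:
        gene_id, tx_id = key
        by_gene.setdefault(gene_id, []).append(
            Transcript(
                transcript_id=tx_id,
                exon_count=exon_counts.get(key, 0) or 1,
                cds_length=cds_nt.get(key, 0) // 3,
            )
        )
    genes = []
    for gene_id in gene_order:
        if gene_id not in by_gene:
            logger.warning("%s: gene %s has no transcripts; dropped", path, gene_id)
            continue
        transcripts = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        genes.append(GeneAnnotation(gene_id=gene_id, transcripts=transcripts, species=species))
    return genes


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a two-column TSV of ortholog gene-id pairs (optional header)."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            h, m = parts[0].strip(), parts[1].strip()
            if lineno == 1 and {h.lower(), m.lower()} & {
                "human_gene_id", "human", "gene_h", "other_gene_id", "other", "gene_m",
            }:
                continue  # header row
            rows.append((h, m))
    return OrthologTable(rows=rows)


POINTS_COLUMNS = ["x", "n_pairs", "n_both_im", "imco", "p_im_h", "p_im_m", "product", "q_hm"]


def write_points_table(points: Sequence["IdentityPoint"], path: str | Path) -> None:
    """Write per-identity estimates as TSV; undefined q_hm becomes NA."""
    df = pd.DataFrame(
        [
            {
                "x": p.x,
                "n_pairs": p.n_pairs,
                "n_both_im": p.n_both_im,
                "imco": p.imco,
                "p_im_h": p.p_im_h,
                "p_im_m": p.p_im_m,
                "product": p.product,
                "q_hm": math.nan if p.q_hm is None else p.q_hm,
            }
            for p in points
        ],
        columns=POINTS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_points_table(path: str | Path) -> list["IdentityPoint"]:
    """Read a points table written by :func:`write_points_table`."""
    from .cooccurrence import IdentityPoint

    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    points = []
    for row in df.itertuples(index=False):
        points.append(
            IdentityPoint(
                x=float(row.x),
                n_pairs=int(row.n_pairs),
                n_both_im=int(row.n_both_im),
                imco=float(row.imco),
                p_im_h=float(row.p_im_h),
                p_im_m=float(row.p_im_m),
                q_hm=None if pd.isna(row.q_hm) else float(row.q_hm),
            )
        )
    return points
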