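"""Synthetic ortholog datasets with the statistical structure the
analysis assumes.

The generator emulates, per ortholog pair:

* percent identity x drawn from a truncated normal (mean 85, sd 10,
  truncated to [30, 100] — the bulk of human-mouse orthologs sits at
  high identity);
* longest-isoform exon counts E per species from a shifted negative
  binomial whose mean ``exp(a + b*x)`` rises with identity (b > 0, the
  vertebrate regime) or falls (b < 0, the fruit-fly-like regime);
* isoform multiplicity via the saturating model
  ``p = 1 - (1 - q)**(E - 1)``: each internal exon boundary offers an
  independent chance q of supporting an alternative isoform, so
  single-exon genes never have IM and p approaches 1 for exon-rich
  genes;
* optional coupling c between the two species' IM draws (c = 0
  independent, c = 1 comonotone via a shared uniform).

On top of the in-memory pairs it can materialise file fixtures: paired
FASTA (substitution-only divergence, so the target identity is exact),
paired GTF whose transcript structure is consistent with the drawn IM
flags and exon counts, an ortholog TSV, and Poisson conflict records
with an outlier regime.  Everything is reproducible from (config, seed);
each operation uses its own deterministic substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .cooccurrence import OrthologPair
from .curation import ConflictRecord

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class IdentityDist:
    """Truncated-normal distribution of percent identity."""

    mean: float = 85.0
    sd: float = 10.0
    lower: float = 30.0
    upper: float = 100.0


@dataclass(frozen=True)
class ExonModel:
    """log E[exons] = intercept + slope * identity; NB dispersion."""

    intercept: float = math.log(3.0)
    slope: float = 0.012  # per identity percent; negative = fly-like regime
    dispersion: float = 2.0


@dataclass(frozen=True)
class IMModel:
    """Per-exon-boundary escape probability and cross-species coupling."""

    q_h: float = 0.25
    q_m: float = 0.25
    coupling: float = 0.0

    def __post_init__(self) -> None:
        for name in ("q_h", "q_m", "coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class LengthDist:
    """Normal protein-length distribution, clipped below."""

    mean: float = 450.0
    sd: float = 120.0
    minimum: int = 50


@dataclass(frozen=True)
class ConflictModel:
    """Per-residue conflict rate with a contaminating outlier regime."""

    rate: float = 0.001
    outlier_fraction: float = 0.05
    outlier_multiplier: float = 20.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_pairs: int = 12000
    seed: int = 0
    identity_dist: IdentityDist = field(default_factory=IdentityDist)
    exon_model: ExonModel = field(default_factory=ExonModel)
    im_model: IMModel = field(default_factory=IMModel)
    length_dist: LengthDist = field(default_factory=LengthDist)
    conflict_model: ConflictModel = field(default_factory=ConflictModel)

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "SyntheticConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sub = {
            "identity_dist": IdentityDist,
            "exon_model": ExonModel,
            "im_model": IMModel,
            "length_dist": LengthDist,
            "conflict_model": ConflictModel,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    """Deterministic per-operation substream of the config seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


# substream indices, one per operation
_STREAM_PAIRS, _STREAM_SEQS, _STREAM_GTF, _STREAM_CONFLICTS = range(4)


def im_probability(q: float, exons: np.ndarray | int) -> np.ndarray | float:
    """Saturating IM probability: p = 1 - (1 - q)**(E - 1)."""
    e = np.asarray(exons)
    return 1.0 - (1.0 - q) ** (e - 1)


def _draw_exons(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Shifted negative binomial: 1 + NB with mean (mean - 1)."""
    shifted = np.clip(mean - 1.0, 1e-9, None)
    lam = rng.gamma(shape=dispersion, scale=shifted / dispersion)
    return 1 + rng.poisson(lam)


class SyntheticTruth(NamedTuple):
    """Latent values behind each generated pair, as a DataFrame."""

    table: pd.DataFrame


def generate_pairs(config: SyntheticConfig) -> tuple[list[OrthologPair], SyntheticTruth]:
    """Draw ortholog pairs from the generative model."""
    rng = _rng(config, _STREAM_PAIRS)
    n = config.n_pairs
    idist = config.identity_dist
    a_trunc = (idist.lower - idist.mean) / idist.sd
    b_trunc = (idist.upper - idist.mean) / idist.sd
    x = stats.truncnorm.rvs(
        a_trunc, b_trunc, loc=idist.mean, scale=idist.sd, size=n, random_state=rng
    )
    em = config.exon_model
    mean_e = np.exp(em.intercept + em.slope * x)
    exons_h = _draw_exons(rng, mean_e, em.dispersion)
    exons_m = _draw_exons(rng, mean_e, em.dispersion)
    imm = config.im_model
    p_h = im_probability(imm.q_h, exons_h)
    p_m = im_probability(imm.q_m, exons_m)
    shared = rng.random(n) < imm.coupling
    u0, uh, um = rng.random(n), rng.random(n), rng.random(n)
    v_h = np.where(shared, u0, uh)
    v_m = np.where(shared, u0, um)
    im_h = v_h < p_h
    im_m = v_m < p_m

    pairs = [
        OrthologPair(
            human_gene=f"hsg{i:06d}",
            other_gene=f"msg{i:06d}",
            psi=float(x[i]),
            im_h=bool(im_h[i]),
            im_m=bool(im_m[i]),
            exons_h=int(exons_h[i]),
            exons_m=int(exons_m[i]),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "human_gene": [p.human_gene for p in pairs],
            "other_gene": [p.other_gene for p in pairs],
            "psi_target": x,
            "exons_h": exons_h,
            "exons_m": exons_m,
            "p_im_h": p_h,
            "p_im_m": p_m,
            "im_h": im_h,
            "im_m": im_m,
        }
    )
    return pairs, SyntheticTruth(table=truth)


def _mutate(rng, residues: np.ndarray, n_sub: int) -> np.ndarray:
    """Substitute n_sub positions with a *different* residue each."""
    out = residues.copy()
    if n_sub == 0:
        return out
    pos = rng.choice(len(residues), size=n_sub, replace=False)
    for i in pos:
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_sequences(
    pairs: Sequence[OrthologPair],
    config: SyntheticConfig,
    fasta_h: str | Path,
    fasta_m: str | Path,
) -> list[int]:
    """Write paired FASTA files realising each pair's target identity.

    Divergence is substitution-only (no indels): for a protein of length
    L at target identity x, exactly ``round(L * (1 - x/100))`` positions
    are replaced by different residues, so the realised identity equals
    the target within rounding.  Returns the drawn protein lengths.
    """
    rng = _rng(config, _STREAM_SEQS)
    ld = config.length_dist
    lengths = np.maximum(
        np.rint(rng.normal(ld.mean, ld.sd, size=len(pairs))).astype(int), ld.minimum
    )
    with open(fasta_h, "w") as fh, open(fasta_m, "w") as fm:
        for pair, L in zip(pairs, lengths):
            if not 0.0 <= pair.psi <= 100.0:
                raise ValidationError("target identity outside [0, 100]")
            base = rng.choice(AMINO_ACIDS, size=L)
            n_sub = int(round(L * (1.0 - pair.psi / 100.0)))
            other = _mutate(rng, base, n_sub)
            fh.write(f">{pair.human_gene}\n{''.join(base)}\n")
            fm.write(f">{pair.other_gene}\n{''.join(other)}\n")
    return [int(L) for L in lengths]


def _truncated_binomial_geq1(rng, n: int, q: float) -> int:
    """Binomial(n, q) conditioned on being >= 1 (n >= 1, q > 0)."""
    if n < 1 or q <= 0.0:
        raise ValidationError(
            "a gene flagged IM needs >= 2 exons and q > 0 to draw extra isoforms"
        )
    while True:
        k = int(rng.binomial(n, q))
        if k >= 1:
            return k


def _write_gene_gtf(fh, gene_id: str, chrom: str, offset: int,
                    transcripts: list[tuple[str, int, int]]) -> int:
    """Write exon+CDS lines for one gene; returns the next free offset.

    ``transcripts`` holds (transcript_id, exon_count, cds_nt) tuples; the
    CDS is distributed over non-overlapping ascending exons.
    """
    pos = offset
    for tx_id, n_exons, cds_nt in transcripts:
        if cds_nt < 3 * n_exons:
            raise ValidationError("cds_nt must allow >= 1 codon per exon")
        per = 3 * (cds_nt // (3 * n_exons))  # >= 3, multiple of 3
        start = pos
        remaining = cds_nt
        for e in range(n_exons):
            size = per if e < n_exons - 1 else remaining
            end = start + size - 1
            for feature in ("exon", "CDS"):
                fh.write(
                    f"{chrom}\tsim\t{feature}\t{start}\t{end}\t.\t+\t.\t"
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}";\n'
                )
            remaining -= size
            start = end + 101  # intron spacer
        pos = start + 1000
    return pos


def generate_gtf(
    pairs: Sequence[OrthologPair],
    config: SyntheticConfig,
    gtf_h: str | Path,
    gtf_m: str | Path,
    lengths: Sequence[int] | None = None,
) -> None:
    """Write paired GTF files consistent with the pairs' IM and exon counts.

    Each gene gets one transcript per isoform; the number of extra
    isoforms is 1 + Binomial(E - 1, q) truncated to agree with the drawn
    IM flag.  The longest transcript carries the pair's exon count and
    the largest CDS.  ``lengths`` (residues, e.g. from
    :func:`generate_sequences`) fixes the longest CDS per pair; drawn
    otherwise.
    """
    rng = _rng(config, _STREAM_GTF)
    ld = config.length_dist
    if lengths is None:
        lengths = np.maximum(
            np.rint(rng.normal(ld.mean, ld.sd, size=len(pairs))).astype(int),
            ld.minimum,
        ).tolist()
    with open(gtf_h, "w") as fh, open(gtf_m, "w") as fm:
        off_h = off_m = 1
        for pair, L in zip(pairs, lengths):
            for handle, gene_id, exons, has_im, q, offset, which in (
                (fh, pair.human_gene, pair.exons_h, pair.im_h,
                 config.im_model.q_h, off_h, "h"),
                (fm, pair.other_gene, pair.exons_m, pair.im_m,
                 config.im_model.q_m, off_m, "m"),
            ):
                if has_im:
                    n_extra = _truncated_binomial_geq1(rng, exons - 1, q)
                else:
                    n_extra = 0
                # keep the primary transcript strictly longest even when
                # the drawn exon count exceeds the protein length
                cds_longest = 3 * max(int(L), exons + 1)
                transcripts = [(f"{gene_id}.t1", exons, cds_longest)]
                for j in range(n_extra):
                    e_j = int(rng.integers(1, exons + 1))
                    cds_j = int(cds_longest * rng.uniform(0.3, 0.9))
                    cds_j -= cds_j % 3
                    cds_j = min(max(cds_j, 3 * e_j), cds_longest - 3)
                    transcripts.append((f"{gene_id}.t{j + 2}", e_j, cds_j))
                new_off = _write_gene_gtf(handle, gene_id, "chr1", offset, transcripts)
                if which == "h":
                    off_h = new_off
                else:
                    off_m = new_off


class ConflictSample(NamedTuple):
    records: list[ConflictRecord]
    is_outlier: np.ndarray


def generate_conflicts(config: SyntheticConfig, n: int | None = None) -> ConflictSample:
    """Draw per-gene conflict counts: Poisson baseline plus an outlier
    regime with an inflated rate."""
    rng = _rng(config, _STREAM_CONFLICTS)
    cm = config.conflict_model
    ld = config.length_dist
    n = config.n_pairs if n is None else n
    lengths = np.maximum(
        np.rint(rng.normal(ld.mean, ld.sd, size=n)).astype(int), ld.minimum
    )
    is_outlier = rng.random(n) < cm.outlier_fraction
    rates = np.where(is_outlier, cm.rate * cm.outlier_multiplier, cm.rate)
    counts = rng.poisson(rates * lengths)
    records = [
        ConflictRecord(gene_id=f"hsg{i:06d}", length=int(lengths[i]),
                       n_conflicts=int(counts[i]))
        for i in range(n)
    ]
    return ConflictSample(records=records, is_outlier=is_outlier)


def write_ortholog_tsv(pairs: Sequence[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("human_gene_id\tother_gene_id\n")
        for p in pairs:
            fh.write(f"{p.human_gene}\t{p.other_gene}\n")


def write_conflicts_tsv(records: Sequence[ConflictRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength\tn_conflicts\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.length}\t{r.n_conflicts}\n")


def read_conflicts_tsv(path: str | Path) -> list[ConflictRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ConflictRecord(gene_id=str(r.gene_id), length=int(r.length),
                       n_conflicts=int(r.n_conflicts))
        for r in df.itertuples(index=False)
    ]
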