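"""End-to-end orchestration: files in, tables + figures out.

The stages mirror the analysis: optional conflict-based curation,
longest-isoform selection, global alignment to percent identity, IM
annotation, pair building, per-identity estimation, minimum-observation
filtering, LOESS smoothing, Spearman trend tests, and the exon-count
analyses.  Tables are TSV; figures are a courtesy output (matplotlib,
Agg backend) and nothing downstream depends on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from ._errors import ValidationError
from .alignment import ScoringScheme, global_align, percent_identity
from .cooccurrence import (
    DEFAULT_MIN_OBS,
    IdentityPoint,
    OrthologPair,
    TrendResult,
    build_pairs,
    estimate_points,
    exon_points,
    filter_min_obs,
    imco_by_exon_product,
    spearman_trend,
)
from .curation import estimate_conflict_rate, poisson_conflict_filter
from .im_model import annotate_im, im_by_exon_count
from .sequence_io import (
    GeneAnnotation,
    OrthologTable,
    read_fasta,
    read_gtf,
    read_ortholog_table,
    write_points_table,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_conflicts,
    generate_gtf,
    generate_pairs,
    generate_sequences,
    read_conflicts_tsv,
    write_conflicts_tsv,
    write_ortholog_tsv,
)
from .trend import DEFAULT_DEGREE, DEFAULT_LEVEL, DEFAULT_SPAN, SmoothedCurve, loess_smooth

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Inputs, parameters and output directory for one pipeline run."""

    fasta_h: Path
    fasta_m: Path
    gtf_h: Path
    gtf_m: Path
    orthologs: Path
    outdir: Path
    conflicts: Path | None = None
    min_obs: int = DEFAULT_MIN_OBS
    identity_grain: float = 1.0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    span: float = DEFAULT_SPAN
    degree: int = DEFAULT_DEGREE
    level: float = DEFAULT_LEVEL
    alpha: float = 0.05
    band: tuple[float, float] = (50.0, 70.0)  # identity band, annotation only
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fasta_h", "fasta_m", "gtf_h", "gtf_m", "orthologs", "conflicts"):
            p = getattr(self, name)
            if p is None:
                continue
            p = Path(p)
            setattr(self, name, p)
            if not p.exists():
                raise ValidationError(f"{name}: no such file {p}")
        self.outdir = Path(self.outdir)


@dataclass
class RunResult:
    """Everything one run computed, plus where it was written."""

    pairs: list[OrthologPair]
    points: list[IdentityPoint]
    points_filtered: list[IdentityPoint]
    trends: pd.DataFrame
    exon_table: pd.DataFrame
    product_table: pd.DataFrame
    im_by_exons_h: pd.DataFrame
    im_by_exons_m: pd.DataFrame
    curves: dict[str, SmoothedCurve]
    dropped: dict[str, int]
    tables: dict[str, Path]
    figures: dict[str, Path]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=FLOAT_FMT)


def _curve_frame(curve: SmoothedCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {"x": curve.grid, "fitted": curve.fitted, "lower": curve.lower,
         "upper": curve.upper}
    )


def compute_identities(
    seqs_h, seqs_m, table: OrthologTable, scoring: ScoringScheme
) -> dict[tuple[str, str], float]:
    """Percent identity per ortholog row; rows missing a sequence are skipped."""
    h = {s.seq_id: s for s in seqs_h}
    m = {s.seq_id: s for s in seqs_m}
    identities: dict[tuple[str, str], float] = {}
    for h_id, m_id in table.rows:
        if h_id not in h or m_id not in m:
            continue
        identities[(h_id, m_id)] = percent_identity(
            global_align(h[h_id], m[m_id], scoring)
        )
    return identities


def _safe_trend(xs, ys) -> TrendResult | None:
    try:
        return spearman_trend(xs, ys)
    except ValidationError:
        return None


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage and write tables and figures under ``config.outdir``."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    dropped: dict[str, int] = {}

    seqs_h = read_fasta(config.fasta_h, species="human")
    seqs_m = read_fasta(config.fasta_m, species="other")
    genes_h = read_gtf(config.gtf_h, species="human")
    genes_m = read_gtf(config.gtf_m, species="other")
    table = read_ortholog_table(config.orthologs)
    n_input = len(table)

    if config.conflicts is not None:
        records = read_conflicts_tsv(config.conflicts)
        rate = estimate_conflict_rate(records)
        retained, excluded = poisson_conflict_filter(records, rate, config.alpha)
        excluded_set = set(excluded)
        rows = [
            (h, m) for h, m in table.rows
            if h not in excluded_set and m not in excluded_set
        ]
        dropped["conflict_filter"] = len(table.rows) - len(rows)
        logger.info(
            "conflict filter: rate=%.3g, excluded %d gene(s), dropped %d pair(s)",
            rate, len(excluded), dropped["conflict_filter"],
        )
        table = OrthologTable(rows=rows)

    def _annotate(genes: Sequence[GeneAnnotation]):
        out, skipped = [], 0
        for g in genes:
            try:
                out.append(annotate_im(g))
            except ValidationError:
                skipped += 1
        return out, skipped

    im_h, skip_h = _annotate(genes_h)
    im_m, skip_m = _annotate(genes_m)
    if skip_h or skip_m:
        logger.warning("skipped %d human / %d other gene(s) without coding "
                       "transcripts", skip_h, skip_m)

    identities = compute_identities(seqs_h, seqs_m, table, config.scoring)
    pairs = build_pairs(im_h, im_m, table, identities)
    dropped["missing_annotation_or_identity"] = len(table.rows) - len(pairs)
    if not pairs:
        raise ValidationError("pipeline aborted at pair building: no usable pairs")
    assert n_input == len(pairs) + sum(dropped.values())

    points = estimate_points(pairs, grain=config.identity_grain)
    points_f = filter_min_obs(points, config.min_obs)

    curves: dict[str, SmoothedCurve] = {}
    if len(points_f) >= max(5, config.degree + 2):
        xf = [p.x for p in points_f]
        wf = [p.n_pairs for p in points_f]
        for name, ys in (
            ("imco", [p.imco for p in points_f]),
            ("p_im_h", [p.p_im_h for p in points_f]),
            ("p_im_m", [p.p_im_m for p in points_f]),
            ("product", [p.product for p in points_f]),
        ):
            curves[name] = loess_smooth(
                xf, ys, weights=wf, span=config.span,
                degree=config.degree, level=config.level,
            )

    exon_table = exon_points(pairs, grain=config.identity_grain)
    exon_table_f = exon_table[exon_table["n_pairs"] >= config.min_obs]
    product_table = imco_by_exon_product(pairs)
    genes_h_used = {p.human_gene for p in pairs}
    genes_m_used = {p.other_gene for p in pairs}
    im_by_e_h = im_by_exon_count([g for g in im_h if g.gene_id in genes_h_used])
    im_by_e_m = im_by_exon_count([g for g in im_m if g.gene_id in genes_m_used])

    trend_rows = []
    for analysis, xs, ys in (
        ("imco_vs_identity", [p.x for p in points_f], [p.imco for p in points_f]),
        ("p_im_h_vs_identity", [p.x for p in points_f], [p.p_im_h for p in points_f]),
        ("p_im_m_vs_identity", [p.x for p in points_f], [p.p_im_m for p in points_f]),
        ("product_vs_identity", [p.x for p in points_f], [p.product for p in points_f]),
        ("exons_h_vs_identity", exon_table_f["x"], exon_table_f["mean_exons_h"]),
        ("exons_m_vs_identity", exon_table_f["x"], exon_table_f["mean_exons_m"]),
        ("imco_vs_exon_product", product_table["product"], product_table["imco"]),
        ("im_fraction_vs_exons_h", im_by_e_h["exons"], im_by_e_h["im_fraction"]),
        ("im_fraction_vs_exons_m", im_by_e_m["exons"], im_by_e_m["im_fraction"]),
    ):
        t = _safe_trend(list(xs), list(ys))
        if t is not None:
            trend_rows.append(
                {"analysis": analysis, "rho": t.rho, "p_value": t.p_value, "n": t.n}
            )
    trends = pd.DataFrame(trend_rows, columns=["analysis", "rho", "p_value", "n"])

    tables: dict[str, Path] = {}
    write_points_table(points, outdir / "points.tsv")
    tables["points"] = outdir / "points.tsv"
    write_points_table(points_f, outdir / "points_filtered.tsv")
    tables["points_filtered"] = outdir / "points_filtered.tsv"
    for name, df in (
        ("exons_by_identity", exon_table),
        ("imco_by_exon_product", product_table),
        ("im_by_exon_count_human", im_by_e_h),
        ("im_by_exon_count_other", im_by_e_m),
        ("trend_summary", trends),
    ):
        path = outdir / f"{name}.tsv"
        _write_tsv(df, path)
        tables[name] = path
    for name, curve in curves.items():
        path = outdir / f"smoothed_{name}.tsv"
        _write_tsv(_curve_frame(curve), path)
        tables[f"smoothed_{name}"] = path

    figures = _make_figures(outdir, points_f, curves, exon_table_f, product_table,
                            im_by_e_h, im_by_e_m, config.band)
    logger.info("pipeline: %d input rows -> %d pairs (%s dropped)",
                n_input, len(pairs), dropped)
    return RunResult(
        pairs=pairs,
        points=points,
        points_filtered=points_f,
        trends=trends,
        exon_table=exon_table,
        product_table=product_table,
        im_by_exons_h=im_by_e_h,
        im_by_exons_m=im_by_e_m,
        curves=curves,
        dropped=dropped,
        tables=tables,
        figures=figures,
    )


def _plot_curve(ax, curve: SmoothedCurve | None, color: str, label: str) -> None:
    if curve is None:
        return
    ax.fill_between(curve.grid, curve.lower, curve.upper, color="0.8", alpha=0.6)
    ax.plot(curve.grid, curve.fitted, color=color, label=label)


def _make_figures(outdir, points_f, curves, exon_table, product_table,
                  im_by_e_h, im_by_e_m, band) -> dict[str, Path]:
    figures: dict[str, Path] = {}
    xf = [p.x for p in points_f]

    def save(fig, name):
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        figures[name] = path

    fig, ax = plt.subplots()
    ax.plot(xf, [p.imco for p in points_f], "k.", ms=4)
    _plot_curve(ax, curves.get("imco"), "tab:blue", "LOESS")
    ax.set(xlabel="% sequence identity", ylabel="IMco")
    save(fig, "imco_vs_identity")

    fig, ax = plt.subplots()
    _plot_curve(ax, curves.get("imco"), "tab:blue", "IMco")
    _plot_curve(ax, curves.get("product"), "tab:cyan", "P(IM_H|x)*P(IM_M|x)")
    ax.set(xlabel="% sequence identity", ylabel="probability")
    ax.legend()
    save(fig, "imco_vs_product_overlay")

    fig, ax = plt.subplots()
    ax.plot(xf, [p.p_im_h for p in points_f], "k.", ms=4, label="human")
    ax.plot(xf, [p.p_im_m for p in points_f], ".", color="0.5", ms=4, label="other")
    _plot_curve(ax, curves.get("p_im_h"), "gold", None)
    _plot_curve(ax, curves.get("p_im_m"), "tab:red", None)
    ax.set(xlabel="% sequence identity", ylabel="species IM fraction")
    ax.legend()
    save(fig, "species_im_vs_identity")

    fig, ax = plt.subplots()
    ax.plot(im_by_e_h["exons"], im_by_e_h["im_fraction"], "k.-", label="human")
    ax.plot(im_by_e_m["exons"], im_by_e_m["im_fraction"], ".-", color="0.5",
            label="other")
    ax.set(xlabel="exons of longest isoform", ylabel="fraction with IM")
    ax.legend()
    save(fig, "im_vs_exon_count")

    fig, ax = plt.subplots()
    ax.plot(exon_table["x"], exon_table["mean_exons_h"], "k.", label="human")
    ax.plot(exon_table["x"], exon_table["mean_exons_m"], ".", color="0.5",
            label="other")
    ax.set(xlabel="% sequence identity", ylabel="mean exons of longest isoform")
    ax.legend()
    save(fig, "exons_vs_identity")

    fig, ax = plt.subplots()
    ax.plot(product_table["product"], product_table["imco"], "k.", ms=4)
    ax.set(xlabel="exons_h * exons_m", ylabel="IMco", xscale="log")
    save(fig, "imco_vs_exon_product")

    fig, ax = plt.subplots()
    ax.plot(xf, [p.imco for p in points_f], "k.", ms=4)
    _plot_curve(ax, curves.get("imco"), "tab:blue", None)
    ax.axvspan(band[0], band[1], color="0.85")
    ax.set(xlabel="% sequence identity", ylabel="IMco")
    save(fig, "imco_vs_identity_band")
    return figures


def make_fixtures(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise a full synthetic input bundle for :func:`run_pipeline`.

    Writes paired FASTA and GTF files, the ortholog table, conflict
    records and the generative ground truth — 7 files total.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs, truth = generate_pairs(config)
    paths = {
        "fasta_h": outdir / "human.fa",
        "fasta_m": outdir / "other.fa",
        "gtf_h": outdir / "human.gtf",
        "gtf_m": outdir / "other.gtf",
        "orthologs": outdir / "orthologs.tsv",
        "conflicts": outdir / "conflicts.tsv",
        "truth": outdir / "truth.tsv",
    }
    lengths = generate_sequences(pairs, config, paths["fasta_h"], paths["fasta_m"])
    generate_gtf(pairs, config, paths["gtf_h"], paths["gtf_m"], lengths=lengths)
    write_ortholog_tsv(pairs, paths["orthologs"])
    sample = generate_conflicts(config)
    write_conflicts_tsv(sample.records, paths["conflicts"])
    truth.table.to_csv(paths["truth"], sep="\t", index=False, float_format=FLOAT_FMT)
    return paths
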