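"""Isoform-multiplicity co-occurrence (IMco) and its decomposition.

For a set of ortholog pairs with percent sequence identity psi, IMco at
identity value x is the fraction of pairs, among those with psi rounding
to x, in which *both* orthologs have isoform multiplicity — the
empirical estimate of P(IM_H, IM_M | x).  The joint probability factors
as

    P(IM_H, IM_M | x) = Q_HM * P(IM_H | x) * P(IM_M | x)

with Q_HM = sqrt( P(IM_H|IM_M,x) * P(IM_M|IM_H,x)
                  / (P(IM_H|x) * P(IM_M|x)) ),

which on empirical counts reduces to ``n * n_hm / (n_h * n_m)`` and
equals 1 when the two species' IM states are independent.  Estimates are
made at each individual (rounded) identity value — no clustering across
values — and estimates based on fewer than ``min_n`` pairs (default 5)
can be discarded as too noisy.

Trend statistics use Spearman's rank correlation computed over the
per-value points (x, statistic), not over raw pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .im_model import GeneIM
from .sequence_io import OrthologTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_OBS = 5  # minimum pairs behind a per-identity estimate


@dataclass(frozen=True)
class OrthologPair:
    """One human/other-species ortholog pair with its covariates."""

    human_gene: str
    other_gene: str
    psi: float  # percent identity, 0..100
    im_h: bool
    im_m: bool
    exons_h: int
    exons_m: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi <= 100.0:
            raise ValidationError(
                f"pair ({self.human_gene}, {self.other_gene}): psi out of [0, 100]"
            )
        if self.exons_h < 1 or self.exons_m < 1:
            raise ValidationError("exon counts must be positive")


@dataclass(frozen=True)
class IdentityPoint:
    """All estimates at one identity value x."""

    x: float
    n_pairs: int
    n_both_im: int
    imco: float
    p_im_h: float
    p_im_m: float
    q_hm: float | None  # None when Eq. is undefined (no IM in a species)

    @property
    def product(self) -> float:
        return self.p_im_h * self.p_im_m


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p_value: float
    n: int


def build_pairs(
    genes_h: Sequence[GeneIM],
    genes_m: Sequence[GeneIM],
    table: OrthologTable,
    identities: Mapping[tuple[str, str], float],
) -> list[OrthologPair]:
    """Join ortholog rows with IM annotations and identity values.

    Rows whose genes lack an annotation or identity are dropped; the
    drop count is logged, not fatal.
    """
    h_by_id = {g.gene_id: g for g in genes_h}
    m_by_id = {g.gene_id: g for g in genes_m}
    pairs = []
    dropped = 0
    for h_id, m_id in table.rows:
        gh, gm = h_by_id.get(h_id), m_by_id.get(m_id)
        psi = identities.get((h_id, m_id))
        if gh is None or gm is None or psi is None:
            dropped += 1
            continue
        pairs.append(
            OrthologPair(
                human_gene=h_id,
                other_gene=m_id,
                psi=float(psi),
                im_h=gh.has_im,
                im_m=gm.has_im,
                exons_h=gh.exons_longest,
                exons_m=gm.exons_longest,
            )
        )
    if dropped:
        logger.info("build_pairs: dropped %d of %d rows lacking annotation or identity",
                    dropped, len(table.rows))
    return pairs


def round_half_up(values: np.ndarray, grain: float = 1.0) -> np.ndarray:
    """Round to the nearest multiple of ``grain``, halves away from zero."""
    return np.floor(np.asarray(values, dtype=float) / grain + 0.5) * grain


def q_hm_from_counts(n: int, n_h: int, n_m: int, n_hm: int) -> float | None:
    """Q_HM from empirical counts: n * n_hm / (n_h * n_m).

    Undefined (None) when either species has no IM gene in the group;
    raises on inconsistent count ordering.
    """
    if not (0 <= n_hm <= min(n_h, n_m) and max(n_h, n_m) <= n):
        raise ValidationError(
            f"inconsistent counts: n={n}, n_h={n_h}, n_m={n_m}, n_hm={n_hm}"
        )
    if n_h == 0 or n_m == 0:
        return None
    return n * n_hm / (n_h * n_m)


def estimate_points(
    pairs: Sequence[OrthologPair], grain: float = 1.0
) -> list[IdentityPoint]:
    """Per-identity-value estimates of IMco and its factors.

    Pairs are grouped by psi rounded (half-up) to the nearest multiple
    of ``grain`` (default: integer percent).  Within each group, imco,
    p_im_h and p_im_m are plain fractions and q_hm comes from
    :func:`q_hm_from_counts`.
    """
    if not pairs:
        raise ValidationError("estimate_points needs at least one pair")
    df = pd.DataFrame(
        {
            "x": round_half_up(np.array([p.psi for p in pairs]), grain),
            "im_h": [p.im_h for p in pairs],
            "im_m": [p.im_m for p in pairs],
        }
    )
    df["both"] = df["im_h"] & df["im_m"]
    points = []
    for x, grp in df.groupby("x", sort=True):
        n = len(grp)
        n_h = int(grp["im_h"].sum())
        n_m = int(grp["im_m"].sum())
        n_hm = int(grp["both"].sum())
        points.append(
            IdentityPoint(
                x=float(x),
                n_pairs=n,
                n_both_im=n_hm,
                imco=n_hm / n,
                p_im_h=n_h / n,
                p_im_m=n_m / n,
                q_hm=q_hm_from_counts(n, n_h, n_m, n_hm),
            )
        )
    return points


def filter_min_obs(
    points: Sequence[IdentityPoint], min_n: int = DEFAULT_MIN_OBS
) -> list[IdentityPoint]:
    """Drop per-identity estimates based on fewer than ``min_n`` pairs."""
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    kept = [p for p in points if p.n_pairs >= min_n]
    if not kept and points:
        logger.warning("filter_min_obs: every point fell below min_n=%d", min_n)
    return kept


def exon_points(pairs: Sequence[OrthologPair], grain: float = 1.0) -> pd.DataFrame:
    """Mean longest-isoform exon counts per identity value.

    Returns columns ``x``, ``n_pairs``, ``mean_exons_h``, ``mean_exons_m``.
    """
    if not pairs:
        raise ValidationError("exon_points needs at least one pair")
    df = pd.DataFrame(
        {
            "x": round_half_up(np.array([p.psi for p in pairs]), grain),
            "exons_h": [p.exons_h for p in pairs],
            "exons_m": [p.exons_m for p in pairs],
        }
    )
    out = (
        df.groupby("x", sort=True)
        .agg(n_pairs=("exons_h", "size"),
             mean_exons_h=("exons_h", "mean"),
             mean_exons_m=("exons_m", "mean"))
        .reset_index()
    )
    return out


def imco_by_exon_product(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    """IMco grouped by the product of the two species' exon counts.

    Exact integer products, no binning.  Returns columns ``product``,
    ``n_pairs``, ``imco``.
    """
    if not pairs:
        raise ValidationError("imco_by_exon_product needs at least one pair")
    df = pd.DataFrame(
        {
            "product": [p.exons_h * p.exons_m for p in pairs],
            "both": [p.im_h and p.im_m for p in pairs],
        }
    )
    out = (
        df.groupby("product", sort=True)["both"]
        .agg(n_pairs="size", imco="mean")
        .reset_index()
    )
    out["imco"] = out["imco"].astype(float)
    return out


def _all_permutations(n: int) -> np.ndarray:
    """All n! index permutations, built level-by-level (n <= 10)."""
    perms = np.zeros((1, 1), dtype=np.int8)
    for k in range(2, n + 1):
        m = perms.shape[0]
        new = np.empty((m * k, k), dtype=np.int8)
        for pos in range(k):
            block = new[pos * m:(pos + 1) * m]
            block[:, pos] = k - 1
            block[:, :pos] = perms[:, :pos]
            block[:, pos + 1:] = perms[:, pos:]
        perms = new
    return perms


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho, n <= 10."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    perm_idx = _all_permutations(n)
    threshold = (abs(rho_obs) - 1e-12) * denom
    count = 0
    for lo in range(0, perm_idx.shape[0], 500_000):
        dots = ryc[perm_idx[lo:lo + 500_000]] @ rxc
        count += int(np.count_nonzero(np.abs(dots) >= threshold))
    return count / perm_idx.shape[0]


def spearman_trend(xs: Sequence[float], ys: Sequence[float]) -> TrendResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n > 10 the p-value uses the
    t-distribution approximation; for n <= 10 it is exact, from the full
    permutation distribution of the ranks.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValidationError("xs and ys must have equal length")
    n = len(xs)
    if n < 3:
        raise ValidationError("spearman_trend needs at least 3 points")
    rx = stats.rankdata(xs)
    ry = stats.rankdata(ys)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return TrendResult(rho=math.nan, p_value=math.nan, n=n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        p = float(stats.spearmanr(xs, ys).pvalue)
    return TrendResult(rho=rho, p_value=p, n=n)
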