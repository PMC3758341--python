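# imco — isoform-multiplicity co-occurrence vs protein divergence

A gene has **isoform multiplicity (IM)** when it expresses more than one
isoform (through alternative splicing or alternative transcription
initiation/termination). Given a set of one-to-one ortholog pairs
between two species — say human and mouse — and their percent protein
sequence identity x (the inverse of protein divergence), the
**co-occurrence of isoform multiplicity**

    IMco(x) = P(IM_H, IM_M | x)

is the fraction of pairs at identity x in which *both* orthologs have
IM. `imco` estimates this curve and its decomposition

    P(IM_H, IM_M | x) = Q_HM · P(IM_H | x) · P(IM_M | x),
    Q_HM = sqrt( P(IM_H | IM_M, x) · P(IM_M | IM_H, x)
                 / (P(IM_H | x) · P(IM_M | x)) ),

where Q_HM = 1 means the two species' IM states are independent given
identity. On empirical counts Q_HM reduces to `n·n_HM / (n_H·n_M)`. The
package also quantifies the gene-level mechanism behind the monotone
IMco-identity relationship: the probability of IM saturates with the
exon count of the longest isoform, and mean exon count itself varies
monotonically with identity.

It is a library for comparative genomicists studying how alternative
splicing capacity co-evolves with protein divergence, with:

- **sequence_io** — FASTA, Ensembl-dialect GTF and ortholog-TSV readers;
  TSV writers with `NA` for missing values;
- **curation** — the Poisson sequence-conflict filter (a gene is
  excluded when its conflict count has upper-tail probability < 0.05
  under a pooled per-residue rate), predicted-RefSeq (`XP_`/`ZP_`)
  exclusion, and longest-CDS isoform selection;
- **alignment** — global Needleman–Wunsch alignment (BLOSUM62, affine
  gaps 10/0.5 by default) and psi = 100·2·n_id/(n_a + n_b);
- **im_model** — per-gene IM annotation, exon counts, and the RNA-seq
  collapse rules (IM in ≥1 tissue per individual; "any" vs "each"
  across individuals);
- **cooccurrence** — per-identity-value estimation (no clustering
  across values), the Q_HM factorisation, the <5-observation filter,
  exon-count analyses and Spearman trend tests (exact permutation
  p-values for n ≤ 10);
- **trend** — LOESS smoothing (tricube kernel, count-weighted) with a
  pointwise dispersion envelope that tightens with sample size;
- **synthetic_data** — a generative model producing ortholog pairs,
  FASTA/GTF/TSV fixtures and conflict records with the statistical
  structure above, so the whole pipeline is testable without database
  downloads;
- **pipeline / cli** — end-to-end orchestration plus a thin `imco`
  command (`simulate`, `run`, `align`, `estimate`).

## Worked example

```python
from imco import (SyntheticConfig, generate_pairs, estimate_points,
                  filter_min_obs, spearman_trend)

pairs, truth = generate_pairs(SyntheticConfig(n_pairs=12000, seed=1))
points = filter_min_obs(estimate_points(pairs))   # drop estimates with < 5 pairs
trend = spearman_trend([p.x for p in points], [p.imco for p in points])
print(f"IMco vs identity: Spearman rho = {trend.rho:.3f}, p = {trend.p_value:.2e}")
```

prints

```
IMco vs identity: Spearman rho = 0.759, p = 1.01e-09
```

together with, for a few identity values (`examples/01_simulate_and_estimate.py`):

```
  x =  65.0%  n =   72  IMco = 0.500  P(IM_H|x) = 0.653  P(IM_M|x) = 0.708
  x =  85.0%  n =  508  IMco = 0.516  P(IM_H|x) = 0.734  P(IM_M|x) = 0.703
  x =  95.0%  n =  292  IMco = 0.551  P(IM_H|x) = 0.733  P(IM_M|x) = 0.771
```

The positive rho says that ortholog pairs at high sequence identity
(low protein divergence) are more likely to *both* have multiple
isoforms than diverged pairs — and in this synthetic dataset that trend
arises purely from the exon-count mechanism, since IM was generated
with no direct dependence on identity. The `examples/` directory holds
one short script per capability (alignment, Q_HM decomposition, the
exon mechanism and its reversed fly-like regime, the full file-based
pipeline, RNA-seq collapsing).

A full file-based run (`imco run --fasta-h ... --outdir out/`) writes
the per-identity points table, smoothed curves with envelopes, exon
tables, a trend summary, and seven figures, including the variant that
shades the 50–70% identity band where protein function conservation
changes character.

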