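# Methods

## The statistic

For ortholog pairs between a reference species (labelled "human"/H
throughout) and a second species (M), with percent protein sequence
identity psi as the inverse measure of protein divergence, the package
estimates, at each identity value x:

- **IMco** = P(IM_H, IM_M | x): the fraction of pairs whose genes both
  have more than one annotated isoform;
- the species marginals P(IM_H | x), P(IM_M | x) and their product;
- the coupling factor **Q_HM** relating the joint to the product,

      Q_HM = sqrt( P(IM_H|IM_M,x) · P(IM_M|IM_H,x) / (P(IM_H|x) · P(IM_M|x)) ),

  which on the empirical counts of one identity group collapses
  algebraically to `n · n_HM / (n_H · n_M)`, so the identity
  IMco = Q_HM · P(IM_H|x) · P(IM_M|x) holds *exactly* (to float
  round-off, asserted at 1e-12) on every estimated point. Q_HM is
  undefined (reported `NA`) when a group has no IM gene in one species,
  since the conditionals lose their denominators.

Estimation is strictly per identity value: pairs are grouped by psi
rounded half-up to the nearest multiple of the identity grain (default
1 percent, matching the resolution at which such curves are usually
drawn and plotted); no clustering or binning across values is applied.
Because groups in the low-identity tail can hold very few pairs, IMco
estimates there are noisy and pile up at 0 and 1; the
minimum-observation filter (default: at least 5 pairs) removes them
without touching any retained value.

### Trend tests

Monotone dependence is quantified with Spearman's rank correlation over
the per-value points (x, statistic) — after per-x estimation, not over
raw pairs, so every point contributes equally regardless of its pair
count. Ties get average ranks. Two-sided p-values use the
t-approximation for n > 10 and the exact permutation distribution
(full n! enumeration, vectorised) for n ≤ 10.

## Percent identity

psi = 100 · 2·n_id / (n_a + n_b): identical aligned residue pairs over
the average of the two *unaligned* protein lengths, from an optimal
global (Needleman–Wunsch) alignment of the longest isoform of each
gene. Scoring is BLOSUM62 with affine gap penalties, open 10 and extend
0.5 (a gap of length L costs 10 + 0.5·(L−1)); all three are
configurable, and psi is insensitive to reasonable scoring choices in
the identity range analysed. Positions aligned to gaps never count
toward n_id. Biopython's `PairwiseAligner` performs the dynamic
programming; when several alignments are co-optimal the aligner's first
traceback is used, which is deterministic for fixed inputs (co-optimal
alignments can in principle differ in n_id; this choice is a documented
convention, not an optimisation over tracebacks).

## Curation

Curated protein databases annotate sequence conflicts between
independently reported sequences of one protein. The package pools a
single genome-wide per-residue conflict rate (total conflicts / total
residues) and excludes a gene of length L with k conflicts when the
Poisson upper tail P(X ≥ k | mu = rate·L) falls below alpha
(default 0.05) — i.e. genes with significantly *more* conflicts than
chance predicts. The upper-tail (rather than two-sided) form follows
from the filter's purpose: too few conflicts are not evidence of a bad
record. k = 0 is always retained (P(X ≥ 0) = 1), and exclusion is
monotone in k at fixed mu. Isoform identifiers with the predicted
RefSeq prefixes `XP_`/`ZP_` are dropped outright.

**Longest isoform** means largest CDS length in residues (GTF CDS
nucleotides floor-divided by 3; the stop codon is not subtracted since
only relative lengths matter). Ties break to the lexicographically
smallest transcript id for reproducibility. The exon-count covariate
is the exon count of that same transcript, so the sequence aligned and
the exon count analysed always refer to one isoform.

## RNA-seq IM collapsing

Per-sample IM calls indexed by (gene, individual, tissue) collapse in
two steps: a gene has IM for an individual when it has IM in at least
one tissue; across individuals either "any" (≥ 1 individual) or "each"
(every individual). A gene with no sample for an individual counts as
no-IM there (absence-of-evidence convention, logged), which makes the
"each" call set a subset of the "any" set by construction. Any FPKM
thresholding happens upstream; the table this package consumes is
already boolean.

## LOESS smoothing and envelope

At each grid point (the sorted unique observed x values — no
interpolation grid, so smoothed rows align with the points table), the
span-fraction nearest neighbours get tricube kernel weights scaled by
the distance to the farthest included neighbour, multiplied by the
prior weights (the pair count behind each point), and a local
polynomial is fitted by weighted least squares on a centred basis.
Defaults: span 0.75, degree 2, envelope level 95%, no robustness
iterations — the conventions of the standard R smoother for this kind
of figure.

The envelope is fitted ± z·SE with SE derived under the variance model
Var(y_i) = sigma²/w_i: a fraction estimated from w_i pairs is w_i times
more precise, so the envelope tightens where the data are dense and
widens in the sparse low-identity tail. sigma² is estimated from the
kernel- and count-weighted local residuals with an approximate
degrees-of-freedom correction; when a neighbourhood has no residual
degrees of freedom the SE is 0 (exact local interpolation). Two
consequences verified by tests: doubling all counts shrinks the
envelope by sqrt(2) without moving the fit, and the smoother is exactly
equivariant under affine transforms of y. The envelope is a pointwise
dispersion band, not a simultaneous confidence or prediction band.

## The synthetic generator

The generator encodes the study conditions the analysis assumes, as a
minimal generative mechanism:

| parameter | default | meaning |
|---|---|---|
| n_pairs | 12000 | ortholog pairs (the scale of a curated two-species set) |
| identity | truncnorm(85, 10) on [30, 100] | percent-identity distribution |
| exon intercept a | log 3 | log mean exon count at x = 0 |
| exon slope b | +0.012 / percent | exon-identity gradient; negative = fly-like regime |
| NB dispersion | 2.0 | overdispersion of exon counts (shifted to ≥ 1) |
| q_h, q_m | 0.25 | per-exon-boundary chance of supporting an extra isoform |
| coupling c | 0 | shared-uniform mixture between species' IM draws |
| protein length | normal(450, 120), min 50 | residues |
| conflict model | rate 1e-3, 5% outliers at 20x | Poisson conflict regimes |

Per pair: x ~ identity distribution; per species, exon count
E = 1 + NB with mean exp(a + b·x) − 1; IM probability
p = 1 − (1 − q)^(E−1) — the minimal saturating form with p = 0 for
single-exon genes and p → 1 for exon-rich genes; IM booleans drawn
with a mixture coupling (with probability c both species compare the
same uniform to their p, else independent uniforms; c = 0 independent,
c = 1 comonotone). Crucially, IM depends on identity *only through*
exon count, so a positive IMco-identity trend in the output
demonstrates that the exon mechanism alone suffices to produce it.
At these defaults roughly 72% of genes per species have IM, in the
range reported for curated mammalian annotation sets.

File fixtures: FASTA pairs use substitution-only divergence (exactly
round(L·(1−x/100)) positions replaced by different residues, no
indels), so the target identity is realised exactly up to rounding and
the alignment stage can be validated end-to-end; GTFs give each gene
one transcript per isoform with the longest transcript carrying the
drawn exon count and strictly largest CDS, with isoform counts
1 + truncated Binomial(E−1, q) consistent with the drawn IM flags;
conflict records mix the baseline and outlier Poisson regimes. All
randomness flows from one seed through fixed per-operation substreams,
making every output byte-reproducible.

What the generator does *not* emulate: indels and rearrangements (an
optional indel process was considered and left out so that target
identity stays exact), codon-level evolution, annotation-platform
biases, correlated exon counts between orthologs, and tissue-level
expression structure. Passing tests therefore show the estimators are
correct and the exon mechanism is sufficient — not that real annotation
sets are free of the biases the generator omits.

## Numerical and design choices

- Identity grain: round half-up to integer percent (`--identity-grain`
  exposed); half-up rather than banker's rounding keeps the group
  boundaries intuitive and deterministic.
- Q_HM degenerate denominators propagate as missing (`NA`), never 0
  or 1.
- Exact-permutation Spearman p-values only for n ≤ 10 (10! ≈ 3.6M
  permutations, enumerated vectorised in chunks); beyond that the
  t-approximation is standard and accurate.
- Tables are written with 12 significant digits; round-trips preserve
  values to 10 significant digits, and reruns with identical inputs are
  byte-identical.
- Problem sizes in the test-suite and acceptance script (12000 pairs
  for statistical analyses, 20000 for the Q_HM calibration, a few
  hundred for file-based end-to-end runs, alignment oracles at lengths
  ≤ 8) are chosen so each check is decisive at desk scale while the
  whole suite stays fast.
- Figures are a courtesy output; every asserted number lives in the
  TSV tables, which are recomputable from the points table alone.

## Limitations

- Percent identity from a single fixed scoring scheme; no scoring
  sensitivity analysis is automated.
- n_id of a co-optimal alignment is convention-dependent (see above).
- The per-x Spearman convention (points, not raw pairs) is a documented
  choice; correlations computed over raw pairs would weight dense
  identity regions more heavily.
- No phylogenetic correction across pairs and no confidence intervals
  on individual IMco points (the envelope summarises dispersion of the
  smoothed curve only).
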