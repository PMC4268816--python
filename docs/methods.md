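# Methods

## Scope and data model

The package analyses a set of nucleotide coding sequences. Sequences are
normalised to uppercase DNA on input (U→T; IUPAC ambiguity letters→N) and
filtered before any statistic is computed:

1. records not strictly longer than `min_len_nt` (default 300 nt) are
   rejected (`too_short`) — short CDSs make per-gene codon proportions too
   noisy to be useful;
2. an incomplete terminal codon is trimmed, then a terminal stop codon is
   trimmed;
3. records with an in-frame internal stop are rejected (`internal_stop`)
   rather than truncated: the intended inputs are predicted CDSs, and an
   internal stop indicates a frame or prediction error, not a usable gene.

Codons containing N are excluded from all counting — numerators and
denominators alike — in every index. Rejections are returned as data and
written to a TSV log; `retained + rejected = input` always holds.

Internally codons are DNA-spelled; all report files print RNA spelling, the
convention of codon-usage tables.

## Indices

**RSCU.** For codon *i* of an amino acid with family size *n*:
`RSCU_i = n · g_i / Σ_family g`. Families with zero total have undefined
(NaN) RSCU; single-codon families (Met, Trp) get RSCU 1 when present.
Printed-table comparisons round half away from zero to 2 decimals, matching
how such tables are typeset.

**ENC.** Wright's estimator. Per family with total *n* ≥ 2 the homozygosity
is `F = (n·Σp² − 1)/(n − 1)`; F is averaged over the amino acids of each
degeneracy class (9 two-fold, Ile as the only three-fold, 5 four-fold, and
the three six-fold amino acids Leu/Ser/Arg as their own class), and
`ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`. If Ile is unobserved, F̄₃ is imputed
as the mean of F̄₂ and F̄₄ (the estimator's standard repair, keeping genes
comparable); if any other class mean is undefined or zero, ENC is reported
missing. Sums above 61 are capped at 61, the theoretical uniform-usage
ceiling. The expected-ENC curve under pure third-position composition *s* is
`2 + s + 29/(s² + (1−s)²)`, also capped at 61; its maximum (60.5) sits at
s = 0.5 and its end points are 31 (s = 0) and 32 (s = 1). One sometimes sees
this formula typeset with denominator `s² + (1 − s²)`, which is identically 1
and yields a constant ≈31–32 — an evident typographical corruption of
`(1 − s)²`; the standard form is used here.

**GC metrics.** GC1/GC2/GC3 are G+C fractions per codon position over all
counted sense codons; GC3s restricts third positions to the 59 analysis
codons (Met, Trp and stops excluded); GC12 = (GC1+GC2)/2. GC3 (all sense
codons) and GC3s are deliberately distinct quantities: the neutrality plot
uses GC3, the ENC curve and the CA correlations use GC3s. Both are reported
per gene so either convention can be checked.

**CAI.** Relative adaptiveness is computed on a reference count table
(typically pooled ribosomal-protein genes): zero-count codons receive a
pseudocount of 0.5 before RSCU, then `w_i = RSCU_i / RSCU_max(family)`, so
max w = 1 in every family and w > 0 everywhere. The pseudocount keeps the
geometric mean finite without materially distorting observed ratios; 0.5 is
the usual additive-smoothing compromise. CAI of a gene is
`exp(mean of log w)` over its analysis-codon occurrences; Met/Trp never
contribute. When no reference list is supplied, the whole gene set is pooled
as its own reference (self-referential CAI, as classic codon-usage tools do);
all results in the documentation use an explicit reference set.

**GRAVY / Aromo.** Mean Kyte–Doolittle hydropathy and the fraction of
F/Y/W residues of the translated protein; unknown residues (X, from
N-containing codons) are excluded from both numerator and denominator.

## Dataset diagnostics

**Neutrality plot.** Ordinary least squares of GC12 on GC3, with the
Spearman rank correlation (the package's correlation convention throughout)
reported alongside. A slope near 1 indicates mutational pressure acting on
all positions; near 0, selective constraint on positions 1–2. Constant GC3
leaves the slope undefined (NaN), not an error.

**ENC–GC3s profile.** Per-gene `ratio = (ENC_exp − ENC_obs)/ENC_exp`,
histogrammed in left-closed bins of width 0.05 on [−1, 1). Genes under pure
compositional bias pile up around 0; selection pushes genes below the curve
(positive ratios).

**PR2.** Third-position A/T/G/C are tallied over the eight four-fold
degenerate families (Ala, Arg-CGN, Gly, Leu-CUN, Pro, Ser-UCN, Thr, Val);
per gene `x = G3/(G3+C3)`, `y = A3/(A3+T3)`, reported with dataset mean ± SD.
The axis assignment follows the conventional "y against x" reading; genes
with a zero denominator are excluded and tallied.

**Correspondence analysis.** Standard CA of the genes × 59 RSCU matrix
(missing RSCU imputed as 0; all-zero rows dropped with a warning): with P
the matrix normalised to total 1, row/column masses r and c, the SVD of
`D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}` gives principal row and column coordinates
and per-axis inertia fractions. CA axis signs are arbitrary; axis 1 is
oriented so that its correlation with gene GC content is negative (GC-rich
genes on the left), and tests compare coordinates up to sign.
Rank-deficient inputs return fewer axes rather than failing. CA is run on
RSCU rather than raw counts so that amino-acid composition differences do
not dominate the ordination.

**Gene classes and correlations.** Genes are labelled with precedence
ribosomal > hydrophobic (GRAVY strictly above a threshold, default 5) >
aromatic (Aromo ≥ 0.15) > other. The default GRAVY cutoff of 5 is kept for
compatibility with published class definitions even though it exceeds the
Kyte–Doolittle attainable mean of 4.5 (no gene can be hydrophobic under it);
set `gravy_threshold=0.5` or similar for a usable classification. The
correlation battery reports Spearman ρ with two-sided p for twelve standard
pairs (axis1 against GC/GC3s/ENC; CAI against ENC/GC3s/GC/axis1; length
against axis1/ENC/CAI; GRAVY and Aromo against ENC), with pairwise deletion
and a 5-complete-pair minimum.

## Optimal codons

Genes with defined CAI are sorted by CAI (ties broken lexicographically by
id for determinism); the top and bottom `floor(0.05·N)` (minimum 1) form the
high/low pools, whose member counts are summed. Each of the 59 analysis
codons is tested with a 2×2 Pearson chi-square without continuity
correction: rows codon vs rest-of-family, columns high vs low pool; a zero
margin leaves the test undefined. A codon is flagged optimal iff p < 0.01
and pooled RSCU(high) > RSCU(low) — there is no requirement that
RSCU(high) > 1, and no multiple-testing correction by default (a Bonferroni
switch exists). The codon-vs-rest-of-family table is the family-conditional
comparison implied by reporting per-family RSCU; the alternative
(codon vs all other codons) would confound amino-acid composition with codon
choice.

### A caveat on the CAI-extremes screen

Because CAI is computed from the very codon counts that are subsequently
pooled and tested, ranking genes by CAI selects the extreme pools along the
direction of the reference-weight vector in codon-usage space. Even with no
selection at all and homogeneous mutation (the generator's unbiased null),
the high and low pools therefore differ systematically, and the pooled
chi-square — whose detection threshold shrinks with pool size while the
conditioning-induced shift does not — flags several codons per run (about
6–13 of 59 at α = 0.01 with 1,000 genes of 100–400 codons; the effect is
independent of gene length and grows with the number of genes, and is much
stronger when per-gene GC3 varies). A nonempty optimal-codon list from this
screen is thus not, by itself, evidence of translational selection;
corroboration should come from the independent signatures (CAI–ENC
correlation, low-ENC outliers below the expected curve, axis-1 structure).
This circularity is a property of the method, not of the implementation.

## Synthetic data generator

`simulate_cds_set` emulates a transcriptome-derived CDS set. Per gene:
internal length is uniform on 100–400 codons (comfortably above the 300-nt
filter, in the range of typical predicted CDSs); a GC3 target *t* is drawn
from Beta(2, 2) (wide spread centred on 0.5, mirroring datasets whose
per-gene GC3 spans nearly the full unit interval) or fixed via `gc3_fixed`;
an expression level *e* is drawn from Beta(2, 5) (most genes lowly
expressed). Amino acids are i.i.d. uniform over the 20 (composition is not a
quantity under study here); each amino acid's codon is drawn from its family
with weight `t` for G/C-ending and `1 − t` for A/T-ending codons, times
`exp(s_sel · e)` on the family's preferred codon. The default preferred set
is one C-ending (else G-ending) codon per multi-codon family — 18 G/C-ending
codons, the composition optimal-codon studies typically report. A start
codon is prepended, a random stop appended; the designated "ribosomal"
reference ids are the top 5% of genes by expression. All randomness flows
from one integer seed; a fixed seed gives byte-identical FASTA.

Two optional couplings exist for testing specific diagnostics:
`gc12_coupling` tilts amino-acid composition of high-GC3 genes toward amino
acids with GC-rich first/second codon positions (creating a genuine
neutrality-plot slope), and `length_expression_coupling` makes highly
expressed genes shorter (reproducing the negative length–bias correlations).

What the generator does **not** emulate: assembly artifacts and sequencing
error, isoforms, codon-pair or dinucleotide effects, amino-acid composition
evolution, and within-gene heterogeneity of mutational bias. Passing tests
on synthetic data therefore validate the statistical machinery and its
directional signatures, not the biology of any particular genome.

## Numerical conventions

- Missing values (undefined ENC, CAI of empty genes, RSCU of unobserved
  families, undefined chi-squares) are NaN and propagate as data, never
  exceptions; errors are reserved for malformed inputs.
- RSCU is kept at full precision internally; only printed-table comparisons
  round (half away from zero, 2 decimals).
- CA keeps axes with singular values above a relative tolerance of
  `max(m, n)·eps·σ₁`, so duplicated-row and rank-deficient inputs shrink the
  axis set instead of producing noise axes.
- Simulation-backed tests use fixed seeds and 3-standard-error bands;
  problem sizes (150–1,000 genes, 100–400 codons) are chosen so each check
  runs in seconds while keeping Monte-Carlo error well inside those bands.
- Pipeline outputs are written to a staging directory and moved into place
  only on success; no timestamps are recorded, so identical inputs and
  configuration reproduce identical bytes.
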