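# Methods

This note documents the statistical model, the numerical conventions, the
synthetic-data generator and the genuinely open design choices of
`maxgrowth`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The package rests on one biological premise: selection for fast growth
biases the synonymous codon usage of highly expressed genes (HEG —
operationally, ribosomal proteins) toward codons matched to abundant tRNAs,
and the strength of that bias tracks the minimal doubling time `d` across
bacteria and archaea.  The predictor is purely correlative — an empirical
regression, not a mechanistic model — so it estimates the *maximal* growth
capacity a genome is selected for, not realised growth in any particular
environment.

### ENC′ (background-corrected effective number of codons)

For each synonymous family, expected codon frequencies are the
position-independent products of the background nucleotide frequencies
(A, C, G, T over the coding sequence, N excluded), renormalised within the
family.  With observed frequencies `p_i`, expectations `e_i`, family size
`k` and `n` counted codons, the corrected homozygosity is

    X² = n · Σ (p_i − e_i)²/e_i
    F̂′ = (X² + n − k) / (k·(n − 1))

Families with `n < 2` are inestimable and skipped.  Class means `F̄_k` are
simple averages over the families of each degeneracy class and combine as
`ENC′ = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` (translation table 11; the
constant 2 is Met + Trp).  This sixfold-as-own-class layout reproduces the
exact bounds — 20 when every amino acid uses one codon (with a uniform
background), 61 when usage matches the background — and the result is capped
to [20, 61] against sampling noise.  A split-sixfold convention
(Leu/Ser/Arg split into 2- and 4-fold sub-families, generic family-count
weights) is available via `sixfold="split"`; its natural floor is 23, so
the own-class layout is the default.

Missing-class handling (needed for short genes): an absent threefold class
is imputed as `(F̄₂ + F̄₄)/2`; any other single absent class as the mean of
the observed class means; with ≥ 2 classes absent the index is undefined and
the gene is dropped from gene-averaged means.

ENC′ is exactly invariant under gene permutation; under duplication of the
whole gene set it is invariant only up to the finite-sample correction term
`(n − k)/(k(n − 1))`, a sub-0.2-unit effect at genome-scale counts that the
suite checks explicitly.

### ΔENC′, P and S

`ΔENC′ = (ENC′_all − ENC′_HEG)/ENC′_all`.  The "all genes" side is the
partition's background/control set; users wanting the strict
every-coding-sequence convention simply include the HEG there (the
difference is a few percent of genes at genome scale).

`P = C₁/(C₁+C₂)` for Phe (TTC/TTT), Ile (ATC/ATT), Tyr (TAC/TAT),
Asn (AAC/AAT); C₁ is the codon Watson-Crick-paired to the single tRNA
anticodon, hence translationally optimal in every species.  `S_i` is the
log odds ratio of P in HEG versus all genes and S the mean of the `S_i`
weighted by the HEG `C₁+C₂` counts — count weighting follows the
information content of each amino acid's sample.

Pseudocounts: in gene-averaged mode, 0.5 is added to both C₁ and C₂ of a
gene when either count is zero (small per-gene counts make zeros common and
the log odds must stay finite).  Concatenated genome-scale counts get no
pseudocount; an amino acid with degenerate frequencies (0 or 1) there is
dropped from S with a warning, and S is undefined only when no amino acid
remains usable.

### Two computation modes

*Concatenated*: pool each gene set, one count table per set, background =
average coding nucleotide frequency of the pool.  Correct for single
genomes.  *Gene-averaged* (`ΔENC′_a`, `S_a`): ENC′ and P per gene, each
gene against its own background; set-level values from the per-gene means
by the same formulas.  Pooling across a metagenome would inflate ENC′
spuriously because different species prefer different codons; per-gene
computation avoids that, which is why the community workflow uses it
throughout.  For a single gene the two modes agree exactly (tested).

### Composite F and the regression

ΔENC′ and S are z-standardised (sample sd, ddof = 1) and F is the first
principal component of their 2×2 correlation matrix — for two variables the
loadings are `(1, ±1)/√2`; the sign is flipped so that stronger selection
increases F.  Using the correlation rather than covariance matrix is
deliberate: the indices live on different scales.

The response is Box-Cox transformed: `Φ_λ(d) = (d^λ − 1)/λ`, `ln d` at
λ = 0, evaluated via `expm1`/`log1p` so the λ → 0 limit is numerically
exact.  Refits estimate λ by profile likelihood
(`scipy.stats.boxcox_normmax`) or fix λ = 0; coefficients come from OLS
(statsmodels).  The published mesophilic coefficients (intercept 0.8741,
slope −0.6496) are used with λ = 0: the transform is documented as
approximating the log, and the worked trio F ∈ {−0.23, −0.20, −0.25} then
back-transforms to ≈ 2.7–2.8 h, reproducing the reported ~3 hours
(recomputed by `scripts/acceptance.py`, target `t6`).

The original publication does not print the PCA standardisation constants
or loadings, so a published-coefficient model cannot map raw (ΔENC′, S) to
F by itself.  Two supported routes: pass F directly, or anchor the
published coefficients with a composite fitted on a training index table
(`maxgrowth fit --published-coefficients`).  Published mode deliberately
refuses OGT-adjusted predictions — the OGT term's coefficients are not
printed — and reports the mesophilic model instead; OGT models
(`Φ = a + b·F + c·OGT`) are available by refit.  Mesophiles are defined as
15 °C ≤ OGT ≤ 60 °C (psychrophiles below, thermophiles above).

### Classification and nulls

Classes are right-open: [0,1) very fast, [1,2) fast, [2,5) intermediate,
[5,∞) slow (5 h inclusive-slow per the class definition).  Under a
uniformly random predicted class with observed class sizes `n_c`, the
expected proportions are exact = 25 %, exact-or-adjacent
`Σ n_c·a_c/(4·Σn_c)` with `a_c` the number of acceptable classes (self +
adjacent), and gross errors (slow ↔ fast/very fast)
`[2·n_slow + n_vf + n_fast]/(4·Σn_c)`.  With the mesophile sizes
46/26/41/74 these give 25 %, ≈ 59.0 % and ≈ 29.4 % (targets t1–t3; the
sizes sum to 187, target t4).

### Pairwise relative differences

`Δ_ij = |t(v_i) − t(v_j)|` normalised by the maximum over all unordered
pairs (optionally Box-Cox-transforming first, as for doubling times); the
extreme pair maps to exactly 1.  214 species yield 22 791 unordered pairs
(target t5).  All-identical input degenerates to a zero matrix with a
warning rather than an error.

## Metagenome workflow

ORFs ≥ 450 nt (default) are extracted from contigs in all six frames as
stop-bounded regions trimmed to their first start codon (ATG/GTG/TTG by
default; trimming can be disabled for raw stop-to-stop behaviour, since the
original pipeline's getorf mode is not documented).  Regions opening at a
contig edge are kept; regions without a closing stop are not.  Codons
containing N are skipped individually rather than discarding the gene,
because metagenome contigs contain Ns.

HEG detection offers three routes: explicit id lists, annotation keyword
match ("ribosomal protein"), or protein-level similarity against a
reference FASTA — local BLOSUM62 alignment (Biopython PairwiseAligner,
gap open −11/extend −1) with a Karlin-Altschul expectation
(λ = 0.267, K = 0.041) thresholded at 1e-5 by default.  The packaged
reference FASTA is a synthetic stand-in (random sequences, clearly labelled
in the file); point `--heg-similarity` at a real ribosomal-protein database
for production use.  The same applies to the packaged ubi-tRNA anticodon
list used by the trait module: it is a constructed stand-in (Watson-Crick
anticodons of commonly preferred codons) to be replaced by the published
nearly-ubiquitous-tRNA list.

Bootstrap: each replicate resamples background genes and HEG genes with
replacement, independently, to their original cardinalities, and recomputes
the full prediction ("independently and simultaneously": the error bar
reflects both sets).  Genes, not contigs, are the resampling unit.
Per-gene statistics are cached once, so 1000 replicates (the default) cost
milliseconds.  Community comparisons pair replicates by iteration under a
shared master seed; the p-value is the fraction of iterations whose
difference contradicts the sign of the observed mean difference, reported
as `p < 1/B` when no iteration contradicts it.  Swapping the arguments
mirrors both the differences and the expectation, so the p-value is
symmetric by construction.

Resampling to original cardinality (rather than a fixed size) is an
assumption — the original description does not say — recorded here as the
package's choice.

## Genome traits

Stable-RNA multiplicities and origin-relative positions complement the
codon-usage indices.  rRNA operons are counted as clusters of 16S anchors
merged within a configurable gap (default 3 kb; the merging is
order-independent); tRNAs split into ubi / non-ubi by anticodon membership.
Relative origin distance = smallest circular distance / (replicon/2), so
0 is the origin and 1 the opposite point; it is rotation-invariant and
symmetric about the origin (property-tested).  Origins are inputs; archaea
(multiple, hard-to-assess origins) skip distance traits when flagged.

## Synthetic data generator

`generate_genome` emulates mutation–selection structure: background genes
draw codons iid from the G+C-driven mutational background (codon probability
∝ product of its nucleotide frequencies); HEG genes reweight optimal codons
by `exp(s_strength)` *within* each synonymous family, preserving the
amino-acid marginal exactly — so any HEG-vs-background index contrast is a
pure codon-bias signal.  The optimal set is the four C₁ codons plus the most
background-consistent codon of every other family, giving both ΔENC′ and S
signal.  Defaults (500 genes, 50 HEG, 900 nt mean length, G+C 0.5,
s_strength 1, lengths sd 20 % floored at 450 nt) sketch a small realistic
genome; tests use smaller instances (40–80 genes) to keep the suite in
seconds.

What the generator does **not** emulate: amino-acid composition differences
between HEG and background (real ribosomal proteins are compositionally
distinct), within-genome G+C heterogeneity, strand bias, sequencing error,
chimeric contigs, or phylogenetic structure.  Passing tests therefore
demonstrate the statistical machinery — index definitions, monotonicity in
injected selection, bootstrap behaviour, parameter recovery — not field
accuracy on real communities, which requires real genomes with known
doubling times.

`generate_training_table` embeds a latent composite in the two index
columns such that refitting the composite on the emitted table reproduces
the latent scores exactly; `d` then follows
`Φ⁻¹_λ(intercept + slope·F + ε)`.  With ε = 0 and the true λ, refitting
recovers the coefficients to machine precision — the basis of the exact
parameter-recovery tests; with ε ~ N(0, 0.3) at n = 200 recovery is checked
within three standard errors.

## Problem sizes and numerical conventions

Test-suite simulations use 40–820-gene genomes, 60–200-species training
tables, and 25–300 bootstrap replicates — sizes chosen so the full suite
runs in seconds while leaving each statistical check well-powered; the
bootstrap-scaling check scales HEG and background sets together, since the
1/√n law applies to the community size, not one set.  Other conventions:
family homozygosities are floored at 1e-12 (the ENC′ cap absorbs the
consequences); ties in the optimal-codon choice break lexicographically;
training tables need ≥ 5 rows (OLS with two parameters retains degrees of
freedom) and composites ≥ 3 rows with nonzero variance; all randomness
flows through `numpy.random.default_rng(seed)`.

## Known limitations

- The predictor is trained on cultivable prokaryotes; genomes under recent
  lifestyle shifts (ongoing reduction, pseudogene accumulation) retain
  ancestral codon bias and will be predicted faster than they grow.
- Published-mode F is defined only up to the composite anchoring table.
- Naive ORF extraction has no coding-potential model; very short or
  edge-truncated genes are missed by design.
- The packaged reference files are synthetic stand-ins (see above).
- Predictions are maximal-growth capacities, not realised rates.
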