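# Methods

## The model

All rate estimation rests on a Goldman–Yang-style Markov substitution process
on the 61 sense codons of the standard nuclear code, on the fixed unrooted
three-taxon tree relating an outgroup (labelled **At**) and two ingroup
lineages (**Ci**, **Cr**).  Instantaneous rates are

    q_ij = 0                          two or three positions differ
    q_ij ∝ π_j                        synonymous transversion
    q_ij ∝ κ π_j                      synonymous transition
    q_ij ∝ ω π_j                      non-synonymous transversion
    q_ij ∝ κ ω π_j                    non-synonymous transition

with equilibrium codon frequencies π estimated by F3x4 (position-specific
nucleotide frequencies multiplied out over sense codons) by default; F61 and
uniform are available.  The generator is rescaled so branch lengths are
expected substitutions per codon site; for site-class mixtures the rescaling
factor is the class-weighted mean rate per branch, so a branch length retains
that meaning averaged over classes.

The model zoo and its nested test pairs:

| test  | null | alternative | df |
|-------|------|-------------|----|
| B     | M0 (one ω) | free-ratio (one ω per branch) | 3 |
| B_Ci, B_Cr | M0 | two-ratio with the named foreground branch | 1 |
| S_21  | M1a (ω0<1, ω1=1) | M2a (adds ω2≥1) | 2 |
| S_87  | M7 (beta-distributed ω, 10 equal-probability categories at their medians) | M8 (adds a class with ω_s≥1) | 2 |
| BS_Ci, BS_Cr | branch-site model A with foreground ω2 fixed at 1 | same with ω2≥1 free | 1 |

Statistics are 2Δλ clamped at zero; P values come from the χ² upper tail at
the df above.  The one-ratio/free-ratio comparison defaults to the
parameter-count difference (2 on this tree) in `lrt`, with the stated df=3
used by the pipeline through `df_override`, which is how the table above is
produced.  Both site tests and the branch-site test are boundary-null tests
and therefore conservative at nominal levels; the calibration tests assert a
type-I rate ≤ 0.07 at α = 0.05 rather than equality.  Per-gene multiplicity
within each test family is controlled by Benjamini–Hochberg q-values
(Storey π0 smoothing optional), with outliers reported at q < 0.20.

Likelihoods are computed by pruning over the single internal node with
per-column likelihoods aggregated over unique column patterns.  Optimization
is bounded L-BFGS-B on the natural parameters (ω ∈ [1e-4, 99], κ ∈ [0.05, 50],
t ∈ [0, 20], proportions in (1e-9, 1−1e-9), ftol 1e-10), from a deterministic
start (Jukes–Cantor distance-based branch lengths plus model defaults) and,
by default, three seeded random restarts.  Alternative models are
warm-started from the fitted null through an exact parameter embedding
(`nested_start`), which makes the nesting inequalities hold structurally up
to the 1e-9 proportion bound.  Non-convergence is flagged in the results
object, never silent.

Per-branch dN and dS follow the mutational-opportunity convention: site
counts N and S are computed from the fitted matrix with ω set to 1
(S = 3L·ρ_S1, N = 3L − S, where ρ_S1 is the synonymous share of the total
rate), and dS = t·ρ_S/(3ρ_S1), dN = t·ρ_N/(3ρ_N1).  Under this convention
dN/dS equals the model's ω exactly; ω is reported as undefined (NaN) when
dS = 0.  The Nei–Gojobori counting estimator (equal-weight pathway
averaging, Jukes–Cantor correction, changes to stop codons treated as
non-synonymous for site counting) is carried as an independent cross-check,
not as the estimator of record.  The counting method ignores the
transition/transversion bias in its site counts, which depresses its ω
relative to the MLE when κ > 1; the likelihood/counting concordance check
is therefore run at κ = 1, where both estimators address the same
quantity.

## Orthology and alignment preparation

Triplets are reciprocal best hits across the six directed species pairs.
Best hits come from exact affine-gap local alignment (match +1, mismatch −2,
gap open −5, gap extend −2, with the open cost on the first gap position)
of candidate subjects shortlisted by shared 11-mer count; a query reports no
best hit when the runner-up subject scores ≥ (1 − 0.18) of the top score,
a conservative reading of a best-hit overhang margin that suppresses
paralogue-ambiguous assignments.  Hits are kept when identity over alignment
columns (gap columns counting as mismatches) is ≥ 0.70 and either sequence is
aligned over ≥ 0.60 of its length; ingroup contigs shorter than 250 bp are
excluded up front.  Candidates far below the top seed count (fewer than 3
shared 11-mers, or under 30% of the top count) are not aligned: at those seed
counts a subject cannot approach the top score, and pruning them keeps the
search near-linear in gene number.

Each triplet is aligned progressively at the protein level — the two ingroup
sequences first (they are mutually closest), the outgroup against the
resulting two-row profile (mean BLOSUM62 column score, affine gaps) — and
back-threaded to nucleotides, so gaps occur in codon multiples.  The
alignment is then cut to the region covered by all three rows, trimmed to At
codon boundaries, stripped of the annotated transit peptide (At codons
1..cleavage−1, consumed from an input table), and reduced by complete
deletion of any codon column containing a gap, ambiguity or stop.  The
complete-deletion policy is required by the 61-state likelihood alphabet.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
every planted parameter recorded in a ground-truth ledger:

- **Sequences.** Per gene, a three-taxon codon alignment simulated forward
  from the internal node (state drawn from π; under reversibility root
  placement is bookkeeping only), with branch lengths {At: 0.30, Ci: 0.07,
  Cr: 0.07} substitutions/codon — placing ingroup dS near 0.06 — κ = 2, and
  per-gene, per-branch ω.  Gene lengths are lognormal with mean 594 bp and
  mode near 380 bp, floored at 150 bp.
- **ω structure.** Per-gene ω is a unit-mean gamma (shape 2) multiplier on a
  genome-wide mean of 0.17, scaled by class effects: the planted fast class
  (CRG, ×1.5 on the Cr branch) and slower photosynthesis/cold classes
  (PGO ×0.6, CGO ×0.7 on Cr).  Class sizes are proportional to 55/56/67/332
  of 2922.
- **Expression.** A Gaussian copula couples the expression latent to the ω
  quantile with rank correlation −0.35, giving a planted Spearman of
  (6/π)·asin(−0.35/2) ≈ −0.34 between expression level and ω.  The
  expression matrix covers 14 organs (5 developmental stages for flower and
  leaf), and five stress series with paired controls; organ specificity is
  planted so that the noise-free τ equals the per-gene specificity latent,
  and stress persistence counts are planted directly.  Gaussian noise
  (sd 0.5 log2 units) is added on top; ground-truth breadth statistics are
  computed from the noise-free matrix.
- **Codon usage.** Per-gene codon frequencies interpolate between a skewed
  background and an optimal-codon-enriched distribution (one designated
  C/G-ending codon per degenerate family), with the mixing weight increasing
  in expression — planting the positive Fop–expression and GC3 structure.
  The ribosomal reference set for optimal-codon inference (77/2922 scaled)
  is drawn from the top 30% expression tier rather than the extreme tip,
  so the reference genes span a codon-bias gradient — the property the
  correspondence-analysis ranking requires, and one real ribosomal gene
  sets have.
- **Decoys.** A fraction (5%) of genes emit an extra ingroup-only paralogue
  duplicated at the internal node with 0.3 substitutions/codon of extra
  divergence, exercising the RBH exclusion logic.

What the generator does **not** emulate: indels inside coding regions
(alignments are simulated gap-free), sequencing error and assembly
artifacts, correlated evolution among genes, expression measurement
structure beyond iid log-normal noise, and any mechanistic link between
expression and ω (the copula reproduces the sign and scale of the
correlation, nothing more).  Passing tests therefore demonstrate that the
pipeline recovers planted statistical structure of this kind, not that real
transcriptome data meet these assumptions.

## Expression and codon-usage statistics

Breadth statistics follow the stated conventions exactly: values are
back-transformed (2^x) before thresholding; an organ counts toward spatial
breadth when any of its stage samples exceeds 75 (strict); temporal breadth
counts threshold exceedances along the flower or leaf series; stress
persistence counts timepoints with treated ≥ 3× control (inclusive); τ is
computed on linear per-organ aggregates (organ maximum across stages); mean
and maximum expression are reported on the log2 scale.

Optimal codons are inferred from the reference set: genes shorter than 100
codons are discarded, the remainder ranked by the first axis of a
correspondence analysis (chi-square-metric SVD) of their RSCU matrix, the
top and bottom 50% pooled, and each codon tested in a 2×2 table (codon vs
rest of family, high vs low pool; Pearson χ² with Yates correction, Fisher
exact when any expected cell < 5, α = 0.01).  Several codons per family may
be flagged; the per-codon statistics are retained for audit.  Fop divides
optimal-codon counts by counts in optimal-bearing degenerate families.

## Class-level statistics

Class-vs-rest contrasts use the two-sided Wilcoxon rank-sum test (exact
enumeration when min(n) ≤ 8 without ties, tie- and continuity-corrected
normal approximation otherwise) on the metric or on its OLS residuals
against gene length or mean expression ("residuals of the correlation" is
implemented as linear OLS; a rank-based variant is available).  Holm–
Bonferroni correction is applied within each family of 8 class×lineage
tests.  The bootstrap null redraws B = 10,000 random pseudo-classes of the
class's size without replacement (a with-replacement flag exists) and
reports the fraction of replicates with P ≤ observed.  Partial Spearman
correlations are partial Pearson correlations on ranks.  All resampling is
seeded and seeds are echoed in outputs.

## Problem sizes used by tests and the acceptance script

The test suite exercises the stated study conditions directly: 100 genes ×
500 codons for one-ratio recovery, 200 null simulations × 300 codons per
calibration test, 40 planted genes for branch-site power, and one full
pipeline run at the default 2,000 genes.  `scripts/acceptance.py` recomputes
the same quantities at sizes chosen to keep a single-CPU run short while
leaving Monte-Carlo error well inside the margins of interest: 100
simulations per calibration test, 30 genes for power, and the full
2,000-gene end-to-end study (the optimal-codon stage needs the full
reference set).  Pipeline-scale fits use the deterministic start without
random restarts; restarts change the optimum only in the rare multimodal
cases the diagnostics flag, and the warm-start chain preserves nesting
regardless.

## Known limitations

- The branch-site and site tests are conservative on 3-taxon trees with
  partial genes; absolute power values here do not transfer to other tree
  shapes.
- ω estimates on short branches are heavy-tailed; means across genes are
  dominated by ratio noise (medians are stable), and ω is undefined at
  dS = 0.  Class comparisons are rank-based for this reason.  A ~600 bp
  gene at ingroup dS ≈ 0.06 carries only a handful of non-synonymous
  events per branch, so per-gene ω estimates attenuate class contrasts:
  on estimated values the reliable end-to-end property is the sign of the
  class contrast, with significance guaranteed only on the planted values
  themselves.
- The internal aligner is a heuristic (seeded candidates, protein-level
  progressive alignment); for real data an external hit table can be
  ingested directly.
- Bayes empirical Bayes identification of selected sites is out of scope;
  the likelihood-ratio tests flag genes, not sites.
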