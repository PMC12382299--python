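# Methods

## The study system and its models

The package targets testcross hybrid panels: `n_f` fully homozygous father
lines (doubled haploids; marker dosages 0 or 2) each crossed to a small set
of common maternal testers.  Only the fathers segregate, so a hybrid's
marker genotype is taken to be its father's dosage and the testers enter
every model as a fixed "mother" effect.  This identification is the
package's central modelling assumption and is stated here prominently: with
two common testers, all segregating variation traces to the father, and
the father dosage carries it.

**Stage 1 (adjusted means).**  Plot values (arithmetic means over the
plants scored per plot) enter

    y_ijkl = mu + G_i + E_j + (GE)_ij + R_jk + C_jl + e_ijkl

with genotype G fixed and year E, genotype-by-year GE, row-within-year R
and column-within-year C random, residuals homoscedastic and independent.
The per-year variant drops E and GE and un-nests row/column.  The mother is
deliberately *not* a term here: mother differences flow into the genotype
means and are separated later by the GWAS fixed effect.  Adjusted means are
reported on the trait scale (intercept folded in).  Terms whose factor has
fewer than two levels in the data at hand are dropped automatically, so the
same code handles balanced single-year layouts (where it reproduces
classical ANOVA quantities exactly — a standing test).

**Heritability.**  Broad-sense, entry-mean basis, from the
pairwise-contrast form suited to unbalanced data:

    H^2 = sigma2_G / (sigma2_G + v_bar_Delta / 2),

where sigma2_G comes from the all-random dual of the stage-1 model and
v_bar_Delta is the mean of var(BLUE_i − BLUE_j) over all genotype pairs,
computed from the precision matrix of the genotype-fixed fit.  On a
balanced one-way layout this equals sigma2_G/(sigma2_G + sigma2_e/r)
exactly.  H² is clamped to [0, 1] with a warning if numerical noise
exceeds the bounds; a zero genotypic variance gives H² = 0.

**Stage 2 (GWAS).**  Null model per trait: y = Xβ + Zg + e with
g ~ N(0, G σ²_g), where G is the VanRaden GRM of the father lines
(dosages centered by 2p_i, denominator 2Σp_i(1−p_i); monomorphic markers
excluded from both sums; mean imputation beforehand).  X holds the
intercept, the mother factor and the first three principal components of
the centered dosage matrix.  Marker tests are Wald t-tests of the marker
fixed effect.

Two scan methods are implemented:

- `exact` (default): the variance ratio λ = σ²_g/σ²_e is re-profiled for
  *every marker* by REML over a fixed grid ({0} ∪ 70 log-spaced points in
  [10⁻³, 10³]) after a single eigendecomposition of ZGZ′ — the rotation
  trick of the FaST-LMM family makes each grid point an ordinary weighted
  regression, so the whole scan is O(grid × n × markers) per trait.
- `p3d`: the EMMAX-style two-step that holds λ at the null-model REML
  estimate and re-estimates only the residual scale per marker.

The default is `exact` because the p3d shortcut is measurably conservative
in panels of this size: each trait's λ̂ error (CV ≈ 20% at n ≈ 400) shifts
that trait's entire scan, and the net effect is a ~15–20% deficit in the
p ≤ 10⁻³ tail (empirically 0.00083 instead of 0.001 over 5×10⁵ null
tests), while the exact scan measures 0.00095–0.001.  With λ known both
flavours are exactly calibrated, so the deficit is purely the held-λ
approximation.  The p3d option remains available and is continuously
validated against a per-marker REML oracle (agreement within 0.2 in
−log10 p for weak signals; at a strong QTL the null-model λ̂ absorbs part
of the QTL variance and p3d deviates further at the QTL itself — the
standard, documented behaviour of held-parameter scans).  Both flavours
collapse to the textbook regression t-test when σ²_g is estimated at zero.
No multiple-testing correction is applied; the fixed threshold p ≤ 10⁻³
is kept for cross-study comparability.  Traits are scanned only if
H² ≥ 0.1.  The tested marker is *not* removed from the GRM (no
leave-one-chromosome-out).

**Stage 3 (haplotype blocks).**  Pairwise LD is the squared Pearson
correlation of imputed dosage columns (constant markers: r² ≡ 0 off the
diagonal).  Blocks are built greedily per chromosome: seed at the
unassigned adjacent pair with the highest r² (leftmost on ties; admitted
only if r² ≥ 0.4), then extend outward in both directions.  A candidate
joins when its r² with the nearest *conforming* edge marker reaches the
threshold; up to 12 consecutive non-conforming markers may be provisionally
skipped and are absorbed as members only when a later marker conforms again
(the skip counter resets after each absorption; skipped runs never serve as
LD anchors).  A side also closes when it reaches a marker already assigned
to an earlier block, so blocks never overlap and member lists are
contiguous in map order.  Tolerated markers count as members for span and
allele enumeration.  Block ids are genome-ordered zero-padded counters
(`b000001`, ...).  A block is significant for a trait when any member
marker is.  Haplotype alleles are the distinct complete dosage patterns
over a block's members in the *raw* (non-imputed) father calls; lines with
missing member calls go to an "incomplete" bin, patterns with fewer than 3
carriers to "rare"; per-allele trait summaries (mean, median, quartiles)
are computed over the adjusted means of the carriers' hybrids.

**Stage 4 (block variance).**  For each flagged (block, trait):
y = Xβ + Z_b g_b + Z_r g_r + e with G_b the VanRaden GRM from the block's
members only and G_r from all remaining post-QC markers, each with its own
denominator; X is the GWAS fixed part without any marker term.  The
headline ratio is reported exactly as

    sigma2_gb / (sigma2_gr + sigma2_e)

— note the denominator excludes sigma2_gb.  That convention is unusual
(the ratio can exceed 1 in principle) but it is the scale on which this
package's reference numbers are defined, so it is kept verbatim; the
conventional proportion sigma2_gb/(sigma2_gb+sigma2_gr+sigma2_e) is always
emitted alongside as `alt_ratio` and never silently substituted.
Rank-deficient G_b (few markers) is fine — a PSD covariance is all REML
needs — and is only logged.

**Stage 5 (QTL overlap).**  Literature QTL arrive as an already-positioned
TSV (study, trait, chromosome, bp); placement of probe sequences on a
reference genome is out of scope.  A QTL overlaps a block when
start ≤ pos ≤ end on the same chromosome, both boundaries inclusive.

## The REML engine

All mixed models run through one dense engine: average-information REML
with step-halving, an EM fallback step when the AI update fails to improve
the restricted likelihood, and zero-pinning of components whose update
leaves the parameter space (pinned components are released if their score
turns positive).  Accepted iterations never decrease the REML
log-likelihood.  Convergence requires relative log-likelihood change
< 10⁻⁸ *and* maximum relative parameter change < 10⁻⁶; when no admissible
step remains and the residual EM displacement is negligible the fit is
declared converged at a (boundary) optimum.  The response is standardised
internally so tolerances are unit-free; components, β and the precision
matrix are rescaled on exit.  Aliased fixed columns are dropped by pivoted
QR rank detection and reported.  Everything is dense: the target panels
(≤ a few hundred lines, ≤ a few thousand plots) make n×n algebra the
simple and fast choice.  The engine's optima are routinely checked against
21-point bracketing grids per component and against closed forms (balanced
ANOVA, OLS, GLS at known components).

## The synthetic-data generator

The generator emulates the study conditions the pipeline assumes, with
known truth for recovery tests.  Defaults: 162 father lines × 2 testers,
5 chromosomes × 120 markers in LD blocks of 10, within-block adjacent
r² ≈ 0.85, 10% non-locus-specific noise markers, uniform [0.1, 0.9] founder
allele frequencies (so the MAF filter is exercised but not degenerate),
two years, 15% replicated entries (≈ 49 of 324 per year), variance
components (polygenic, year, G×E, row, col, residual) = (1.0, 0.5, 0.3,
0.2, 0.2, 1.0) in squared trait units, mother effect 1.0.

Within an LD block, dosages follow a Markov copy process: each marker
copies the previous marker's founder allele with probability
√(within_block_corr), else redraws from the block's frequency — giving
expected adjacent-pair r² equal to `within_block_corr` and exactly
identical block columns at 1.0.  Noise markers are drawn independently of
position.  Polygenic father effects are drawn with covariance
σ²_polygenic · G/mean(diag G); the normalisation makes σ²_polygenic the
*average genetic variance per hybrid* (homozygous-line GRMs have mean
diagonal near 2, which would otherwise double the realised variance).
QTL effects are additive in the centered dosage of the middle marker of a
named LD block.  Three pseudo-random streams (genotypes, design,
phenotypes) are spawned from one seed, so changing one component leaves
the others bit-identical.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: genotype-calling errors and missing calls (QC
missing-rate behaviour is exercised with constructed fixtures instead),
pedigree/meiosis structure of nested families, spatial correlation beyond
additive row/column effects, non-Gaussian traits, and G×E beyond an
independent interaction draw.

## Numerical choices and problem sizes

- Mean imputation of missing calls feeds GRM/PCA/LD only; allele
  enumeration always sees raw calls.
- PCA sign convention: the largest-magnitude loading of each component is
  made positive, so scores are reproducible across runs and row orders.
- Degenerate (constant within the tested set) markers get p = 1 and a
  `degenerate` flag rather than an error.
- Exact-scan λ grid: {0} ∪ geomspace(10⁻³, 10³, 70); the grid resolution
  (≈ 21% steps) changes −log10 p by < 0.05 against a continuous optimiser
  (a standing test).
- Cholesky draws of GRM-structured effects add a 10⁻⁸ ridge; GRMs are
  accepted as PSD within a 10⁻⁶-relative tolerance.
- Tie-breaks are positional everywhere (leftmost seed pair; map order),
  never lexicographic in marker names.
- Test-suite and acceptance-script problem sizes (200 fathers × 1,000
  markers × 200 null traits for calibration; 100 replicates for power;
  50 replicates at n = 300 for block-variance recovery; 162 × 600 for the
  end-to-end study) were chosen as the smallest panels at which the
  Monte-Carlo standard errors are decisively smaller than the effects
  being checked.

## Known limitations

- The p3d scan option is conservative at small panel sizes (see above);
  use the default exact scan when calibrated p-values matter.
- The block-ratio denominator convention (excluding σ²_gb) inflates the
  percentage relative to the conventional proportion; both are reported,
  and consumers must not mix the two scales.
- The greedy block builder is order-dependent by construction (strongest
  seed first); it is deterministic, but it is not a likelihood-based block
  definition and can split regions a confidence-interval method would
  join.
- Heritability is broad-sense on an entry-mean basis; it is not comparable
  to narrow-sense estimates from pedigree models.
- With two testers the mother effect is estimable but tester-by-father
  interaction is not separable from the father main effect; the models
  assume it is negligible.
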