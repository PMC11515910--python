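# Methods

## The mapping model

A chromosome segment substitution line (CSSL, or introgression line)
population carries donor-species chromosome segments in an otherwise
uniform recipient background, so the genome of the population decomposes
into a set of non-overlapping segment markers, each of which a line carries
as donor-homozygous (AA), heterozygous (Aa) or not at all (aa).  The trait
model is the standard additive + dominance decomposition over all m markers
at once:

    y_i = mu + sum_j w_ij a_j + sum_j v_ij d_j + e_i,
    w = 1 / 0 / -1   and   v = 0 / 1 / 0   for AA / Aa / aa.

All 2m effects are estimated jointly by an L1-penalized least-squares fit
(the intercept is unpenalized):

    min over (mu, a, d) of
    (1/2n) sum_i (y_i - mu - [Wa + Vd]_i)^2 + lambda * sum_j (|a_j| + |d_j|).

Joint estimation matters in CSSLs: single-marker tests confound every
co-introgressed segment, whereas the penalized multi-locus fit conditions
each marker on all others and returns a sparse effect set.

Each selected marker is then scored with a likelihood-ratio test on its
*conditional residual* — the phenotype minus every fitted term except the
one under test (for the additive test at marker k the term w_k a_k is kept;
for the dominance test, v_k d_k).  The null is a single normal N(mu0,
sigma0^2); the alternative gives each observed genotype class its own mean
with a pooled maximum-likelihood variance; both use 1/n variance
estimators, from which

    LOD = (L_A - L_0) / ln 10 = (n/2) * log10(sigma0^2 / sigma^2).

This closed form is exercised against the explicit sum-of-log-densities
computation in the tests.  Default significance: LOD >= 2.5 for phenotypic
traits, LOD >= 4 for expression traits.

## Numerical choices

- **Solver.** scikit-learn coordinate descent (`Lasso`/`LassoCV`), whose
  objective is identical to the one above.  The design is stored sparsely
  via the donor-dosage shift `C = W + 1` (absorbed by the intercept and
  undone after the fit), which makes one full fit of a 307 x 2896 design a
  couple of seconds.
- **Penalty path.** 100 geometric path points down to `alpha_min_ratio =
  0.01` of the smallest fully-shrinking penalty — glmnet's default floor
  for n < p.  `lambda_="auto"` picks the 10-fold cross-validated penalty at
  minimum CV error (folds shuffled, seeded); the one-standard-error rule is
  available as `lambda_="cv_1se"`.  `lambda_ = 0` is solved exactly by
  least squares.
- **Standardization.** Predictors are scaled to unit variance before
  penalization and coefficients reported on the original scale (glmnet's
  default); toggleable.
- **Degenerate LRT inputs.** A single genotype class returns LOD 0 with a
  flag; an exactly separable alternative (pooled variance 0) and any LOD
  above the cap return the cap (default 300) with a flag.  The dominance
  test requires at least two heterozygous lines, otherwise LOD 0 with a
  "no_heterozygotes" flag.  Lines with a missing genotype at the tested
  marker are dropped from that test; for the global fit, missing design
  entries are mean-imputed per column and flagged.
- **Coefficient zeroing.** Solver outputs below 1e-10 in absolute value are
  treated as exact zeros so the non-zero locus set is well defined.

## Expression traits

Expression is made comparable across genes by the rank-based inverse
normal transform Phi^-1((r - c)/(n + 1 - 2c)) with the qqnorm/ppoints
offset c = 3/8 for n <= 10 and c = 1/2 otherwise.  Ties receive average
ranks; this is deliberately order-independent, whereas R's `qqnorm`
assigns tied values distinct scores in input order.  eQTLs are classified
local when the marker lies within 1 Mb of the gene on the same chromosome
(nearest interval edges, 0 if overlapping), distal otherwise.  Hotspots
are markers regulating at least 5x the mean number of eGenes per eQTL
(per-timepoint mean by default; the pooled mode matches a single
population-wide figure).  Sharing between timepoints requires same-signed
additive effects within 2-fold.  Colocalization requires the identical
marker to lie within 300 kb of a significant trait QTL and within 1 Mb of
the gene.  The perturbation network keeps an eQTL-eGene edge only in lines
that carry the marker's introgression and in which the gene is
differentially expressed; the differential-expression reference is the
recipient parent (the background genome), selectable.

## Expression-pattern analytics

Fold changes against each parent use a 0.1-FPKM pseudocount and an
inclusive 3-fold threshold.  Among lines carrying a gene's introgression,
the gene is "no_change" if no carrier differs from either parent, "stable"
if the majority match the donor, "altered" if the majority differ from the
donor; calls are then filtered on differential expression in the
*non-carrying* lines, judged against the recipient parent (those lines
carry the recipient allele, so divergence from the recipient is the
background-instability signal): stable tolerates at most 7 such lines,
altered demands at least 20, anything else is "ambiguous".  The 7 and 20
derive from 1/4 and 3/4 of the maximum introgression frequency of the
mapped population (~28 lines) and are exposed as flags.  Rank enrichment
sorts, per gene, all lines by that gene's expression and asks how often
the line at each rank carries the introgression; a quadratic fit and
bottom/top-5%-vs-middle-quartiles enrichment summarize extremeness.

## Segment calling and the marker partition

Parental-differentiating SNPs are tallied in consecutive non-overlapping
bins of 30.  The donor:recipient ratio is computed on *allele* counts (a
homozygous call contributes two alleles, a heterozygous call one to each
side): above 5 the bin is donor-homozygous, below 1/5 recipient-homozygous,
otherwise heterozygous.  A zero recipient tally with donor alleles present
is an infinite ratio (donor); a bin with no called alleles is het; a bin
with >50% missing inherits its predecessor's state (het at a chromosome
start).  Chromosome-terminal windows shorter than 30 SNPs are dropped.
Runs of equal-state non-recipient bins merge into segments with no gap
tolerance.  A bin straddling a true segment boundary carries mixed allele
counts and may be called het; breakpoints are therefore accurate to one
bin, which is what the tests assert.

The population-level partition splits the introgressed footprint at the
union of all segment endpoints.  Every junction between adjacent atoms is
some segment's endpoint, so re-merging identical-membership atoms could
only fuse abutting same-line segments — which would break the requirement
that every input segment be an exact union of markers — and is guarded
against.  The resulting atom set is provably minimal; an exhaustive-search
oracle confirms this on small random instances.

The ancient-introgression scan averages per-SNP donor-allele frequency
differences between a recipient-species panel and a donor-species panel in
windows of 500 SNPs and flags windows with mean difference > 0.2 and
windowed minor-haplotype frequency > 0.05 in the recipient panel (computed
as min(p, 1-p) of the windowed mean frequency).

## The synthetic population generator

The generator emulates the mapped population's published shape: 307 lines;
per-line segment counts 1 + Poisson(2.96) clipped to [1, 21] (expected
total ~1217 segments); segments placed on a candidate-breakpoint grid 2.4x
finer than the 1448-marker target, with block-constant Gamma(0.85) start
weights that create introgression hotspots (per-marker carrier maxima in
the high twenties, matching the population's maximum introgression
frequency); mean segment length 5 markers; a carried segment is
heterozygous with probability 0.10.  The marker map is then *derived* from
the drawn segments by the minimum-overlap principle — identical-membership
runs merge, uncovered cells emit no marker — so the realized map has the
structural properties of a partition: every marker is carried by at least
one line, no two adjacent markers have identical membership, and the
realized marker count fluctuates around 1448.

Traits follow the 8-QTL design: one purely additive QTL (d/a = 0), one
purely dominant (a = 0), and six additive-dominance QTLs with d/a in
{-3, -1, -0.5, 0.5, 1, 3}; each QTL's effect pair is rescaled so its
realized genetic variance on the drawn genotypes is exactly 1 (computed
from the empirical genotype frequencies, not Hardy-Weinberg formulas);
residuals are N(0, 2) around a mean of 100.  QTL markers are drawn
uniformly among markers with at least 2 donor-homozygous carriers, and
QTLs with a dominance component additionally require at least 2
heterozygous lines (without which their dominance variance is
unreachable); positions are redrawn each replicate so reported powers
average over the carrier-frequency distribution of the map rather than one
arbitrary placement.  Expression simulation plants additive/dominance
effects on log-expression with N(0, 1) noise and exponentiates (log-normal
FPKM); cis plans put each gene inside its marker.

**What the generator does not emulate.**  Real linkage disequilibrium
within and between segments beyond shared breakpoints; genotyping error in
the matrix; the exact carrier-frequency profile and correlation structure
of the real 1448-atom map; heterozygous tracts shorter than fixed segments
(in advanced-backcross material selfing erodes residual heterozygosity, so
real het tracts are shorter; simulated het tracts share the fixed-segment
length distribution, which duplicates their dominance indicator across the
markers they span and makes at-marker dominance placement harder than it
likely is in the real matrix).  Passing tests therefore demonstrate the
method's behaviour under a faithful *structural* emulation, not a
reproduction of the real matrix.

## Monte Carlo power study

One genotype draw is held fixed; each of 200 replicates simulates a fresh
trait, runs the full fit-plus-LRT scan, credits a QTL as detected only
when the relevant LOD at its own marker reaches 2.5, and counts non-QTL
markers with either LOD above threshold as false positives (reported per
mille of non-QTL marker x replicate pairs).  Average additive power is
taken over the seven QTLs with a non-zero additive effect, dominance power
over the seven with a non-zero dominance effect.  200 replicates at the
full 307 x ~1448 scale run in about 11 minutes on one CPU; the replicate
count and all sizes are parameters.

Measured at seed 1, the study gives average additive power ~93%, average
dominance power ~16%, and a false-positive rate ~9 per mille.  The
dominance deficit traces to the het-tract length issue above (duplicated
dominance columns make the at-marker credit unattainable for part of the
placements); the additive excess indicates the emulated map splits effects
across correlated neighbors less than the real matrix does.  Both numbers
are reported as measured; `scripts/acceptance.py` recomputes them from
scratch.

## Other problem sizes used in the tests

Parameter recovery in the noiseless limit (residual SD 0.01) uses an
intercross-like 150 x 400 identifiable design, because recovery *at a
specific marker* is undefined wherever two markers have identical design
columns — which a CSSL map legitimately contains (two separated regions
carried by the same line set; het tracts spanning several markers).
Planted-eQTL recovery uses 300 lines with a ~300-marker map and 40 genes
with 2-SD cis effects.  Partition minimality is checked exhaustively on
instances with up to 6 lines and 8 breakpoints.

## Known limitations

- Single-environment, single-trait model: no epistasis, no multi-trait or
  multi-environment joint fits, no effect confidence intervals.
- LOD inflation under under-fitting: if the penalty leaves other QTLs
  under-removed, the conditional residual retains their signal and the
  3-class alternative absorbs part of it, which inflates LODs at the
  tested locus.  This is inherent to the conditional-residual construction
  and is why the CV-minimum penalty is the default rather than the
  more-shrinking one-standard-error rule.
- Dominance testing needs heterozygotes; in nearly fixed material the
  dominance scan is mostly uninformative and is flagged as such.
- The significance thresholds (2.5 / 4) are fixed conventions, not
  permutation-calibrated genome-wide error rates.
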