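# Methods

This note documents the models, numerical choices, and simulation
conditions behind `coevoscan`, and what the synthetic-data tests do and
do not establish about real data.

## Codon substitution model

All selection analyses use the Goldman–Yang codon model over the 61
sense codons of the universal genetic code.  The instantaneous rate
from codon *i* to codon *j* is

- 0 if *i* and *j* differ at more than one nucleotide position,
- proportional to the target codon frequency π*j* otherwise,
- multiplied by κ when the change is a transition,
- multiplied by ω when the change is nonsynonymous.

Codon frequencies use the F3x4 scheme: the product of the three
position-specific nucleotide compositions, renormalized over sense
codons.  If a nucleotide is absent at a codon position, a pseudocount
of 0.5 is added to all four counts at that position so every sense
codon keeps positive mass; the correction is triggered only when a zero
occurs, so hand-computable compositions are reproduced exactly in the
common case.

The generator is scaled so that one unit of branch length is one
expected substitution per codon at stationarity.  For site-mixture
models the scale is the **mixture-average rate**: all ω classes share
one set of branch lengths, a unit of which is one expected substitution
per codon averaged over classes, so a high-ω class substitutes faster
than a low-ω class in absolute terms.  This matches the convention of
the standard ML implementations of these models; scaling each class to
unit rate separately would discard the rate signal that distinguishes
positively selected sites and visibly cripples both the
likelihood-ratio test and the site posteriors.

Likelihoods are computed by Felsenstein pruning with per-node scaling,
batched across mixture classes; identical codon columns are collapsed
to unique site patterns with multiplicities.  Transition probabilities
come from the eigendecomposition of the π-symmetrized generator, which
is cheap enough to refresh at every optimizer step.

Gap and ambiguous codons are treated as missing data (partial
likelihood vectors of one).  In-frame stop codons are a load error
unless explicitly masked.  The sliding-window scan separately enforces
a strict gap-free rule (below), so missing-data handling only affects
whole-gene fits.

## Model fits

All fits are box-constrained quasi-Newton (L-BFGS-B) on log-transformed
parameters (logit for p0), with jittered restarts and a relative
log-likelihood tolerance of 1e-8.  Bounds: κ ∈ [0.01, 100],
ω ∈ [1e-4, 99], beta shapes ∈ [0.005, 99], ω_s ∈ (1, 99], branch
lengths ∈ [1e-7, 50].  ω at the upper bound is reported as a capped
sentinel (it arises when a window or branch shows no synonymous
change); alignments with no variation at all return an
omega-undefined sentinel rather than a fit.

- **M0** — one ω shared by all sites and branches; branch lengths
  co-estimated by default, or held at the input tree's values
  (`optimize_branch_lengths=False`), which the window scan and the
  replicate-heavy calibrations use for speed.
- **M7** — site ω ~ Beta(p, q) discretized into K = 10
  equal-probability categories; the category value is the conditional
  mean of its quantile slice (not the median).
- **M8** — proportion p0 of sites follow the discretized beta and the
  remainder sit at a single ω_s ≥ 1.  The ≥ 1 constraint makes the
  comparison one-sided toward positive selection.  M8 is started from
  the fitted M7 (`site_test` chains M7 → M8), which both stabilizes and
  roughly halves the optimization.
- **Free-ratio** — an independent ω per branch with shared κ and π;
  branches are identified by the label of the node below them, so an
  unrooted 5-taxon binary tree has 7 branches.  Each branch's generator
  is scaled to unit rate on its own, so its length remains expected
  substitutions per codon on that branch.

The M7-vs-M8 likelihood-ratio statistic 2Δℓ is referred to χ² with two
degrees of freedom.  Because the null (M7) pins p0 to the boundary of
M8's parameter space, this reference is conservative: the realized
type-I error at α = 0.05 sits well below 0.05 (and in our calibration
runs often below 0.01).  The acceptance suite therefore asserts that
the test is *not anti-conservative* (rate ≤ 0.07) rather than a
two-sided band.  The free-ratio comparison against the one-ratio
constraint uses df = (number of branches − 1); this operationalization
of "branch support" is labeled as such in the output.

## Bayes Empirical Bayes site posteriors

Per-codon P(ω > 1) integrates over mixture-parameter uncertainty with a
uniform grid prior: 10 midpoints per dimension spanning p0 ∈ [0, 1],
p, q ∈ (0, 2], ω_s ∈ [1, 11].  For each (p, q) grid value the beta part
is rediscretized into its own K equal-probability category means; site
likelihoods are evaluated at those category means and at the ω_s grid
values, with κ, branch lengths, and the mixture rate scale held at the
M8 optimum.  Each grid cell is weighted by its whole-alignment
likelihood, and P(ω > 1 | site) is the cell-weighted average of the
selected-class responsibility.  An earlier design that evaluated the
beta part on a fixed equal-width ω grid measurably blunted site
recovery and was replaced by the per-grid-point discretization above.
The table also reports the posterior mean ω per site, so a "flagged
sites had ω above some value" reading can be applied either to the
posterior mean or to the flag threshold.

## Sliding-window scan and empirical null

Windows are 102 nt (34 codons) advancing in 3 nt steps, 0-based
half-open in alignment nucleotide coordinates, starting at phase 0
(multiples of the step).  A window is excluded if **any** taxon has a
gap or ambiguous codon in **any** of its columns (the strictest
reading); exclusions are counted.  Each retained window receives an M0
fit of its own ω and κ with π from the window's composition.  By
default the whole-gene M0 branch lengths are reused in every window
("fixed-branch-lengths" mode, recorded in the report); "refit-all"
re-estimates branch lengths per window.

The empirical null pools the gap-free windows of a collection of
background genes, samples n windows uniformly without replacement
(seeded), fits each, and reports the median and the central 95%
interval as order statistics of the sample.

## Divergence summaries

Ortholog pair identity is the HSP-length-weighted average percent
identity over HSPs passing an E-value cutoff of 1e-5.  Weighting uses
the HSP alignment length as reported by standard tabular search output,
gap columns included; this will necessarily lead to some
underestimation of the true divergence between protein pairs, but it is
unlikely that the rank order of divergences among pairs would be
significantly affected.  Pairs whose HSPs are all filtered are counted
as no-hit and excluded from the 5-point histogram, whose bins are
half-open [lo, lo + 5).

## ChIP-Seq window enrichment

The pipeline starts downstream of read mapping: it ingests per-base
coverage (or mapped fragment intervals) over a hybrid genome built by
concatenating two species' contigs under species prefixes.  Per-base
counts are summarized as medians in 100 bp windows sliding in 50 bp
steps; the window grid starts at multiples of 50 and trailing partial
windows are dropped.  Bases with zero input coverage are masked in
per-base ratios (no pseudocounts); window-level ratios use medians,
which are robust to isolated zeros.  Enrichment for a region is the
mean of (IP median / input median) over all windows overlapping the
region by ≥ 1 bp, normalized by the same quantity at a control region,
with the standard error over covering windows.  Windows that straddle
a region boundary mix enriched and background bases, which biases
recovered folds a few percent toward 1; the recovery tolerance in the
tests (15%) accommodates this known edge effect.  An alternative
per-base-ratio averaging mode is intentionally not the default: the
windowed-median reading matches the procedure the pipeline is built
around.

## Synthetic data: what it emulates, and what it does not

**Codon simulator.** The root codon of each site is drawn from π and
evolved down the tree by the transition probabilities of the same
scaled generators the fitters use.  Site ω is drawn once per site from
the model's (discretized) mixture and does not switch along the tree —
matching the assumption of the site models being tested.  A per-branch
ω map is supported for the branch-model arm.  The default 5-taxon tree
has the sensu stricto shape with a total length of ≈ 4.3 expected
substitutions per codon, representative of a rapidly evolving gene in
a clade whose outer species pairs show substantial synonymous-site
divergence; this is also the information regime in which the M7/M8
test has useful power at the simulated effect sizes.

**ChIP simulator.** Input coverage at every base is independent noise
with mean μ = 30 (matching a deeply sequenced input of ~25–40×); IP
coverage has mean μ·s·f(b) with s = 0.35 (IP depth roughly a third of
input) and f(b) the planted fold inside enriched regions, 1 elsewhere.
Noise is negative binomial with dispersion 0.1 by default — real ChIP
coverage is overdispersed — with a Poisson mode for mean-matching
oracle checks.

Deliberate non-features: the codon simulator has no indels, no
alignment error, no codon-usage covariation along the gene, and no
among-site rate variation beyond the ω mixture; the ChIP simulator has
no mappability or GC structure, no fragment-level autocorrelation, and
no read-level artifacts.  Consequently, passing recovery tests shows
the estimators are correct and well calibrated under the stated
generative models — it does not certify robustness to alignment error
or to coverage biases in real libraries.  Correlation between
simulated replicate IP tracks is driven by the shared enrichment
structure; simulated *input* replicates are structureless and
uncorrelated by design, unlike real inputs whose correlation reflects
shared coverage biases.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations to
desk scale: 1,000-codon genes for recovery (20 replicates per ω for
M0), 500-codon replicates for null calibration (120 in the test suite,
40 in the script), 50 power replicates, 3 BEB replicates of 1,000
codons, a 300-codon gene and a 12-gene background set for the window
scan, and 15 kb toy contigs for the ChIP arm.  These counts are the
package's own choices for routine verification; all are parameters,
and larger runs only tighten the Monte-Carlo error around the same
expectations.
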