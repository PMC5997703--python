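# Methods

`mtcontinuity` implements the population-genetic toolkit used to ask
whether serially sampled ancient mitochondrial genomes from one region
are consistent with a single maternal gene pool evolving by drift alone.
This note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic data can and cannot show.

## Data model

Haplotypes are aligned full mitogenomes (or HVRI fragments) in rCRS
coordinates, 1-based closed intervals, alphabet `{A,C,G,T,N,-}`.  The
alignment is assumed collinear with the rCRS; no indel re-mapping is
attempted, because mitochondrial consensus sequences are conventionally
reported against the reference.  Any IUPAC ambiguity code is read as N,
since downstream statistics treat only the four called bases as
informative.  Missing data is handled by complete deletion (drop every
column with an N or gap anywhere) for haplotype-based statistics, which
matches classical sequence-statistics software; pairwise deletion is
available for distance matrices.

The HVRI window defaults to rCRS 16059–16365 (307 columns), the overlap
window in which published control-region fragments can be compared.

## Differentiation: ΦST, linearization, permutation test

Differentiation between groups is ΦST, the AMOVA estimator with the
pairwise-difference distance: nucleotide mismatch counts enter the AMOVA
sums of squared deviations directly (they are not squared again), which
is the behavior of standard AMOVA software in "pairwise difference" mode
for sequence data.  The estimator can be slightly negative for weakly
structured data; raw values are reported, but are clamped to 0 before
Slatkin's linearization FST/(1−FST) (which diverges at 1 and requires
non-negativity) and before use as an NMDS dissimilarity.  Degenerate
data with no molecular variance gets ΦST = 0 by convention.

Significance uses permutation of individuals between the two populations
(10,000 permutations by default) with the (b+1)/(B+1) p-value estimator,
which never returns an exact zero.  Whether to permute individuals or
haplotype classes is a genuine free choice; individuals are permuted
here, matching the exchangeability assumption actually tested.

## Diversity, sharing, haplogroup intervals

Haplotype diversity is Hd = n/(n−1)(1 − Σp²) over identical-sequence
classes after complete deletion — exactly the probability that two
haplotypes drawn without replacement differ.  Its standard error uses
Nei's variance formula.

Haplotype sharing between groups A and B counts cross-group pairs of
identical haplotypes, normalized by Nmax = Ntot(Ntot−1)/2 with
Ntot = |A|+|B|.  Pair counting keeps numerator and denominator
commensurable; a "distinct shared haplotypes" numerator is available via
`mode="distinct"`.

Haplogroup frequency intervals are Bayesian: posterior Beta(k+1, n−k+1)
under a uniform prior, reported as the 95% highest-posterior-density
interval (not equal-tailed), so k = 0 and k = n yield intervals abutting
0 and 1.  The HPD is found by bounded minimization of the interval width
over the lower endpoint.

## Ordination

PCA of population × haplogroup frequency matrices is a plain SVD of the
column-centered (and by default unit-scaled) matrix; constant columns
are dropped with a warning under scaling.  NMDS of linearized-FST
matrices is SMACOF majorization with Kruskal's monotone (isotonic)
regression on the dissimilarity ranks, best of 8 random restarts,
deterministic under seed; Kruskal stress-1 is non-increasing across
iterations by construction of the majorizing step.

## Serial coalescent

Genealogies are simulated backwards in time in generations for a single
panmictic haploid population — the natural Ne semantics for maternally
inherited mtDNA (all effective sizes here are haploid female sizes).
Ancient samples activate at their ages rounded to the nearest generation
(25 y per generation).  With k active lineages the coalescence rate is
k(k−1)/2 · 1/N(t); waiting times are drawn by closed-form inversion of
the cumulative hazard, so no discretization error enters.

The size trajectory is N(t) = N_recent·e^(−rt) between the present and
an anchor time, with r = ln(N_recent/N_ancient)/anchor_gen — a
per-generation rate is dimensionally required for the hazard — and
constant N_ancient earlier, which keeps the deep-past hazard finite.
The anchor defaults to the older sample's age, i.e. the growth phase
spans the interval actually separating the two samples.

Mutations are finite-sites Jukes–Cantor: per-branch counts are
Poisson(μ·L·branch length) with μ = 3.4×10⁻⁷ per site per generation
for the whole molecule and L = 16,569 bp; positions are uniform, each
hit replaces the current base by one of the other three, and the root
sequence is uniform random.  Back mutations are therefore possible, as
in the DNA-sequence output of standard coalescent simulators.  The
engine is validated against analytic expectations (E[T₂] = N,
E[π] = 2NμL, Watterson's E[S]), against a discrete-generation
Bernoulli simulator (KS tests), and against msprime as an independent
oracle — msprime is a test-time cross-check only, never a runtime
dependency.

## The continuity test

For two samples of sizes (n₁, n₂) at two times, the null hypothesis is
that both derive from one resident population that changed only by
drift.  Because the true effective sizes are unknown, the test scans an
11 × 11 grid of (ancient Ne, recent Ne) pairs — by default log-spaced
over 500–50,000, a range bracketing skyline estimates of regional human
female Ne — and in each cell runs 1000 serial-coalescent replicates
(121,000 simulations per comparison), recording the proportion of
replicates with simulated ΦST ≥ observed.  Ties count as exceedances,
conservative toward non-rejection; monomorphic replicates have ΦST = 0
and are flagged.  Continuity is rejected at level α only when the
proportion is below α in every cell.  No multiple-testing correction is
applied by default across comparisons; an optional Bonferroni report is
provided.

Each grid cell draws an independent reproducible random stream spawned
from the run seed, so results are independent of evaluation order.  An
optional early stop accelerates verdict-only runs exactly: once a cell
accumulates ⌈α·n_reps⌉ exceedances its proportion can no longer fall
below α and non-rejection is decided.

Calibration and power, measured by the test suite in a scaled mode
(1,000-bp locus, 7 × 7 grid, 200 replicates): with observed data
generated under a grid-interior continuous demography the test rejects
in ≤ α-plus-Monte-Carlo-margin of trials; with two independent
(long-isolated) maternal pools it rejects essentially always.  The
scaled problem sizes were chosen so the whole suite exercises the full
statistical structure at laptop-scale cost; the acceptance script runs
the full-size grid (11 × 11 × 1000 at L = 16,569).

## Ancient-DNA QC estimators

The contamination point estimate follows the private-consensus-allele
approach: retain sites where the sample consensus is rare (< 5%) in a
modern panel and depth ≥ 10 (base quality filtering is assumed upstream),
zero alternative bases that form a transition pair with the consensus
(post-mortem deamination mimics contamination at C↔T / G↔A), then
estimate Σ(alternative)/Σ(consensus+alternative) pooled across sites
with a Wilson score 95% CI (stable at small counts).  Zeroing is per
alternative base, not per site, to keep the remaining signal.  One known
bias is documented: a panel-rare site whose only alternatives are
transitions still contributes consensus reads to the denominator and so
dilutes the pooled estimate slightly; the synthetic QC fixtures avoid
such sites so that parameter recovery is exact.  The panel (e.g. "311
modern mtDNAs") is an input table of per-site consensus frequencies, not
bundled data.

Sex assignment uses Ry = n_Y/(n_X+n_Y) with a normal-approximation CI
and the standard shotgun thresholds: female when the CI is wholly below
0.016, male when wholly above 0.075, otherwise indeterminate.  The
thresholds are configurable; male fixtures are generated at Ry ≈ 0.1,
the band produced by one Y and one X chromosome given their mappable
lengths.

## Synthetic data: what it shows and what it does not

The generator reproduces the study design — 41 ancient individuals
(temporal groups of 11/16/11 with means near 7,000/4,800/3,000 BP plus
3 undated, spatial groups of 23/7/9 plus 2 unassigned, ages spanning
13,790–1,380 BP) and a present-day sample — from a single simulated
population growing from 2,000 to 8,000 haploid females over the last 560
generations.  That demography gives haplotype diversity in the observed
0.95–1.0 band.  Haplogroup labels are synthetic clade names cut from the
true genealogy at half the TMRCA; isotope values are inert draws from
the aquatic-diet band (δ13C −22..−16‰, δ15N +10..+17‰); missing data is
independent per-cell N at rate 0.002 in ancient rows.

Because the generator *is* the package's own coalescent, passing
round-trip tests shows internal consistency and correct statistical
calibration, not field realism: real data add alignment error,
reference bias, damage-driven miscalls, correlated missingness around
primer/fragment boundaries, and non-panmictic structure.  The external
validity of the simulator itself rests on the analytic and msprime
cross-checks.

## Degenerate inputs and tie-breaks

Monomorphic data: ΦST = 0 (flagged in simulations, returned as 0 for
observed data).  All-missing columns: explicit "no comparable sites"
error.  Negative ΦST: reported raw, clamped only where a transform
requires it.  FST ≥ 1: capped at 1−10⁻⁶ with a warning before
linearization.  Permutation p-values: never exactly 0.  NMDS with a
duplicate population: coincident points, as the zero dissimilarity
demands.

## Known limitations

Single non-recombining locus only; no migration, admixture or
population structure in the simulator (so the continuity test cannot
distinguish gene flow from structure — rejection only says drift alone
is insufficient); no radiocarbon calibration (ages are taken as given);
haplogroup nomenclature assignment, consensus calling from reads, and
skyline Ne estimation are upstream tools' jobs and out of scope.
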